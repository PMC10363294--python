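"""Synthetic cohorts with quantile-driven outcomes.

Generates data with the statistical structure the selection method assumes:

- **Cell intensities.**  Each subject's cell signal intensities are drawn
  from a two-component log-normal mixture — a dim "background" population
  and a bright "expressing" sub-population — with subject-level variation in
  the mixture weight (Beta-distributed), in both component locations, and in
  both component spreads.  This reproduces the phenomenon that motivates
  quantile markers: two tumors can share nearly the same mean intensity yet
  have very different distribution spreads and upper tails.  The default
  parameterization deliberately separates roles: a bounded (uniform)
  subject-level shift of the dim component carries the outcome signal, large
  bounded variation of the component spreads provides the cross-subject
  shape diversity that makes the driving quantile identifiable among its
  grid neighbours, and the expressing fraction is concentrated so that the
  driving probability sits at the dim component's centre.  ``make_matched_pair`` constructs
  such pairs exactly (equal theoretical mean, different high quantiles) by
  trading the expressing fraction against the expressing brightness.

- **Outcome.**  A designated "true" probability ``p_star`` defines the
  subject-level signal: the analytic ``p_star``-quantile of the subject's
  own mixture, standardized across the cohort.  Survival times follow a
  proportional-hazards model with exponential baseline and linear predictor
  ``beta * z``; independent exponential censoring (rate calibrated
  analytically to hit a target censoring fraction) is combined with an
  administrative cutoff.  Binary and continuous outcomes use the same
  linear predictor through a logistic or Gaussian link.

The ground-truth record (true quantiles, ``p_star``, ``beta``) is returned
separately and is never consumed by the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantiles import CellSample

__all__ = [
    "SimConfig",
    "mixture_quantile",
    "make_matched_pair",
    "simulate_cell_sample",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults give a screening-size survival cohort.

    Intensities are in arbitrary fluorescence units; times in months.
    ``censoring_fraction`` is the target fraction of subjects censored
    (events ~ 30% by default, typical of a long-follow-up cohort).
    """

    n_subjects: int = 200
    cells_per_subject: tuple[int, int] = (100, 500)
    p_star: float = 0.30
    beta: float = 1.0
    outcome_kind: str = "survival"
    # two-component log-normal mixture (log-scale parameters); the dim
    # component centre carries the prognostic signal (mu_low_sd, uniform so
    # the risk distribution is bounded and optimal cutpoints stay interior),
    # while wide bounded spread variation (sigma_*_range, uniform) produces
    # the matched-centre / different-tail diversity that localizes
    # information at the driving quantile
    mu_low: float = 5.0
    sigma_low_range: tuple[float, float] = (0.15, 1.25)
    mu_high: float = 7.0
    sigma_high_range: tuple[float, float] = (0.5, 1.1)
    weight_alpha: float = 160.0
    weight_beta: float = 240.0
    mu_low_sd: float = 0.18
    mu_high_sd: float = 0.30
    # survival model
    baseline_hazard: float = 0.005
    censoring_fraction: float = 0.70
    admin_cutoff: float = 240.0
    n_matched_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_star < 1.0):
            raise ValueError("p_star must be in (0, 1)")
        for rng_ in (self.sigma_low_range, self.sigma_high_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("sigma ranges must be positive (low, high) pairs")
        if min(self.mu_low_sd, self.mu_high_sd) < 0:
            raise ValueError("subject-level SDs must be non-negative")
        lo, hi = self.cells_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_subject must be a valid (low, high) range")
        if not (0.0 <= self.censoring_fraction < 1.0):
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


def _mixture_cdf(x, w, mu1, s1, mu2, s2):
    return (1.0 - w) * stats.norm.cdf((np.log(x) - mu1) / s1) + w * stats.norm.cdf(
        (np.log(x) - mu2) / s2
    )


def mixture_quantile(p: float, w: float, mu1: float, s1: float,
                     mu2: float, s2: float) -> float:
    """Analytic quantile of a two-component log-normal mixture (numeric
    inversion of the mixture CDF)."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    lo = float(np.exp(min(mu1, mu2) - 10 * max(s1, s2)))
    hi = float(np.exp(max(mu1, mu2) + 10 * max(s1, s2)))
    return float(optimize.brentq(
        lambda x: _mixture_cdf(x, w, mu1, s1, mu2, s2) - p, lo, hi, xtol=1e-10,
    ))


def make_matched_pair(w: float, mu1: float, mu2: float, s1: float, s2: float,
                      weight_ratio: float = 2.0):
    """Partner parameters with identical theoretical mean, different tails.

    The partner multiplies the expressing fraction by ``weight_ratio`` and
    dims both components so each component's mean contribution is unchanged:
    ``mu2' = mu2 - ln(ratio)`` and ``mu1' = mu1 - ln((1-w')/(1-w))``.
    The total mean is then exactly equal while upper quantiles differ
    (many-dim vs few-bright expressing cells).
    """
    w2 = w * weight_ratio
    if not (0.0 < w2 < 1.0):
        raise ValueError("weight_ratio pushes the mixture weight outside (0,1)")
    mu2_b = mu2 - np.log(weight_ratio)
    mu1_b = mu1 - np.log((1.0 - w2) / (1.0 - w))
    return w2, mu1_b, mu2_b


def simulate_cell_sample(subject_id: str, w: float, mu1: float, s1: float,
                         mu2: float, s2: float, n_cells: int,
                         seed) -> CellSample:
    """Draw one subject's cells from its mixture; deterministic given seed."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("mixture weight must be in [0, 1]")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("component SDs must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    bright = rng.random(n_cells) < w
    logx = np.where(
        bright,
        rng.normal(mu2, s2, n_cells),
        rng.normal(mu1, s1, n_cells),
    )
    return CellSample(subject_id, np.exp(logx))


def _solve_censoring_rate(lam: np.ndarray, target_event: float, tau: float) -> float:
    """Exponential censoring rate whose expected event fraction (with the
    administrative cutoff tau) equals ``target_event``."""

    def event_frac(c):
        tot = lam + c
        return float(np.mean(lam / tot * (1.0 - np.exp(-tot * tau))))

    max_event = event_frac(0.0)
    if target_event > max_event + 1e-12:
        raise ValueError(
            f"infeasible censoring target: even with no random censoring "
            f"only {max_event:.3f} of subjects would have events before the "
            f"administrative cutoff, but {target_event:.3f} were requested"
        )
    if abs(target_event - max_event) < 1e-12:
        return 0.0
    hi = 1.0
    while event_frac(hi) > target_event:
        hi *= 10.0
        if hi > 1e8:
            break
    return float(optimize.brentq(lambda c: event_frac(c) - target_event, 0.0, hi))


def simulate_cohort(cfg: SimConfig):
    """Simulate a full cohort.

    Returns ``(cell_table, clinical_table, truth)``: a long-format cell
    DataFrame (``subject_id, cell_id, intensity``), a clinical DataFrame
    (``subject_id`` plus ``time``/``event`` for survival, ``event`` for
    binary, ``value`` for continuous), and a ground-truth dict with the
    per-subject true quantiles — for recovery tests only, never an input to
    the analysis.
    """
    n = cfg.n_subjects
    param_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
    )
    w = param_rng.beta(cfg.weight_alpha, cfg.weight_beta, n)
    # two latent expression subtypes: the dim-component centre sits at
    # mu_low +/- mu_low_sd (equal mixing, uniform jitter), so the cohort's
    # risk distribution is bimodal and bounded — the dichotomization the
    # method searches for genuinely exists in the population
    subtype = np.where(param_rng.random(n) < 0.5, -1.0, 1.0)
    jitter = param_rng.uniform(-0.4 * cfg.mu_low_sd, 0.4 * cfg.mu_low_sd, n)
    mu1 = cfg.mu_low + subtype * cfg.mu_low_sd + jitter
    mu2 = cfg.mu_high + param_rng.normal(0.0, cfg.mu_high_sd, n)
    s1 = param_rng.uniform(*cfg.sigma_low_range, n)
    s2 = param_rng.uniform(*cfg.sigma_high_range, n)
    lo, hi = cfg.cells_per_subject
    n_cells = param_rng.integers(lo, hi + 1, n)

    if cfg.n_matched_pairs:
        if 2 * cfg.n_matched_pairs > n:
            raise ValueError("more matched pairs than subjects")
        for k in range(cfg.n_matched_pairs):
            a, b = 2 * k, 2 * k + 1
            w[b], mu1[b], mu2[b] = make_matched_pair(
                w[a], mu1[a], mu2[a], s1[a], s2[a]
            )
            s1[b], s2[b] = s1[a], s2[a]

    ids = [f"S{i + 1:04d}" for i in range(n)]
    samples = [
        simulate_cell_sample(
            ids[i], w[i], mu1[i], s1[i], mu2[i], s2[i], int(n_cells[i]),
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, i)),
        )
        for i in range(n)
    ]
    cell_table = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, n_cells),
            "cell_id": np.concatenate([np.arange(1, m + 1) for m in n_cells]),
            "intensity": np.concatenate([s.intensities for s in samples]),
        }
    )

    true_q = np.array(
        [
            mixture_quantile(cfg.p_star, w[i], mu1[i], s1[i], mu2[i], s2[i])
            for i in range(n)
        ]
    )
    # standardize on the log scale: intensities are log-normal, so the
    # log-quantile is the natural (near-Gaussian) scale for a log-linear
    # hazard; raw-scale standardization would let a few extreme subjects
    # dominate the risk distribution
    log_q = np.log(true_q)
    z = (log_q - log_q.mean()) / log_q.std(ddof=0)

    out_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
    )
    truth = {
        "p_star": cfg.p_star,
        "beta": cfg.beta,
        "subject_id": ids,
        "true_quantile": true_q.tolist(),
        "z": z.tolist(),
        "outcome_kind": cfg.outcome_kind,
        "seed": cfg.seed,
    }
    if cfg.outcome_kind == "survival":
        lam = cfg.baseline_hazard * np.exp(cfg.beta * z)
        t_event = out_rng.exponential(1.0 / lam)
        target_event = 1.0 - cfg.censoring_fraction
        rate = _solve_censoring_rate(lam, target_event, cfg.admin_cutoff)
        c_rand = (
            out_rng.exponential(1.0 / rate, n) if rate > 0
            else np.full(n, np.inf)
        )
        c_time = np.minimum(c_rand, cfg.admin_cutoff)
        time = np.minimum(t_event, c_time)
        event = (t_event <= c_time).astype(int)
        clinical = pd.DataFrame(
            {"subject_id": ids, "time": time, "event": event}
        )
        truth["censoring_rate"] = rate
        truth["realized_event_fraction"] = float(event.mean())
    elif cfg.outcome_kind == "binary":
        target = 1.0 - cfg.censoring_fraction

        def prevalence(alpha):
            return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + cfg.beta * z)))))

        alpha = float(optimize.brentq(
            lambda a: prevalence(a) - target, -30.0, 30.0
        ))
        pr = 1.0 / (1.0 + np.exp(-(alpha + cfg.beta * z)))
        event = (out_rng.random(n) < pr).astype(int)
        clinical = pd.DataFrame({"subject_id": ids, "event": event})
        truth["intercept"] = alpha
        truth["realized_event_fraction"] = float(event.mean())
    elif cfg.outcome_kind == "continuous":
        value = cfg.beta * z + out_rng.normal(0.0, 1.0, n)
        clinical = pd.DataFrame({"subject_id": ids, "value": value})
    else:
        raise ValueError(f"unknown outcome kind {cfg.outcome_kind!r}")

    return cell_table, clinical, truth
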