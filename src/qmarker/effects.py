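"""Effect-size estimation for dichotomized markers.

Everything downstream of the cutpoint search measures the prognostic value
of a High/Low marker on the log scale: log hazard ratio for survival
outcomes (Cox proportional hazards, Efron tie handling), log odds ratio for
binary outcomes, and the group mean difference (an OLS slope on the 0/1
indicator) for continuous outcomes.  95% intervals are Wald on the log
scale; exponentiation happens only in reports.

The univariable Cox fit with a single binary covariate is solved here by a
one-dimensional Newton iteration on the Efron partial likelihood.  The
selection and bootstrap layers call it hundreds of thousands of times, so it
is written as a handful of vectorized array operations; the test suite
checks it against lifelines' ``CoxPHFitter`` on random data.  Multivariable
and stratified fits, which run only a handful of times per analysis, go
through lifelines directly.

Rubin's rule for pooling estimates across multiply-imputed datasets is also
provided: the pooled estimate is the mean, and the total variance combines
the mean within-imputation variance W with the between-imputation variance
B as ``T = W + (1 + 1/m) B``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import OutcomeSpec, as_outcome

__all__ = [
    "EffectEstimate",
    "cox_loghr",
    "logistic_logor",
    "linear_slope",
    "estimate_effect",
    "multivariable_cox",
    "rubin_pool",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class EffectEstimate:
    """A log-scale effect size with Wald inference.

    ``scale`` is one of ``loghr``, ``logor``, ``slope``.  Invalid estimates
    (monotone likelihood, empty groups, zero cells) carry ``valid=False``
    and a ``reason`` code; their numeric fields are NaN.
    """

    log_effect: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    scale: str
    n_events: int | None = None
    valid: bool = True
    reason: str | None = None

    @property
    def effect(self) -> float:
        """Exponentiated estimate (HR or OR); identity for slopes."""
        if self.scale == "slope":
            return self.log_effect
        return float(np.exp(self.log_effect))

    def to_dict(self) -> dict:
        d = {
            "log_effect": self.log_effect,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "n_events": self.n_events,
            "scale": self.scale,
            "valid": self.valid,
            "reason": self.reason,
        }
        if self.scale in ("loghr", "logor") and self.valid:
            d["effect"] = self.effect
            d["effect_ci"] = [float(np.exp(self.ci_low)), float(np.exp(self.ci_high))]
        return d


def _invalid(scale: str, n: int, reason: str, n_events: int | None = None) -> EffectEstimate:
    nan = float("nan")
    return EffectEstimate(nan, nan, nan, nan, nan, n, scale, n_events, False, reason)


def _wald(log_effect: float, se: float, n: int, scale: str,
          n_events: int | None = None) -> EffectEstimate:
    z = log_effect / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return EffectEstimate(
        log_effect=float(log_effect),
        se=float(se),
        ci_low=float(log_effect - _Z975 * se),
        ci_high=float(log_effect + _Z975 * se),
        p_value=p,
        n=n,
        scale=scale,
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# univariable Cox, binary covariate, Efron ties
# ---------------------------------------------------------------------------


def _efron_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                  tol: float = 1e-10, max_iter: int = 60):
    """Newton maximization of the Efron partial likelihood, binary x.

    Returns (beta, information) or (None, reason) on non-convergence.
    """
    order = np.argsort(time, kind="stable")
    ts, es, xs = time[order], event[order].astype(bool), x[order].astype(float)
    tau = np.unique(ts[es])
    first_idx = np.searchsorted(ts, tau, side="left")
    ev_group = np.searchsorted(tau, ts[es])       # event-time bin of each event
    d = np.bincount(ev_group, minlength=tau.size).astype(float)
    # flattened (event time j, within-tie index l) pairs for the Efron terms
    jidx = np.repeat(np.arange(tau.size), d.astype(int))
    l_frac = np.concatenate([np.arange(int(dj)) / dj for dj in d])
    sum_x_events = float(xs[es].sum())
    x_ev = xs[es]

    beta = 0.0
    info = float("nan")
    for _ in range(max_iter):
        r = np.exp(beta * xs)
        rx = r * xs
        # risk-set sums: reverse cumulative sums evaluated at each event time
        s_r = np.cumsum(r[::-1])[::-1]
        s_rx = np.cumsum(rx[::-1])[::-1]
        S_R = s_r[first_idx]
        S_Rx = s_rx[first_idx]
        r_ev = np.exp(beta * x_ev)
        S_E = np.bincount(ev_group, weights=r_ev, minlength=tau.size)
        S_Ex = np.bincount(ev_group, weights=r_ev * x_ev, minlength=tau.size)
        phi = S_R[jidx] - l_frac * S_E[jidx]
        num = S_Rx[jidx] - l_frac * S_Ex[jidx]
        ratio = num / phi
        score = sum_x_events - float(ratio.sum())
        info = float((ratio - ratio**2).sum())  # x binary => x^2 = x
        if info <= 0:
            return None, "degenerate-information"
        step = score / info
        # damp the step: a raw Newton step can overshoot badly when few
        # events sit on one side, tripping the divergence guard spuriously
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(beta) > 15:
            return None, "monotone-likelihood"
        if abs(score) < tol or abs(step) < 1e-12:
            return beta, info
    return None, "non-convergence"


def cox_loghr(predictor, time, event) -> EffectEstimate:
    """Univariable Cox log hazard ratio for a 0/1 marker (High vs Low).

    Efron tie handling, Wald SE/CI.  Monotone likelihood (all events in one
    group) yields a flagged invalid estimate rather than an exception, so
    callers running many splits can record and skip it.
    """
    x = np.asarray(predictor, dtype=float).ravel()
    spec = OutcomeSpec.survival(time, event)
    if x.size != spec.n:
        raise ValueError("predictor and outcome length mismatch")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("predictor must be 0/1")
    n_ev = spec.n_events
    if n_ev == 0:
        raise ValueError("no events: partial likelihood undefined")
    if x.sum() == 0 or x.sum() == x.size:
        return _invalid("loghr", spec.n, "one-sided-predictor", n_ev)
    ev_high = int(spec.event[x == 1].sum())
    ev_low = n_ev - ev_high
    if min(ev_high, ev_low) == 0:
        return _invalid("loghr", spec.n, "monotone-likelihood", n_ev)
    beta, info = _efron_newton(x, spec.time, spec.event.astype(float))
    if beta is None:
        return _invalid("loghr", spec.n, str(info), n_ev)
    se = float(1.0 / np.sqrt(info))
    return _wald(beta, se, spec.n, "loghr", n_ev)


def logistic_logor(predictor, outcome) -> EffectEstimate:
    """Univariable log odds ratio for a 0/1 marker and a 0/1 outcome.

    For the saturated binary-binary model the MLE is the closed-form 2x2
    log cross-product ratio ``ln(ad/bc)`` with SE
    ``sqrt(1/a + 1/b + 1/c + 1/d)``.  A zero interior cell flags the
    estimate invalid (no continuity correction is applied).
    """
    x = np.asarray(predictor, dtype=float).ravel()
    spec = as_outcome(outcome, "binary")
    if x.size != spec.n:
        raise ValueError("predictor and outcome length mismatch")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("predictor must be 0/1")
    yv = spec.event.astype(float)
    a = float(((x == 1) & (yv == 1)).sum())
    b = float(((x == 1) & (yv == 0)).sum())
    c = float(((x == 0) & (yv == 1)).sum())
    d = float(((x == 0) & (yv == 0)).sum())
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("2x2 table has an empty margin")
    if min(a, b, c, d) == 0:
        return _invalid("logor", spec.n, "zero-cell", int(a + c))
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return _wald(log_or, se, spec.n, "logor", int(a + c))


def linear_slope(predictor, outcome) -> EffectEstimate:
    """Mean outcome difference High minus Low (the OLS slope on the 0/1
    indicator), with the pooled-variance t-based SE and p-value."""
    x = np.asarray(predictor, dtype=float).ravel()
    spec = as_outcome(outcome, "continuous")
    if x.size != spec.n:
        raise ValueError("predictor and outcome length mismatch")
    yv = spec.value
    hi, lo = yv[x == 1], yv[x == 0]
    if hi.size == 0 or lo.size == 0:
        return _invalid("slope", spec.n, "one-sided-predictor")
    if hi.size < 2 or lo.size < 2:
        return _invalid("slope", spec.n, "group-too-small")
    diff = float(hi.mean() - lo.mean())
    df = hi.size + lo.size - 2
    sp2 = ((hi.size - 1) * hi.var(ddof=1) + (lo.size - 1) * lo.var(ddof=1)) / df
    if sp2 <= 0:
        return _invalid("slope", spec.n, "zero-variance")
    se = float(np.sqrt(sp2 * (1 / hi.size + 1 / lo.size)))
    tq = float(stats.t.ppf(0.975, df))
    p = 2.0 * float(stats.t.sf(abs(diff / se), df))
    return EffectEstimate(diff, se, diff - tq * se, diff + tq * se, p,
                          spec.n, "slope")


def estimate_effect(predictor, outcome) -> EffectEstimate:
    """Dispatch to the outcome-appropriate univariable effect estimator."""
    spec = as_outcome(outcome)
    if spec.kind == "survival":
        return cox_loghr(predictor, spec.time, spec.event)
    if spec.kind == "binary":
        return logistic_logor(predictor, spec)
    return linear_slope(predictor, spec)


# ---------------------------------------------------------------------------
# multivariable Cox (lifelines) and Rubin pooling
# ---------------------------------------------------------------------------


def _encode(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """One-hot encode non-numeric covariates (drop-first)."""
    out = pd.DataFrame(index=df.index)
    for c in cols:
        col = df[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            out = pd.concat([out, dummies], axis=1)
        else:
            out[c] = col.astype(float)
    return out


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify the first column linearly dependent on its predecessors
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            raise ValueError(
                f"design matrix is singular: column {names[j - 1]!r} is "
                "collinear with the preceding columns"
            )
    raise ValueError("design matrix is singular")


def multivariable_cox(
    data: pd.DataFrame,
    predictor_col: str,
    duration_col: str,
    event_col: str,
    covariate_cols: list[str] | None = None,
    strata: str | list[str] | None = None,
) -> tuple[EffectEstimate, pd.DataFrame]:
    """Adjusted Cox model for a dichotomized marker.

    Fits a (optionally stratified) proportional-hazards model with the 0/1
    marker plus covariates via lifelines and returns the marker's adjusted
    estimate together with the full coefficient table.  Non-numeric
    covariates are one-hot encoded.  Raises on a singular design, naming the
    offending column.
    """
    from lifelines import CoxPHFitter

    covariate_cols = list(covariate_cols or [])
    design = _encode(data, [predictor_col] + covariate_cols)
    _check_full_rank(design.to_numpy(dtype=float), list(design.columns))
    n_events = int(data[event_col].sum())
    n_coef = design.shape[1]
    if n_events < 5 * n_coef:
        warnings.warn(
            f"only {n_events} events for {n_coef} coefficients; "
            "adjusted estimates may be unstable",
            stacklevel=2,
        )
    fit_df = design.copy()
    fit_df[duration_col] = data[duration_col].to_numpy(dtype=float)
    fit_df[event_col] = data[event_col].to_numpy(dtype=float)
    strata_list = [strata] if isinstance(strata, str) else strata
    if strata_list:
        for s in strata_list:
            fit_df[s] = data[s].to_numpy()
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col=duration_col, event_col=event_col,
            strata=strata_list)
    summary = cph.summary
    row = summary.loc[predictor_col]
    est = EffectEstimate(
        log_effect=float(row["coef"]),
        se=float(row["se(coef)"]),
        ci_low=float(row["coef lower 95%"]),
        ci_high=float(row["coef upper 95%"]),
        p_value=float(row["p"]),
        n=int(len(fit_df)),
        scale="loghr",
        n_events=n_events,
    )
    return est, summary


def rubin_pool(estimates, variances, scale: str = "loghr") -> EffectEstimate:
    """Pool estimates across imputed datasets by Rubin's rule.

    pooled = mean(estimates); total variance T = W + (1 + 1/m) B where W is
    the mean within-imputation variance and B the sample variance of the
    estimates (B = 0 when m = 1).
    """
    est = np.asarray(estimates, dtype=float).ravel()
    var = np.asarray(variances, dtype=float).ravel()
    if est.size != var.size:
        raise ValueError("estimates and variances length mismatch")
    if est.size < 1:
        raise ValueError("need at least one estimate")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    m = est.size
    pooled = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1)) if m > 1 else 0.0
    total = w + (1.0 + 1.0 / m) * b
    return _wald(pooled, float(np.sqrt(total)), m, scale)
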