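"""Optimal single-split dichotomization of a continuous predictor.

Given a continuous marker and an outcome, find the threshold that best
separates subjects into Low (``value <= cutoff``) and High
(``value > cutoff``) groups — a depth-1 regression/survival tree.  The split
criterion depends on the outcome kind:

- survival: two-sample log-rank chi-square,
- binary: Pearson chi-square of the 2x2 table,
- continuous: between-group sum of squares.

Candidate cutoffs are midpoints between consecutive distinct sorted values,
restricted so that each side keeps at least ``min_per_side`` subjects
(default ``max(7, ceil(0.05 n))``, mirroring common recursive-partitioning
minimum-bucket practice).  The search is exhaustive and deterministic; ties
in the criterion are broken towards the smallest cutoff.

The statistics are evaluated for all candidate thresholds at once: subjects
are ordered by marker value, so moving the threshold corresponds to growing
a prefix of the High group, and the log-rank O-E / variance terms (or 2x2
cell counts, or group sums) for every prefix come from cumulative sums.
This is what makes the repeated split-sampling and bootstrap layers above
affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .outcomes import OutcomeSpec, as_outcome

__all__ = [
    "NoSplitError",
    "CutpointResult",
    "candidate_cutoffs",
    "split_statistic",
    "optimal_cutpoint",
    "default_min_per_side",
    "CutpointSearcher",
]


class NoSplitError(ValueError):
    """No admissible cutoff exists (constant marker, empty candidate set,
    or an outcome that cannot be split, e.g. survival with zero events)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class CutpointResult:
    """An optimal dichotomization threshold and its split statistic."""

    cutoff: float
    statistic: float
    n_low: int
    n_high: int
    n_events_low: int | None = None
    n_events_high: int | None = None


def default_min_per_side(n: int) -> int:
    return max(7, int(np.ceil(0.05 * n)))


def candidate_cutoffs(values, min_per_side: int) -> np.ndarray:
    """Midpoints between consecutive distinct values leaving at least
    ``min_per_side`` observations strictly on each side, in ascending order.
    """
    x = np.asarray(values, dtype=float)
    if min_per_side < 1:
        raise ValueError("min_per_side must be >= 1")
    if x.size < 2 * min_per_side:
        raise ValueError(
            f"need at least {2 * min_per_side} observations, got {x.size}"
        )
    distinct = np.unique(x)
    if distinct.size < 2:
        return np.empty(0)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    # counts strictly below each midpoint; sides are (<= mid) vs (> mid)
    n_low = np.searchsorted(np.sort(x), mids, side="right")
    ok = (n_low >= min_per_side) & (x.size - n_low >= min_per_side)
    return mids[ok]


# ---------------------------------------------------------------------------
# survival: log-rank machinery
# ---------------------------------------------------------------------------


def _logrank_tables(time: np.ndarray, event: np.ndarray):
    """Per-event-time totals: unique event times tau, at-risk n_j, events d_j."""
    tau = np.unique(time[event == 1])
    n_j = (time[:, None] >= tau[None, :]).sum(axis=0).astype(float)
    d_j = ((time[:, None] == tau[None, :]) & (event[:, None] == 1)).sum(axis=0).astype(float)
    return tau, n_j, d_j


def _logrank_chi2_prefix(
    time: np.ndarray, event: np.ndarray, order_desc: np.ndarray, m_high: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square for every High-group prefix size in ``m_high``.

    ``order_desc`` sorts subjects by marker value descending, so the High
    group at prefix size m is ``order_desc[:m]``.
    """
    tau, n_j, d_j = _logrank_tables(time, event)
    if tau.size == 0:
        return np.zeros(m_high.size)
    t_s = time[order_desc]
    e_s = event[order_desc]
    at_risk = (t_s[:, None] >= tau[None, :]).astype(float)
    died = ((t_s[:, None] == tau[None, :]) & (e_s[:, None] == 1)).astype(float)
    # row m of the cumulative sums = totals over the first m subjects
    n1 = np.cumsum(at_risk, axis=0)[m_high - 1]          # (M, J)
    d1 = np.cumsum(died, axis=0)[m_high - 1]
    frac = n1 / n_j
    o_minus_e = (d1 - d_j * frac).sum(axis=1)
    denom = np.maximum(n_j - 1.0, 1.0)
    var = (d_j * frac * (1.0 - frac) * (n_j - d_j) / denom).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / var, 0.0)
    return chi2


def _logrank_chi2(time: np.ndarray, event: np.ndarray, high: np.ndarray) -> float:
    """Two-sample log-rank chi-square for a single High/Low partition."""
    tau, n_j, d_j = _logrank_tables(time, event)
    if tau.size == 0:
        return 0.0
    th, eh = time[high], event[high]
    n1 = (th[:, None] >= tau[None, :]).sum(axis=0).astype(float)
    d1 = ((th[:, None] == tau[None, :]) & (eh[:, None] == 1)).sum(axis=0).astype(float)
    frac = n1 / n_j
    o_minus_e = (d1 - d_j * frac).sum()
    denom = np.maximum(n_j - 1.0, 1.0)
    var = (d_j * frac * (1.0 - frac) * (n_j - d_j) / denom).sum()
    return float(o_minus_e**2 / var) if var > 0 else 0.0


# ---------------------------------------------------------------------------
# binary / continuous criteria
# ---------------------------------------------------------------------------


def _pearson_chi2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square (no continuity correction) of the 2x2 table
    [[a, b], [c, d]] with rows = groups, columns = outcome 1/0."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    return float(n * (a * d - b * c) ** 2 / denom)


def _between_ss(sum_h: float, m_h: float, total: float, n: int):
    """Between-group sum of squares for High-group (sum, size) prefixes."""
    m_l = n - m_h
    sum_l = total - sum_h
    grand = total / n
    return m_h * (sum_h / m_h - grand) ** 2 + m_l * (sum_l / m_l - grand) ** 2


def split_statistic(values, cutoff: float, outcome) -> float:
    """Split criterion for dichotomizing ``values`` at ``cutoff``.

    Larger is better.  Raises for a one-sided split or a survival outcome
    with zero events.
    """
    y = as_outcome(outcome)
    x = np.asarray(values, dtype=float)
    if x.size != y.n:
        raise ValueError("values and outcome length mismatch")
    high = x > cutoff
    if high.all() or not high.any():
        raise ValueError("cutoff yields a one-sided split")
    if y.kind == "survival":
        if y.n_events == 0:
            raise ValueError("survival outcome with zero events cannot be split")
        return _logrank_chi2(y.time, y.event, high)
    if y.kind == "binary":
        e = y.event.astype(float)
        a = float(e[high].sum())
        b = float(high.sum() - a)
        c = float(e[~high].sum())
        d = float((~high).sum() - c)
        return _pearson_chi2(a, b, c, d)
    v = y.value
    return float(
        _between_ss(float(v[high].sum()), float(high.sum()), float(v.sum()), v.size)
    )


def _statistics_for_candidates(
    x: np.ndarray, y: OutcomeSpec, cuts: np.ndarray
) -> np.ndarray:
    """Criterion values for every candidate cutoff, vectorized."""
    order_desc = np.argsort(-x, kind="stable")
    xs_desc = x[order_desc]
    # High-group size for each cutoff: number of values strictly above it
    m_high = np.searchsorted(-xs_desc, -cuts, side="left")
    if y.kind == "survival":
        return _logrank_chi2_prefix(y.time, y.event, order_desc, m_high)
    n = x.size
    if y.kind == "binary":
        e_cum = np.concatenate([[0.0], np.cumsum(y.event[order_desc].astype(float))])
        tot = float(y.event.sum())
        a = e_cum[m_high]
        b = m_high - a
        c = tot - a
        d = (n - m_high) - c
        stats = np.array(
            [_pearson_chi2(ai, bi, ci, di) for ai, bi, ci, di in zip(a, b, c, d)]
        )
        return stats
    v_cum = np.concatenate([[0.0], np.cumsum(y.value[order_desc])])
    total = float(y.value.sum())
    return _between_ss(v_cum[m_high], m_high.astype(float), total, n)


class CutpointSearcher(BaseEstimator):
    """Exhaustive optimal-cutpoint search as an sklearn estimator.

    ``fit(x, y)`` finds the admissible threshold maximizing the
    outcome-appropriate split criterion; ``predict(x)`` dichotomizes new
    marker values at the fitted threshold (1 = High, i.e. ``x > cutoff_``).

    Parameters
    ----------
    min_per_side : int or None
        Minimum subjects on each side of the split; ``None`` uses
        ``max(7, ceil(0.05 n))``.
    outcome_kind : {"survival", "binary", "continuous"} or None
        Forces the interpretation of ``y``; inferred when ``None``.
    require_estimable : bool, default False
        Restrict the search to splits whose dichotomized effect is
        estimable: at least one event on each side (survival), or all four
        2x2 cells positive (binary).  Used by the optimism corrector, whose
        apparent performance must be a finite log effect.

    Attributes
    ----------
    cutoff_ : float
        Optimal threshold.
    statistic_ : float
        Criterion value at the optimum.
    n_low_, n_high_ : int
        Group sizes; ``n_events_low_``/``n_events_high_`` when the outcome
        carries events.

    Raises
    ------
    NoSplitError
        When no admissible candidate exists (constant marker, too few
        subjects, or zero events for a survival outcome).
    """

    def __init__(
        self,
        min_per_side: int | None = None,
        outcome_kind: str | None = None,
        require_estimable: bool = False,
    ):
        self.min_per_side = min_per_side
        self.outcome_kind = outcome_kind
        self.require_estimable = require_estimable

    def fit(self, x, y) -> "CutpointSearcher":
        xv = np.asarray(x, dtype=float).ravel()
        spec = as_outcome(y, self.outcome_kind)
        if xv.size != spec.n:
            raise ValueError("x and y length mismatch")
        if not np.all(np.isfinite(xv)):
            raise ValueError("marker values must be finite")
        mps = self.min_per_side or default_min_per_side(xv.size)
        if spec.kind == "survival" and spec.n_events == 0:
            raise NoSplitError("no-events")
        if np.unique(xv).size < 2:
            raise NoSplitError("constant-predictor")
        cuts = candidate_cutoffs(xv, mps)
        if cuts.size == 0:
            raise NoSplitError("no-admissible-cutoff")
        stats = _statistics_for_candidates(xv, spec, cuts)
        stats = np.where(np.isfinite(stats), stats, -np.inf)
        if self.require_estimable and spec.event is not None:
            order_desc = np.argsort(-xv, kind="stable")
            m_high = np.searchsorted(-xv[order_desc], -cuts, side="left")
            ev_cum = np.concatenate(
                [[0.0], np.cumsum(spec.event[order_desc].astype(float))]
            )
            total_ev = float(spec.event.sum())
            a = ev_cum[m_high]          # events on the high side
            c = total_ev - a
            ok = (a >= 1) & (c >= 1)
            if spec.kind == "binary":   # also need non-events on both sides
                ok &= (m_high - a >= 1) & ((xv.size - m_high) - c >= 1)
            stats = np.where(ok, stats, -np.inf)
            if not np.any(np.isfinite(stats)):
                raise NoSplitError("no-estimable-split")
        best = int(np.argmax(stats))  # first max -> smallest cutoff on ties
        if not np.isfinite(stats[best]):
            raise NoSplitError("criterion-undefined")
        self.cutoff_ = float(cuts[best])
        self.statistic_ = float(stats[best])
        high = xv > self.cutoff_
        self.n_low_ = int((~high).sum())
        self.n_high_ = int(high.sum())
        if spec.event is not None:
            self.n_events_low_ = int(spec.event[~high].sum())
            self.n_events_high_ = int(spec.event[high].sum())
        else:
            self.n_events_low_ = self.n_events_high_ = None
        self.min_per_side_ = int(mps)
        return self

    def predict(self, x) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise AttributeError("CutpointSearcher is not fitted")
        return (np.asarray(x, dtype=float) > self.cutoff_).astype(int)

    def result_(self) -> CutpointResult:
        return CutpointResult(
            cutoff=self.cutoff_,
            statistic=self.statistic_,
            n_low=self.n_low_,
            n_high=self.n_high_,
            n_events_low=self.n_events_low_,
            n_events_high=self.n_events_high_,
        )


def optimal_cutpoint(values, outcome, min_per_side: int | None = None) -> CutpointResult:
    """Functional wrapper over :class:`CutpointSearcher`."""
    searcher = CutpointSearcher(min_per_side=min_per_side)
    searcher.fit(values, outcome)
    return searcher.result_()
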