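"""Selection of the optimal quantile predictor by repeated split-sampling.

The screening algorithm, for each candidate quantile probability p on the
grid:

1. split subjects into training (default 80%) and test (20%) sets,
   stratified on event status so every split keeps the cohort's event
   fraction;
2. find the optimal dichotomization cutoff for Q_n(p) on the training set
   only;
3. apply that cutoff to the test set and record the test-set log effect
   (log HR / log OR / slope);
4. repeat for many splits (default 100) and summarize each quantile by the
   median of its valid test-set log effects;
5. rank quantiles by |median log effect| and select the top one (the
   exponentiated median is reported as HR*).

The identical train/test partitions are shared across quantiles so the
comparison is fair.  Per-split randomness is derived from
``SeedSequence(master_seed, spawn_key=(split_index,))``, so adding splits
never reshuffles earlier ones and the whole procedure is reproducible from
the master seed.  Degenerate splits (no admissible training cutoff, a
one-sided test dichotomy, monotone likelihood) are recorded with a reason
code, not raised; quantiles whose valid-split fraction falls below
``valid_fraction`` (default 50%) are excluded from ranking and listed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cutpoint import CutpointSearcher, NoSplitError, default_min_per_side
from .effects import estimate_effect
from .outcomes import OutcomeSpec, as_outcome
from .quantiles import QuantileMatrix

__all__ = [
    "SplitConfig",
    "SplitRecord",
    "SelectionResult",
    "stratified_split",
    "evaluate_split",
    "select_optimal",
    "QuantileSelector",
]


@dataclass(frozen=True)
class SplitConfig:
    """Configuration of the repeated split-sampling screen."""

    train_fraction: float = 0.8
    n_splits: int = 100
    master_seed: int = 0
    min_per_side: int | None = None
    valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not (0.0 <= self.valid_fraction <= 1.0):
            raise ValueError("valid_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SplitRecord:
    """Outcome of one training-cutoff / test-effect evaluation."""

    split_index: int
    cutoff: float
    log_effect: float
    valid: bool
    reason: str | None = None


def _stratum_train_size(size: int, fraction: float) -> int:
    # round-half-to-even, then force both sides non-empty
    k = int(np.round(fraction * size))
    return min(max(k, 1), size - 1)


def stratified_split(
    outcome, cfg: SplitConfig, split_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """One event-stratified train/test partition of subject indices.

    Subjects with and without event are each split at ``train_fraction``
    (train size = round(fraction * stratum size)) and recombined.  The
    partition is fully determined by ``(master_seed, split_index)``.
    """
    spec = as_outcome(outcome)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.master_seed, spawn_key=(split_index,))
    )
    mask = spec.event_mask
    train_parts, test_parts = [], []
    for stratum in (np.flatnonzero(mask), np.flatnonzero(~mask)):
        if stratum.size < 2:
            raise ValueError(
                "each outcome stratum needs at least 2 subjects "
                f"(got {stratum.size})"
            )
        k = _stratum_train_size(stratum.size, cfg.train_fraction)
        perm = rng.permutation(stratum)
        train_parts.append(perm[:k])
        test_parts.append(perm[k:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def evaluate_split(
    values,
    outcome,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    min_per_side: int | None = None,
    split_index: int = 0,
) -> SplitRecord:
    """Training-set cutoff, test-set effect, for one partition.

    Never raises for degenerate data; failures become records with
    ``valid=False`` and a reason code (``no-split:*``,
    ``one-sided-test-split``, ``monotone-likelihood``, ...).
    """
    x = np.asarray(values, dtype=float)
    spec = as_outcome(outcome)
    nan = float("nan")
    try:
        searcher = CutpointSearcher(min_per_side=min_per_side).fit(
            x[train_idx], spec.subset(train_idx)
        )
    except NoSplitError as exc:
        return SplitRecord(split_index, nan, nan, False, f"no-split:{exc.reason}")
    cutoff = searcher.cutoff_
    high_test = (x[test_idx] > cutoff).astype(int)
    if high_test.sum() in (0, high_test.size):
        return SplitRecord(split_index, cutoff, nan, False, "one-sided-test-split")
    try:
        est = estimate_effect(high_test, spec.subset(test_idx))
    except ValueError as exc:
        return SplitRecord(split_index, cutoff, nan, False, str(exc))
    if not est.valid:
        return SplitRecord(split_index, cutoff, nan, False, est.reason)
    return SplitRecord(split_index, cutoff, est.log_effect, True)


_QCOL = re.compile(r"^q(\d{1,2})$")


def _coerce_matrix(X, probabilities) -> tuple[np.ndarray, np.ndarray]:
    """Extract (values, probabilities) from the accepted input layouts."""
    if isinstance(X, QuantileMatrix):
        return X.values, X.grid.probabilities
    if isinstance(X, pd.DataFrame):
        if probabilities is not None:
            probs = np.asarray(probabilities, dtype=float)
            if len(probs) != X.shape[1]:
                raise ValueError("probabilities do not match the column count")
            return X.to_numpy(dtype=float), probs
        cols = [(c, int(m.group(1)) / 100.0) for c in X.columns
                if (m := _QCOL.match(str(c)))]
        if not cols:
            raise ValueError(
                "no quantile columns (q05, q10, ...) found; pass "
                "`probabilities` explicitly for unlabeled input"
            )
        names, probs = zip(*cols)
        return X[list(names)].to_numpy(dtype=float), np.asarray(probs)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-d (subjects x quantiles)")
    if probabilities is None:
        raise ValueError("probabilities required for array input")
    probs = np.asarray(probabilities, dtype=float)
    if probs.size != arr.shape[1]:
        raise ValueError("probabilities do not match the column count")
    return arr, probs


class QuantileSelector(BaseEstimator):
    """Repeated split-sample selection of the optimal quantile predictor.

    ``fit(X, y)`` expects per-subject quantile features (a
    :class:`~qmarker.quantiles.QuantileMatrix`, a DataFrame with ``qNN``
    columns such as the :class:`~qmarker.quantiles.QuantileFeaturizer`
    output, or a 2-d array plus ``probabilities``) and an outcome
    (``OutcomeSpec``, ``(time, event)`` tuple, 2-column array, or 0/1 /
    real vector).

    Parameters
    ----------
    train_fraction : float, default 0.8
    n_splits : int, default 100
    random_state : int, default 0
        Master seed for the split stream.
    min_per_side : int or None
        Minimum group size in the training cutpoint search.
    valid_fraction : float, default 0.5
        Minimum fraction of valid splits for a quantile to enter ranking.
    outcome_kind : str or None
        Force outcome interpretation.

    Attributes
    ----------
    probabilities_ : ndarray
        The candidate grid.
    median_log_effects_ : ndarray
        Median valid test-set log effect per quantile (NaN when excluded).
    valid_counts_ : ndarray of int
    ranking_ : ndarray
        Probabilities ordered by decreasing |median log effect| (included
        quantiles first, excluded ones appended).
    selected_probability_ : float
        The optimal quantile; ties go to the smallest probability.
    top_probabilities_ : ndarray
        Up to the three highest-ranked probabilities.
    records_ : dict prob -> list of SplitRecord
    train_cutoffs_ : dict prob -> ndarray of per-split training cutoffs
    splits_ : list of (train_idx, test_idx)
    excluded_ : dict prob -> reason summary
    """

    def __init__(
        self,
        train_fraction: float = 0.8,
        n_splits: int = 100,
        random_state: int = 0,
        min_per_side: int | None = None,
        valid_fraction: float = 0.5,
        outcome_kind: str | None = None,
    ):
        self.train_fraction = train_fraction
        self.n_splits = n_splits
        self.random_state = random_state
        self.min_per_side = min_per_side
        self.valid_fraction = valid_fraction
        self.outcome_kind = outcome_kind

    def _config(self) -> SplitConfig:
        return SplitConfig(
            train_fraction=self.train_fraction,
            n_splits=self.n_splits,
            master_seed=self.random_state,
            min_per_side=self.min_per_side,
            valid_fraction=self.valid_fraction,
        )

    def fit(self, X, y, probabilities=None) -> "QuantileSelector":
        values, probs = _coerce_matrix(X, probabilities)
        spec = as_outcome(y, self.outcome_kind)
        if values.shape[0] != spec.n:
            raise ValueError("X and y disagree on the number of subjects")
        cfg = self._config()
        # identical partitions shared across all quantiles
        splits = [stratified_split(spec, cfg, i) for i in range(cfg.n_splits)]

        records: dict[float, list[SplitRecord]] = {}
        medians = np.full(probs.size, np.nan)
        valid_counts = np.zeros(probs.size, dtype=int)
        excluded: dict[float, str] = {}
        for j, p in enumerate(probs):
            col = values[:, j]
            recs = [
                evaluate_split(col, spec, tr, te, cfg.min_per_side, i)
                for i, (tr, te) in enumerate(splits)
            ]
            records[float(p)] = recs
            effects = np.array([r.log_effect for r in recs if r.valid])
            valid_counts[j] = effects.size
            if effects.size >= cfg.valid_fraction * cfg.n_splits and effects.size > 0:
                medians[j] = float(np.median(effects))
            else:
                reasons = pd.Series(
                    [r.reason for r in recs if not r.valid]
                ).value_counts()
                excluded[float(p)] = (
                    f"{effects.size}/{cfg.n_splits} valid splits; "
                    + ", ".join(f"{k}: {v}" for k, v in reasons.items())
                )
        if not np.any(np.isfinite(medians)):
            raise RuntimeError(
                "no quantile had enough valid splits; reasons per quantile: "
                + "; ".join(f"p={p:g} -> {r}" for p, r in excluded.items())
            )
        included = np.isfinite(medians)
        # rank by |median| descending; ties towards smaller probability
        inc_idx = np.flatnonzero(included)
        order = inc_idx[np.lexsort((probs[inc_idx], -np.abs(medians[inc_idx])))]
        exc_idx = np.flatnonzero(~included)
        self.probabilities_ = probs
        self.median_log_effects_ = medians
        self.valid_counts_ = valid_counts
        self.ranking_ = probs[np.concatenate([order, exc_idx])]
        self.selected_probability_ = float(probs[order[0]])
        self.selected_median_log_effect_ = float(medians[order[0]])
        self.top_probabilities_ = probs[order[: min(3, order.size)]]
        self.records_ = records
        self.train_cutoffs_ = {
            float(p): np.array([r.cutoff for r in records[float(p)]])
            for p in probs
        }
        self.splits_ = splits
        self.excluded_ = excluded
        self.n_subjects_ = int(values.shape[0])
        return self

    def result_(self) -> "SelectionResult":
        return SelectionResult(
            probabilities=self.probabilities_,
            median_log_effects=self.median_log_effects_,
            valid_counts=self.valid_counts_,
            n_splits=self.n_splits,
            ranking=self.ranking_,
            selected_probability=self.selected_probability_,
            selected_median_log_effect=self.selected_median_log_effect_,
            top_probabilities=self.top_probabilities_,
            records=self.records_,
            train_cutoffs=self.train_cutoffs_,
            excluded=self.excluded_,
            master_seed=self.random_state,
        )


@dataclass(frozen=True)
class SelectionResult:
    """Report of the split-sample screen."""

    probabilities: np.ndarray
    median_log_effects: np.ndarray
    valid_counts: np.ndarray
    n_splits: int
    ranking: np.ndarray
    selected_probability: float
    selected_median_log_effect: float
    top_probabilities: np.ndarray
    records: dict[float, list[SplitRecord]]
    train_cutoffs: dict[float, np.ndarray]
    excluded: dict[float, str]
    master_seed: int

    @property
    def selected_hr_star(self) -> float:
        """Exponentiated median log effect of the selected quantile (HR*)."""
        return float(np.exp(self.selected_median_log_effect))

    def to_dict(self) -> dict:
        return {
            "probabilities": [float(p) for p in self.probabilities],
            "median_log_effects": [
                None if not np.isfinite(v) else float(v)
                for v in self.median_log_effects
            ],
            "valid_counts": [int(v) for v in self.valid_counts],
            "n_splits": int(self.n_splits),
            "ranking": [float(p) for p in self.ranking],
            "selected_probability": float(self.selected_probability),
            "selected_median_log_effect": float(self.selected_median_log_effect),
            "selected_hr_star": self.selected_hr_star,
            "top_probabilities": [float(p) for p in self.top_probabilities],
            "excluded": {f"{p:g}": r for p, r in self.excluded.items()},
            "master_seed": int(self.master_seed),
        }

    def detail_frame(self) -> pd.DataFrame:
        """Per-quantile per-split detail table (long format)."""
        rows = []
        for p, recs in self.records.items():
            for r in recs:
                rows.append(
                    {
                        "probability": p,
                        "split_index": r.split_index,
                        "train_cutoff": r.cutoff,
                        "test_log_effect": r.log_effect,
                        "valid": r.valid,
                        "reason": r.reason,
                    }
                )
        return pd.DataFrame(rows)


def select_optimal(
    qm, outcome, cfg: SplitConfig | None = None
) -> SelectionResult:
    """Functional wrapper over :class:`QuantileSelector`."""
    cfg = cfg or SplitConfig()
    selector = QuantileSelector(
        train_fraction=cfg.train_fraction,
        n_splits=cfg.n_splits,
        random_state=cfg.master_seed,
        min_per_side=cfg.min_per_side,
        valid_fraction=cfg.valid_fraction,
    )
    selector.fit(qm, outcome)
    return selector.result_()
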