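"""Bootstrap optimism correction for a data-driven dichotomization cutoff.

Choosing the cutoff that maximizes a split statistic and then measuring the
effect of the resulting High/Low marker on the same data overstates the
effect ("apparent performance").  The bootstrap estimate of that selection
bias works as follows, for a fixed marker (one chosen quantile):

1. apparent performance: cutoff searched on the full sample, log effect of
   the dichotomized marker measured on the full sample;
2. for each of ``n_boot`` bootstrap resamples (subjects drawn with
   replacement, same n): search the cutoff in the resample, measure the log
   effect in the resample ("bootstrap performance") and the log effect of
   the same cutoff applied back to the original sample ("test
   performance");
3. optimism of a resample = bootstrap performance - test performance;
4. corrected log effect = apparent - median(optimism).  The exponentiated
   corrected value is reported as HR**.

The median (not mean) of the optimism estimates is used.  The 95% interval
for the corrected effect is the apparent Wald interval shifted by the
median optimism on the log scale — a documented convention, since an exact
interval for an optimism-corrected estimate is not well defined.
Degenerate resamples (no admissible cutoff, monotone likelihood) are
dropped and counted; more than 50% invalid resamples aborts with a reason
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .cutpoint import CutpointSearcher, NoSplitError
from .effects import EffectEstimate, estimate_effect
from .outcomes import as_outcome

__all__ = ["BootstrapRecord", "OptimismReport", "OptimismCorrector", "bootstrap_optimism"]


@dataclass(frozen=True)
class BootstrapRecord:
    """One bootstrap resample's cutoff and performance pair."""

    index: int
    cutoff: float
    bootstrap_log_effect: float
    test_log_effect: float
    valid: bool
    reason: str | None = None

    @property
    def optimism(self) -> float:
        return self.bootstrap_log_effect - self.test_log_effect


@dataclass(frozen=True)
class OptimismReport:
    """Apparent, optimism and corrected effect estimates for one marker."""

    apparent: EffectEstimate
    apparent_cutoff: float
    records: tuple[BootstrapRecord, ...]
    median_optimism: float
    corrected_log_effect: float
    corrected_ci_low: float
    corrected_ci_high: float
    n_boot: int
    n_invalid: int
    seed: int

    @property
    def corrected_effect(self) -> float:
        """Exponentiated corrected estimate (HR** for survival outcomes)."""
        if self.apparent.scale == "slope":
            return self.corrected_log_effect
        return float(np.exp(self.corrected_log_effect))

    def to_dict(self) -> dict:
        d = {
            "apparent": self.apparent.to_dict(),
            "apparent_cutoff": self.apparent_cutoff,
            "median_optimism": self.median_optimism,
            "corrected_log_effect": self.corrected_log_effect,
            "corrected_ci_low": self.corrected_ci_low,
            "corrected_ci_high": self.corrected_ci_high,
            "n_boot": self.n_boot,
            "n_invalid": self.n_invalid,
            "seed": self.seed,
        }
        if self.apparent.scale in ("loghr", "logor"):
            d["corrected_effect"] = self.corrected_effect
            d["corrected_effect_ci"] = [
                float(np.exp(self.corrected_ci_low)),
                float(np.exp(self.corrected_ci_high)),
            ]
        return d

    def detail_rows(self) -> list[dict]:
        return [
            {
                "index": r.index,
                "cutoff": r.cutoff,
                "bootstrap_log_effect": r.bootstrap_log_effect,
                "test_log_effect": r.test_log_effect,
                "optimism": r.optimism if r.valid else float("nan"),
                "valid": r.valid,
                "reason": r.reason,
            }
            for r in self.records
        ]


class OptimismCorrector(BaseEstimator):
    """Bootstrap optimism correction as an sklearn estimator.

    ``fit(x, y)`` runs the full procedure on marker values ``x`` and
    outcome ``y``.

    Parameters
    ----------
    n_boot : int, default 200
        Number of bootstrap resamples.
    random_state : int, default 0
    min_per_side : int or None
        Passed to the cutpoint search.
    outcome_kind : str or None

    Attributes
    ----------
    apparent_ : EffectEstimate
        Full-sample effect of the full-sample cutoff.
    apparent_cutoff_ : float
    median_optimism_ : float
    corrected_log_effect_ : float
        ``apparent_.log_effect - median_optimism_`` exactly.
    records_ : tuple of BootstrapRecord
    n_invalid_ : int
    """

    def __init__(
        self,
        n_boot: int = 200,
        random_state: int = 0,
        min_per_side: int | None = None,
        outcome_kind: str | None = None,
    ):
        self.n_boot = n_boot
        self.random_state = random_state
        self.min_per_side = min_per_side
        self.outcome_kind = outcome_kind

    def fit(self, x, y) -> "OptimismCorrector":
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        xv = np.asarray(x, dtype=float).ravel()
        spec = as_outcome(y, self.outcome_kind)
        n = spec.n
        if xv.size != n:
            raise ValueError("x and y length mismatch")

        searcher = CutpointSearcher(
            min_per_side=self.min_per_side, require_estimable=True
        ).fit(xv, spec)
        self.apparent_cutoff_ = searcher.cutoff_
        apparent = estimate_effect(searcher.predict(xv), spec)
        if not apparent.valid:
            raise RuntimeError(
                f"apparent effect is not estimable: {apparent.reason}"
            )
        self.apparent_ = apparent

        records: list[BootstrapRecord] = []
        nan = float("nan")
        for b in range(self.n_boot):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=self.random_state, spawn_key=(1, b)
                )
            )
            idx = rng.integers(0, n, size=n)
            xb, yb = xv[idx], spec.subset(idx)
            try:
                bs = CutpointSearcher(
                    min_per_side=self.min_per_side, require_estimable=True
                ).fit(xb, yb)
            except NoSplitError as exc:
                records.append(
                    BootstrapRecord(b, nan, nan, nan, False, f"no-split:{exc.reason}")
                )
                continue
            boot_est = estimate_effect(bs.predict(xb), yb)
            if not boot_est.valid:
                records.append(
                    BootstrapRecord(b, bs.cutoff_, nan, nan, False,
                                    f"bootstrap:{boot_est.reason}")
                )
                continue
            high_main = (xv > bs.cutoff_).astype(int)
            if high_main.sum() in (0, high_main.size):
                records.append(
                    BootstrapRecord(b, bs.cutoff_, boot_est.log_effect, nan,
                                    False, "one-sided-main-sample")
                )
                continue
            test_est = estimate_effect(high_main, spec)
            if not test_est.valid:
                records.append(
                    BootstrapRecord(b, bs.cutoff_, boot_est.log_effect, nan,
                                    False, f"test:{test_est.reason}")
                )
                continue
            records.append(
                BootstrapRecord(b, bs.cutoff_, boot_est.log_effect,
                                test_est.log_effect, True)
            )

        valid = [r for r in records if r.valid]
        n_invalid = len(records) - len(valid)
        if n_invalid > 0.5 * self.n_boot:
            from collections import Counter

            hist = Counter(r.reason for r in records if not r.valid)
            raise RuntimeError(
                f"{n_invalid}/{self.n_boot} bootstrap iterations invalid: "
                + ", ".join(f"{k}: {v}" for k, v in hist.most_common())
            )
        optimism = np.array([r.optimism for r in valid])
        self.median_optimism_ = float(np.median(optimism))
        self.corrected_log_effect_ = apparent.log_effect - self.median_optimism_
        self.records_ = tuple(records)
        self.n_invalid_ = n_invalid
        return self

    def report_(self) -> OptimismReport:
        return OptimismReport(
            apparent=self.apparent_,
            apparent_cutoff=self.apparent_cutoff_,
            records=self.records_,
            median_optimism=self.median_optimism_,
            corrected_log_effect=self.corrected_log_effect_,
            corrected_ci_low=self.apparent_.ci_low - self.median_optimism_,
            corrected_ci_high=self.apparent_.ci_high - self.median_optimism_,
            n_boot=self.n_boot,
            n_invalid=self.n_invalid_,
            seed=self.random_state,
        )


def bootstrap_optimism(
    values,
    outcome,
    n_boot: int = 200,
    seed: int = 0,
    min_per_side: int | None = None,
) -> OptimismReport:
    """Functional wrapper over :class:`OptimismCorrector`."""
    corr = OptimismCorrector(
        n_boot=n_boot, random_state=seed, min_per_side=min_per_side
    )
    corr.fit(values, outcome)
    return corr.report_()
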