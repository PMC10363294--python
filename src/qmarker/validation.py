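"""External validation of frozen quantile biomarkers.

Once a quantile has been selected on the screening cohort, its
dichotomization cutoff is *frozen* and carried to an independent cohort.
Two cutoff types are supported:

- ``apparent``: the optimal cutpoint searched on the entire screening set;
- ``median_training``: the median of the training-set cutoffs over the same
  repeated splits used during selection.

In the external cohort the marker (a quantile at the frozen probability, or
the mean-intensity comparator ``ccmsi``) is recomputed per subject from the
external cell-level data, dichotomized at the frozen cutoff — never
re-fitted — and evaluated with a univariable Cox model, a parsimonious
multivariable Cox model (covariates backward-eliminated at p < 0.05 before
the marker is added; the marker itself is never eliminated), and
Kaplan-Meier curves per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cutpoint import CutpointSearcher
from .effects import EffectEstimate, estimate_effect, multivariable_cox
from .outcomes import OutcomeSpec, as_outcome
from .quantiles import CellSample, compartment_mean, empirical_quantile, qc_filter
from .selection import SplitConfig, stratified_split

logger = logging.getLogger(__name__)

__all__ = [
    "FrozenCutoff",
    "ValidationReport",
    "derive_cutoffs",
    "marker_values",
    "validate_external",
    "km_estimate",
]

CCMSI = "ccmsi"


@dataclass(frozen=True)
class FrozenCutoff:
    """A screening-derived dichotomization threshold, never re-fitted."""

    marker: str
    probability: float | str  # grid probability, or "ccmsi"
    cutoff: float
    cutoff_type: str  # "apparent" | "median_training"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cutoff_type not in ("apparent", "median_training"):
            raise ValueError(f"unknown cutoff type {self.cutoff_type!r}")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "probability": self.probability,
            "cutoff": self.cutoff,
            "cutoff_type": self.cutoff_type,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenCutoff":
        return cls(
            marker=d["marker"],
            probability=d["probability"],
            cutoff=float(d["cutoff"]),
            cutoff_type=d["cutoff_type"],
            provenance=dict(d.get("provenance", {})),
        )


def derive_cutoffs(
    values,
    outcome,
    cfg: SplitConfig | None = None,
    marker: str = "marker",
    probability: float | str = CCMSI,
    provenance: dict | None = None,
) -> tuple[FrozenCutoff, FrozenCutoff]:
    """Derive the two frozen cutoff types from screening data.

    Type (i) ``apparent`` searches the cutoff on the entire screening
    sample; type (ii) ``median_training`` is the median of the cutoffs found
    on the training part of each of the ``cfg.n_splits`` repeated partitions
    (the same partitions the selection step used, given the same master
    seed).  When every training split lands on the same cutoff — common for
    well-separated markers — the two types coincide.
    """
    cfg = cfg or SplitConfig()
    spec = as_outcome(outcome)
    xv = np.asarray(values, dtype=float).ravel()
    prov = dict(provenance or {})
    prov.setdefault("master_seed", cfg.master_seed)
    prov.setdefault("n_splits", cfg.n_splits)

    apparent = CutpointSearcher(min_per_side=cfg.min_per_side).fit(xv, spec)
    train_cuts = []
    for i in range(cfg.n_splits):
        tr, _ = stratified_split(spec, cfg, i)
        try:
            s = CutpointSearcher(min_per_side=cfg.min_per_side).fit(
                xv[tr], spec.subset(tr)
            )
            train_cuts.append(s.cutoff_)
        except Exception:  # no-split on this partition; skip
            continue
    if not train_cuts:
        raise RuntimeError("no training split produced an admissible cutoff")
    return (
        FrozenCutoff(marker, probability, apparent.cutoff_, "apparent", prov),
        FrozenCutoff(
            marker, probability, float(np.median(train_cuts)),
            "median_training", prov,
        ),
    )


def marker_values(
    samples: Sequence[CellSample],
    probability: float | str,
    min_cells: int = 20,
) -> pd.Series:
    """Per-subject marker value: quantile at ``probability`` or the ccMSI.

    Subjects contributing multiple tissue samples have their derived values
    averaged (one marker value per subject).
    """
    samples = qc_filter(samples, min_cells)
    if not samples:
        raise ValueError("no samples passed QC")
    if probability == CCMSI:
        vals = [(s.subject_id, compartment_mean(s)) for s in samples]
    else:
        p = float(probability)
        vals = [(s.subject_id, empirical_quantile(s.intensities, p)) for s in samples]
    ser = pd.DataFrame(vals, columns=["subject_id", "value"]).groupby(
        "subject_id", sort=False
    )["value"]
    n_multi = int((ser.count() > 1).sum())
    if n_multi:
        logger.info("averaged marker values for %d subject(s) with multiple samples",
                    n_multi)
    return ser.mean()


def km_estimate(time, event, group) -> dict:
    """Per-group Kaplan-Meier product-limit curves with at-risk counts.

    Returns ``{label: {"time": [...], "survival": [...], "at_risk": [...]}}``
    with the time grid anchored at 0 (S(0) = 1).
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    g = np.asarray(group)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    curves: dict = {}
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        times = sf.index.to_numpy(dtype=float)
        surv = sf.iloc[:, 0].to_numpy(dtype=float)
        table = kmf.event_table
        at_risk = table["at_risk"].reindex(sf.index).ffill().to_numpy()
        curves[str(label)] = {
            "time": [float(x) for x in times],
            "survival": [float(s) for s in surv],
            "at_risk": [int(a) for a in at_risk],
        }
    return curves


@dataclass(frozen=True)
class ValidationReport:
    """External-cohort evaluation of one frozen marker."""

    cutoff: FrozenCutoff
    n_analyzed: int
    n_high: int
    n_low: int
    univariable: EffectEstimate
    multivariable: EffectEstimate | None
    coefficient_table: pd.DataFrame | None
    retained_covariates: tuple[str, ...]
    km_curves: dict
    n_excluded_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff.to_dict(),
            "n_analyzed": self.n_analyzed,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "univariable": self.univariable.to_dict(),
            "multivariable": (
                self.multivariable.to_dict() if self.multivariable else None
            ),
            "coefficients": (
                {
                    k: {kk: float(vv) for kk, vv in row.items()}
                    for k, row in self.coefficient_table[
                        ["coef", "se(coef)", "p"]
                    ].to_dict(orient="index").items()
                }
                if self.coefficient_table is not None
                else None
            ),
            "retained_covariates": list(self.retained_covariates),
            "km_curves": self.km_curves,
            "n_excluded_missing": self.n_excluded_missing,
        }


def _parsimonious_covariates(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariate_cols: list[str],
    strata,
    alpha: float = 0.05,
) -> list[str]:
    """Backward elimination of covariates at ``alpha``, marker excluded.

    At each step the covariate whose best (smallest) coefficient p-value is
    largest is dropped, until all remaining covariates have at least one
    coefficient with p < alpha.  Multi-level covariates are kept or dropped
    as a block.
    """
    from lifelines import CoxPHFitter

    from .effects import _encode

    remaining = list(covariate_cols)
    strata_list = [strata] if isinstance(strata, str) else (strata or [])
    while remaining:
        design = _encode(df, remaining)
        fit_df = design.copy()
        fit_df[duration_col] = df[duration_col].to_numpy(dtype=float)
        fit_df[event_col] = df[event_col].to_numpy(dtype=float)
        for s in strata_list:
            fit_df[s] = df[s].to_numpy()
        cph = CoxPHFitter()
        try:
            cph.fit(fit_df, duration_col=duration_col, event_col=event_col,
                    strata=strata_list or None)
        except Exception:
            # unstable fit: drop the last covariate and retry
            remaining = remaining[:-1]
            continue
        pvals = cph.summary["p"]
        cov_p = {
            c: min(
                (pvals[col] for col in pvals.index if col == c or
                 str(col).startswith(f"{c}_")),
                default=1.0,
            )
            for c in remaining
        }
        worst = max(cov_p, key=cov_p.get)
        if cov_p[worst] < alpha:
            break
        remaining.remove(worst)
    return remaining


def validate_external(
    frozen: FrozenCutoff,
    samples: Sequence[CellSample],
    clinical: pd.DataFrame,
    *,
    subject_col: str = "subject_id",
    duration_col: str = "time",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
    strata: str | list[str] | None = None,
    min_cells: int = 20,
) -> ValidationReport:
    """Evaluate a frozen marker on an external cohort.

    Recomputes the marker per external subject, dichotomizes at the frozen
    cutoff (never re-fitted), and reports the univariable Cox estimate, the
    parsimonious multivariable estimate, and per-group Kaplan-Meier curves.
    Subjects with missing covariates are dropped from the multivariable
    model only (complete-case, logged).
    """
    values = marker_values(samples, frozen.probability, min_cells)
    clin = clinical.copy()
    clin[subject_col] = clin[subject_col].astype(str)
    merged = clin.merge(
        values.rename("marker_value"), left_on=subject_col, right_index=True,
        how="inner",
    )
    n_missing_marker = len(clin) - len(merged)
    if n_missing_marker:
        logger.info("%d clinical subject(s) lack marker data", n_missing_marker)
    if merged.empty:
        raise ValueError("no overlap between cell-level and clinical subjects")

    high = (merged["marker_value"].to_numpy() > frozen.cutoff).astype(int)
    if high.sum() in (0, len(high)):
        raise ValueError(
            "cutoff-outside-external-range: frozen cutoff "
            f"{frozen.cutoff:g} puts all external subjects on one side"
        )
    merged["marker_high"] = high
    outcome = OutcomeSpec.survival(
        merged[duration_col].to_numpy(dtype=float),
        merged[event_col].to_numpy(),
    )
    univariable = estimate_effect(high, outcome)

    km = km_estimate(
        outcome.time, outcome.event,
        np.where(high == 1, "High", "Low"),
    )

    multivariable = None
    coef_table = None
    retained: tuple[str, ...] = ()
    covariate_cols = list(covariate_cols or [])
    strata_cols = [strata] if isinstance(strata, str) else list(strata or [])
    n_excluded = 0
    if covariate_cols or strata_cols:
        needed = covariate_cols + strata_cols
        complete = merged.dropna(subset=needed)
        n_excluded = len(merged) - len(complete)
        if n_excluded:
            logger.info(
                "complete-case multivariable model: excluded %d subject(s) "
                "with missing covariates", n_excluded,
            )
        kept = _parsimonious_covariates(
            complete, duration_col, event_col, covariate_cols, strata or None
        )
        retained = tuple(kept)
        multivariable, coef_table = multivariable_cox(
            complete, "marker_high", duration_col, event_col, kept,
            strata=strata,
        )
    else:
        multivariable, coef_table = multivariable_cox(
            merged, "marker_high", duration_col, event_col, [],
        )

    return ValidationReport(
        cutoff=frozen,
        n_analyzed=len(merged),
        n_high=int(high.sum()),
        n_low=int(len(high) - high.sum()),
        univariable=univariable,
        multivariable=multivariable,
        coefficient_table=coef_table,
        retained_covariates=retained,
        km_curves=km,
        n_excluded_missing=n_excluded,
    )
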