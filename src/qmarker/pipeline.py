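"""End-to-end screening and validation runs over files on disk.

``run_screen`` executes the whole screening workflow for one marker
(one cell-level table): QC filtering -> quantile features -> repeated
split-sample selection -> bootstrap optimism correction for the top-ranked
quantiles -> frozen cutoffs, writing machine-readable reports plus a
provenance manifest.  ``run_validate`` replays frozen cutoffs against an
external cohort.

Reports are deterministic byte-for-byte given (inputs, config, seeds):
JSON is written with sorted keys and no timestamps; the frozen-cutoffs file
carries a SHA-256 checksum of its payload, which ``run_validate`` verifies
before trusting the cutoffs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .optimism import bootstrap_optimism
from .outcomes import OutcomeSpec
from .quantiles import (
    DEFAULT_GRID,
    QuantileGrid,
    build_quantile_matrix,
    compartment_mean,
    qc_filter,
    read_cell_table,
)
from .selection import SplitConfig, select_optimal
from .validation import CCMSI, FrozenCutoff, derive_cutoffs, validate_external

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_screen", "run_validate"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a screening / validation run."""

    cells: str | None = None
    clinical: str | None = None
    external_cells: str | None = None
    external_clinical: str | None = None
    out_dir: str = "qmarker_out"
    marker: str = "marker"
    outcome_kind: str = "survival"
    subject_col: str = "subject_id"
    intensity_col: str = "intensity"
    duration_col: str = "time"
    event_col: str = "event"
    value_col: str = "value"
    grid: tuple[float, ...] | None = None
    min_cells: int = 20
    log_transform: bool = False
    train_fraction: float = 0.8
    n_splits: int = 100
    n_boot: int = 200
    top_k: int = 3
    min_per_side: int | None = None
    valid_fraction: float = 0.5
    seed: int = 0
    covariates: tuple[str, ...] = ()
    strata: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("grid", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def split_config(self) -> SplitConfig:
        return SplitConfig(
            train_fraction=self.train_fraction,
            n_splits=self.n_splits,
            master_seed=self.seed,
            min_per_side=self.min_per_side,
            valid_fraction=self.valid_fraction,
        )

    def quantile_grid(self) -> QuantileGrid:
        if self.grid is None:
            return DEFAULT_GRID
        return QuantileGrid(np.asarray(self.grid, dtype=float))


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=2, allow_nan=False)


def _sanitize(obj):
    """Replace NaN/inf with None so reports are strict JSON."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(_canonical_json(_sanitize(obj)) + "\n")


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_outcome(cfg: RunConfig, clinical: pd.DataFrame) -> None:
    """Validate that the clinical table carries the configured outcome."""
    need = [cfg.subject_col]
    if cfg.outcome_kind == "survival":
        need += [cfg.duration_col, cfg.event_col]
    elif cfg.outcome_kind == "binary":
        need += [cfg.event_col]
    else:
        need += [cfg.value_col]
    missing = [c for c in need if c not in clinical.columns]
    if missing:
        raise KeyError(f"clinical table missing column(s): {missing}")


def _aligned_outcome(cfg: RunConfig, clinical: pd.DataFrame,
                     subject_ids) -> OutcomeSpec:
    clin = clinical.set_index(clinical[cfg.subject_col].astype(str))
    clin = clin.loc[list(subject_ids)]
    if cfg.outcome_kind == "survival":
        return OutcomeSpec.survival(
            clin[cfg.duration_col].to_numpy(dtype=float),
            clin[cfg.event_col].to_numpy(),
        )
    if cfg.outcome_kind == "binary":
        return OutcomeSpec.binary(clin[cfg.event_col].to_numpy())
    return OutcomeSpec.continuous(clin[cfg.value_col].to_numpy(dtype=float))


def run_screen(cfg: RunConfig) -> dict:
    """Execute the screening workflow; write reports under ``cfg.out_dir``.

    Returns the report bundle as a dict (the same content that is written
    to disk).
    """
    if cfg.cells is None or cfg.clinical is None:
        raise ValueError("screen requires cells and clinical paths")
    clinical = pd.read_csv(cfg.clinical)
    _load_outcome(cfg, clinical)  # validation-first: fail before computing

    samples = read_cell_table(
        cfg.cells,
        subject_col=cfg.subject_col,
        intensity_col=cfg.intensity_col,
        log_transform=cfg.log_transform,
    )
    n_before = len(samples)
    samples = qc_filter(samples, cfg.min_cells)
    clinical_ids = set(clinical[cfg.subject_col].astype(str))
    matched = [s for s in samples if s.subject_id in clinical_ids]
    dropped_clinical = len(samples) - len(matched)
    if dropped_clinical:
        logger.warning("%d QC-passing subject(s) absent from the clinical table",
                       dropped_clinical)
    if not matched:
        raise ValueError("no subject has both cell-level and clinical data")

    grid = cfg.quantile_grid()
    qm = build_quantile_matrix(matched, grid)
    outcome = _aligned_outcome(cfg, clinical, qm.subject_ids)
    split_cfg = cfg.split_config()
    selection = select_optimal(qm, outcome, split_cfg)

    top = [float(p) for p in selection.top_probabilities[: cfg.top_k]]
    optimism = {}
    for p in top:
        report = bootstrap_optimism(
            qm.column(p), outcome, n_boot=cfg.n_boot, seed=cfg.seed,
            min_per_side=cfg.min_per_side,
        )
        optimism[f"{p:g}"] = report.to_dict()

    prov = {
        "marker": cfg.marker,
        "seed": cfg.seed,
        "n_splits": cfg.n_splits,
        "cells_sha256": _file_sha256(cfg.cells),
    }
    cutoffs: list[dict] = []
    for p in top:
        app, med = derive_cutoffs(
            qm.column(p), outcome, split_cfg, marker=cfg.marker,
            probability=p, provenance=prov,
        )
        cutoffs += [app.to_dict(), med.to_dict()]
    ccmsi_values = np.array([compartment_mean(s) for s in matched])
    app, med = derive_cutoffs(
        ccmsi_values, outcome, split_cfg, marker=cfg.marker,
        probability=CCMSI, provenance=prov,
    )
    cutoffs += [app.to_dict(), med.to_dict()]

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = qm.to_frame()
    features["ccmsi"] = ccmsi_values
    features["n_cells"] = [s.n_cells for s in matched]
    features.to_csv(out / "quantile_matrix.csv", float_format="%.10g")
    selection_dict = selection.to_dict()
    _write_json(out / "selection.json", selection_dict)
    selection.detail_frame().to_csv(out / "selection_detail.csv", index=False,
                                    float_format="%.10g")
    _write_json(out / "optimism.json", optimism)

    cutoff_payload = _canonical_json(_sanitize({"cutoffs": cutoffs}))
    cutoff_doc = {"cutoffs": _sanitize(cutoffs), "sha256": _sha256_text(cutoff_payload)}
    (out / "frozen_cutoffs.json").write_text(
        _canonical_json(cutoff_doc) + "\n"
    )

    manifest = {
        "config": _sanitize(asdict(cfg)),
        "inputs": {
            "cells_sha256": _file_sha256(cfg.cells),
            "clinical_sha256": _file_sha256(cfg.clinical),
        },
        "grid": [float(p) for p in grid.probabilities],
        "qc": {
            "n_samples_read": n_before,
            "n_after_qc": len(samples),
            "n_analyzed": qm.n_subjects,
            "n_without_clinical": dropped_clinical,
        },
        "invalid_split_counts": {
            f"{p:g}": int(cfg.n_splits - c)
            for p, c in zip(selection.probabilities, selection.valid_counts)
        },
        "seeds": {"master_seed": cfg.seed},
    }
    _write_json(out / "manifest.json", manifest)

    return {
        "selection": selection_dict,
        "optimism": optimism,
        "cutoffs": cutoffs,
        "manifest": manifest,
    }


def _verify_cutoffs_file(path: str | Path) -> list[FrozenCutoff]:
    doc = json.loads(Path(path).read_text())
    payload = _canonical_json({"cutoffs": doc["cutoffs"]})
    if _sha256_text(payload) != doc.get("sha256"):
        raise ValueError(
            f"{Path(path).name}: checksum mismatch — the frozen cutoffs "
            "were not produced by run_screen or were edited afterwards"
        )
    return [FrozenCutoff.from_dict(d) for d in doc["cutoffs"]]


def run_validate(cfg: RunConfig, cutoffs_path: str | Path,
                 cutoff_type: str = "apparent") -> dict:
    """Validate frozen cutoffs on the external cohort.

    Each frozen marker (quantile probabilities and the ccMSI comparator) is
    evaluated univariably and multivariably; per-marker degeneracies (e.g. a
    cutoff outside the external marker range) are reported as flags while
    the remaining markers are still processed.
    """
    if cfg.external_cells is None or cfg.external_clinical is None:
        raise ValueError("validate requires external_cells and external_clinical")
    cutoffs = _verify_cutoffs_file(cutoffs_path)
    cutoffs = [c for c in cutoffs if c.cutoff_type == cutoff_type]
    if not cutoffs:
        raise ValueError(f"no cutoffs of type {cutoff_type!r} in the file")
    clinical = pd.read_csv(cfg.external_clinical)
    _load_outcome(cfg, clinical)
    samples = read_cell_table(
        cfg.external_cells,
        subject_col=cfg.subject_col,
        intensity_col=cfg.intensity_col,
        log_transform=cfg.log_transform,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, dict] = {}
    for fc in cutoffs:
        key = f"{fc.marker}_q{fc.probability}" if fc.probability != CCMSI \
            else f"{fc.marker}_ccmsi"
        try:
            rep = validate_external(
                fc, samples, clinical,
                subject_col=cfg.subject_col,
                duration_col=cfg.duration_col,
                event_col=cfg.event_col,
                covariate_cols=list(cfg.covariates),
                strata=cfg.strata,
                min_cells=cfg.min_cells,
            )
            reports[key] = rep.to_dict()
            km_rows = []
            for label, curve in rep.km_curves.items():
                for t, s, r in zip(curve["time"], curve["survival"],
                                   curve["at_risk"]):
                    km_rows.append({"group": label, "time": t,
                                    "survival": s, "at_risk": r})
            pd.DataFrame(km_rows).to_csv(
                out / f"km_{key}.csv", index=False, float_format="%.10g"
            )
        except ValueError as exc:
            logger.warning("marker %s skipped: %s", key, exc)
            reports[key] = {"cutoff": fc.to_dict(), "error": str(exc)}
    bundle = {
        "cutoff_type": cutoff_type,
        "markers": reports,
        "inputs": {
            "external_cells_sha256": _file_sha256(cfg.external_cells),
            "external_clinical_sha256": _file_sha256(cfg.external_clinical),
        },
    }
    _write_json(out / "validation.json", bundle)
    return bundle
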