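"""Frozen cutoffs, external-cohort validation, Kaplan-Meier curves."""

import numpy as np
import pandas as pd
import pytest

from conftest import cells_to_samples, cohort_outcome

from qmarker import (
    CellSample,
    FrozenCutoff,
    OutcomeSpec,
    SimConfig,
    SplitConfig,
    cox_loghr,
    derive_cutoffs,
    km_estimate,
    marker_values,
    optimal_cutpoint,
    simulate_cohort,
    validate_external,
)


class TestDeriveCutoffs:
    def test_apparent_type_is_full_sample_cutpoint(self, small_cohort):
        x = small_cohort["qm"].column(0.30)
        y = small_cohort["outcome"]
        cfg = SplitConfig(n_splits=20, master_seed=2)
        app, med = derive_cutoffs(x, y, cfg, probability=0.30)
        assert app.cutoff == optimal_cutpoint(x, y).cutoff
        assert app.cutoff_type == "apparent"
        assert med.cutoff_type == "median_training"
        assert med.provenance["master_seed"] == 2

    def test_identical_training_cutoffs_collapse_to_apparent(self, rng):
        # two-valued marker: the gap midpoint is the only candidate, so all
        # training cutoffs coincide and the median equals the apparent one
        x = np.r_[np.zeros(60), np.full(60, 10.0)]
        hi = (x > 5).astype(int)
        t = rng.exponential(10.0 / np.exp(0.9 * hi))
        c = rng.exponential(30.0, 120)
        y = OutcomeSpec.survival(np.minimum(t, c), (t <= c).astype(int))
        app, med = derive_cutoffs(x, y, SplitConfig(n_splits=30, master_seed=1))
        assert app.cutoff == 5.0
        assert med.cutoff == app.cutoff

    def test_deterministic_pair(self, small_cohort):
        x = small_cohort["qm"].column(0.30)
        y = small_cohort["outcome"]
        cfg = SplitConfig(n_splits=10, master_seed=8)
        assert derive_cutoffs(x, y, cfg) == derive_cutoffs(x, y, cfg)


class TestMarkerValues:
    def test_quantile_and_ccmsi_paths(self):
        s = CellSample("A", np.arange(1.0, 41.0))
        q = marker_values([s], 0.5, min_cells=20)
        assert q["A"] == 20.0  # ceil(40*0.5) = 20th order statistic
        m = marker_values([s], "ccmsi", min_cells=20)
        assert m["A"] == pytest.approx(20.5)

    def test_multiple_samples_per_subject_are_averaged(self):
        s1 = CellSample("A", np.full(25, 10.0))
        s2 = CellSample("A", np.full(25, 20.0))
        vals = marker_values([s1, s2], "ccmsi", min_cells=20)
        assert vals["A"] == pytest.approx(15.0)
        assert len(vals) == 1


class TestKaplanMeier:
    def test_toy_product_limit(self):
        curves = km_estimate([1.0, 2.0, 3.0], [1, 0, 1], ["g", "g", "g"])
        c = curves["g"]
        lookup = dict(zip(c["time"], c["survival"]))
        assert lookup[0.0] == 1.0
        assert lookup[1.0] == pytest.approx(2.0 / 3.0)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_no_censoring_reduces_to_ecdf_complement(self, rng):
        t = rng.exponential(5.0, 200)
        curves = km_estimate(t, np.ones(200, dtype=int), np.full(200, "all"))
        c = curves["all"]
        for time, surv in zip(c["time"], c["survival"]):
            assert surv == pytest.approx(np.mean(t > time), abs=1e-12)

    def test_curves_non_increasing_and_at_risk_counts(self, small_cohort):
        y = small_cohort["outcome"]
        group = np.where(
            small_cohort["qm"].column(0.30)
            > np.median(small_cohort["qm"].column(0.30)),
            "High", "Low",
        )
        curves = km_estimate(y.time, y.event, group)
        assert set(curves) == {"High", "Low"}
        for c in curves.values():
            surv = np.asarray(c["survival"])
            assert np.all(np.diff(surv) <= 1e-12)
            assert np.all((surv >= 0) & (surv <= 1))
            assert c["at_risk"][0] == len(surv) * 0 + c["at_risk"][0]  # present

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1], ["a", "a"])


@pytest.fixture(scope="module")
def external_setup():
    """Frozen cutoff from a screening cohort plus an external cohort sharing
    the same generating process (true dichotomized HR known)."""
    scr_cfg = SimConfig(n_subjects=150, cells_per_subject=(60, 120), seed=21)
    scr_cells, scr_clin, _ = simulate_cohort(scr_cfg)
    scr_samples = cells_to_samples(scr_cells)
    x = marker_values(scr_samples, 0.30)
    y = cohort_outcome(scr_clin)
    app, _ = derive_cutoffs(
        x.to_numpy(), y, SplitConfig(n_splits=20, master_seed=21),
        marker="sim", probability=0.30,
    )
    ext_cfg = SimConfig(n_subjects=160, cells_per_subject=(60, 120), seed=22)
    ext_cells, ext_clin, _ = simulate_cohort(ext_cfg)
    return app, cells_to_samples(ext_cells), ext_clin


class TestValidateExternal:
    def test_univariable_matches_cox_composition(self, external_setup):
        frozen, samples, clinical = external_setup
        rep = validate_external(frozen, samples, clinical)
        vals = marker_values(samples, 0.30)
        merged = clinical.set_index("subject_id").join(vals.rename("v"), how="inner")
        high = (merged["v"].to_numpy() > frozen.cutoff).astype(int)
        est = cox_loghr(high, merged["time"].to_numpy(), merged["event"].to_numpy())
        assert rep.univariable.log_effect == pytest.approx(est.log_effect)
        assert rep.n_high + rep.n_low == rep.n_analyzed
        assert set(rep.km_curves) == {"High", "Low"}

    def test_cutoff_outside_external_range_errors(self, external_setup):
        frozen, samples, clinical = external_setup
        broken = FrozenCutoff(
            frozen.marker, frozen.probability, cutoff=1e12,
            cutoff_type="apparent", provenance=frozen.provenance,
        )
        with pytest.raises(ValueError, match="cutoff-outside-external-range"):
            validate_external(broken, samples, clinical)

    def test_parsimonious_model_drops_noise_covariate(self, external_setup):
        frozen, samples, clinical = external_setup
        rng = np.random.default_rng(5)
        clin = clinical.copy()
        # strong covariate: built from the realized hazard ordering
        clin["riskscore"] = -np.log(clin["time"] + 1) + rng.normal(0, 0.3, len(clin))
        clin["pure_noise"] = rng.normal(size=len(clin))
        rep = validate_external(
            frozen, samples, clin, covariate_cols=["riskscore", "pure_noise"]
        )
        assert "riskscore" in rep.retained_covariates
        assert "pure_noise" not in rep.retained_covariates
        assert rep.multivariable is not None
        assert "marker_high" in rep.coefficient_table.index

    def test_frozen_cutoff_provenance_is_carried_through(self, external_setup):
        frozen, samples, clinical = external_setup
        rep = validate_external(frozen, samples, clinical)
        assert rep.cutoff.provenance == frozen.provenance
        assert rep.cutoff.cutoff == frozen.cutoff  # never re-fitted

    def test_recovers_generating_effect_size(self):
        # external cohort with a strong known signal at the frozen quantile
        scr = SimConfig(n_subjects=200, cells_per_subject=(60, 120), seed=31)
        cells, clin, _ = simulate_cohort(scr)
        x = marker_values(cells_to_samples(cells), 0.30)
        y = cohort_outcome(clin)
        app, _ = derive_cutoffs(x.to_numpy(), y,
                                SplitConfig(n_splits=10, master_seed=31),
                                probability=0.30)
        ext = SimConfig(n_subjects=400, cells_per_subject=(60, 120), seed=32)
        ecells, eclin, _ = simulate_cohort(ext)
        rep = validate_external(app, cells_to_samples(ecells), eclin)
        assert rep.univariable.valid
        assert rep.univariable.log_effect > 0.5  # strongly positive, as generated
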