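"""Repeated split-sampling: stratified splits, per-split records, selection."""

import numpy as np
import pytest

from qmarker import (
    OutcomeSpec,
    QuantileSelector,
    SplitConfig,
    cox_loghr,
    evaluate_split,
    optimal_cutpoint,
    select_optimal,
    stratified_split,
)


def _outcome(n_events, n_total, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    e = np.r_[np.ones(n_events), np.zeros(n_total - n_events)]
    t = rng.exponential(20, n_total) + 1
    return OutcomeSpec.survival(t, e)


class TestStratifiedSplit:
    def test_event_stratum_split_exactly(self):
        y = _outcome(10, 50)
        cfg = SplitConfig(train_fraction=0.8, master_seed=3)
        train, test = stratified_split(y, cfg, 0)
        assert y.event[train].sum() == 8  # round(0.8 * 10)
        assert (1 - y.event[train]).sum() == 32  # round(0.8 * 40)

    def test_partition_is_disjoint_and_exhaustive(self):
        y = _outcome(13, 47)
        cfg = SplitConfig(master_seed=5)
        train, test = stratified_split(y, cfg, 7)
        assert set(train) | set(test) == set(range(47))
        assert set(train) & set(test) == set()

    def test_same_seed_and_index_reproduce_the_partition(self):
        y = _outcome(10, 40)
        cfg = SplitConfig(master_seed=11)
        assert np.array_equal(
            stratified_split(y, cfg, 4)[0], stratified_split(y, cfg, 4)[0]
        )

    def test_different_indices_differ(self):
        y = _outcome(10, 40)
        cfg = SplitConfig(master_seed=11)
        assert not np.array_equal(
            stratified_split(y, cfg, 0)[0], stratified_split(y, cfg, 1)[0]
        )

    def test_tiny_stratum_is_an_error(self):
        y = _outcome(1, 30)
        with pytest.raises(ValueError, match="stratum"):
            stratified_split(y, SplitConfig(), 0)

    @pytest.mark.parametrize(
        "n_events,n_total,fraction",
        [(5, 25, 0.8), (7, 31, 0.8), (12, 100, 0.5), (30, 60, 0.75), (3, 9, 0.8)],
    )
    def test_train_counts_follow_rounding_across_shapes(
        self, n_events, n_total, fraction
    ):
        y = _outcome(n_events, n_total)
        cfg = SplitConfig(train_fraction=fraction, master_seed=1)
        train, test = stratified_split(y, cfg, 0)
        exp_ev = min(max(int(np.round(fraction * n_events)), 1), n_events - 1)
        exp_non = min(
            max(int(np.round(fraction * (n_total - n_events))), 1),
            n_total - n_events - 1,
        )
        assert y.event[train].sum() == exp_ev
        assert len(train) == exp_ev + exp_non
        assert len(test) == n_total - len(train)


class TestEvaluateSplit:
    def test_equals_manual_chain_of_cutpoint_then_cox(self, small_cohort):
        x = small_cohort["qm"].column(0.30)
        y = small_cohort["outcome"]
        cfg = SplitConfig(master_seed=2)
        train, test = stratified_split(y, cfg, 0)
        rec = evaluate_split(x, y, train, test)
        res = optimal_cutpoint(x[train], y.subset(train))
        assert rec.cutoff == res.cutoff
        est = cox_loghr(
            (x[test] > res.cutoff).astype(int), y.time[test], y.event[test]
        )
        assert rec.log_effect == pytest.approx(est.log_effect)
        # repeat is identical
        assert evaluate_split(x, y, train, test) == rec

    def test_one_sided_test_split_flagged(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(8, 1, 30), 100.0]
        y = OutcomeSpec.survival(
            rng.exponential(10 / np.exp(0.5 * (x > 4)), 61),
            np.ones(61, dtype=int),
        )
        train = np.arange(60)
        test = np.array([60])  # single subject, inevitably one-sided
        rec = evaluate_split(x, y, train, test, min_per_side=5)
        assert not rec.valid
        assert rec.reason == "one-sided-test-split"


class TestQuantileSelector:
    def test_selected_attains_max_median_and_ranking_is_permutation(
        self, small_cohort
    ):
        sel = QuantileSelector(n_splits=25, random_state=4).fit(
            small_cohort["qm"], small_cohort["outcome"]
        )
        med = sel.median_log_effects_
        finite = np.isfinite(med)
        best = np.nanmax(np.abs(med[finite]))
        j = list(sel.probabilities_).index(sel.selected_probability_)
        assert abs(med[j]) == pytest.approx(best)
        assert sorted(sel.ranking_) == sorted(sel.probabilities_)
        assert len(sel.top_probabilities_) == 3
        assert sel.top_probabilities_[0] == sel.selected_probability_

    def test_singleton_grid_selects_that_quantile(self, small_cohort):
        x = small_cohort["qm"].column(0.30).reshape(-1, 1)
        sel = QuantileSelector(n_splits=10, random_state=1).fit(
            x, small_cohort["outcome"], probabilities=[0.30]
        )
        assert sel.selected_probability_ == 0.30

    def test_shared_splits_across_quantiles(self, small_cohort):
        sel = QuantileSelector(n_splits=5, random_state=9).fit(
            small_cohort["qm"], small_cohort["outcome"]
        )
        # every quantile was evaluated on the identical partitions
        assert len(sel.splits_) == 5
        for recs in sel.records_.values():
            assert [r.split_index for r in recs] == list(range(5))

    def test_determinism_end_to_end(self, small_cohort):
        a = QuantileSelector(n_splits=8, random_state=7).fit(
            small_cohort["qm"], small_cohort["outcome"]
        )
        b = QuantileSelector(n_splits=8, random_state=7).fit(
            small_cohort["qm"], small_cohort["outcome"]
        )
        assert a.selected_probability_ == b.selected_probability_
        assert np.array_equal(
            a.median_log_effects_, b.median_log_effects_, equal_nan=True
        )

    def test_median_over_valid_splits_only(self, small_cohort):
        sel = QuantileSelector(n_splits=25, random_state=4).fit(
            small_cohort["qm"], small_cohort["outcome"]
        )
        for j, p in enumerate(sel.probabilities_):
            effs = [r.log_effect for r in sel.records_[float(p)] if r.valid]
            if np.isfinite(sel.median_log_effects_[j]):
                assert sel.median_log_effects_[j] == pytest.approx(
                    float(np.median(effs))
                )


class TestSelectOptimalFunctional:
    def test_matches_estimator_path(self, small_cohort):
        cfg = SplitConfig(n_splits=10, master_seed=3)
        res = select_optimal(small_cohort["qm"], small_cohort["outcome"], cfg)
        sel = QuantileSelector(n_splits=10, random_state=3).fit(
            small_cohort["qm"], small_cohort["outcome"]
        )
        assert res.selected_probability == sel.selected_probability_
        assert res.to_dict()["selected_hr_star"] == pytest.approx(
            np.exp(sel.selected_median_log_effect_)
        )

    def test_protective_signal_preserves_sign(self):
        from qmarker import SimConfig, simulate_cohort, build_quantile_matrix, qc_filter
        from conftest import cells_to_samples, cohort_outcome

        cfg = SimConfig(n_subjects=150, cells_per_subject=(60, 120), beta=-1.2, seed=6)
        cells, clin, _ = simulate_cohort(cfg)
        qm = build_quantile_matrix(qc_filter(cells_to_samples(cells)))
        res = select_optimal(qm, cohort_outcome(clin), SplitConfig(n_splits=30, master_seed=6))
        assert res.selected_median_log_effect < 0
        assert res.selected_hr_star < 1.0
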