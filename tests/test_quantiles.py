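"""Cell-table reading, QC filtering and empirical quantile features."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmarker import (
    DEFAULT_GRID,
    CellSample,
    QuantileFeaturizer,
    QuantileGrid,
    build_quantile_matrix,
    compartment_mean,
    empirical_quantile,
    qc_filter,
    read_cell_table,
)

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)
samples_strategy = st.lists(finite_floats, min_size=1, max_size=60)
probs_strategy = st.floats(min_value=0.001, max_value=0.999)


class TestReadCellTable:
    def test_groups_rows_by_subject(self, tmp_path):
        path = tmp_path / "cells.csv"
        pd.DataFrame(
            {
                "subject_id": ["A", "A", "A", "B", "B"],
                "cell_id": [1, 2, 3, 1, 2],
                "intensity": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        ).to_csv(path, index=False)
        samples = read_cell_table(path)
        assert [s.subject_id for s in samples] == ["A", "B"]
        assert [s.n_cells for s in samples] == [3, 2]
        # row order within subject preserved
        assert samples[0].intensities.tolist() == [1.0, 2.0, 3.0]

    def test_missing_intensity_column_is_config_error(self, tmp_path):
        path = tmp_path / "cells.csv"
        pd.DataFrame({"subject_id": ["A"], "signal": [1.0]}).to_csv(path, index=False)
        with pytest.raises(KeyError, match="intensity"):
            read_cell_table(path)

    def test_non_numeric_rows_dropped_and_counts_conserved(self, tmp_path, rng):
        n_subjects, n_rows = 100, 10_000
        subjects = rng.integers(0, n_subjects, n_rows)
        df = pd.DataFrame(
            {
                "subject_id": [f"P{s:03d}" for s in subjects],
                "intensity": rng.exponential(100.0, n_rows),
            }
        )
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        samples = read_cell_table(path)
        assert len(samples) == len(set(subjects))
        assert sum(s.n_cells for s in samples) == n_rows
        # corrupt a few rows: they are dropped, the rest survive
        df["intensity"] = df["intensity"].astype(object)
        df.loc[[5, 17, 99], "intensity"] = "not-a-number"
        df.to_csv(path, index=False)
        samples = read_cell_table(path)
        assert sum(s.n_cells for s in samples) == n_rows - 3

    def test_all_rows_unparseable_is_input_error(self, tmp_path):
        path = tmp_path / "cells.csv"
        pd.DataFrame({"subject_id": ["A"], "intensity": ["x"]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="no parseable"):
            read_cell_table(path)


class TestQcFilter:
    @pytest.mark.parametrize(
        "n_cells,kept", [(19, False), (20, True), (21, True)]
    )
    def test_twenty_cell_boundary(self, n_cells, kept):
        sample = CellSample("S", np.ones(n_cells))
        assert (sample in qc_filter([sample], min_cells=20)) is kept

    def test_empty_input_gives_empty_output(self):
        assert qc_filter([], min_cells=20) == []

    def test_min_cells_must_be_positive(self):
        with pytest.raises(ValueError):
            qc_filter([], min_cells=0)


class TestEmpiricalQuantile:
    @pytest.mark.parametrize(
        "sample,p,expected",
        [
            ([7.0], 0.3, 7.0),
            ([1, 2, 3, 4, 5], 0.5, 3.0),
            ([2, 4, 6, 8], 0.5, 4.0),  # p exactly on the k/n lattice
            ([2, 4, 6, 8], 0.26, 4.0),
            ([10, 20], 0.99, 20.0),
        ],
    )
    def test_order_statistic_convention(self, sample, p, expected):
        assert empirical_quantile(sample, p) == expected

    def test_rejects_empty_sample_and_bad_p(self):
        with pytest.raises(ValueError):
            empirical_quantile([], 0.5)
        for p in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                empirical_quantile([1.0, 2.0], p)

    @settings(derandomize=True, max_examples=200)
    @given(xs=samples_strategy, p=probs_strategy)
    def test_matches_numpy_inverted_cdf(self, xs, p):
        assert empirical_quantile(xs, p) == pytest.approx(
            float(np.quantile(xs, p, method="inverted_cdf")), rel=0, abs=0
        )

    @settings(derandomize=True, max_examples=200)
    @given(xs=samples_strategy, p1=probs_strategy, p2=probs_strategy)
    def test_monotone_in_p_and_member_of_sample(self, xs, p1, p2):
        lo, hi = sorted((p1, p2))
        qlo, qhi = empirical_quantile(xs, lo), empirical_quantile(xs, hi)
        assert qlo <= qhi
        assert qlo in xs and qhi in xs

    @settings(derandomize=True, max_examples=100)
    @given(
        xs=samples_strategy,
        p=probs_strategy,
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-1e3, max_value=1e3),
    )
    def test_scale_equivariance(self, xs, p, a, b):
        lhs = empirical_quantile([a * x + b for x in xs], p)
        rhs = a * empirical_quantile(xs, p) + b
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(xs=st.lists(finite_floats, min_size=1, max_size=41))
    def test_median_is_lower_median(self, xs):
        srt = sorted(xs)
        n = len(srt)
        lower_median = srt[(n - 1) // 2] if n % 2 == 0 else srt[n // 2]
        assert empirical_quantile(xs, 0.5) == lower_median


class TestQuantileMatrix:
    def test_default_grid_has_twenty_columns(self, small_cohort):
        qm = small_cohort["qm"]
        assert qm.values.shape[1] == 20
        assert len(DEFAULT_GRID) == 20

    def test_constant_sample_gives_constant_row(self):
        qm = build_quantile_matrix([CellSample("S", np.full(50, 3.7))])
        assert np.all(qm.values == 3.7)

    def test_matches_scalar_quantile_loop(self, rng):
        x = rng.lognormal(5, 1, 500)
        qm = build_quantile_matrix([CellSample("S", x)])
        expected = [empirical_quantile(x, p) for p in DEFAULT_GRID.probabilities]
        assert qm.values[0].tolist() == expected

    def test_rows_non_decreasing(self, small_cohort):
        assert np.all(np.diff(small_cohort["qm"].values, axis=1) >= 0)

    def test_grid_validation(self):
        for bad in ([0.2, 0.1], [0.0, 0.5], [0.5, 1.0], []):
            with pytest.raises(ValueError):
                QuantileGrid(np.asarray(bad, dtype=float))


class TestCompartmentMean:
    def test_small_examples(self):
        assert compartment_mean(CellSample("a", [2, 4, 6])) == 4.0
        assert compartment_mean(CellSample("b", [5.0])) == 5.0

    def test_matches_compensated_summation(self, rng):
        x = rng.lognormal(6, 2, 1000)
        expected = math.fsum(x) / len(x)
        assert compartment_mean(CellSample("s", x)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_bracketed_by_sample_range(self, rng):
        x = rng.exponential(10, 200)
        m = compartment_mean(CellSample("s", x))
        assert x.min() <= m <= x.max()


class TestQuantileFeaturizer:
    def test_transform_produces_wide_features(self, small_cohort):
        feat = QuantileFeaturizer(min_cells=20)
        wide = feat.fit_transform(small_cohort["cells"])
        assert list(wide.columns[:2]) == ["q05", "q10"]
        assert {"q99", "ccmsi", "n_cells"} <= set(wide.columns)
        assert len(wide) == len(small_cohort["samples"])

    def test_sklearn_param_interface(self):
        feat = QuantileFeaturizer(min_cells=30)
        assert feat.get_params()["min_cells"] == 30
        feat.set_params(log_transform=True)
        assert feat.log_transform is True

    def test_requires_expected_columns(self):
        feat = QuantileFeaturizer()
        with pytest.raises(KeyError):
            feat.fit(pd.DataFrame({"x": [1.0]}))
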