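"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from qmarker import (
    CellSample,
    OutcomeSpec,
    SimConfig,
    build_quantile_matrix,
    qc_filter,
    simulate_cohort,
)


def cells_to_samples(cell_table):
    return [
        CellSample(str(sid), grp["intensity"].to_numpy())
        for sid, grp in cell_table.groupby("subject_id", sort=False)
    ]


def cohort_outcome(clinical):
    return OutcomeSpec.survival(
        clinical["time"].to_numpy(), clinical["event"].to_numpy()
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 120-subject survival cohort with a real quantile signal."""
    cfg = SimConfig(n_subjects=120, cells_per_subject=(60, 120), seed=1)
    cell_table, clinical, truth = simulate_cohort(cfg)
    samples = qc_filter(cells_to_samples(cell_table))
    qm = build_quantile_matrix(samples)
    outcome = cohort_outcome(clinical)
    return {
        "cells": cell_table,
        "clinical": clinical,
        "truth": truth,
        "samples": samples,
        "qm": qm,
        "outcome": outcome,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
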