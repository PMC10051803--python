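"""Shared fixtures: default-scale synthetic cohorts and cross-fitted
Medical Device Scores, session-scoped because the heavier end-to-end
checks reuse them."""

from __future__ import annotations

import pytest

from mdsc import (
    Cohort,
    PatientRecord,
    crossfit_mds,
    default_config,
    generate_cohort,
    min_count_filter,
)

#: Seeds for the repeated end-to-end runs (floor/ceiling, attenuation,
#: calibration checks).
RUN_SEEDS = (101, 102, 103, 104, 105)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-size cohort (n = 1581) from the shipped calibration."""
    return generate_cohort(default_config(n_patients=1581, seed=11))


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    return min_count_filter(default_cohort, 5)


@pytest.fixture(scope="session")
def rf_oof(filtered_cohort):
    """Out-of-fold random-forest MDS for every patient."""
    return crossfit_mds(filtered_cohort, "RF", n_folds=5, seed=7)


@pytest.fixture(scope="session")
def five_runs():
    """Five independent (cohort, cross-fitted MDS) end-to-end runs."""
    runs = []
    for seed in RUN_SEEDS:
        cohort = min_count_filter(
            generate_cohort(default_config(n_patients=1581, seed=seed)), 5
        )
        runs.append((cohort, crossfit_mds(cohort, "RF", n_folds=5, seed=seed)))
    return runs


def make_toy_cohort(spec):
    """Build a small hand-written cohort.

    ``spec``: iterable of (patient_id, gmfm66, gmfcs, devices); age/sex/
    subtype filled with fixed valid values.
    """
    records = [
        PatientRecord(
            patient_id=pid,
            age=8.0,
            sex="female",
            cp_subtype="bilateral_spastic",
            gmfcs=level,
            gmfm66=float(score),
            devices=frozenset(devices),
        )
        for pid, score, level, devices in spec
    ]
    return Cohort.from_records(records)


@pytest.fixture
def toy_cohort():
    """Six patients, device B used 4 times (below the n=5 threshold)."""
    return make_toy_cohort(
        [
            ("p1", 80.0, 1, {"A", "B"}),
            ("p2", 70.0, 2, {"A", "B"}),
            ("p3", 55.0, 3, {"A", "B", "C"}),
            ("p4", 45.0, 3, {"A", "C"}),
            ("p5", 30.0, 4, {"A", "B", "C"}),
            ("p6", 15.0, 5, {"A", "C"}),
        ]
    )
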