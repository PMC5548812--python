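"""Shared fixtures: planted Sugeno truth models and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from infarctgrowth.anfis import ANFISModel, GaussianMF, Rule, predict
from infarctgrowth.growth_models import CTObservation, PatientRecord

#: Consequents of the planted three-diagonal-rule truth model.
PLANTED_CONSEQUENTS = (
    (0.5, 0.2, 1.0),
    (0.8, -0.1, 3.0),
    (-0.2, 0.4, 2.0),
)


def planted_truth_from(X: np.ndarray) -> ANFISModel:
    """Three-diagonal-rule Sugeno truth whose premises sit on X's data range.

    Using the same premise initialization the fitter would build keeps the
    truth inside the hypothesis class, so noiseless recovery is exact.
    """
    proto = ANFISModel.from_data_range(X)
    return ANFISModel(
        proto.input_names,
        proto.mfs,
        [Rule((k, k), np.array(c)) for k, c in enumerate(PLANTED_CONSEQUENTS)],
    )


@pytest.fixture(scope="session")
def planted_rates():
    """(X, y, truth): noiseless rate triples from the planted truth model."""
    rng = np.random.default_rng(3)
    X = np.column_stack(
        [rng.uniform(0.5, 12.0, 500), rng.uniform(0.5, 25.0, 500)]
    )
    truth = planted_truth_from(X)
    return X, predict(truth, X), truth


@pytest.fixture(scope="session")
def planted_cohort(planted_rates):
    """Patient records whose growth rates follow the planted truth exactly.

    Times are fixed at 6/36/74 h so v1 = igr1*t1, v2 = v1 + 30*igr2 and
    v3 = v2 + 38*igr3 reconstruct the planted rate triples exactly.
    """
    X, y, truth = planted_rates
    records = []
    for i in range(200):
        igr1, igr2, igr3 = X[i, 0], X[i, 1], y[i]
        v1 = igr1 * 6.0
        v2 = v1 + igr2 * 30.0
        v3 = max(v2 + igr3 * 38.0, 0.0)
        records.append(
            PatientRecord(
                patient_id=f"P{i:03d}",
                scans=(
                    CTObservation(v1, 6.0),
                    CTObservation(v2, 36.0),
                    CTObservation(v3, 74.0),
                ),
            )
        )
    return records, truth


def make_record(v1, t1, v2, t2, t3, v3=float("nan"), pid="X") -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        scans=(
            CTObservation(v1, t1),
            CTObservation(v2, t2),
            CTObservation(v3, t3),
        ),
    )
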