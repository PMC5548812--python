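"""Synthetic cohorts of serial CT measurements.

Real data of this kind are three (volume, time) pairs per patient: scan
times right-skewed with means around 6, 37 and 74 hours after onset, and
volumes rising from ~73 cm^3 to ~350 cm^3 with large spread.  The
generator draws the first scan time and the two inter-scan gaps from
log-normal distributions parameterized directly by target mean/SD (so the
time marginals are calibrated by construction), and derives volumes from a
latent per-patient saturating-exponential growth law

    V(t) = Vmax * (1 - exp(-k t)),

with Vmax and k log-normal across patients, followed by multiplicative
Gaussian measurement noise floored at zero.  A bounded law is used because
real infarcts plateau as the lesion fills the arterial territory.

A planted-truth mode replaces the third volume by V2 + g(IGR1, IGR2) *
(t3 - t2) for a supplied Sugeno rule model g, giving an exact ground truth
for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .anfis import ANFISModel, predict
from .errors import ConfigError
from .growth_models import CTObservation, PatientRecord

__all__ = [
    "MarginalTarget",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_planted_igr_data",
]


@dataclass(frozen=True)
class MarginalTarget:
    """Target mean/SD of one log-normal marginal (both > 0)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.sd > 0):
            raise ConfigError(
                f"log-normal target needs mean > 0 and sd > 0, got {self}"
            )

    def lognormal_params(self) -> Tuple[float, float]:
        """(mu, sigma) of the underlying normal for this mean/SD."""
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        return math.log(self.mean) - sigma2 / 2.0, math.sqrt(sigma2)


# Default time targets: first-scan time and the two inter-scan gaps.  The
# gap targets are chosen so that the implied second- and third-scan
# marginals have means 37.26 and 74.11 h and SDs ~24.5 and ~54.4 h under
# independent gaps (SD of a sum of independent gaps adds in quadrature).
_DEFAULT_T1 = MarginalTarget(6.39, 6.76)
_DEFAULT_GAP12 = MarginalTarget(30.87, 23.53)
_DEFAULT_GAP23 = MarginalTarget(36.85, 48.55)
# Growth-law defaults, calibrated by moment matching so the noiseless
# volume marginals land near 73 / 251 / 353 cm^3 on the default time grid.
_DEFAULT_VMAX = MarginalTarget(450.0, 120.0)
_DEFAULT_K = MarginalTarget(0.030, 0.012)


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort parameters.

    noise_sd is the SD of multiplicative measurement noise (fraction of the
    true volume); growth_law is 'saturating' (default), 'linear'
    (V = Vmax*k*t, unbounded) or 'logistic', selectable for stress tests.
    """

    n_patients: int = 67
    seed: int = 0
    t1: MarginalTarget = _DEFAULT_T1
    gap12: MarginalTarget = _DEFAULT_GAP12
    gap23: MarginalTarget = _DEFAULT_GAP23
    vmax: MarginalTarget = _DEFAULT_VMAX
    growth_rate: MarginalTarget = _DEFAULT_K
    noise_sd: float = 0.05
    growth_law: str = "saturating"
    planted_model: Optional[ANFISModel] = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.growth_law not in ("saturating", "linear", "logistic"):
            raise ConfigError(f"unknown growth law {self.growth_law!r}")


@dataclass
class SyntheticCohort:
    """Generated records plus the latent truth behind them.

    ``truth`` has one row per record: Vmax, k, the noiseless volumes, and a
    flag marking records whose *observed* volumes are non-monotone (possible
    under measurement noise, kept deliberately — real lesions occasionally
    measure smaller on a later scan).
    """

    records: List[PatientRecord]
    truth: pd.DataFrame


def _law(config: CohortConfig, vmax, k, t):
    if config.growth_law == "saturating":
        return vmax * (1.0 - np.exp(-k * t))
    if config.growth_law == "linear":
        return vmax * k * t
    # logistic with midpoint at 1/k hours
    return vmax / (1.0 + np.exp(-k * (t - 1.0 / k)))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort; reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    mu, sig = config.t1.lognormal_params()
    t1 = rng.lognormal(mu, sig, n)
    mu, sig = config.gap12.lognormal_params()
    t2 = t1 + rng.lognormal(mu, sig, n)
    mu, sig = config.gap23.lognormal_params()
    t3 = t2 + rng.lognormal(mu, sig, n)
    mu, sig = config.vmax.lognormal_params()
    vmax = rng.lognormal(mu, sig, n)
    mu, sig = config.growth_rate.lognormal_params()
    k = rng.lognormal(mu, sig, n)

    v1 = _law(config, vmax, k, t1)
    v2 = _law(config, vmax, k, t2)
    v3 = _law(config, vmax, k, t3)
    if config.planted_model is not None and n > 0:
        igr1 = v1 / t1
        igr2 = (v2 - v1) / (t2 - t1)
        igr3 = predict(config.planted_model, np.column_stack([igr1, igr2]))
        v3 = np.maximum(v2 + igr3 * (t3 - t2), 0.0)

    noise = rng.normal(0.0, config.noise_sd, size=(3, n)) if config.noise_sd else 0.0
    obs = np.vstack([v1, v2, v3])
    obs = np.maximum(obs * (1.0 + noise), 0.0)

    records, rows = [], []
    for i in range(n):
        rec = PatientRecord(
            patient_id=f"S{i:04d}",
            scans=(
                CTObservation(float(obs[0, i]), float(t1[i])),
                CTObservation(float(obs[1, i]), float(t2[i])),
                CTObservation(float(obs[2, i]), float(t3[i])),
            ),
        )
        records.append(rec)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "vmax": float(vmax[i]),
                "k": float(k[i]),
                "v1_true": float(v1[i]),
                "v2_true": float(v2[i]),
                "v3_true": float(v3[i]),
                "t1": float(t1[i]),
                "t2": float(t2[i]),
                "t3": float(t3[i]),
                "nonmonotone": bool(
                    obs[0, i] > obs[1, i] or obs[1, i] > obs[2, i]
                ),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "vmax", "k", "v1_true", "v2_true", "v3_true",
            "t1", "t2", "t3", "nonmonotone",
        ],
    )
    return SyntheticCohort(records=records, truth=truth)


def generate_planted_igr_data(
    n: int,
    truth_model: ANFISModel,
    noise_sd: float,
    seed: int,
    igr1_range: Tuple[float, float] = (0.5, 12.0),
    igr2_range: Tuple[float, float] = (0.5, 25.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """(IGR1, IGR2) drawn uniformly over a rectangle; IGR3 = truth + noise.

    Default ranges bracket the growth rates seen clinically (IGR1 about
    5.6 +/- 3 cm^3/h, IGR2 about 8.3 +/- 7 cm^3/h).
    """
    if n < 0 or noise_sd < 0:
        raise ConfigError("n and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [
            rng.uniform(*igr1_range, size=n),
            rng.uniform(*igr2_range, size=n),
        ]
    )
    y = predict(truth_model, X) if n else np.empty(0)
    if noise_sd > 0 and n:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return X, y
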