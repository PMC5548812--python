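"""Monte-Carlo resampling protocol for ANFIS training.

The cohort is repeatedly split at random into a training fraction (60% by
default) and a validation remainder; an ANFIS is hybrid-trained on each
training split and scored by mean squared error of the predicted third
growth rate on the validation split; the model with the lowest validation
MSE across repetitions (30 by default) is retained.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .anfis import ANFISModel, predict, train
from .errors import ConfigError, InsufficientDataError
from .growth_models import PatientRecord, compute_growth_rates, igr3_to_volume

__all__ = [
    "MCSConfig",
    "MCSResult",
    "HoldoutEvaluation",
    "split_cohort",
    "igr_matrix",
    "run_mcs",
    "evaluate_holdout",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCSConfig:
    """Configuration of the Monte-Carlo training protocol.

    ``rounding="ceil"`` makes a 67-patient cohort split 41/26 (the
    training-side size is rounded up); ``"half-up"`` rounds to nearest.
    """

    repetitions: int = 30
    train_fraction: float = 0.60
    seed: int = 0
    rounding: str = "ceil"
    n_mf: int = 3
    rule_base: str = "diagonal"
    order: int = 1
    epochs: int = 50
    step_size: float = 0.01
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must lie strictly between 0 and 1")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if self.rounding not in ("half-up", "ceil"):
            raise ConfigError("rounding must be 'half-up' or 'ceil'")


@dataclass
class MCSResult:
    """Outcome of a Monte-Carlo training run."""

    best_model: ANFISModel
    best_mse: float
    best_repetition: int
    mse_per_repetition: List[float]
    retained_mse_trace: List[float]
    split_indices: List[Tuple[np.ndarray, np.ndarray]]


@dataclass
class HoldoutEvaluation:
    """Per-patient holdout predictions with squared errors on both scales."""

    table: pd.DataFrame
    mse_igr3: float
    mse_iv3: float


def _train_size(n: int, fraction: float, rounding: str) -> int:
    if rounding == "ceil":
        k = math.ceil(n * fraction)
    else:  # round half up
        k = math.floor(n * fraction + 0.5)
    return min(max(k, 1), n - 1)


def split_cohort(
    records: Sequence,
    fraction: float = 0.60,
    rng: Optional[np.random.Generator] = None,
    rounding: str = "half-up",
) -> Tuple[list, list]:
    """Random disjoint, exhaustive train/validation partition of a cohort."""
    n = len(records)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 records to split, got {n}")
    if not (0.0 < fraction < 1.0):
        raise ConfigError("fraction must lie strictly between 0 and 1")
    rng = rng if rng is not None else np.random.default_rng()
    perm = rng.permutation(n)
    k = _train_size(n, fraction, rounding)
    train_idx, val_idx = perm[:k], perm[k:]
    return [records[i] for i in train_idx], [records[i] for i in val_idx]


def igr_matrix(records: Sequence[PatientRecord]) -> Tuple[np.ndarray, np.ndarray]:
    """(IGR1, IGR2) design matrix and IGR3 target vector for complete records."""
    X, y = [], []
    for rec in records:
        if not rec.is_complete:
            raise InsufficientDataError(
                f"record {rec.patient_id!r} lacks a measured third volume"
            )
        rates = compute_growth_rates(rec)
        X.append([rates.igr1, rates.igr2])
        y.append(rates.igr3)
    return np.array(X, dtype=float), np.array(y, dtype=float)


def run_mcs(records: Sequence[PatientRecord], config: MCSConfig) -> MCSResult:
    """Repeated random resampling; retain the least-validation-MSE model.

    Per repetition: re-split the cohort, hybrid-train a fresh ANFIS on the
    training side, compute the validation MSE of predicted IGR3, and keep
    the model iff its MSE is strictly lower than the incumbent's (ties keep
    the earlier model).  Repetitions whose training diverges to non-finite
    error are discarded with a warning.  Each repetition draws its own
    generator from a spawned seed sequence, so repetition k is reproducible
    in isolation.
    """
    X_all, y_all = igr_matrix(records)
    n = len(records)
    if n < 4:
        raise InsufficientDataError(f"cohort of {n} is too small for MCS")
    children = np.random.SeedSequence(config.seed).spawn(config.repetitions)

    best_model: Optional[ANFISModel] = None
    best_mse = math.inf
    best_rep = -1
    mse_per_rep: List[float] = []
    retained_trace: List[float] = []
    splits: List[Tuple[np.ndarray, np.ndarray]] = []

    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        k = _train_size(n, config.train_fraction, config.rounding)
        tr, va = perm[:k], perm[k:]
        splits.append((tr, va))
        model = ANFISModel.from_data_range(
            X_all[tr],
            n_mf=config.n_mf,
            rule_base=config.rule_base,
            order=config.order,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            train(
                model,
                X_all[tr],
                y_all[tr],
                epochs=config.epochs,
                step_size=config.step_size,
                tol=config.tol,
            )
        try:
            resid = predict(model, X_all[va]) - y_all[va]
            mse = float(np.mean(resid**2))
        except Exception as exc:  # validation point outside all rule support
            warnings.warn(
                f"repetition {rep} failed validation ({exc}); discarded",
                RuntimeWarning,
                stacklevel=2,
            )
            mse = math.nan
        if not math.isfinite(mse):
            warnings.warn(
                f"repetition {rep} produced non-finite MSE; discarded",
                RuntimeWarning,
                stacklevel=2,
            )
            mse_per_rep.append(math.nan)
            retained_trace.append(best_mse)
            continue
        mse_per_rep.append(mse)
        logger.info("MCS repetition %d: validation MSE %.6g", rep, mse)
        if mse < best_mse:
            best_model, best_mse, best_rep = model, mse, rep
        retained_trace.append(best_mse)

    if best_model is None:
        raise InsufficientDataError("every MCS repetition diverged")
    best_model.training_meta = dict(best_model.training_meta)
    best_model.training_meta.update(
        {"mcs_seed": config.seed, "mcs_repetition": best_rep}
    )
    return MCSResult(
        best_model=best_model,
        best_mse=best_mse,
        best_repetition=best_rep,
        mse_per_repetition=mse_per_rep,
        retained_mse_trace=retained_trace,
        split_indices=splits,
    )


def evaluate_holdout(
    model: ANFISModel, records: Sequence[PatientRecord]
) -> HoldoutEvaluation:
    """Predict IGR3 for each record, convert to IV3, report squared errors."""
    X, y = igr_matrix(records)
    pred_igr3 = predict(model, X)
    rows = []
    for rec, igr3_hat, igr3_true in zip(records, pred_igr3, y):
        iv3_hat = igr3_to_volume(rec.v2, float(igr3_hat), rec.t2, rec.t3)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "igr3_true": igr3_true,
                "igr3_pred": float(igr3_hat),
                "iv3_true": rec.v3,
                "iv3_pred": iv3_hat,
                "sq_err_igr3": (float(igr3_hat) - igr3_true) ** 2,
                "sq_err_iv3": (iv3_hat - rec.v3) ** 2,
            }
        )
    table = pd.DataFrame(rows)
    return HoldoutEvaluation(
        table=table,
        mse_igr3=float(table["sq_err_igr3"].mean()),
        mse_iv3=float(table["sq_err_iv3"].mean()),
    )
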