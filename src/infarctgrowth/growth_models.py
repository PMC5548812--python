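"""Closed-form infarct growth models.

Serial non-contrast CT in malignant MCA stroke yields, per patient, three
(volume, time) pairs: V1@t1, V2@t2, V3@t3, with times in hours since symptom
onset and volumes in cm^3 (1 ml == 1 cm^3).  Growth rates are finite
differences; the infarct is assumed to have volume zero at onset, so the
first growth rate is V1/t1.

Three fixed closed forms extrapolate the third-scan volume from the first
two scans (no per-patient curve fitting):

* linear      -- V3 = V2 + ((V2 - V1)/(t2 - t1)) * (t3 - t2)
* logarithmic -- V3 = V2 + (V2/t2) * ln(t3 - t2)
* exponential -- V3 = V2 + V2 * exp(-( (t3 - t1) / (100 * ln((V2-V1)/(t2-t1))) ))

The logarithmic form takes the raw hour gap as the ln argument; for gaps
under one hour the increment is negative and the prediction carries a
warning flag.  The exponential form requires a strictly positive inter-scan
slope different from 1 (ln of the slope appears in a denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

from .errors import InvalidTimeError, LogDomainError

__all__ = [
    "CTObservation",
    "PatientRecord",
    "GrowthRates",
    "GrowthModelPrediction",
    "compute_igr1",
    "compute_igr_between",
    "compute_growth_rates",
    "predict_linear",
    "predict_logarithmic",
    "predict_exponential",
    "igr3_to_volume",
    "volume_to_igr3",
]


@dataclass(frozen=True)
class CTObservation:
    """One infarct-volume measurement from one CT scan.

    volume : cm^3, finite and non-negative (NaN marks a not-yet-measured
             third scan in pure-prediction mode)
    time   : hours since stroke onset, finite and strictly positive
    """

    volume: float
    time: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time <= 0:
            raise InvalidTimeError(
                f"scan time must be finite and > 0 hours, got {self.time!r}"
            )
        if math.isnan(self.volume):
            return  # unmeasured volume (prediction target)
        if not math.isfinite(self.volume) or self.volume < 0:
            raise ValueError(
                f"infarct volume must be finite and >= 0 cm^3, got {self.volume!r}"
            )

    @property
    def is_measured(self) -> bool:
        return not math.isnan(self.volume)


@dataclass(frozen=True)
class PatientRecord:
    """Three time-ordered CT observations for one patient.

    The third scan's volume may be NaN (unmeasured) when the record is used
    purely to predict IV3; such records are rejected by training and
    evaluation code, which require ``is_complete``.
    """

    patient_id: str
    scans: Tuple[CTObservation, CTObservation, CTObservation]
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scans) != 3:
            raise ValueError(f"expected exactly 3 scans, got {len(self.scans)}")
        times = [s.time for s in self.scans]
        if not (times[0] < times[1] < times[2]):
            raise InvalidTimeError(
                f"scan times must be strictly increasing, got {times}"
            )
        if not (self.scans[0].is_measured and self.scans[1].is_measured):
            raise ValueError("first and second scan volumes must be measured")

    # Convenience accessors mirroring the field notation.
    @property
    def v1(self) -> float:
        return self.scans[0].volume

    @property
    def v2(self) -> float:
        return self.scans[1].volume

    @property
    def v3(self) -> float:
        return self.scans[2].volume

    @property
    def t1(self) -> float:
        return self.scans[0].time

    @property
    def t2(self) -> float:
        return self.scans[1].time

    @property
    def t3(self) -> float:
        return self.scans[2].time

    @property
    def is_complete(self) -> bool:
        """True when all three volumes are measured."""
        return self.scans[2].is_measured


@dataclass(frozen=True)
class GrowthRates:
    """Infarct growth rates in cm^3/hour.

    igr1 = V1/t1 (onset volume assumed zero), igr2 = (V2-V1)/(t2-t1),
    igr3 = (V3-V2)/(t3-t2).  igr3 is None when the third volume is the
    prediction target.  Rates after the first may be negative (a lesion can
    shrink between scans).
    """

    igr1: float
    igr2: float
    igr3: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("igr1", "igr2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.igr3 is not None and not math.isfinite(self.igr3):
            raise ValueError(f"igr3 must be finite, got {self.igr3!r}")


@dataclass(frozen=True)
class GrowthModelPrediction:
    """Predicted third-scan volume and the growth rate it implies.

    Invariant: predicted_iv3 == V2 + predicted_igr3 * (t3 - t2).
    ``flags`` carries soft warnings (e.g. sub-hour gap in the log model).
    """

    method: str
    predicted_iv3: float
    predicted_igr3: float
    flags: Tuple[str, ...] = ()


def compute_igr1(scan1: CTObservation) -> float:
    """First growth rate, cm^3/hour, assuming zero volume at stroke onset."""
    if scan1.time <= 0:
        raise InvalidTimeError(f"first scan time must be > 0, got {scan1.time}")
    return scan1.volume / scan1.time


def compute_igr_between(earlier: CTObservation, later: CTObservation) -> float:
    """Growth rate between two scans, cm^3/hour; negative if the lesion shrank."""
    dt = later.time - earlier.time
    if dt <= 0:
        raise InvalidTimeError(
            f"later scan must be strictly after earlier one (dt={dt})"
        )
    return (later.volume - earlier.volume) / dt


def compute_growth_rates(record: PatientRecord) -> GrowthRates:
    """All growth rates for a record; igr3 only when the third volume exists."""
    igr1 = compute_igr1(record.scans[0])
    igr2 = compute_igr_between(record.scans[0], record.scans[1])
    igr3 = (
        compute_igr_between(record.scans[1], record.scans[2])
        if record.is_complete
        else None
    )
    return GrowthRates(igr1=igr1, igr2=igr2, igr3=igr3)


def predict_linear(record: PatientRecord) -> GrowthModelPrediction:
    """Continue the scan-1 -> scan-2 slope to t3 (static-slope model)."""
    dt21 = record.t2 - record.t1
    dt32 = record.t3 - record.t2
    if dt21 <= 0 or dt32 <= 0:
        raise InvalidTimeError("need t1 < t2 < t3 for linear prediction")
    slope = (record.v2 - record.v1) / dt21
    return GrowthModelPrediction(
        method="linear",
        predicted_iv3=record.v2 + slope * dt32,
        predicted_igr3=slope,
    )


def predict_logarithmic(record: PatientRecord) -> GrowthModelPrediction:
    """Natural-logarithmic growth: increment (V2/t2) * ln(t3 - t2).

    The ln argument is the raw hour gap, so a gap under one hour yields a
    negative increment; the prediction is returned with a ``"subhour_gap"``
    flag rather than raising.
    """
    dt32 = record.t3 - record.t2
    if dt32 <= 0:
        raise InvalidTimeError("need t3 > t2 for logarithmic prediction")
    if record.t2 <= 0:
        raise InvalidTimeError("need t2 > 0 for logarithmic prediction")
    iv3 = record.v2 + (record.v2 / record.t2) * math.log(dt32)
    flags = ("subhour_gap",) if dt32 < 1.0 else ()
    return GrowthModelPrediction(
        method="logarithmic",
        predicted_iv3=iv3,
        predicted_igr3=(iv3 - record.v2) / dt32,
        flags=flags,
    )


def predict_exponential(record: PatientRecord) -> GrowthModelPrediction:
    """Exponential-decay extrapolation with the inter-scan slope inside a ln.

    Requires slope (V2-V1)/(t2-t1) > 0 and != 1; the constant 100 scales the
    time axis (the form is used exactly as published, not re-derived).
    """
    dt21 = record.t2 - record.t1
    dt32 = record.t3 - record.t2
    if dt21 <= 0 or dt32 <= 0 or record.t3 <= record.t1:
        raise InvalidTimeError("need t1 < t2 < t3 for exponential prediction")
    slope = (record.v2 - record.v1) / dt21
    if slope <= 0:
        raise LogDomainError(
            f"exponential model needs a growing lesion (slope {slope:g} <= 0)"
        )
    log_slope = math.log(slope)
    if log_slope == 0.0:
        raise ZeroDivisionError(
            "exponential model undefined at slope exactly 1 cm^3/hour (ln = 0)"
        )
    iv3 = record.v2 + record.v2 * math.exp(
        -((record.t3 - record.t1) / (100.0 * log_slope))
    )
    return GrowthModelPrediction(
        method="exponential",
        predicted_iv3=iv3,
        predicted_igr3=(iv3 - record.v2) / dt32,
    )


def igr3_to_volume(v2: float, igr3: float, t2: float, t3: float) -> float:
    """Convert a predicted third growth rate to a third-scan volume."""
    if t3 <= t2:
        raise InvalidTimeError(f"need t3 > t2, got t2={t2}, t3={t3}")
    return v2 + igr3 * (t3 - t2)


def volume_to_igr3(v2: float, v3: float, t2: float, t3: float) -> float:
    """Third growth rate implied by measured second and third volumes."""
    if t3 <= t2:
        raise InvalidTimeError(f"need t3 > t2, got t2={t2}, t3={t3}")
    return (v3 - v2) / (t3 - t2)
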