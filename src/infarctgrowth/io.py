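"""Readers, writers and the packaged 26-patient evaluation table.

Patient CSV dialect: comma-separated, UTF-8, '.' decimal, header
``patient_id,v1,t1,v2,t2,v3,t3[,extras...]``; volumes cm^3, times hours
since stroke onset.  ``v3`` may be empty for records whose third volume is
the prediction target.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import importlib.resources
import json
import math
import platform
from pathlib import Path
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy

from ._util import atomic_write_text
from .errors import InvalidTimeError
from .evaluation_stats import round_half_away, summarize_method
from .growth_models import CTObservation, PatientRecord

__all__ = [
    "REQUIRED_COLUMNS",
    "TABLE2_COLUMNS",
    "TABLE2_PRINTED_SUMMARY",
    "read_patients",
    "write_patients",
    "load_table2",
    "summarize_table2",
    "check_table2_reproduction",
    "write_manifest",
]

REQUIRED_COLUMNS = ("patient_id", "v1", "t1", "v2", "t2", "v3", "t3")

#: Fixture column per prediction method (plus the measured column).
TABLE2_COLUMNS = {
    "original": "original_iv3",
    "anfis": "anfis_iv3",
    "linear": "linear_iv3",
    "logarithmic": "log_iv3",
    "exponential": "exp_iv3",
}

#: Printed footer of the published 26-patient table: per column the
#: paired-test P value, population skewness, non-excess kurtosis and
#: Pearson correlation with the measured column, all at 2 dp, plus the
#: measured column's printed mean +/- sample SD.
TABLE2_PRINTED_SUMMARY = {
    "original": {"p_value": 1.00, "skewness": 0.57, "kurtosis": 4.03, "crr": 1.00},
    "anfis": {"p_value": 0.32, "skewness": 0.69, "kurtosis": 4.49, "crr": 0.82},
    "linear": {"p_value": 0.01, "skewness": 0.96, "kurtosis": 3.32, "crr": 0.48},
    "logarithmic": {"p_value": 0.00, "skewness": -0.13, "kurtosis": 2.92, "crr": 0.70},
    "exponential": {"p_value": 0.00, "skewness": 0.13, "kurtosis": 2.60, "crr": 0.63},
}
TABLE2_PRINTED_MEAN_SD = {"original": (332.01, 112.21)}


def read_patients(path) -> List[PatientRecord]:
    """Read and validate a patient CSV; raises with per-row diagnostics."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records: List[PatientRecord] = []
    problems: List[str] = []
    for i, row in df.iterrows():
        try:
            numeric = {}
            for c in ("v1", "t1", "v2", "t2", "v3", "t3"):
                val = row[c]
                if c == "v3" and (val is None or (isinstance(val, float) and math.isnan(val)) or str(val).strip() == ""):
                    numeric[c] = math.nan
                    continue
                numeric[c] = float(val)
            covariates = {c: row[c] for c in extra_cols}
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    scans=(
                        CTObservation(numeric["v1"], numeric["t1"]),
                        CTObservation(numeric["v2"], numeric["t2"]),
                        CTObservation(numeric["v3"], numeric["t3"]),
                    ),
                    covariates=covariates,
                )
            )
        except (ValueError, TypeError, InvalidTimeError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(problems))
    return records


def write_patients(records: Sequence[PatientRecord], path) -> None:
    """Write records in the standard CSV dialect (atomic)."""
    extra_keys: List[str] = []
    for rec in records:
        for key in rec.covariates:
            if key not in extra_keys:
                extra_keys.append(key)
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "v1": rec.v1, "t1": rec.t1,
            "v2": rec.v2, "t2": rec.t2,
            "v3": "" if math.isnan(rec.v3) else rec.v3,
            "t3": rec.t3,
        }
        for key in extra_keys:
            row[key] = rec.covariates.get(key, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + extra_keys)
    atomic_write_text(path, df.to_csv(index=False))


def load_table2() -> pd.DataFrame:
    """The packaged 26-patient test table, values exactly as printed.

    Columns: age, risk_factors, vessels, original_iv3, anfis_iv3,
    linear_iv3, log_iv3, exp_iv3, time_to_ct3_hours.
    """
    ref = importlib.resources.files("infarctgrowth") / "data" / "table2.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if len(df) != 26:
        raise RuntimeError(f"packaged table must have 26 rows, found {len(df)}")
    return df


def summarize_table2(
    fixture: Optional[pd.DataFrame] = None, test_kind: str = "t"
) -> pd.DataFrame:
    """Recompute the published summary block from the per-patient rows.

    One row per method with n, mean, sample SD, CRR vs the measured column,
    population skewness, non-excess kurtosis, paired-test p-value and MSE.
    """
    df = load_table2() if fixture is None else fixture
    truth = df[TABLE2_COLUMNS["original"]].to_numpy(dtype=float)
    rows = []
    for method, col in TABLE2_COLUMNS.items():
        pred = df[col].to_numpy(dtype=float)
        ev = summarize_method(method, pred, truth, test_kind=test_kind)
        rows.append(
            {
                "method": method,
                "n": ev.n,
                "mean": ev.mean,
                "sd": ev.sd,
                "crr": ev.crr,
                "skewness": ev.skewness,
                "kurtosis": ev.kurtosis,
                "p_value": ev.p_value,
                "mse": ev.mse,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def check_table2_reproduction(summary: Optional[pd.DataFrame] = None) -> List[str]:
    """Compare the recomputed block with the printed footer at 2 dp.

    Returns a list of mismatch descriptions (empty when everything printed
    is reproduced).  The printed P-value row is reported for information
    but not treated as a failure: the publication does not state which test
    produced it.
    """
    if summary is None:
        summary = summarize_table2()
    mismatches: List[str] = []
    for method, printed in TABLE2_PRINTED_SUMMARY.items():
        for stat in ("skewness", "kurtosis", "crr"):
            got = round_half_away(float(summary.loc[method, stat]), 2)
            if got != printed[stat]:
                mismatches.append(
                    f"{method} {stat}: computed {got:.2f}, printed {printed[stat]:.2f}"
                )
    for method, (mean, sd) in TABLE2_PRINTED_MEAN_SD.items():
        got_mean = round_half_away(float(summary.loc[method, "mean"]), 2)
        got_sd = round_half_away(float(summary.loc[method, "sd"]), 2)
        if got_mean != mean:
            mismatches.append(f"{method} mean: computed {got_mean}, printed {mean}")
        if got_sd != sd:
            mismatches.append(f"{method} sd: computed {got_sd}, printed {sd}")
    return mismatches


def write_manifest(out_path, params: Mapping[str, object]) -> Path:
    """Write a machine-readable reproduction manifest next to an output."""
    from . import __version__

    manifest = {
        "tool": "infarctgrowth",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    path = Path(str(out_path) + ".manifest.json")
    atomic_write_text(path, json.dumps(manifest, indent=2))
    return path


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, Path):
        return str(v)
    return repr(v)
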