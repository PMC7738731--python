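"""Long-format daily weight records and their CSV round trip.

The canonical in-memory container is a pandas DataFrame with one row per
measurement and the fixed column set ``puppy_id, litter_id, breed, sex,
day, weight_g``.  Sex is one of {male, female, unknown}; day is an integer
number of days since birth; weight is in grams on whatever scale the
breeder used (typically with 5-g divisions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DatasetError

__all__ = ["COLUMNS", "SEXES", "validate_records", "load_dataset", "export_dataset"]

COLUMNS = ["puppy_id", "litter_id", "breed", "sex", "day", "weight_g"]
SEXES = ("male", "female", "unknown")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a weight-record table and return a normalized copy.

    Checks the column set, positive weights, non-negative integer days,
    recognized sex labels and uniqueness of (puppy_id, day).  Raises
    :class:`DatasetError` naming the offending row (1-based data row,
    header excluded) on the first violation.
    """
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    df = records[COLUMNS].copy()
    if len(df) == 0:
        raise DatasetError("dataset contains no records")

    def fail(mask: np.ndarray, what: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask)[0])
            raise DatasetError(f"{what} at data row {row + 1}")

    day = pd.to_numeric(df["day"], errors="coerce")
    fail(day.isna().to_numpy(), "non-numeric day")
    fail((day < 0).to_numpy(), "negative day")
    fail((day != day.round()).to_numpy(), "non-integer day")
    df["day"] = day.astype(int)

    weight = pd.to_numeric(df["weight_g"], errors="coerce")
    fail(weight.isna().to_numpy(), "non-numeric weight_g")
    fail((weight <= 0).to_numpy(), "non-positive weight_g")
    df["weight_g"] = weight.astype(float)

    sex = df["sex"].astype(str)
    fail(~sex.isin(SEXES).to_numpy(), f"sex not in {SEXES}")
    df["sex"] = sex

    dup = df.duplicated(subset=["puppy_id", "day"])
    fail(dup.to_numpy(), "duplicate (puppy_id, day)")
    return df.reset_index(drop=True)


def load_dataset(path) -> pd.DataFrame:
    """Read a weight-record CSV and validate it."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV, unreadable file
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    return validate_records(df)


def export_dataset(records: pd.DataFrame, path) -> None:
    """Write a validated weight-record table to CSV with the fixed header."""
    validate_records(records).to_csv(path, index=False)
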