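"""CSV input/output with strict schema validation for sample tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dissolution import GROWTH_FORMS, POROSITY_CLASSES, SAMPLE_COLUMNS, TREATMENTS

__all__ = ["SampleSchemaError", "read_samples", "write_samples", "validate_samples"]

_NUMERIC = ["w0_g", "w1_g", "surface_area_cm2", "volume_ml", "duration_d"]
_POSITIVE = ["w0_g", "surface_area_cm2", "volume_ml", "duration_d"]
_ENUMS = {
    "growth_form": GROWTH_FORMS,
    "porosity_class": POROSITY_CLASSES,
    "treatment": TREATMENTS,
}


class SampleSchemaError(ValueError):
    """Raised for a sample table violating the documented CSV schema."""


def validate_samples(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate schema and invariants; returns the table with numeric dtypes enforced."""
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSchemaError(f"{source}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    if extra:
        raise SampleSchemaError(f"{source}: unknown column(s) {extra}")
    df = df[SAMPLE_COLUMNS].copy()
    problems: list[str] = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[coerced.isna()]:
            problems.append(f"row {idx}: non-numeric {col} = {df.loc[idx, col]!r}")
        df[col] = coerced
    for col in _POSITIVE:
        vals = df[col].to_numpy(dtype=float)
        for idx in df.index[(~np.isfinite(vals)) | (vals <= 0)]:
            problems.append(f"row {idx}: {col} must be > 0, got {df.loc[idx, col]!r}")
    for col, allowed in _ENUMS.items():
        ok = df[col].astype(str).isin(allowed)
        for idx in df.index[~ok]:
            problems.append(f"row {idx}: {col} = {df.loc[idx, col]!r} not in {allowed}")
    if problems:
        raise SampleSchemaError(f"{source}: " + "; ".join(problems[:20]))
    return df


def read_samples(path) -> pd.DataFrame:
    """Read and validate a CoralSample CSV (UTF-8, documented header)."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    return validate_samples(df, source=str(path))


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a validated sample table as CSV (lossless round-trip)."""
    validate_samples(df).to_csv(Path(path), index=False)
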