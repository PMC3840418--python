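"""A (year, value) time series with a kind tag, shared by the sea-level and reef models."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TRAJECTORY_KINDS"]

TRAJECTORY_KINDS = ("temperature_degC", "sea_level_mm", "reef_elevation_mm")


@dataclass
class Trajectory:
    """Time series of a climate or reef quantity on a strictly increasing year grid."""

    years: np.ndarray
    values: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.years.shape != self.values.shape:
            raise ValueError("years and values must be 1-D of equal length")
        if self.years.size and not (np.diff(self.years) > 0).all():
            raise ValueError("years must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"kind must be one of {TRAJECTORY_KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.years.size

    def at(self, t) -> np.ndarray | float:
        """Linear interpolation at year(s) ``t`` (must lie inside the span)."""
        t = np.asarray(t, dtype=float)
        if (t < self.years[0]).any() or (t > self.years[-1]).any():
            raise ValueError(f"year outside trajectory span [{self.years[0]}, {self.years[-1]}]")
        out = np.interp(t, self.years, self.values)
        return float(out) if out.ndim == 0 else out

    def rate(self) -> np.ndarray:
        """Per-year rate of change by centered finite differences (one-sided at the ends)."""
        return np.gradient(self.values, self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})

    def to_csv(self, path) -> None:
        """Write as two-column CSV with the kind recorded in a header comment."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# kind: {self.kind}\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"# {key}: {val}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        path = Path(path)
        kind = None
        meta: dict = {}
        with path.open() as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            key, _, val = line.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            if key == "kind":
                kind = val
            else:
                meta[key] = val
        if kind is None:
            raise ValueError(f"{path}: missing '# kind:' header comment")
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        return cls(df["year"].to_numpy(), df["value"].to_numpy(), kind, meta)
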