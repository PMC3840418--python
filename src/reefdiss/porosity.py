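"""Reference table of scleractinian coral skeletal porosity by family.

Perforate corals (e.g. Acroporidae, Poritidae) have porous walls and
coenosteum that expose a large internal surface area to seawater; imperforate
corals (e.g. Faviidae, Pectiniidae) have fused, solid walls.  The packaged
table lists coral families, species counts and their porosity class; globally
roughly 404 species are perforate and 432 imperforate.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_porosity_table",
    "validate_porosity_table",
    "species_porosity_counts",
    "porosity_class",
]

POROSITY_CLASSES = ("perforate", "imperforate")


class PorosityTableError(ValueError):
    """Raised for a malformed porosity reference table."""


def load_porosity_table() -> pd.DataFrame:
    """Load the packaged family-level porosity reference table.

    Returns a DataFrame with columns ``family`` (unique), ``n_species``
    (non-negative int) and ``porosity`` ({perforate, imperforate}).
    """
    with resources.files("reefdiss.data").joinpath("porosity_table.csv").open("rb") as fh:
        table = pd.read_csv(fh)
    return validate_porosity_table(table)


def validate_porosity_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"family", "n_species", "porosity"}
    missing = required - set(table.columns)
    if missing:
        raise PorosityTableError(f"missing columns: {sorted(missing)}")
    if table["family"].str.lower().duplicated().any():
        dup = table.loc[table["family"].str.lower().duplicated(), "family"].tolist()
        raise PorosityTableError(f"duplicate families: {dup}")
    counts = pd.to_numeric(table["n_species"], errors="raise")
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise PorosityTableError("n_species must be non-negative integers")
    bad = set(table["porosity"].str.lower()) - set(POROSITY_CLASSES)
    if bad:
        raise PorosityTableError(f"unknown porosity classes: {sorted(bad)}")
    return table


def species_porosity_counts(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Total species per porosity class, e.g. ``{'perforate': 404, 'imperforate': 432}``."""
    if table is None:
        table = load_porosity_table()
    else:
        table = validate_porosity_table(table)
    grouped = table.groupby(table["porosity"].str.lower())["n_species"].sum()
    return {cls: int(grouped.get(cls, 0)) for cls in POROSITY_CLASSES}


def porosity_class(family: str, table: pd.DataFrame | None = None) -> str:
    """Case-insensitive family lookup; returns 'perforate', 'imperforate' or 'unknown'."""
    if table is None:
        table = load_porosity_table()
    else:
        table = validate_porosity_table(table)
    hit = table.loc[table["family"].str.lower() == family.strip().lower(), "porosity"]
    if hit.empty:
        return "unknown"
    return hit.iloc[0].lower()
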