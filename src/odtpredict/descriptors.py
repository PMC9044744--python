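"""Tablet-geometry descriptors and per-API molecular-descriptor merging.

The tablet is modelled as a flat-faced right circular cylinder whose diameter
equals the punch-die bore of the tablet press and whose height is the tablet
thickness. Derived quantities — lateral/flat/total surface area, volume, and
surface-area-to-volume ratio — are physical descriptors known to influence
disintegration (a higher surface-to-volume ratio exposes more tablet to the
medium).

Molecular descriptors of the active pharmaceutical ingredient (2-D
autocorrelations, charge indices, XLogP, ...) are *consumed* as a table keyed
by API name, not computed here: descriptor generation depends on third-party
cheminformatics software and is outside this package's contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, MergeKeyError
from .io import FormulationTable

__all__ = [
    "TabletGeometry",
    "tablet_geometry",
    "add_geometry_columns",
    "read_descriptor_table",
    "merge_api_descriptors",
    "drop_degenerate_columns",
    "GEOMETRY_COLUMNS",
]

#: Canonical names of the derived geometry columns, in output order.
GEOMETRY_COLUMNS = (
    "Lateral tablet surface area [mm2]",
    "Flat tablet surface area [mm2]",
    "Total tablet surface area [mm2]",
    "Volume (tablet) [mm3]",
    "Surface area to volume ratio [mm]",
)


@dataclass(frozen=True)
class TabletGeometry:
    """Cylinder geometry of one tablet (areas mm², volume mm³, ratio 1/mm)."""

    lateral_area: float
    flat_area: float
    total_area: float
    volume: float
    sa_to_v: float


def tablet_geometry(punch_die: float, thickness: float) -> TabletGeometry:
    """Geometry of a flat-faced cylindrical tablet.

    Parameters
    ----------
    punch_die : float
        Die bore of the tablet press in mm (equals tablet diameter).
    thickness : float
        Tablet thickness (cylinder height) in mm.
    """
    if not (punch_die > 0 and thickness > 0):
        raise DomainError(
            f"punch_die and thickness must be strictly positive, got {punch_die}, {thickness}"
        )
    r = punch_die / 2.0
    flat = 2.0 * math.pi * r * r
    lateral = math.pi * punch_die * thickness
    volume = math.pi * r * r * thickness
    total = flat + lateral
    return TabletGeometry(lateral, flat, total, volume, total / volume)


def add_geometry_columns(
    table: FormulationTable,
    die_column: str = "Punch die of tablet press [mm]",
    thickness_column: str = "Thickness [mm]",
) -> FormulationTable:
    """Append the five derived geometry columns (category ``manufacturing``)."""
    d = table.data[die_column].to_numpy(dtype=float)
    h = table.data[thickness_column].to_numpy(dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise DomainError("non-positive punch die or thickness in table")
    r = d / 2.0
    flat = 2.0 * np.pi * r**2
    lateral = np.pi * d * h
    volume = np.pi * r**2 * h
    total = flat + lateral
    out = table.data.copy()
    cats = dict(table.categories)
    for name, values in zip(GEOMETRY_COLUMNS, (lateral, flat, total, volume, total / volume)):
        out[name] = values
        cats[name] = "manufacturing"
    return FormulationTable(out, cats)


def read_descriptor_table(path: str | Path, key: str = "API name") -> pd.DataFrame:
    """Read a per-API molecular-descriptor CSV keyed by API name."""
    df = pd.read_csv(path)
    if key not in df.columns:
        raise MergeKeyError(f"descriptor table missing key column {key!r}")
    return df


def merge_api_descriptors(
    table: FormulationTable,
    descriptors: pd.DataFrame,
    key: str = "API name",
) -> FormulationTable:
    """Left-join API molecular descriptors onto the formulation table.

    Every formulation keeps its row; descriptor columns are appended with
    category ``descriptor``, and all records sharing an API share descriptor
    values exactly. A formulation whose API has no descriptor row, or a
    descriptor table with a duplicated API, raises :class:`MergeKeyError`.
    """
    api_col = table.api_column
    if api_col is None:
        raise MergeKeyError("formulation table has no API-name column to join on")
    if descriptors[key].duplicated().any():
        dupes = sorted(descriptors.loc[descriptors[key].duplicated(), key].unique())
        raise MergeKeyError(f"duplicate descriptor rows for API(s): {dupes}")
    missing = sorted(set(table.data[api_col].astype(str)) - set(descriptors[key].astype(str)))
    if missing:
        raise MergeKeyError(f"no descriptor row for API(s): {missing}")

    desc = descriptors.rename(columns={key: api_col})
    clash = [c for c in desc.columns if c != api_col and c in table.data.columns]
    if clash:
        raise MergeKeyError(f"descriptor columns already present in table: {clash}")
    merged = table.data.merge(desc, on=api_col, how="left", sort=False)
    cats = dict(table.categories)
    for c in desc.columns:
        if c != api_col:
            cats[c] = "descriptor"
    return FormulationTable(merged, cats)


def drop_degenerate_columns(
    table: FormulationTable,
    min_distinct: int = 2,
) -> tuple[FormulationTable, list[str]]:
    """Remove uninformative composition/descriptor columns.

    A column is degenerate if it has fewer than ``min_distinct`` finite
    distinct values or contains any non-finite value. Target, id, API and
    manufacturing columns are never removed. Returns the reduced table and
    the list of dropped column names.
    """
    dropped: list[str] = []
    for col in table.columns_of("composition", "descriptor"):
        vals = table.data[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or len(np.unique(vals)) < min_distinct:
            dropped.append(col)
    if not dropped:
        return table, dropped
    out = table.data.drop(columns=dropped)
    cats = {c: v for c, v in table.categories.items() if c not in dropped}
    return FormulationTable(out, cats), dropped
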