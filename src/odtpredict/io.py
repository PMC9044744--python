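"""Formulation tables: data model, CSV round-trip, preprocessing rules.

A formulation table is a wide table with one row per directly-compressed ODT
formulation: excipient mass percentages under *topological encoding* (an
absent excipient is an exact 0, never a missing value), manufacturing
parameters (tablet mass, thickness, punch die diameter, hardness), optional
per-API molecular descriptors, and the disintegration time in seconds as the
prediction target.

Preprocessing implemented here:

* exclusion of formulations whose disintegration time exceeds the
  pharmacopoeial 3-minute limit (strictly greater than 180 s; a tablet
  disintegrating in exactly 180 s is compliant and retained),
* the split of a generic colloidal-silica column into separate ``Aerosil``
  (fumed silica) and ``Colloidal silica`` variables, which differ in
  physicochemical behaviour,
* advisory validation (composition mass balance, negative values,
  manufacturing parameters outside the curated database envelope).
"""

from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, ParseError, SchemaError

__all__ = [
    "CATEGORIES",
    "ColumnRegistry",
    "FormulationRecord",
    "FormulationTable",
    "ValidationReport",
    "default_registry",
    "read_formulation_table",
    "write_formulation_table",
    "filter_by_disintegration",
    "split_silica_variable",
    "validate_table",
]

#: Recognised column categories.
CATEGORIES = ("id", "api", "composition", "manufacturing", "descriptor", "target")

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    """Normalization used for case-insensitive column matching."""
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass(frozen=True)
class ColumnRegistry:
    """Maps canonical column names to categories.

    Matching against file headers is case-insensitive after whitespace
    normalization; the canonical spelling is restored on read.
    """

    categories: Mapping[str, str]
    envelope: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise SchemaError(f"unknown category {cat!r} for column {col!r}")
        targets = [c for c, cat in self.categories.items() if cat == "target"]
        if len(targets) != 1:
            raise SchemaError(f"registry must declare exactly one target column, got {targets}")

    @property
    def target(self) -> str:
        return next(c for c, cat in self.categories.items() if cat == "target")

    @property
    def api_column(self) -> str | None:
        return next((c for c, cat in self.categories.items() if cat == "api"), None)

    def canonical(self, name: str) -> str | None:
        """Return the canonical spelling of ``name``, or None if unregistered."""
        key = _norm(name)
        for col in self.categories:
            if _norm(col) == key:
                return col
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ColumnRegistry":
        categories: dict[str, str] = {}
        for cat in CATEGORIES:
            for col in raw.get(cat, []) or []:
                categories[col] = cat
        envelope = {k: (float(v[0]), float(v[1])) for k, v in (raw.get("envelope") or {}).items()}
        return cls(categories=categories, envelope=envelope)


def default_registry() -> ColumnRegistry:
    """The packaged canonical registry (28 composition + 9 manufacturing names)."""
    text = resources.files("odtpredict.data").joinpath("column_registry.yaml").read_text("utf-8")
    return ColumnRegistry._from_mapping(yaml.safe_load(text))


@dataclass
class FormulationRecord:
    """One tablet formulation. Percentages are mass %, geometry in mm, time in s."""

    record_id: str
    api_name: str
    composition: dict[str, float]
    api_fraction: float
    tablet_mass: float
    thickness: float
    punch_die: float
    hardness: float
    disintegration_time: float


@dataclass
class FormulationTable:
    """Ordered collection of formulations backed by a pandas DataFrame.

    ``data`` holds one row per formulation; ``categories`` maps every column
    to one of :data:`CATEGORIES`. Exactly one target column is required and
    record ids must be unique.
    """

    data: pd.DataFrame
    categories: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.categories]
        if missing:
            raise SchemaError(f"columns without a declared category: {missing}")
        targets = self.columns_of("target")
        if len(targets) != 1:
            raise SchemaError(f"exactly one target column required, got {targets}")
        ids = self.data[self.id_column] if self.id_column else self.data.index
        if pd.Series(ids).duplicated().any():
            raise SchemaError("duplicate record_id values")

    # -- column accessors ---------------------------------------------------
    def columns_of(self, *cats: str) -> list[str]:
        return [c for c in self.data.columns if self.categories[c] in cats]

    @property
    def target_column(self) -> str:
        return self.columns_of("target")[0]

    @property
    def id_column(self) -> str | None:
        cols = self.columns_of("id")
        return cols[0] if cols else None

    @property
    def api_column(self) -> str | None:
        cols = self.columns_of("api")
        return cols[0] if cols else None

    @property
    def feature_columns(self) -> list[str]:
        """Model-input columns: composition, manufacturing and descriptors."""
        return self.columns_of("composition", "manufacturing", "descriptor")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def record_ids(self) -> list[str]:
        if self.id_column:
            return [str(v) for v in self.data[self.id_column]]
        return [str(i) for i in self.data.index]

    @property
    def y(self) -> np.ndarray:
        return self.data[self.target_column].to_numpy(dtype=float)

    def X(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.feature_columns
        return self.data[cols].to_numpy(dtype=float)

    def copy(self) -> "FormulationTable":
        return FormulationTable(self.data.copy(), dict(self.categories))

    def records(self) -> Iterator[FormulationRecord]:
        comp_cols = self.columns_of("composition")

        def col(row, name, default=float("nan")):
            return float(row[name]) if name in row.index else default

        for rid, (_, row) in zip(self.record_ids, self.data.iterrows()):
            yield FormulationRecord(
                record_id=rid,
                api_name=str(row[self.api_column]) if self.api_column else "",
                composition={c: float(row[c]) for c in comp_cols if c != "API [%]"},
                api_fraction=col(row, "API [%]"),
                tablet_mass=col(row, "Tablet mass [mg]"),
                thickness=col(row, "Thickness [mm]"),
                punch_die=col(row, "Punch die of tablet press [mm]"),
                hardness=col(row, "Hardness [N]"),
                disintegration_time=float(row[self.target_column]),
            )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_formulation_table(
    path: str | Path | _io.IOBase,
    registry: ColumnRegistry | None = None,
) -> FormulationTable:
    """Read a formulation CSV, restoring canonical column names and categories.

    Registered columns take their declared category; unregistered numeric
    columns are treated as molecular descriptors. Empty composition cells are
    filled with exact 0 (topological encoding); empty cells elsewhere stay
    missing. Raises :class:`SchemaError` if the target or API-name column is
    absent and :class:`ParseError` (with row and column) for non-numeric
    values in numeric columns.
    """
    registry = registry or default_registry()
    df = pd.read_csv(path, dtype=str, keep_default_na=True, skipinitialspace=True)

    rename: dict[str, str] = {}
    categories: dict[str, str] = {}
    for col in df.columns:
        canon = registry.canonical(col)
        if canon is not None:
            rename[col] = canon
            categories[canon] = registry.categories[canon]
        else:
            rename[col] = str(col).strip()
            categories[str(col).strip()] = "descriptor"
    df = df.rename(columns=rename)

    if registry.target not in df.columns:
        raise SchemaError(f"missing mandatory target column {registry.target!r}")
    api_col = registry.api_column
    if api_col is not None and api_col not in df.columns:
        raise SchemaError(f"missing mandatory column {api_col!r}")

    for col, cat in categories.items():
        if cat in ("id", "api"):
            continue
        filled = df[col]
        if cat == "composition":
            filled = filled.fillna("0")
        parsed = pd.to_numeric(filled, errors="coerce")
        bad = parsed.isna() & filled.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[i]!r} in column {col!r}, row {i + 2} of file"
            )
        df[col] = parsed
    if df[registry.target].isna().any():
        i = int(np.flatnonzero(df[registry.target].isna().to_numpy())[0])
        raise ParseError(f"missing target value in row {i + 2} of file")

    return FormulationTable(df.reset_index(drop=True), categories)


def write_formulation_table(table: FormulationTable, path: str | Path | _io.IOBase) -> None:
    """Write a formulation table as RFC-4180 CSV at full float precision."""
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing rules
# ---------------------------------------------------------------------------

def filter_by_disintegration(table: FormulationTable, max_time: float = 180.0) -> FormulationTable:
    """Drop formulations whose disintegration time *exceeds* ``max_time``.

    "Exceeds" is strict: a tablet disintegrating in exactly ``max_time``
    seconds is within the 3-minute pharmacopoeial limit and is retained.
    Row order is preserved; the operation is idempotent.
    """
    keep = table.data[table.target_column].to_numpy(dtype=float) <= max_time
    return FormulationTable(table.data.loc[keep].reset_index(drop=True), dict(table.categories))


def split_silica_variable(
    table: FormulationTable,
    silica_column: str = "Silica [%]",
    grade_column: str = "Silica grade",
    aerosil_pattern: str = "aerosil",
) -> tuple[FormulationTable, list[str]]:
    """Split a generic silica column into ``Aerosil [%]`` and ``Colloidal silica [%]``.

    Fumed silica (Aerosil) and other colloidal-silica grades behave
    differently as glidants, so they are encoded as two variables. If both
    split columns already exist the table is returned unchanged. Records with
    mass in *both* split columns are reported as warnings (the mass balance is
    still preserved). Returns ``(table, warnings)``.
    """
    warnings: list[str] = []
    aero, coll = "Aerosil [%]", "Colloidal silica [%]"
    df = table.data
    if aero in df.columns and coll in df.columns:
        both = (df[aero].to_numpy(float) > 0) & (df[coll].to_numpy(float) > 0)
        for rid in np.asarray(table.record_ids)[both]:
            warnings.append(f"record {rid}: mass in both 'Aerosil' and 'Colloidal silica'")
        return table, warnings

    norm_cols = {_norm(c): c for c in df.columns}
    sil = norm_cols.get(_norm(silica_column))
    if sil is None:
        # nothing to split
        return table, warnings
    grade = norm_cols.get(_norm(grade_column))
    if grade is None:
        raise ContractError(
            f"silica column {sil!r} present but grade annotation {grade_column!r} missing"
        )

    amounts = df[sil].to_numpy(dtype=float)
    grades = df[grade].astype(str).str.strip().str.casefold()
    is_aero = grades.str.contains(aerosil_pattern, regex=False).to_numpy()
    out = df.drop(columns=[sil, grade]).copy()
    out[aero] = np.where(is_aero, amounts, 0.0)
    out[coll] = np.where(is_aero, 0.0, amounts)
    categories = {c: v for c, v in table.categories.items() if c not in (sil, grade)}
    categories[aero] = "composition"
    categories[coll] = "composition"
    return FormulationTable(out, categories), warnings


@dataclass
class ValidationReport:
    """Advisory findings from :func:`validate_table`; never mutates data."""

    findings: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.findings

    def add(self, record_id: str, kind: str, message: str) -> None:
        self.findings.append({"record_id": record_id, "kind": kind, "message": message})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"n_findings": len(self.findings), "findings": self.findings}, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def validate_table(
    table: FormulationTable,
    tolerance: float = 2.0,
    envelope: Mapping[str, tuple[float, float]] | None = None,
) -> ValidationReport:
    """Advisory checks: mass balance, negative values, envelope violations.

    The composition of each record (API fraction plus all excipients) should
    sum to 100 ± ``tolerance`` mass %; deviations are flagged, not rejected,
    because literature-derived rows may omit trace components. Manufacturing
    parameters and the target are compared against ``envelope`` (defaults to
    the curated-database min/max).
    """
    report = ValidationReport()
    if envelope is None:
        envelope = default_registry().envelope
    comp_cols = table.columns_of("composition")
    ids = table.record_ids
    if comp_cols:
        sums = table.data[comp_cols].sum(axis=1).to_numpy(dtype=float)
        for i in np.flatnonzero(np.abs(sums - 100.0) > tolerance):
            report.add(ids[i], "composition_sum",
                       f"composition sums to {sums[i]:.2f}%, outside 100±{tolerance:g}%")
    numeric_cols = table.columns_of("composition", "manufacturing", "target", "descriptor")
    vals = table.data[numeric_cols].to_numpy(dtype=float)
    for i, j in zip(*np.nonzero(vals < 0)):
        report.add(ids[i], "negative_value", f"{numeric_cols[j]!r} = {vals[i, j]:g} is negative")
    for col, (lo, hi) in envelope.items():
        if col not in table.data.columns:
            continue
        v = table.data[col].to_numpy(dtype=float)
        for i in np.flatnonzero((v < lo) | (v > hi)):
            report.add(ids[i], "out_of_envelope",
                       f"{col!r} = {v[i]:g} outside envelope [{lo:g}, {hi:g}]")
    return report
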