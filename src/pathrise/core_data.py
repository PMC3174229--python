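"""Domain types, validation and file I/O for alien-flora species tables.

The unit of analysis is one alien (neophyte) plant species in a regional
flora, annotated with its pathway(s) of introduction, its stage along the
naturalization-invasion continuum, the calendar year of its first record in
the wild, a set of biological traits, and range measures (occupied mapping
grid cells, occupied habitat types).  Pathway membership is multi-label: a
species introduced both as an escape from cultivation and as a seed
contaminant belongs to both pathways, so per-pathway counts sum to more than
the number of species.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PATHWAYS",
    "STATUSES",
    "LIFE_FORMS",
    "LIFE_SPANS",
    "STRATEGIES",
    "DISPERSAL_MODES",
    "REPRODUCTION_MODES",
    "ORIGINS",
    "SpeciesRecord",
    "FloraTable",
    "FloraValidationError",
    "SchemaError",
    "read_flora",
    "write_flora",
    "pathway_counts",
]

PATHWAYS = ("release", "escape", "contaminant", "stowaway")
STATUSES = ("casual", "naturalized", "invasive")  # ordered along the continuum
LIFE_FORMS = ("herb", "grass", "woody")
LIFE_SPANS = ("annual", "perennial")
STRATEGIES = ("C", "R", "S")
DISPERSAL_MODES = ("wind", "water", "animal", "self", "unspecialized")
REPRODUCTION_MODES = ("seed_only", "seed_and_vegetative")
ORIGINS = ("europe", "other_continent")

MIN_RECORD_YEAR = 1500  # neophytes: introductions after 1500 A.D.

#: canonical column order of the CSV representation
_COLUMNS = (
    "species_id",
    "genus",
    "family",
    "order",
    "pathway_release",
    "pathway_escape",
    "pathway_contaminant",
    "pathway_stowaway",
    "status",
    "first_record_year",
    "life_form",
    "life_span",
    "strategy",
    "height_m",
    "reproduction",
    "propagule_size_mg",
    "dispersal",
    "origin",
    "grid_cells",
    "habitats_total",
    "habitats_seminatural",
)

_MULTI_SEP = ";"


class SchemaError(ValueError):
    """Raised when an input file lacks mandatory columns."""


class FloraValidationError(ValueError):
    """Raised when rows violate the species-record invariants.

    ``errors`` is a list of (row_label, message) pairs; row_label is the
    1-based data row number (or species_id when available).
    """

    def __init__(self, errors: Sequence[tuple[object, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


@dataclass
class SpeciesRecord:
    """One alien species with taxonomy, pathways, status, traits and range."""

    species_id: str
    genus: str
    family: str
    order: str
    pathways: frozenset = frozenset()
    status: str = "casual"
    first_record_year: int | None = None
    life_form: frozenset = frozenset()
    life_span: frozenset = frozenset()
    strategy: frozenset | None = None
    height_m: float | None = None
    reproduction: str | None = None
    propagule_size_mg: float | None = None
    dispersal: frozenset | None = None
    origin: str | None = None
    grid_cells: int | None = None
    habitats_total: int | None = None
    habitats_seminatural: int | None = None

    def __post_init__(self):
        self.pathways = frozenset(self.pathways)
        self.life_form = frozenset(self.life_form)
        self.life_span = frozenset(self.life_span)
        if self.strategy is not None:
            self.strategy = frozenset(self.strategy) or None
        if self.dispersal is not None:
            self.dispersal = frozenset(self.dispersal) or None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not self.pathways:
            errs.append("empty pathway set")
        bad = self.pathways - set(PATHWAYS)
        if bad:
            errs.append(f"unknown pathway(s) {sorted(bad)}")
        if self.status not in STATUSES:
            errs.append(f"unknown status {self.status!r}")
        if self.first_record_year is not None:
            this_year = datetime.date.today().year
            if not (MIN_RECORD_YEAR <= self.first_record_year <= this_year):
                errs.append(
                    f"first_record_year {self.first_record_year} outside "
                    f"[{MIN_RECORD_YEAR}, {this_year}]"
                )
        if self.life_form - set(LIFE_FORMS):
            errs.append(f"unknown life form(s) {sorted(self.life_form - set(LIFE_FORMS))}")
        if self.life_span - set(LIFE_SPANS):
            errs.append(f"unknown life span(s) {sorted(self.life_span - set(LIFE_SPANS))}")
        if self.strategy and self.strategy - set(STRATEGIES):
            errs.append(f"unknown strategy {sorted(self.strategy - set(STRATEGIES))}")
        if self.dispersal and self.dispersal - set(DISPERSAL_MODES):
            errs.append(f"unknown dispersal {sorted(self.dispersal - set(DISPERSAL_MODES))}")
        if self.reproduction is not None and self.reproduction not in REPRODUCTION_MODES:
            errs.append(f"unknown reproduction {self.reproduction!r}")
        if self.origin is not None and self.origin not in ORIGINS:
            errs.append(f"unknown origin {self.origin!r}")
        if self.height_m is not None and not self.height_m > 0:
            errs.append("height_m must be positive")
        if self.propagule_size_mg is not None and not self.propagule_size_mg > 0:
            errs.append("propagule_size_mg must be positive")
        for f in ("grid_cells", "habitats_total", "habitats_seminatural"):
            v = getattr(self, f)
            if v is not None and v < 0:
                errs.append(f"{f} must be non-negative")
        if (
            self.habitats_total is not None
            and self.habitats_seminatural is not None
            and self.habitats_seminatural > self.habitats_total
        ):
            errs.append(
                f"habitats_seminatural ({self.habitats_seminatural}) exceeds "
                f"habitats_total ({self.habitats_total})"
            )
        return errs


@dataclass
class FloraTable:
    """An ordered collection of species records plus provenance metadata."""

    records: list[SpeciesRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    def validate(self) -> None:
        """Raise :class:`FloraValidationError` if any record is invalid."""
        errors: list[tuple[object, str]] = []
        seen: set[str] = set()
        for i, rec in enumerate(self.records, start=1):
            label = rec.species_id or i
            for msg in rec.validate():
                errors.append((label, msg))
            if rec.species_id in seen:
                errors.append((label, "duplicate species_id"))
            seen.add(rec.species_id)
        if errors:
            raise FloraValidationError(errors)

    # -- conversion ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "species_id": r.species_id,
                    "genus": r.genus,
                    "family": r.family,
                    "order": r.order,
                    **{f"pathway_{p}": int(p in r.pathways) for p in PATHWAYS},
                    "status": r.status,
                    "first_record_year": r.first_record_year,
                    "life_form": _join(r.life_form, LIFE_FORMS),
                    "life_span": _join(r.life_span, LIFE_SPANS),
                    "strategy": _join(r.strategy, STRATEGIES),
                    "height_m": r.height_m,
                    "reproduction": r.reproduction,
                    "propagule_size_mg": r.propagule_size_mg,
                    "dispersal": _join(r.dispersal, DISPERSAL_MODES),
                    "origin": r.origin,
                    "grid_cells": r.grid_cells,
                    "habitats_total": r.habitats_total,
                    "habitats_seminatural": r.habitats_seminatural,
                }
            )
        df = pd.DataFrame(rows, columns=list(_COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: dict | None = None) -> "FloraTable":
        records = []
        for _, row in df.iterrows():
            records.append(_record_from_row(row))
        table = cls(records=records, provenance=dict(provenance or {}))
        table.validate()
        return table


def _join(values: Iterable[str] | None, order: Sequence[str]) -> str | None:
    if not values:
        return None
    vals = set(values)
    return _MULTI_SEP.join(v for v in order if v in vals)


def _split(value: object) -> frozenset | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return frozenset(str(value).split(_MULTI_SEP))


def _opt_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def _opt_float(value: object) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def _opt_int(value: object) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(round(v))


def _record_from_row(row: Mapping) -> SpeciesRecord:
    pathways = frozenset(p for p in PATHWAYS if _truthy(row.get(f"pathway_{p}")))
    return SpeciesRecord(
        species_id=str(row["species_id"]),
        genus=str(row["genus"]),
        family=str(row["family"]),
        order=str(row["order"]),
        pathways=pathways,
        status=str(row["status"]),
        first_record_year=_opt_int(row.get("first_record_year")),
        life_form=_split(row.get("life_form")) or frozenset(),
        life_span=_split(row.get("life_span")) or frozenset(),
        strategy=_split(row.get("strategy")),
        height_m=_opt_float(row.get("height_m")),
        reproduction=_opt_str(row.get("reproduction")),
        propagule_size_mg=_opt_float(row.get("propagule_size_mg")),
        dispersal=_split(row.get("dispersal")),
        origin=_opt_str(row.get("origin")),
        grid_cells=_opt_int(row.get("grid_cells")),
        habitats_total=_opt_int(row.get("habitats_total")),
        habitats_seminatural=_opt_int(row.get("habitats_seminatural")),
    )


def _truthy(value: object) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return False
    return str(value).strip() in {"1", "1.0", "True", "true", "yes"}


# -- I/O ---------------------------------------------------------------------


def read_flora(path: str | Path, schema_config: str | Path | Mapping | None = None) -> FloraTable:
    """Read a delimited species table into a validated :class:`FloraTable`.

    ``schema_config`` maps user column names to the canonical field names; it
    may be a mapping or a path to a YAML file.  A single ``pathways`` column
    holding a ``;``-delimited list is accepted as an alternative to the four
    0/1 indicator columns.  Missing values are empty cells or the literal
    ``NA``.  Rows violating the record invariants are reported with their row
    numbers via :class:`FloraValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=["NA", ""])
    if schema_config is not None:
        mapping = _load_schema_config(schema_config)
        df = df.rename(columns=mapping)
    if "pathways" in df.columns and not any(f"pathway_{p}" in df.columns for p in PATHWAYS):
        lists = df["pathways"].fillna("")
        for p in PATHWAYS:
            df[f"pathway_{p}"] = [
                int(p in str(v).split(_MULTI_SEP)) for v in lists
            ]
        df = df.drop(columns=["pathways"])
    mandatory = ["species_id", "genus", "family", "order", "status"] + [
        f"pathway_{p}" for p in PATHWAYS
    ]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    for col in _COLUMNS:
        if col not in df.columns:
            df[col] = None
    provenance = {}
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return FloraTable.from_dataframe(df, provenance=provenance)


def write_flora(table: FloraTable, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with deterministic column order.

    Provenance metadata goes to a ``<path>.provenance.json`` sidecar so that
    the CSV itself stays a plain rectangular table.
    """
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, index=False, encoding="utf-8")
    if table.provenance:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(table.provenance, indent=2, default=str))


def _load_schema_config(schema_config: str | Path | Mapping) -> dict:
    if isinstance(schema_config, Mapping):
        return dict(schema_config)
    with open(schema_config) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise SchemaError("schema config must be a mapping of column names")
    cfg = dict(cfg.get("columns", cfg))
    return {str(k): str(v) for k, v in cfg.items()}


# -- summaries ---------------------------------------------------------------


def pathway_counts(table: FloraTable) -> dict[str, tuple[int, float]]:
    """Per-pathway species counts and their share of all pathway assignments.

    Because pathway membership is multi-label, the percentage denominator is
    the total number of species-pathway assignments, not the number of
    species, so the four percentages sum to 100% up to rounding.
    """
    counts = {p: 0 for p in PATHWAYS}
    for rec in table:
        for p in rec.pathways:
            counts[p] += 1
    total = sum(counts.values())
    return {
        p: (c, round(100.0 * c / total, 1) if total else 0.0) for p, c in counts.items()
    }
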