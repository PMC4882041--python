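"""Reading, validation and filtering of the macromolecular observation database.

The database is a delimited text file in a configurable dialect (header
names and categorical spellings differ from the canonical schema; the
mapping lives in a versioned YAML config shipped with the package).
Loading produces an :class:`ObservationTable` — a validated long-format
:class:`pandas.DataFrame` plus provenance — and a :class:`ValidationReport`
enumerating every rejected row with its reason.

Analysis subsets mirror the curated study design: the *active growth*
regime keeps exponentially growing, nutrient-sufficient cultures in batch,
turbidostat or semi-continuous systems (chemostats excluded); the
*stationary* regime keeps stationary-phase batch observations.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import vocab

__all__ = [
    "DatabaseDialect",
    "ObservationTable",
    "ValidationReport",
    "read_database",
    "filter_condition",
    "phylum_analysis_sets",
    "count_summary",
    "default_dialect",
]


@dataclass(frozen=True)
class DatabaseDialect:
    """Column/value mapping from an on-disk dialect to the canonical schema."""

    columns: dict[str, str]
    values: dict[str, dict[str, str]]
    required: tuple[str, ...]
    delimiter: str = ","
    version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatabaseDialect":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            columns=dict(raw["columns"]),
            values={k: dict(v) for k, v in raw.get("values", {}).items()},
            required=tuple(raw.get("required", ())),
            delimiter=raw.get("delimiter", ","),
            version=int(raw.get("version", 1)),
        )

    def inverse_columns(self) -> dict[str, str]:
        return {v: k for k, v in self.columns.items()}

    def inverse_values(self) -> dict[str, dict[str, str]]:
        # first spelling listed for each canonical value wins on write
        out: dict[str, dict[str, str]] = {}
        for col, mapping in self.values.items():
            inv: dict[str, str] = {}
            for raw, canonical in mapping.items():
                inv.setdefault(canonical, raw)
            out[col] = inv
        return out


def default_dialect() -> DatabaseDialect:
    """The packaged dialect of the distributed database file."""
    ref = resources.files("phytomacro").joinpath("data/s1_mapping.yaml")
    with resources.as_file(ref) as path:
        return DatabaseDialect.from_yaml(path)


@dataclass
class ValidationReport:
    """Per-load accounting: every input row is either loaded or rejected."""

    n_loaded: int = 0
    n_rejected: int = 0
    n_deduplicated: int = 0
    rejection_reasons: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return self.n_loaded + self.n_rejected

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_loaded": self.n_loaded,
            "n_rejected": self.n_rejected,
            "n_deduplicated": self.n_deduplicated,
            "rejection_reasons": [
                {"row": int(i), "reason": r} for i, r in self.rejection_reasons
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


@dataclass
class ObservationTable:
    """A validated long-format observation table with provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        missing = [c for c in vocab.CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")

    def replace(self, df: pd.DataFrame) -> "ObservationTable":
        return ObservationTable(df=df.reset_index(drop=True), provenance=dict(self.provenance))

    @property
    def n_species(self) -> int:
        return int(self.df["species_key"].nunique())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


class MissingColumnsError(ValueError):
    """Mandatory columns absent from the input file."""


def _species_key(genus: pd.Series, species: pd.Series, strain: pd.Series) -> pd.Series:
    parts = [genus.fillna(""), species.fillna(""), strain.fillna("")]
    key = parts[0].str.strip()
    for p in parts[1:]:
        key = key.str.cat(p.str.strip(), sep="|")
    return key


def _map_values(raw: pd.Series, mapping: dict[str, str], allowed: Iterable[str]) -> pd.Series:
    s = raw.fillna("").astype(str).str.strip()
    mapped = s.map(mapping)
    # spellings already canonical pass through
    passthrough = s.where(s.isin(tuple(allowed)))
    return mapped.fillna(passthrough)


def read_database(
    path: str | Path,
    dialect: DatabaseDialect | None = None,
) -> tuple[ObservationTable, ValidationReport]:
    """Load and validate a database file.

    Every retained row satisfies the record invariants (known phylum,
    non-negative value, percent values ≤ 100, protein-method consistency);
    offending rows are rejected individually and enumerated in the report.
    Missing mandatory columns abort the load.
    """
    dialect = dialect or default_dialect()
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)

    missing = [c for c in dialect.required if c not in raw.columns]
    if missing:
        raise MissingColumnsError(f"input file {path} lacks mandatory columns: {missing}")

    df = pd.DataFrame(index=raw.index)
    for src, dst in dialect.columns.items():
        df[dst] = raw[src] if src in raw.columns else ""

    report = ValidationReport()
    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    # --- categorical normalisation ------------------------------------
    df["phylum"] = df["phylum"].astype(str).str.strip()
    _flag(~df["phylum"].isin(vocab.PHYLA), "unknown phylum")

    for col, allowed in (
        ("habitat", vocab.HABITATS),
        ("culture_system", vocab.CULTURE_SYSTEMS),
        ("growth_phase", vocab.GROWTH_PHASES),
        ("nutrient_status", vocab.NUTRIENT_STATUSES),
    ):
        df[col] = _map_values(df[col], dialect.values.get(col, {}), allowed)
        _flag(df[col].isna(), f"unrecognised {col}")

    df["pool"] = _map_values(df["pool"], dialect.values.get("pool", {}), vocab.POOLS)
    _flag(df["pool"].isna(), "unrecognised macromolecular pool")

    df["basis"] = _map_values(df["basis"], dialect.values.get("basis", {}), vocab.BASES)
    _flag(df["basis"].isna(), "unrecognised basis/units")

    df["protein_method"] = _map_values(
        df["protein_method"], dialect.values.get("protein_method", {}), vocab.PROTEIN_METHODS
    )
    # a method string only means something on protein rows
    df.loc[df["pool"] != "protein", "protein_method"] = "not_applicable"
    _flag(
        (df["pool"] == "protein")
        & (~df["protein_method"].isin(("peptide_or_amino_acid", "n_derived"))),
        "protein row without a usable protein method",
    )

    # --- numeric value -------------------------------------------------
    value = pd.to_numeric(df["value"], errors="coerce")
    _flag(value.isna(), "unparseable numeric value")
    _flag(value < 0, "negative value")
    _flag((df["basis"] == "percent_dry_weight") & (value > 100), "percent dry weight > 100")
    df["value"] = value

    df["species_key"] = _species_key(df["genus"], df["species"], df["strain"])
    _flag(df["species_key"].str.replace("|", "", regex=False).str.strip() == "", "missing taxon")

    bad = reasons != ""
    report.rejection_reasons = [(int(i), r) for i, r in reasons[bad].items()]
    report.n_rejected = int(bad.sum())

    kept = df.loc[~bad].copy()

    # --- deduplication (keep first occurrence, logged) ------------------
    dedup_key = list(vocab.CELL_KEY) + ["pool", "value", "replicate"]
    before = len(kept)
    kept = kept.drop_duplicates(subset=dedup_key, keep="first")
    report.n_deduplicated = before - len(kept)
    report.n_loaded = len(kept) + report.n_deduplicated  # loaded = validated rows

    kept = kept.loc[:, list(vocab.CANONICAL_COLUMNS)].reset_index(drop=True)
    table = ObservationTable(
        df=kept,
        provenance={
            "path": str(path),
            "loaded_at": _dt.datetime.now().isoformat(timespec="seconds"),
            "dialect_version": dialect.version,
            "n_input_rows": int(len(raw)),
        },
    )
    return table, report


def filter_condition(table: ObservationTable, regime: str) -> ObservationTable:
    """Restrict the table to one growth regime.

    ``active_growth``: exponential phase, nutrient-sufficient, grown in
    batch, turbidostat or semi-continuous culture. ``stationary``:
    stationary phase. Rows with unknown phase or status never qualify.
    """
    df = table.df
    if regime == "active_growth":
        mask = (
            (df["growth_phase"] == "exponential")
            & (df["nutrient_status"] == "sufficient")
            & df["culture_system"].isin(vocab.ACTIVE_GROWTH_SYSTEMS)
        )
    elif regime == "stationary":
        mask = df["growth_phase"] == "stationary"
    else:
        raise ValueError(f"unknown regime {regime!r}; expected 'active_growth' or 'stationary'")
    out = table.replace(df.loc[mask])
    out.provenance["regime"] = regime
    return out


def phylum_analysis_sets(table: ObservationTable) -> tuple[ObservationTable, ObservationTable]:
    """Split into (phylum-comparison set, grand-pool set).

    Sparsely observed phyla (Euglenozoa, Rhodophyta) are dropped from
    phylum-level comparisons but retained in the pan-microalgae pool.
    """
    df = table.df
    comparison = table.replace(df.loc[~df["phylum"].isin(vocab.COMPARISON_EXCLUDED_PHYLA)])
    grand = table.replace(df)
    return comparison, grand


def count_summary(table: ObservationTable) -> pd.DataFrame:
    """Exact observation counts per (pool, basis), totals equal table size."""
    counts = (
        table.df.groupby(["pool", "basis"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    assert int(counts["n"].sum()) == len(table)
    return counts
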