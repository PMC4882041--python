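"""Controlled vocabularies for the macromolecular observation database.

The database is a long-format table of literature measurements on
microalgae: one row per (source study, taxon, culture condition,
macromolecular pool, basis) measurement. All categorical columns are
restricted to the closed vocabularies below; loaders reject rows outside
them rather than guessing.
"""

from __future__ import annotations

# Nine phyla are admitted at load time. Euglenozoa and Rhodophyta are so
# sparsely observed that they are excluded from phylum-level comparisons,
# but they still contribute to the pan-microalgae (grand) pool.
PHYLA: tuple[str, ...] = (
    "Cyanobacteria",
    "Chlorophyta",
    "Rhodophyta",
    "Bacillariophyta",
    "Cryptophyta",
    "Dinophyta",
    "Euglenozoa",
    "Haptophyta",
    "Ochrophyta",
)

COMPARISON_EXCLUDED_PHYLA: tuple[str, ...] = ("Euglenozoa", "Rhodophyta")

POOLS: tuple[str, ...] = (
    "protein",
    "lipid",
    "carbohydrate",
    "ash",
    "RNA",
    "DNA",
    "chlorophyll_a",
)

BASES: tuple[str, ...] = ("percent_dry_weight", "mass_per_cell")

HABITATS: tuple[str, ...] = ("marine", "freshwater", "unknown")

CULTURE_SYSTEMS: tuple[str, ...] = (
    "batch",
    "turbidostat",
    "chemostat",
    "semi_continuous",
    "unknown",
)

GROWTH_PHASES: tuple[str, ...] = ("lag", "exponential", "stationary", "unknown")

NUTRIENT_STATUSES: tuple[str, ...] = ("sufficient", "limited", "starved", "unknown")

PROTEIN_METHODS: tuple[str, ...] = (
    "peptide_or_amino_acid",
    "n_derived",
    "not_applicable",
)

#: culture systems admitted into the active-growth analysis subset
#: (chemostats are excluded: steady-state dilution is not "exponential
#: batch-like" growth in the sense of the curated regimes)
ACTIVE_GROWTH_SYSTEMS: tuple[str, ...] = ("batch", "turbidostat", "semi_continuous")

RATIO_KINDS: tuple[str, ...] = ("protein_cho", "protein_lipid", "cho_lipid")

#: (numerator pool, denominator pool) per ratio kind
RATIO_POOLS: dict[str, tuple[str, str]] = {
    "protein_cho": ("protein", "carbohydrate"),
    "protein_lipid": ("protein", "lipid"),
    "cho_lipid": ("carbohydrate", "lipid"),
}

#: canonical column order of the in-memory observation table
CANONICAL_COLUMNS: tuple[str, ...] = (
    "study_id",
    "phylum",
    "genus",
    "species",
    "strain",
    "species_key",
    "habitat",
    "culture_system",
    "growth_phase",
    "nutrient_status",
    "pool",
    "basis",
    "value",
    "protein_method",
    "replicate",
)

#: columns that identify a measurement "cell": one taxon in one study
#: under one culture condition, on one basis. Ratios are only ever formed
#: inside a cell.
CELL_KEY: tuple[str, ...] = (
    "study_id",
    "species_key",
    "phylum",
    "habitat",
    "culture_system",
    "growth_phase",
    "nutrient_status",
    "basis",
)

# Nitrogen-to-protein conversion: the standard factor assumes protein is
# 16% N by mass and all cellular N is protein; the corrected factor
# discounts non-protein (mostly inorganic) N stores in eukaryotes.
STANDARD_N_FACTOR: float = 6.25
CORRECTED_N_FACTOR: float = 4.78
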