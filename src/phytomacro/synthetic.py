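"""Synthetic observation tables with the hierarchical structure the
analysis assumes, paired with their generating truth.

Each response value is drawn from the generative reading of the model:

    y = mu* + P*_phylum + S*_species + eps,   eps ~ N(0, sigma_eps*)

with phylum effects ~ N(0, sigma_P*) and species effects ~ N(0, sigma_S*).
Percent-dry-weight values are truncated at zero (with the clipping rate
reported) to stay physical while keeping the normal generative model.

Protein rows flagged as N-derived are stored pre-multiplied by 6.25/4.78
in eukaryotic phyla, so the harmonisation correction inverts them exactly
— the generator and the analysis are mutual inverses by construction.

The default designs are deliberately unbalanced (species counts per
phylum of 5–25, observation counts per species spanning two orders of
magnitude) because heavy over-representation of a few aquaculture and
biofuel species is the defining nuisance feature of the real literature
database.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .database import DatabaseDialect, ObservationTable, default_dialect

__all__ = [
    "PoolTruth",
    "SyntheticDesign",
    "SyntheticTruth",
    "generate_dataset",
    "generate_fixture_csv",
    "recovery_experiment",
    "tiny_design",
    "table3_protein_design",
    "stress_unbalanced_design",
]


@dataclass(frozen=True)
class PoolTruth:
    """Generating parameters for one macromolecular pool."""

    mu: float
    sigma_p: float
    sigma_s: float
    sigma_e: float


@dataclass(frozen=True)
class SyntheticDesign:
    """Layout and generating conditions of a synthetic dataset.

    ``obs_per_species`` gives, per phylum, the observation count of each
    species; its lengths define the species counts per phylum.
    """

    phyla: tuple[str, ...]
    obs_per_species: tuple[tuple[int, ...], ...]
    pools: dict[str, PoolTruth]
    seed: int
    frac_n_derived: float = 0.35
    marine_fraction: float = 0.75
    growth_phase: str = "exponential"
    nutrient_status: str = "sufficient"
    culture_system: str = "batch"
    basis: str = "percent_dry_weight"

    def __post_init__(self) -> None:
        if len(self.phyla) != len(self.obs_per_species):
            raise ValueError("obs_per_species must have one tuple per phylum")
        for p, counts in zip(self.phyla, self.obs_per_species):
            if len(counts) < 1 or any(n < 1 for n in counts):
                raise ValueError(f"phylum {p} needs >=1 species with >=1 observation each")
        if not self.pools:
            raise ValueError("at least one pool must be generated")

    @property
    def n_species(self) -> int:
        return sum(len(c) for c in self.obs_per_species)

    @property
    def n_obs_per_pool(self) -> int:
        return sum(sum(c) for c in self.obs_per_species)


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated table."""

    seed: int
    pools: dict[str, PoolTruth]
    phylum_effects: dict[str, dict[str, float]]   # pool -> phylum -> P*
    species_effects: dict[str, dict[str, float]]  # pool -> species_key -> S*
    n_clipped: dict[str, int]
    n_obs: dict[str, int]

    def phylum_mean(self, pool: str, phylum: str) -> float:
        return self.pools[pool].mu + self.phylum_effects[pool][phylum]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "pools": {k: asdict(v) for k, v in self.pools.items()},
            "phylum_effects": self.phylum_effects,
            "species_effects": self.species_effects,
            "n_clipped": self.n_clipped,
            "n_obs": self.n_obs,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def generate_dataset(design: SyntheticDesign) -> tuple[ObservationTable, SyntheticTruth]:
    """Simulate an observation table from a design; deterministic per seed.

    All pools share the same species and per-species observation counts,
    and the k-th observation of every pool for a given species belongs to
    the same synthetic source study — so within-study ratio pairing works
    on the generated data exactly as on the curated database.
    """
    rng = np.random.default_rng(design.seed)

    species = []  # (phylum, species_key, habitat, n_obs)
    for p_i, (phylum, counts) in enumerate(zip(design.phyla, design.obs_per_species)):
        for s_i, n in enumerate(counts):
            habitat = "marine" if rng.random() < design.marine_fraction else "freshwater"
            genus = f"Genus{p_i:02d}"
            sp = f"species{p_i:02d}_{s_i:02d}"
            species.append((phylum, genus, sp, habitat, int(n)))

    rows: list[dict] = []
    phylum_effects: dict[str, dict[str, float]] = {}
    species_effects: dict[str, dict[str, float]] = {}
    n_clipped: dict[str, int] = {}
    n_obs: dict[str, int] = {}
    # flagged rows are stored divided by the exact constant the
    # harmonisation step multiplies by, so correction inverts the
    # generator to within one ulp of floating-point rounding
    correction = vocab.CORRECTED_N_FACTOR / vocab.STANDARD_N_FACTOR

    for pool, truth in design.pools.items():
        p_eff = {p: truth.sigma_p * rng.standard_normal() for p in design.phyla}
        s_eff: dict[str, float] = {}
        clipped = 0
        count = 0
        for phylum, genus, sp, habitat, n in species:
            key = f"{genus}|{sp}|"
            s_eff[key] = truth.sigma_s * rng.standard_normal()
            values = (truth.mu + p_eff[phylum] + s_eff[key]
                      + truth.sigma_e * rng.standard_normal(n))
            if design.basis == "percent_dry_weight":
                clipped += int(np.sum(values < 0))
                values = np.clip(values, 0.0, None)
            if pool == "protein":
                n_derived = rng.random(n) < design.frac_n_derived
            else:
                n_derived = np.zeros(n, dtype=bool)
            for k in range(n):
                value = values[k]
                method = "not_applicable"
                if pool == "protein":
                    if n_derived[k]:
                        method = "n_derived"
                        if phylum != "Cyanobacteria":
                            # stored as the literature would report it:
                            # converted with the standard 6.25 factor
                            value = value / correction
                    else:
                        method = "peptide_or_amino_acid"
                rows.append({
                    "study_id": f"S{k:03d}",
                    "phylum": phylum,
                    "genus": genus,
                    "species": sp,
                    "strain": "",
                    "species_key": key,
                    "habitat": habitat,
                    "culture_system": design.culture_system,
                    "growth_phase": design.growth_phase,
                    "nutrient_status": design.nutrient_status,
                    "pool": pool,
                    "basis": design.basis,
                    "value": float(value),
                    "protein_method": method,
                    "replicate": "",
                })
            count += n
        phylum_effects[pool] = p_eff
        species_effects[pool] = s_eff
        n_clipped[pool] = clipped
        n_obs[pool] = count
        if clipped > 0.10 * count:
            warnings.warn(
                f"synthetic pool {pool!r}: {clipped}/{count} values clipped at zero "
                "(>10%); the generating parameters imply substantial negative mass",
                stacklevel=2,
            )

    df = pd.DataFrame(rows, columns=list(vocab.CANONICAL_COLUMNS))
    table = ObservationTable(df=df, provenance={"source": "synthetic", "seed": design.seed})
    truth = SyntheticTruth(
        seed=design.seed, pools=dict(design.pools),
        phylum_effects=phylum_effects, species_effects=species_effects,
        n_clipped=n_clipped, n_obs=n_obs,
    )
    return table, truth


def generate_fixture_csv(
    design: SyntheticDesign,
    path: str | Path,
    dialect: DatabaseDialect | None = None,
) -> SyntheticTruth:
    """Write a fixture file in the distributed-database dialect.

    The file round-trips through :func:`phytomacro.database.read_database`
    with zero rejections; the generating truth is written as a JSON
    sidecar next to the fixture.
    """
    dialect = dialect or default_dialect()
    table, truth = generate_dataset(design)
    inv_cols = dialect.inverse_columns()
    inv_vals = dialect.inverse_values()

    out = pd.DataFrame()
    for canonical in vocab.CANONICAL_COLUMNS:
        if canonical not in inv_cols:
            continue  # derived columns (species_key) are not part of the dialect
        col = table.df[canonical]
        if canonical in inv_vals:
            col = col.map(lambda v: inv_vals[canonical].get(v, v))
        out[inv_cols[canonical]] = col

    path = Path(path)
    out.to_csv(path, index=False, sep=dialect.delimiter)
    truth.to_json(path.with_suffix(".truth.json"))
    return truth


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _head_heavy(total: int, k: int) -> tuple[int, ...]:
    """Deterministically split ``total`` observations over ``k`` species
    with a heavy head (first species over-represented), all counts >= 1."""
    weights = np.array([1.0 / (i + 1) for i in range(k)])
    alloc = np.maximum(1, np.floor(total * weights / weights.sum()).astype(int))
    while alloc.sum() > total:
        alloc[np.argmax(alloc)] -= 1
    alloc[0] += total - alloc.sum()
    return tuple(int(a) for a in alloc)


_MAJOR_POOL_TRUTHS = {
    # medians and a 25/31-32/42-43 variance split consistent with the
    # published phylum-level meta-analysis of actively growing microalgae
    "protein": PoolTruth(mu=32.0, sigma_p=5.5, sigma_s=6.1, sigma_e=7.1),
    "carbohydrate": PoolTruth(mu=15.0, sigma_p=4.0, sigma_s=4.5, sigma_e=5.2),
    "lipid": PoolTruth(mu=17.3, sigma_p=3.8, sigma_s=4.5, sigma_e=5.0),
}


def tiny_design(seed: int = 0, pools: dict[str, PoolTruth] | None = None) -> SyntheticDesign:
    """3 phyla x 4 species x 5 observations: a seconds-scale smoke design."""
    return SyntheticDesign(
        phyla=("Cyanobacteria", "Chlorophyta", "Bacillariophyta"),
        obs_per_species=((5, 5, 5, 5),) * 3,
        pools=pools or dict(_MAJOR_POOL_TRUTHS),
        seed=seed,
    )


def table3_protein_design(seed: int = 0) -> SyntheticDesign:
    """Protein-only design shaped like the published phylum comparison:
    7 phyla with observation counts (25, 75, 16, 82, 76, 19, 22), spread
    head-heavily over realistic species counts."""
    phyla = ("Cyanobacteria", "Chlorophyta", "Cryptophyta", "Bacillariophyta",
             "Haptophyta", "Ochrophyta", "Dinophyta")
    totals = (25, 75, 16, 82, 76, 19, 22)
    n_species = (8, 21, 5, 24, 22, 6, 7)
    return SyntheticDesign(
        phyla=phyla,
        obs_per_species=tuple(_head_heavy(t, k) for t, k in zip(totals, n_species)),
        pools={"protein": _MAJOR_POOL_TRUTHS["protein"]},
        seed=seed,
    )


def stress_unbalanced_design(seed: int = 0) -> SyntheticDesign:
    """One species dominating its phylum (n = 50 vs singletons), next to a
    small balanced phylum — the pathological imbalance partial pooling
    must absorb."""
    return SyntheticDesign(
        phyla=("Haptophyta", "Chlorophyta", "Cyanobacteria"),
        obs_per_species=((50, 1, 1, 1, 1), (3, 3, 3, 3), (1, 1)),
        pools={"protein": _MAJOR_POOL_TRUTHS["protein"]},
        seed=seed,
    )


def recovery_experiment(
    n_reps: int,
    design: SyntheticDesign,
    config,
    pool: str | None = None,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Repeated generate-and-refit calibration harness.

    For each replicate, a fresh dataset is generated (replicate-specific
    seed derived from the design seed), the hierarchical model is fitted,
    and the truth is compared with the posterior. Reports bias, RMSE and
    empirical HDI coverage for the three standard deviations and for the
    phylum means (coverage averaged over phyla).
    """
    from .model import fit_hierarchical, ModelSpec
    from .summary import hdi

    if n_reps < 20:
        raise ValueError("n_reps must be >= 20 for a meaningful coverage estimate")
    pool = pool or next(iter(design.pools))

    results: dict[str, list] = {k: [] for k in ("sigma_p", "sigma_s", "sigma_e", "phylum_mean")}
    covers: dict[str, list] = {k: [] for k in results}

    for rep in range(n_reps):
        rep_design = SyntheticDesign(
            phyla=design.phyla, obs_per_species=design.obs_per_species,
            pools={pool: design.pools[pool]}, seed=int(design.seed + 1000 + rep),
            frac_n_derived=0.0, marine_fraction=design.marine_fraction,
            basis=design.basis,
        )
        table, truth = generate_dataset(rep_design)
        cfg = dataclasses.replace(config, seed=int(design.seed + 5000 + rep))
        sub = table.df.loc[table.df["pool"] == pool]
        draws, _ = fit_hierarchical(sub, ModelSpec(response="value"), cfg)

        t = truth.pools[pool]
        for name, true_val in (("sigma_p", t.sigma_p), ("sigma_s", t.sigma_s),
                               ("sigma_e", t.sigma_e)):
            flat = draws.flat(name)
            lo, hi = hdi(flat, mass)
            results[name].append(float(np.median(flat)) - true_val)
            covers[name].append(lo <= true_val <= hi)

        flat_pm = draws.flat_phylum_means()
        errs, cov = [], []
        for j, phylum in enumerate(draws.phylum_names):
            true_mean = truth.phylum_mean(pool, phylum)
            lo, hi = hdi(flat_pm[:, j], mass)
            errs.append(float(np.median(flat_pm[:, j])) - true_mean)
            cov.append(lo <= true_mean <= hi)
        results["phylum_mean"].append(float(np.mean(np.abs(errs))))
        covers["phylum_mean"].append(float(np.mean(cov)))

    rows = []
    for name in ("sigma_p", "sigma_s", "sigma_e", "phylum_mean"):
        err = np.asarray(results[name], float)
        rows.append({
            "parameter": name,
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "coverage": float(np.mean(covers[name])),
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows)
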