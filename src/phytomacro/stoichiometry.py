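"""Stoichiometric prediction of molar C:N from macromolecular composition.

Each macromolecular pool (as % dry weight) contributes carbon and nitrogen
according to per-macromolecule elemental mass fractions. Total lipid is
split into a phosphorus-free subpool (2/3 of total lipid) and a
phospholipid subpool (1/3); protein is the dominant nitrogen reservoir,
nucleic acids and chlorophyll-a carry the rest. The molar ratio

    C:N = [sum_k pct_k * fC_k / 12.011] / [sum_k pct_k * fN_k / 14.007]

is invariant to uniform rescaling of the profile, so pools need not sum
to 100 and "percent of the measured pools" works identically.

The default elemental constants table was transcribed from the
Geider & LaRoche (2002) compilation of macromolecular elemental
composition and is shipped as a versioned CSV with a provenance column.
Ash never enters the computation (it is the post-combustion inorganic
residue, not an organic pool).

Two policy switches mirror genuinely open reporting choices in published
meta-analyses and are both supported: which protein stream feeds the
computation (peptide/amino-acid assays only — the default, since
N-derived protein is circular when predicting C:N — or the pooled
hierarchical estimate), and whether pools missing from a phylum's profile
are dropped (default) or imputed with the grand medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ATOMIC_MASS_C",
    "ATOMIC_MASS_N",
    "ElementalConstants",
    "MacromolecularProfile",
    "split_lipid",
    "profile_cn",
    "posterior_cn",
    "load_reference_profiles",
    "reference_profile",
    "predicted_cn_table",
]

ATOMIC_MASS_C = 12.011
ATOMIC_MASS_N = 14.007

#: the six organic pools entering C:N, after the lipid split
_CN_POOLS = ("protein", "lipid_p_free", "phospholipid", "carbohydrate",
             "RNA", "DNA", "chlorophyll_a")

LIPID_P_FREE_FRACTION = 2.0 / 3.0
PHOSPHOLIPID_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class ElementalConstants:
    """Per-macromolecule elemental mass fractions (g element / g pool).

    Immutable once constructed; fractions are validated to lie in [0, 1]
    with strictly positive carbon for every pool.
    """

    carbon: Mapping[str, float]
    nitrogen: Mapping[str, float]
    phosphorus: Mapping[str, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pool in _CN_POOLS:
            if pool not in self.carbon or pool not in self.nitrogen:
                raise ValueError(f"constants table lacks pool {pool!r}")
        for name, table in (("carbon", self.carbon), ("nitrogen", self.nitrogen),
                            ("phosphorus", self.phosphorus)):
            for pool, frac in table.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"{name} fraction for {pool} out of [0,1]: {frac}")
        if any(self.carbon[p] <= 0 for p in _CN_POOLS):
            raise ValueError("every pool must have a positive carbon fraction")
        object.__setattr__(self, "carbon", MappingProxyType(dict(self.carbon)))
        object.__setattr__(self, "nitrogen", MappingProxyType(dict(self.nitrogen)))
        object.__setattr__(self, "phosphorus", MappingProxyType(dict(self.phosphorus)))
        object.__setattr__(self, "provenance", MappingProxyType(dict(self.provenance)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElementalConstants":
        df = pd.read_csv(path)
        return cls(
            carbon=dict(zip(df["pool"], df["carbon_fraction"].astype(float))),
            nitrogen=dict(zip(df["pool"], df["nitrogen_fraction"].astype(float))),
            phosphorus=dict(zip(df["pool"], df["phosphorus_fraction"].astype(float))),
            provenance=dict(zip(df["pool"], df.get("provenance", ""))),
        )

    @classmethod
    def default(cls) -> "ElementalConstants":
        ref = resources.files("phytomacro").joinpath("data/elemental_constants.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class MacromolecularProfile:
    """Percent-dry-weight composition; ``None`` marks an unreported pool.

    Ash is carried for bookkeeping but never enters C:N.
    """

    protein: float | None = None
    lipid: float | None = None
    carbohydrate: float | None = None
    RNA: float | None = None
    DNA: float | None = None
    chlorophyll_a: float | None = None
    ash: float | None = None

    def __post_init__(self) -> None:
        total = 0.0
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
            total += v
        if total > 110.0:
            raise ValueError(f"profile sums to {total:.1f} %DW (> 110, implausible)")

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def split_lipid(lipid_total: float) -> tuple[float, float]:
    """Split total lipid into (P-free, phospholipid) = (2/3, 1/3) of total.

    The subpools sum to the total exactly.
    """
    if lipid_total < 0:
        raise ValueError("lipid must be non-negative")
    p_free = LIPID_P_FREE_FRACTION * lipid_total
    return p_free, lipid_total - p_free


def _resolved_pools(
    profile: "MacromolecularProfile | Mapping[str, float | None]",
    impute_with: "MacromolecularProfile | Mapping[str, float | None] | None",
) -> dict[str, float]:
    prof = profile.as_dict() if isinstance(profile, MacromolecularProfile) else dict(profile)
    imp = {}
    if impute_with is not None:
        imp = (impute_with.as_dict() if isinstance(impute_with, MacromolecularProfile)
               else dict(impute_with))

    pools: dict[str, float] = {}
    for name in ("protein", "lipid", "carbohydrate", "RNA", "DNA", "chlorophyll_a"):
        v = prof.get(name)
        if v is None:
            v = imp.get(name)
        pools[name] = 0.0 if v is None else float(v)  # missing & unimputed -> dropped

    p_free, phospho = split_lipid(pools.pop("lipid"))
    pools["lipid_p_free"] = p_free
    pools["phospholipid"] = phospho
    return pools


def profile_cn(
    profile: "MacromolecularProfile | Mapping[str, float | None]",
    constants: ElementalConstants | None = None,
    impute_with: "MacromolecularProfile | Mapping[str, float | None] | None" = None,
) -> float:
    """Molar C:N of a macromolecular profile.

    ``impute_with`` optionally supplies values for pools marked missing
    (``None``); by default missing pools are dropped, which — thanks to
    scale invariance — equals computing C:N of the observed pools alone.

    Raises
    ------
    ValueError
        If the profile contributes no nitrogen (the ratio is undefined).
    """
    constants = constants or ElementalConstants.default()
    pools = _resolved_pools(profile, impute_with)
    mol_c = sum(pct * constants.carbon[p] for p, pct in pools.items()) / ATOMIC_MASS_C
    mol_n = sum(pct * constants.nitrogen[p] for p, pct in pools.items()) / ATOMIC_MASS_N
    if mol_n <= 0.0:
        raise ValueError("profile contains no nitrogenous pool: C:N undefined")
    return mol_c / mol_n


def posterior_cn(
    pool_draws: Mapping[str, np.ndarray],
    constants: ElementalConstants | None = None,
    impute_with: "MacromolecularProfile | Mapping[str, float | None] | None" = None,
    mass: float = 0.95,
) -> dict:
    """Draw-wise C:N across the joint posterior of pool-level means.

    ``pool_draws`` maps pool names (``protein``, ``lipid``,
    ``carbohydrate``, optionally ``RNA``, ``DNA``, ``chlorophyll_a``) to
    equal-length draw vectors. Pools absent from the mapping follow the
    same imputation rule as :func:`profile_cn`, applied identically across
    draws. Returns the C:N draw vector plus median and HDI.
    """
    from .summary import hdi  # local import avoids a cycle

    constants = constants or ElementalConstants.default()
    for required in ("protein", "lipid", "carbohydrate"):
        if required not in pool_draws:
            raise ValueError(f"pool_draws must include {required!r}")

    arrays = {k: np.asarray(v, float).ravel() for k, v in pool_draws.items()}
    n = len(next(iter(arrays.values())))
    if any(a.size != n for a in arrays.values()):
        raise ValueError("all pool draw vectors must have equal length")
    # negative pool-mean draws (possible under a normal model) contribute
    # nothing rather than negative mass
    arrays = {k: np.clip(a, 0.0, None) for k, a in arrays.items()}

    imp = {}
    if impute_with is not None:
        imp = (impute_with.as_dict() if isinstance(impute_with, MacromolecularProfile)
               else dict(impute_with))

    def pool_vec(name: str) -> np.ndarray:
        if name in arrays:
            return arrays[name]
        v = imp.get(name)
        return np.full(n, 0.0 if v is None else float(v))

    lipid = pool_vec("lipid")
    contributions = {
        "protein": pool_vec("protein"),
        "lipid_p_free": LIPID_P_FREE_FRACTION * lipid,
        "phospholipid": PHOSPHOLIPID_FRACTION * lipid,
        "carbohydrate": pool_vec("carbohydrate"),
        "RNA": pool_vec("RNA"),
        "DNA": pool_vec("DNA"),
        "chlorophyll_a": pool_vec("chlorophyll_a"),
    }
    mol_c = sum(v * constants.carbon[p] for p, v in contributions.items()) / ATOMIC_MASS_C
    mol_n = sum(v * constants.nitrogen[p] for p, v in contributions.items()) / ATOMIC_MASS_N
    if np.any(mol_n <= 0):
        raise ValueError("some draws contain no nitrogenous mass: C:N undefined")
    cn = mol_c / mol_n
    lo, hi = hdi(cn, mass)
    return {"draws": cn, "median": float(np.median(cn)), "hdi_low": lo, "hdi_high": hi}


# --------------------------------------------------------------------------
# reference phylum-level median profiles (published meta-analytic medians)
# --------------------------------------------------------------------------

def load_reference_profiles() -> pd.DataFrame:
    """Published phylum-level median composition (% dry weight) of
    microalgae under nutrient-sufficient exponential growth, including the
    pan-microalgae grand medians; blank cells mark pools with too little
    data to estimate for that phylum."""
    ref = resources.files("phytomacro").joinpath("data/phylum_profiles.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_profile(phylum: str, protein: str = "peptide") -> MacromolecularProfile:
    """Reference profile for one phylum (or ``"Grand"``).

    ``protein`` selects the stream: ``"peptide"`` (amino-acid/peptide
    assays, the default for C:N work) or ``"pooled"`` (the full
    hierarchical protein estimate).
    """
    df = load_reference_profiles().set_index("phylum")
    if phylum not in df.index:
        raise KeyError(f"unknown phylum {phylum!r}; available: {list(df.index)}")
    row = df.loc[phylum]
    col = {"peptide": "protein_peptide", "pooled": "protein_pooled"}[protein]

    def get(name: str) -> float | None:
        v = row[name]
        return None if pd.isna(v) else float(v)

    return MacromolecularProfile(
        protein=get(col), lipid=get("lipid"), carbohydrate=get("carbohydrate"),
        RNA=get("rna"), DNA=get("dna"), chlorophyll_a=get("chlorophyll_a"),
        ash=get("ash"),
    )


def predicted_cn_table(
    constants: ElementalConstants | None = None,
    protein: str = "peptide",
    missing: str = "drop",
) -> pd.DataFrame:
    """Predicted molar C:N for every reference phylum plus the grand profile.

    ``missing`` is ``"drop"`` (unreported pools contribute nothing) or
    ``"impute"`` (unreported pools take the grand medians).
    """
    if missing not in ("drop", "impute"):
        raise ValueError("missing must be 'drop' or 'impute'")
    constants = constants or ElementalConstants.default()
    grand = reference_profile("Grand", protein=protein) if missing == "impute" else None
    rows = []
    for phylum in load_reference_profiles()["phylum"]:
        prof = reference_profile(phylum, protein=protein)
        rows.append({
            "phylum": phylum,
            "cn_predicted": profile_cn(prof, constants, impute_with=grand),
        })
    return pd.DataFrame(rows)
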