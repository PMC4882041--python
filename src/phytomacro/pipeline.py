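"""End-to-end orchestration: load -> filter -> harmonise -> fit -> report.

`run_pipeline` drives the full analysis from a :class:`RunConfig` (usually
parsed from YAML): it loads and validates the database, restricts to one
growth regime, applies the protein nitrogen correction, fits the
hierarchical model per analysed variable, and renders the paper-shaped
outputs — per-phylum summary tables with grand means, pairwise contrast
matrices, variance decompositions, ratio summaries, posterior C:N, and
forest plots. A :class:`RunManifest` records config, row counts per
stage, per-fit diagnostics and output checksums, and is written even when
a stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, vocab
from .database import (DatabaseDialect, ObservationTable, default_dialect,
                       filter_condition, phylum_analysis_sets, read_database)
from .harmonization import build_ratios, correct_protein, stratify_protein_method
from .model import (PAPER_CONFIG, TEST_CONFIG, ModelSpec, SamplerConfig,
                    fit_hierarchical)
from .stoichiometry import ElementalConstants, posterior_cn
from .summary import (forest_plot, pairwise_contrasts, summarize_phyla,
                      summarize_ratios, variance_decomposition)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "method_strata_report",
           "habitat_contrast"]

_PRESETS = {"paper": PAPER_CONFIG, "test": TEST_CONFIG}

MAJOR_POOLS = ("protein", "lipid", "carbohydrate")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    input_path: str
    output_dir: str
    regime: str = "active_growth"
    variables: tuple[str, ...] = MAJOR_POOLS
    fit_ratios: bool = True
    preset: str = "test"
    seed: int = 0
    basis: str = "percent_dry_weight"
    constants_path: str | None = None
    dialect_path: str | None = None
    cn_missing: str = "drop"       # or "impute" (grand posterior medians)
    save_draws: bool = False

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown sampler preset {self.preset!r}")
        if not self.variables:
            raise ValueError("config lists no variables to fit")
        unknown = [v for v in self.variables if v not in vocab.POOLS]
        if unknown:
            raise ValueError(f"unknown pools in variables: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["variables"] = tuple(raw.get("variables", MAJOR_POOLS))
        return cls(**raw)

    def sampler_config(self) -> SamplerConfig:
        return dataclasses.replace(_PRESETS[self.preset], seed=self.seed)


@dataclass
class RunManifest:
    """Traceability record of one pipeline run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    status: str = "running"
    failed_stage: str | None = None
    wall_clock_s: float = 0.0

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str),
                        encoding="utf-8")


def _fit_variable(
    df: pd.DataFrame,
    name: str,
    spec: ModelSpec,
    config: SamplerConfig,
    out_dir: Path,
    manifest: RunManifest,
    save_draws: bool,
) -> "tuple":
    draws, report = fit_hierarchical(df, spec, config)
    entry = {
        "variable": name,
        "n_obs": int(len(df)),
        "n_species": int(df["species_key"].nunique()),
        "n_phyla": len(draws.phylum_names),
        "max_rhat": float(report.table["rhat"].max()),
        "converged": bool(report.passed),
        "seed": config.seed,
    }
    if save_draws:
        draws_path = out_dir / f"draws_{name}.csv"
        draws.to_frame().to_csv(draws_path, index=False)
        manifest.add_output(draws_path)
        entry["draws_file"] = draws_path.name
    manifest.fits[name] = entry
    return draws, report


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    manifest_path = out_dir / "manifest.json"
    stage = "setup"
    try:
        dialect = (DatabaseDialect.from_yaml(config.dialect_path)
                   if config.dialect_path else default_dialect())
        constants = (ElementalConstants.from_csv(config.constants_path)
                     if config.constants_path else ElementalConstants.default())
        sampler = config.sampler_config()

        stage = "load"
        table, report = read_database(config.input_path, dialect)
        report.to_json(out_dir / "validation_report.json")
        manifest.add_output(out_dir / "validation_report.json")
        manifest.stages["load"] = {"n_loaded": report.n_loaded,
                                   "n_rejected": report.n_rejected,
                                   "n_records": len(table)}

        stage = "filter"
        regime_table = filter_condition(table, config.regime)
        comparison, grand = phylum_analysis_sets(regime_table)
        manifest.stages["filter"] = {
            "regime": config.regime,
            "n_regime": len(regime_table),
            "n_species": regime_table.n_species,
            "n_comparison": len(comparison),
            "n_grand": len(grand),
        }

        stage = "harmonize"
        comparison = correct_protein(comparison)
        grand = correct_protein(grand)
        n_corrected = int((comparison.df["correction_factor"] != 1.0).sum())
        manifest.stages["harmonize"] = {"n_protein_corrected": n_corrected}

        stage = "fit_pools"
        decomp_rows = []
        pool_draws_by_pool = {}
        for pool in config.variables:
            df = comparison.df
            mask = (df["pool"] == pool) & (df["basis"] == config.basis)
            if pool == "protein":
                mask &= df["protein_method"].isin(
                    ("peptide_or_amino_acid", "n_derived"))
            sub = df.loc[mask]
            if sub.empty:
                manifest.stages.setdefault("skipped_pools", []).append(pool)
                continue
            draws, _ = _fit_variable(
                sub, pool, ModelSpec(response="value", basis=config.basis,
                                     regime=config.regime),
                sampler, out_dir, manifest, config.save_draws)

            n_by_phylum = sub.groupby("phylum").size().to_dict()
            summary = summarize_phyla(draws, n_by_phylum)
            summary.to_csv(out_dir / f"summary_{pool}.csv", index=False)
            manifest.add_output(out_dir / f"summary_{pool}.csv")

            contrasts = pairwise_contrasts(draws.flat_phylum_means(), draws.phylum_names)
            contrasts.to_csv(out_dir / f"contrasts_{pool}.csv", index=False)
            manifest.add_output(out_dir / f"contrasts_{pool}.csv")

            vd = variance_decomposition(draws.sigma_p, draws.sigma_s, draws.sigma_e)
            decomp_rows.append({"pool": pool,
                                "pct_within_species": vd.pct_within_species,
                                "pct_among_species_within_phyla": vd.pct_among_species_within_phyla,
                                "pct_among_phyla": vd.pct_among_phyla})

            fig_path = out_dir / f"forest_{pool}.svg"
            forest_plot(summary, title=f"{pool} (% dry weight)", path=fig_path)
            manifest.add_output(fig_path)
            pool_draws_by_pool[pool] = draws

        if decomp_rows:
            pd.DataFrame(decomp_rows).to_csv(out_dir / "variance_decomposition.csv",
                                             index=False)
            manifest.add_output(out_dir / "variance_decomposition.csv")

        stage = "ratios"
        if config.fit_ratios:
            ratios = build_ratios(comparison)
            ratios.to_csv(out_dir / "ratio_observations.csv", index=False)
            manifest.add_output(out_dir / "ratio_observations.csv")
            for kind in vocab.RATIO_KINDS:
                sub = ratios.loc[ratios["ratio_kind"] == kind]
                if len(sub) < 3:
                    continue
                draws, _ = _fit_variable(
                    sub, kind, ModelSpec(response="log_value", transform="log",
                                         regime=config.regime),
                    sampler, out_dir, manifest, config.save_draws)
                n_by_phylum = sub.groupby("phylum").size().to_dict()
                summary = summarize_ratios(draws, n_by_phylum)
                summary.to_csv(out_dir / f"summary_{kind}.csv", index=False)
                manifest.add_output(out_dir / f"summary_{kind}.csv")

        stage = "cn"
        if all(p in pool_draws_by_pool for p in MAJOR_POOLS):
            cn_rows = []
            shared = set.intersection(
                *(set(pool_draws_by_pool[p].phylum_names) for p in MAJOR_POOLS))
            grand_medians = {
                p: float(np.median(pool_draws_by_pool[p].flat_phylum_means()))
                for p in pool_draws_by_pool}
            impute = grand_medians if config.cn_missing == "impute" else None
            for phylum in sorted(shared):
                per_pool = {}
                for p, d in pool_draws_by_pool.items():
                    j = d.phylum_names.index(phylum)
                    per_pool[p] = d.flat_phylum_means()[:, j]
                n = min(len(v) for v in per_pool.values())
                res = posterior_cn({k: v[:n] for k, v in per_pool.items()},
                                   constants, impute_with=impute)
                cn_rows.append({"phylum": phylum, "cn_median": res["median"],
                                "hdi_low": res["hdi_low"], "hdi_high": res["hdi_high"]})
            pd.DataFrame(cn_rows).to_csv(out_dir / "cn_predicted.csv", index=False)
            manifest.add_output(out_dir / "cn_predicted.csv")

        manifest.status = "success"
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.wall_clock_s = time.time() - t0
        manifest.write(manifest_path)
        raise
    manifest.wall_clock_s = time.time() - t0
    manifest.write(manifest_path)
    return manifest


def method_strata_report(
    table: ObservationTable,
    config: SamplerConfig | None = None,
    basis: str = "percent_dry_weight",
) -> pd.DataFrame:
    """Four independent protein fits, one per method stratum.

    Strata: peptide/amino-acid assays, N-derived as reported, N-derived
    after correction, and the pooled (peptide + corrected) stream. Phyla
    with an empty stratum are simply absent from that stratum's rows.
    """
    config = config or TEST_CONFIG
    protein = table.replace(table.df.loc[
        (table.df["pool"] == "protein") & (table.df["basis"] == basis)])
    if len(protein) == 0:
        raise ValueError("no protein observations to stratify")
    strata = stratify_protein_method(protein)

    frames = []
    for stratum, sub in strata.items():
        if len(sub) == 0 or sub.df["species_key"].nunique() < 2:
            continue
        draws, _ = fit_hierarchical(sub.df, ModelSpec(response="value", basis=basis),
                                    config)
        n_by_phylum = sub.df.groupby("phylum").size().to_dict()
        summary = summarize_phyla(draws, n_by_phylum)
        summary.insert(0, "stratum", stratum)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def habitat_contrast(
    table: ObservationTable,
    pool: str,
    phylum: str | None = None,
    config: SamplerConfig | None = None,
    basis: str = "percent_dry_weight",
    mass: float = 0.95,
) -> dict:
    """Marine-vs-freshwater contrast for one pool, optionally within a phylum.

    Habitat replaces the phylum level in the same two-level-plus-residual
    hierarchical fit (species nested in habitat); the contrast is the
    draw-wise difference (freshwater - marine) with its HDI and the
    HDI-excludes-zero significance flag.
    """
    config = config or TEST_CONFIG
    df = table.df
    mask = (df["pool"] == pool) & (df["basis"] == basis) & df["habitat"].isin(
        ("marine", "freshwater"))
    if pool == "protein":
        mask &= df["protein_method"].isin(("peptide_or_amino_acid", "n_derived"))
    if phylum is not None:
        mask &= df["phylum"] == phylum
    sub = df.loc[mask]
    present = set(sub["habitat"])
    if present != {"marine", "freshwater"}:
        missing = {"marine", "freshwater"} - present
        where = f"phylum {phylum}" if phylum else "the table"
        raise ValueError(f"no {'/'.join(sorted(missing))} observations of {pool} in {where}")

    draws, report = fit_hierarchical(
        (sub["value"].to_numpy(float), sub["species_key"].to_numpy(),
         sub["habitat"].to_numpy()),
        ModelSpec(response="value", basis=basis), config)

    from .summary import hdi
    flat = draws.flat_phylum_means()  # here: habitat-level means
    idx = {name: j for j, name in enumerate(draws.phylum_names)}
    diff = flat[:, idx["freshwater"]] - flat[:, idx["marine"]]
    lo, hi = hdi(diff, mass)
    return {
        "pool": pool,
        "phylum": phylum,
        "freshwater_median": float(np.median(flat[:, idx["freshwater"]])),
        "marine_median": float(np.median(flat[:, idx["marine"]])),
        "n_freshwater": int((sub["habitat"] == "freshwater").sum()),
        "n_marine": int((sub["habitat"] == "marine").sum()),
        "difference_median": float(np.median(diff)),
        "hdi_low": lo,
        "hdi_high": hi,
        "significant": bool(lo > 0 or hi < 0),
        "converged": bool(report.passed),
    }
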