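"""Protein-method harmonisation and within-study macromolecular ratios.

Protein reported via total nitrogen (Kjeldahl-style "N content" times the
standard 6.25 g protein / g N) overestimates true protein in eukaryotes,
whose largest non-protein N pool is inorganic N storage. Those values are
rescaled by 4.78/6.25 (the corrected conversion factor for eukaryotic
microalgae). Cyanobacteria store N predominantly as protein and peptides,
so their N-derived values are left as reported.

Ratios of the three major pools (protein:carbohydrate, protein:lipid,
carbohydrate:lipid) are formed strictly within a measurement *cell* — one
taxon in one study under one culture condition, on one basis — never
across studies, bases or conditions. Ratios are modelled on the natural
log scale downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import vocab
from .database import ObservationTable

__all__ = [
    "correct_protein",
    "stratify_protein_method",
    "build_ratios",
]

_CORRECTION = vocab.CORRECTED_N_FACTOR / vocab.STANDARD_N_FACTOR


def correct_protein(table: ObservationTable) -> ObservationTable:
    """Apply the nitrogen-conversion correction to N-derived protein rows.

    Only rows with ``pool == "protein"`` and ``protein_method ==
    "n_derived"`` in eukaryotic phyla are rescaled. The original value and
    applied factor are kept as audit columns (``value_original``,
    ``correction_factor``), which also makes the operation idempotent.

    Raises
    ------
    ValueError
        If a protein row carries ``protein_method == "not_applicable"``
        (contract violation: the method must be known for protein).
    """
    df = table.df.copy()
    is_protein = df["pool"] == "protein"
    if (is_protein & (df["protein_method"] == "not_applicable")).any():
        raise ValueError("protein rows must carry a protein method, found 'not_applicable'")

    if "correction_factor" in df.columns:  # already corrected once
        return table.replace(df)

    df["value_original"] = df["value"]
    df["correction_factor"] = 1.0
    target = (
        is_protein
        & (df["protein_method"] == "n_derived")
        & (df["phylum"] != "Cyanobacteria")
    )
    df.loc[target, "correction_factor"] = _CORRECTION
    df.loc[target, "value"] = df.loc[target, "value"] * _CORRECTION
    return table.replace(df)


def stratify_protein_method(table: ObservationTable) -> dict[str, ObservationTable]:
    """Split protein rows into the four method strata.

    Returns ``{"peptide", "n_uncorrected", "n_corrected", "pooled"}`` where
    *peptide* holds amino-acid/peptide-residue assays, *n_uncorrected* the
    N-derived values as reported, *n_corrected* the same rows after
    :func:`correct_protein`, and *pooled* the union of peptide and
    corrected-N rows (the best-estimate protein stream).
    """
    protein = table.replace(table.df.loc[table.df["pool"] == "protein"])
    corrected = correct_protein(protein)

    cdf = corrected.df
    peptide = cdf["protein_method"] == "peptide_or_amino_acid"
    nrows = cdf["protein_method"] == "n_derived"

    n_uncorrected = table.df.loc[
        (table.df["pool"] == "protein") & (table.df["protein_method"] == "n_derived")
    ]
    strata = {
        "peptide": corrected.replace(cdf.loc[peptide]),
        "n_uncorrected": protein.replace(n_uncorrected),
        "n_corrected": corrected.replace(cdf.loc[nrows]),
        "pooled": corrected.replace(cdf.loc[peptide | nrows]),
    }
    assert len(strata["pooled"]) == len(strata["peptide"]) + len(strata["n_corrected"])
    return strata


def build_ratios(
    table: ObservationTable,
    replicate_wise: bool = True,
) -> pd.DataFrame:
    """Construct pairwise mass-ratio observations within measurement cells.

    For every cell (study x taxon x condition x basis) holding both pools
    of a ratio kind, one ratio observation is emitted per available
    pairing. If replicate indices are present and ``replicate_wise`` is
    true, pools are paired replicate-by-replicate; otherwise cell means
    are used. Protein entering ratios must already be method-harmonised
    (call :func:`correct_protein` first); the pooled protein stream
    (peptide + corrected N-derived) is used.

    Zero denominators are skipped, counted in the ``n_skipped_zero_denominator``
    attribute of the returned frame rather than raised.

    Returns a DataFrame with the cell key columns plus ``ratio_kind``,
    ``ratio_value`` and ``log_value`` (natural log).
    """
    df = table.df
    df = df.loc[df["pool"].isin(("protein", "carbohydrate", "lipid"))].copy()
    # pooled protein stream only: drop protein rows that are neither
    # peptide-based nor (corrected) N-derived
    df = df.loc[
        (df["pool"] != "protein")
        | df["protein_method"].isin(("peptide_or_amino_acid", "n_derived"))
    ]

    key = list(vocab.CELL_KEY)
    use_replicates = replicate_wise and "replicate" in df.columns and (
        df["replicate"].astype(str).str.strip() != ""
    ).any()
    group_cols = key + (["replicate"] if use_replicates else [])

    # canonical ordering makes the output invariant to input row order
    df = df.sort_values(group_cols + ["pool", "value"], kind="mergesort")
    means = (
        df.groupby(group_cols + ["pool"], observed=True)["value"]
        .mean()
        .unstack("pool")
        .reset_index()
    )

    rows = []
    n_skipped = 0
    for kind, (num, den) in vocab.RATIO_POOLS.items():
        if num not in means.columns or den not in means.columns:
            continue
        sub = means.dropna(subset=[num, den])
        # ratio observations must be strictly positive (they are modelled
        # on the log scale), so zero numerators are skipped like zero
        # denominators
        zero = (sub[den] == 0) | (sub[num] == 0)
        n_skipped += int(zero.sum())
        sub = sub.loc[~zero]
        if sub.empty:
            continue
        out = sub[key].copy()
        out["ratio_kind"] = kind
        out["ratio_value"] = (sub[num] / sub[den]).to_numpy()
        rows.append(out)

    if rows:
        ratios = pd.concat(rows, ignore_index=True)
    else:
        ratios = pd.DataFrame(columns=key + ["ratio_kind", "ratio_value"])
    ratios["log_value"] = np.log(ratios["ratio_value"].astype(float))
    ratios = ratios.sort_values(["ratio_kind"] + key, kind="mergesort").reset_index(drop=True)
    ratios.attrs["n_skipped_zero_denominator"] = n_skipped
    return ratios
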