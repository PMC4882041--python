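# Methods

## Data model and curation

The package operates on a long-format observation table: one row per
(source study, taxon, culture condition, macromolecular pool, basis)
measurement. Nine phyla are admitted (Cyanobacteria, Chlorophyta,
Rhodophyta, Bacillariophyta, Cryptophyta, Dinophyta, Euglenozoa,
Haptophyta, Ochrophyta); rows outside this vocabulary, with negative
values, with percent-dry-weight values above 100, or with protein rows
lacking a usable assay method are rejected individually and enumerated in
a validation report (`n_loaded + n_rejected` always equals the input row
count). Coastal, estuarine and brackish habitat strings are mapped to
*marine*. Duplicate rows — identical on study, taxon, condition, basis,
pool, value and replicate — are dropped keeping the first occurrence, and
the count is logged; the curation literature is silent on duplicates, so
the policy is deliberately conservative and auditable.

Column and categorical-value spellings of the on-disk file are described
by a versioned YAML mapping (`data/s1_mapping.yaml`) rather than code, so
a file with different headers needs a config change, not a release. The
synthetic fixture generator writes this same dialect, which is what makes
the loader round-trip testable without any external download.

Two analysis regimes are defined positively: *active growth* keeps
exponential-phase, nutrient-sufficient observations from batch,
turbidostat and semi-continuous cultures (chemostats are excluded — steady
-state dilution is a different physiological regime); *stationary* keeps
stationary-phase rows. Rows with unknown phase or nutrient status qualify
for neither. Euglenozoa and Rhodophyta are too sparsely observed for
phylum-level comparison and are excluded from the comparison set while
remaining in the pan-microalgae (grand) pool.

## Protein harmonisation

Five assay families report "protein"; the systematic one is total nitrogen
converted at 6.25 g protein / g N, which counts non-protein nitrogen
(mostly inorganic stores) as protein in eukaryotes. N-derived values in
eukaryotic phyla are therefore multiplied by 4.78/6.25 ≈ 0.765;
Cyanobacteria, which store nitrogen as protein and peptides, are left as
reported. The original value and applied factor are retained as audit
columns, which also makes the operation idempotent. Method strata
(peptide-based, N-derived as reported, N-derived corrected, and the pooled
peptide + corrected stream) can each be fitted independently for a
method-comparison table; the pooled stream is the default protein input
to all composition fits.

## Ratios

Protein:carbohydrate, protein:lipid and carbohydrate:lipid are computed
only within a measurement *cell* — one taxon in one study under one
culture condition on one basis — never across studies, bases or
conditions. When replicate indices exist, pools are paired
replicate-wise; otherwise cell means are used (both supported; the
replicate-wise default is a documented choice, not a claim about how any
published compilation did it). Ratios are modelled as natural logs and
back-transformed for reporting; since the median and HDI endpoints
commute with monotone maps, results are independent of the log base.
Cells with a zero numerator or denominator are skipped and counted, not
fatal.

## Hierarchical model and sampler

Each analysed response is decomposed as `y = mu + P_phylum + S_species +
eps` with three separate normal variance components. Sampling uses the
hierarchically centred parameterisation (species means drawn around
phylum means, phylum means around a top-level location `mu`), which keeps
the model identified during sampling without sum-to-zero constraints.

Priors. The three scales carry half-Cauchy(0, 5·SD(y)) priors and `mu` a
Normal(mean(y), (10·SD(y))²) hyperprior. These are weakly informative at
the scale of the data; a half-Student-t(df = 4) alternative is switchable
in `SamplerConfig` for prior-sensitivity checks, since the exact
"uninformative" scale-prior family behind any given published analysis is
rarely recoverable. A hard floor/ceiling on log σ (10⁻⁸ to 10⁴ times the
data scale) keeps degenerate inputs — e.g. all observations identical —
from underflowing the precision arithmetic; with such inputs the residual
scale collapses toward the floor and phylum means recover the constant.

Updates. Locations are conditionally conjugate and Gibbs-sampled; the
scales are updated by univariate slice sampling (stepping-out plus
shrinkage) on log σ. All location updates depend on the data only
through per-species sufficient statistics (counts, sums, sums of
squares), so one full sweep costs O(#species) regardless of the number of
observations; a 4-chain × 5,000-iteration fit of ~300 observations takes
about 1.5 s on one CPU.

Reference settings. The full preset runs 4 chains × 50,000 iterations,
discards the first half and keeps every 5th draw. The test preset used
throughout the test suite scales this to 5,000 (or fewer) iterations with
the same burn-in and thinning fractions — chosen so the whole suite,
including the 100-replicate calibration run, completes in a couple of
minutes while leaving every qualitative conclusion unchanged.

Determinism. Chains are seeded from a `SeedSequence` of (seed, chain);
initial values are data-derived (species/phylum sample means, moment-based
scales) and jittered per chain. Observations are canonically re-sorted
internally, so posterior draws are bit-identical under permutation of
input rows.

Diagnostics. Split-R̂ and bulk ESS (via arviz) are computed for `mu`, the
three scales, and every phylum mean; a fit passes at R̂ < 1.01
(configurable). Single-chain runs and degenerate designs (single species
or single phylum) are flagged rather than rejected. A shrinkage
diagnostic verifies, per species, that the posterior species mean lies no
farther from the phylum median than the raw sample mean does — the
defining direction of partial pooling.

## Posterior summaries

* **HDI**: the shortest contiguous interval containing ⌈mass·n⌉ sorted
  draws, found by exhaustive window search with ties broken toward the
  lower window. This is never wider than the equal-tailed interval built
  from the same order statistics.
* **Grand mean**: phylum-mean draws are combined draw-wise with weights
  1/Var(P_j), the marginal posterior variance per phylum, preserving
  posterior uncertainty. The hierarchical top-level location is
  deliberately not reported as "the" grand mean.
* **Contrasts**: all pairwise phylum differences are formed draw-wise; a
  pair is flagged different when the 95% HDI of the difference excludes
  zero. No frequentist testing or multiplicity correction is performed —
  the posterior of the differences is the inferential object.
* **Variance decomposition**: percentages computed from the posterior
  median SDs (squared, normalised); a draw-wise average version exists as
  a diagnostic. Components sum to 100 within rounding by construction.
* Species-level posteriors are computed but not reported by default;
  their uncertainties are typically too wide to be useful.

## Stoichiometric C:N

Each pool contributes `pct · fC / 12.011` mol C and `pct · fN / 14.007`
mol N per 100 g dry weight; total lipid is split 2/3 phosphorus-free, 1/3
phospholipid (the split conserves the total exactly). The elemental mass
fractions live in a versioned CSV with a provenance column
(`data/elemental_constants.csv`), transcribed from the Geider & LaRoche
(2002) compilation and verified, before freezing, by reproducing the
seven published phylum-level predicted C:N values from the reference
median profiles to within ±0.2 (achieved ≤ 0.06). Ash never enters the
computation. Phosphorus fractions are carried in the constants file for
forward compatibility, but C:P and N:P are not reported.

Two reporting policies are genuinely open and both implemented:

* **Protein stream** — default is the peptide/amino-acid-assay medians:
  predicting C:N from N-derived protein would be circular, since that
  protein *is* a nitrogen measurement. The pooled hierarchical estimate
  is switchable.
* **Missing pools** — default is to drop pools unreported for a phylum
  (scale invariance makes this equivalent to "C:N of the measured
  pools"); imputing them with the grand medians is switchable. The
  defaults were fixed by which combination reproduces the published
  phylum predictions.

`posterior_cn` applies the same computation draw-wise across the joint
posterior of phylum-level pool means (negative pool-mean draws, possible
under a normal model, are clipped to zero mass), yielding a C:N median
and HDI per phylum.

## Synthetic data and calibration

The generator draws data from the model's own generative reading — normal
phylum effects, normal species effects, normal residuals — over an
explicit design (species counts per phylum, observations per species).
Percent-dry-weight values are truncated at zero with the clipping count
reported and a warning above 10%; this keeps values physical while
staying faithful to the normal likelihood (a lognormal generator would
test a different model than the one fitted). Protein rows flagged as
N-derived are stored divided by 4.78/6.25 in eukaryotes, so the
harmonisation correction inverts the generator to within one unit in the
last place of double rounding (two float multiplications cannot be
bit-exact in general).

Three design presets ship: `tiny` (3 phyla × 4 species × 5 obs, for
seconds-scale smoke tests), `table3-protein` (7 phyla with observation
totals 25/75/16/82/76/19/22 spread head-heavily over 8–24 species per
phylum, matching the shape of the real protein comparison), and
`stress-unbalanced` (one species holding 50 of a phylum's 54
observations). Generating parameters for the major pools (e.g. protein:
mean 32, σ_P 5.5, σ_S 6.1, σ_ε 7.1 %DW) reproduce both the published
medians and the published ≈25/31/42 phylum/species/residual variance
split.

`recovery_experiment` is the simulation-based calibration harness:
repeated generate-and-refit replicates report bias, RMSE and empirical
95%-HDI coverage for the three scales and the phylum means. At 100
replicates of the `table3-protein` design the measured coverages are
92–97%, within the 95 ± 5 band. What this does *not* test: real data
violate normality (skewed pools, method-specific biases, correlated
errors within studies), and the generator does not emulate
extraction-efficiency differences between labs — only the
nitrogen-conversion bias is modelled, because it is the only one with a
known, quantifiable factor.

## Pipeline and reproducibility

`run_pipeline` executes load → filter → harmonise → per-variable fit →
summaries/contrasts/variance decomposition → ratio fits → posterior C:N →
forest plots, writing a manifest with the config snapshot, per-stage row
counts, per-fit diagnostics and SHA-256 checksums of every output; the
manifest is written even when a stage fails, recording which one.
Re-running an identical config reproduces all summary CSVs bit-identically.
The marine-vs-freshwater contrast reuses the same hierarchical machinery
with habitat replacing phylum as the upper level within the selected
subset — an interpretation, documented as such, since published habitat
contrasts rarely state their exact model structure.

## Known limitations

* Normal likelihoods for %DW pools (no t or lognormal alternatives) and
  no environmental covariates — temperature, irradiance, CO₂ — are
  modelled; the regime filters are the only physiological control.
* The residual component absorbs between-lab and between-method
  variation beyond the protein correction.
* σ_P is informed by at most 7 phyla and is therefore prior-sensitive;
  the half-t switch exists precisely to check this.
* HDI tie-breaking (toward the lower window) matters only for small,
  tied draw sets.
* With an even number of kept draws, the median is the midpoint of two
  order statistics and does not commute exactly with exponentiation;
  ratio-scale medians are reported as exp(median of log draws).
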