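# Versioned column/value mapping from the distributed database dialect to
# the canonical schema (see phytomacro.vocab.CANONICAL_COLUMNS).
# The fixture generator writes this same dialect, so files round-trip.
version: 1
delimiter: ","
columns:
  source: study_id
  phylum: phylum
  genus: genus
  species: species
  strain: strain
  habitat: habitat
  culture.system: culture_system
  growth.phase: growth_phase
  nutrient.status: nutrient_status
  macromolecule: pool
  units: basis
  value: value
  protein.method: protein_method
  replicate: replicate
required:
  - source
  - phylum
  - genus
  - species
  - macromolecule
  - units
  - value
values:
  habitat:
    marine: marine
    coastal: marine        # coastal/estuarine/brackish species count as marine
    estuarine: marine
    brackish: marine
    freshwater: freshwater
    "": unknown
  culture_system:
    batch: batch
    turbidostat: turbidostat
    chemostat: chemostat
    semi.continuous: semi_continuous
    semi-continuous: semi_continuous
    "": unknown
  growth_phase:
    lag: lag
    exponential: exponential
    stationary: stationary
    "": unknown
  nutrient_status:
    sufficient: sufficient
    replete: sufficient
    limited: limited
    starved: starved
    "": unknown
  pool:
    protein: protein
    lipid: lipid
    carbohydrate: carbohydrate
    ash: ash
    RNA: RNA
    DNA: DNA
    chl.a: chlorophyll_a
    chlorophyll.a: chlorophyll_a
  basis:
    percent.dw: percent_dry_weight
    pg.per.cell: mass_per_cell
  protein_method:
    peptide: peptide_or_amino_acid
    amino.acid: peptide_or_amino_acid
    N.content: n_derived
    "": not_applicable
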