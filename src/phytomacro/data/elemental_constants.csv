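pool,carbon_fraction,nitrogen_fraction,phosphorus_fraction,provenance
protein,0.53,0.165,0.0,Geider & LaRoche (2002) Eur J Phycol 37:1-17
lipid_p_free,0.76,0.0,0.0,Geider & LaRoche (2002); triacylglycerol-dominated P-free lipid
phospholipid,0.65,0.0,0.040,Geider & LaRoche (2002); glycerophospholipid
carbohydrate,0.40,0.0,0.0,hexose monomer equivalent (C6H12O6)
RNA,0.34,0.16,0.091,mean ribonucleotide residue composition
DNA,0.36,0.16,0.095,mean deoxyribonucleotide residue composition
chlorophyll_a,0.7393,0.0627,0.0,molecular formula C55H72MgN4O5 (893.5 g/mol)
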