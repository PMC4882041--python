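phylum,protein_pooled,protein_peptide,lipid,carbohydrate,ash,rna,chlorophyll_a,dna
Cyanobacteria,43.1,42.2,11.7,21.8,8.12,8.7,1.06,0.82
Chlorophyta,32.7,32.8,16.3,14.4,12.1,5.11,1.15,0.81
Cryptophyta,38.5,37.7,16.1,12.5,16.1,,1.18,
Bacillariophyta,27.4,29.2,18.8,12.2,27.5,,1.12,
Haptophyta,32.1,32.5,18.6,16.9,13.7,4.78,1.16,1.01
Ochrophyta,32.6,32.8,21.3,14.4,19.6,0.55,1.1,
Dinophyta,27.4,30.4,15.8,23.0,11.6,,,
Grand,32.2,32.7,17.3,15.0,17.3,5.65,1.13,0.98
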