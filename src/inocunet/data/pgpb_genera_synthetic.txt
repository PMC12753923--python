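# Synthetic stand-in snapshot of a plant growth-promoting bacteria (PGPB)
# genus database, assembled from genera widely reported to carry PGP traits
# (ACC deaminase, siderophore production, phosphate solubilization, N2
# fixation). Replace with a curated database for real analyses.
# One genus per line; case-insensitive.
Acinetobacter
Actinoalloteichus
Agrobacterium
Amycolatopsis
Arthrobacter
Azoarcus
Azospirillum
Azotobacter
Bacillus
Bradyrhizobium
Burkholderia
Chryseobacterium
Cupriavidus
Enterobacter
Ensifer
Flavobacterium
Frankia
Gluconacetobacter
Herbaspirillum
Klebsiella
Kosakonia
Leifsonia
Lysinibacillus
Lysinimonas
Mesorhizobium
Methylobacterium
Microbacterium
Micrococcus
Nocardioides
Novosphingobium
Ochrobactrum
Paenibacillus
Pantoea
Pseudarthrobacter
Pseudomonas
Rahnella
Rhizobium
Rhodococcus
Serratia
Sinomonas
Sinorhizobium
Sphingomonas
Stenotrophomonas
Streptomyces
Variovorax
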