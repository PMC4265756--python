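species_id	display_name	stratum_id	stratum_rank	focal
Hs	Homo sapiens	vertebrata	0	1
Mm	Mus musculus	vertebrata	0	0
Gg	Gallus gallus	vertebrata	0	0
Xt	Xenopus tropicalis	vertebrata	0	0
Dr	Danio rerio	vertebrata	0	0
Ci	Ciona intestinalis	chordata_invert	1	0
Bf	Branchiostoma floridae	chordata_invert	1	0
Sp	Strongylocentrotus purpuratus	bilateria_nonchordate	2	0
Dm	Drosophila melanogaster	bilateria_nonchordate	2	0
Ce	Caenorhabditis elegans	bilateria_nonchordate	2	0
Hv	Hydra vulgaris	cnidaria	3	0
Nv	Nematostella vectensis	cnidaria	3	0
Ta	Trichoplax adhaerens	placozoa	4	0
Aq	Amphimedon queenslandica	porifera	5	0
Oc	Oscarella carmela	porifera	5	0
Mb	Monosiga brevicollis	choanoflagellata	6	0
Sr	Salpingoeca rosetta	choanoflagellata	6	0
Co	Capsaspora owczarzaki	filasterea	7	0
Sa	Sphaeroforma arctica	ichthyosporea	8	0
Am	Allomyces macrogynus	fungi	9	0
Mv	Mortierella verticillata	fungi	9	0
Spu	Spizellomyces punctatus	fungi	9	0
Sc	Saccharomyces cerevisiae	fungi	9	0
Spo	Schizosaccharomyces pombe	fungi	9	0
Dd	Dictyostelium discoideum	amoebozoa_apusozoa	10	0
Tt	Thecamonas trahens	amoebozoa_apusozoa	10	0
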