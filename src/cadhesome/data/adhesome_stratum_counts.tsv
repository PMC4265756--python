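stratum_id	n_families
amoebozoa_apusozoa	45
fungi	8
ichthyosporea	9
filasterea	9
choanoflagellata	9
porifera	17
placozoa	4
cnidaria	4
bilateria_nonchordate	3
chordata_invert	2
vertebrata	2
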