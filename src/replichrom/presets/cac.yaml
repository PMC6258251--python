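# chromatin-assembly-factor deficient: reduced nucleosome deposition rate
strand_length: 200000
fork_speed: 1.0
primer_spacing_mean: 150.0
primer_spacing_min: 50.0
nucleosome_footprint: 147
linker_length: 33
deposition_rate: 0.008
deposition_jitter_sd: 10.0
k_elg1: 1.0
k_spont: 0.001
pcna_block_halfwidth: 15.0
max_displacement: 1000.0
seed: 0
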