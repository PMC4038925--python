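# Default interactive tracking parameters.
threshold: 0.1
max_angle: 35
step_size_vox: 1
g: 0.20
min_length: 0
max_length: 300
seeds_per_axis: 10
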