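# Corpus callosum.
threshold: 0.15
max_angle: 50
step_size: 1.3
g: 0.10
min_length: 0
max_length: 300
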