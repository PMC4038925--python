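# Inferior fronto-occipital fasciculus.
threshold: 0.20
max_angle: 40
step_size: 1.6
g: 0.20
min_length: 0
max_length: 300
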