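# Fornix: short, highly curved; small steps, tight angle.
threshold: 0.10
max_angle: 20
step_size: 0.5
g: 0.30
min_length: 0
max_length: 300
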