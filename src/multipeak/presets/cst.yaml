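# Corticospinal tract: long and straight; large steps, pure in-direction smoothing.
threshold: 0.05
max_angle: 25
step_size: 2
g: 0
min_length: 0
max_length: 300
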