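# Reduced-width variant for CPU-scale experiments.
depth_multiple: 0.33
width_multiple: 0.125
n_classes: 1
input_size: 160
clab: true
hfgm: true
gicm: true
gicm_branch: [6, 4, 3]
gicm_dk: 16
gicm_token_pool: [400, 400, 400]
hfgm_hidden: [null, null]
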