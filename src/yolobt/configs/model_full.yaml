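# Full detector: CLAB backbone + HFGM neck + GICM gates (small variant).
depth_multiple: 0.33
width_multiple: 0.50
n_classes: 1
input_size: 640
clab: true
hfgm: true
gicm: true
gicm_branch: [24, 15, 2]
gicm_dk: 64
gicm_token_pool: [1600, 1600, 400]
hfgm_hidden: [100, null]
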