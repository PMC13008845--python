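# Plain small-variant baseline (all added modules toggled off).
depth_multiple: 0.33
width_multiple: 0.50
n_classes: 1
input_size: 640
clab: false
hfgm: false
gicm: false
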