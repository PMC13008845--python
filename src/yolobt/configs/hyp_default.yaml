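# Full training recipe (the published hyperparameters).
epochs: 600
patience: 50
batch_size: 16
initial_lr: 0.01
momentum: 0.937
weight_decay: 0.0005
warmup_epochs: 3.0
mosaic: true
mixup_alpha: 0.2
split: [0.70, 0.15, 0.15]
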