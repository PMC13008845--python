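# Default synthetic screen generation: 64-channel, mostly clean backgrounds.
n_channels: 64
sfreq: 250
trial_len: 1.0
quality_level: 1.0
erp_amplitude: 10.0
noise_gain: 15.0
mix: {clean: 0.7, moderate: 0.15, severe: 0.15}
quality_range: [0.8, 1.0]
bad_channel_prob: 0.3
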