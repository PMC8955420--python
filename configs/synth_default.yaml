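# Default synthetic dataset: three classes whose gamma-band power on the
# left hemisphere is scaled by 0.5 / 1.0 / 2.0 relative to baseline.
# Channel subsets: "left"/"right" expand to the montage's hemispheric pair
# sides; an explicit channel list is also accepted.
montage: seed62
fs: 200
duration_s: 60.0
n_trials_per_class: 10
noise_power: 0.5
scheme: seed3
base_band_power:
  delta: 20.0
  theta: 10.0
  alpha: 8.0
  beta: 4.0
  gamma: 2.0
effects:
  - {class: negative, band: gamma, gain: 0.5, channels: left}
  - {class: neutral, band: gamma, gain: 1.0, channels: left}
  - {class: positive, band: gamma, gain: 2.0, channels: left}
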