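# Desk-scale end-to-end configuration for `tomoshot run`.
# Simulates a 6-class phantom dataset, trains the one-shot network and
# evaluates the n-way-1-shot protocol on the two held-out classes.
sim:
  classes: 6                  # first 6 phantoms from the built-in library
  tomogram_shape: [150, 150, 100]
  n_particles: 150
  tilt_min: -60.0
  tilt_max: 60.0
  tilt_step: 2.0
  snr: inf                    # or 1000 / 0.5
  n_test_classes: 2
  optics:
    voltage: 300.0
    defocus: -5.0
    spherical_aberration: 2.0
    amplitude_contrast: 0.07
    mtf_cutoff: 0.4

model:
  channels: [4, 8, 32]
  n_pools: 2
  duse_enabled: true
  decoder_enabled: true

train:
  n_way: 2
  episodes_per_epoch: 8
  epochs: 24
  learning_rate: 0.001

eval:
  n_ways: [2]
  episodes: 300
  crf_enabled: true
  dsc_records_per_class: 8
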