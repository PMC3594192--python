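# Demo run configuration for `smforce run-all --config examples/config.yaml`.
# Any omitted key falls back to the built-in defaults (smforce.default_config).
seed: 1
n_curves: 1000
lambda: 0.155          # Poisson tether-attachment rate per approach
force_noise_sd: 3.0    # pN
bin_width: 10.0        # pN, rupture-force histogram
conditions:
  control:
    mixture: [0.5, 66.0, 20.0, 132.0, 30.0]   # w1, mu1, sd1, mu2, sd2 (pN)
  copper:
    mixture: [0.35, 83.0, 20.0, 164.0, 30.0]
images:
  enabled: true
  times_h: [1, 6, 24]
  image_size: [500, 500]
  pixel_size_nm: 10.0
  noise_sd_nm: 0.3
  tilt_nm_per_nm: 0.0005
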