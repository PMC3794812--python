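# Solution photocycle measurement design: 10 log-spaced delays, 30 us - 2 s.
# Omitted sections fall back to the bundled defaults (see trabs.example_config).
name: pyp_solution
kind: pyp_solution
seed: 1
times:
  t_min: 3.0e-5
  t_max: 2.0
  n: 10
noise:
  enabled: false
  snr: null
analysis:
  window_nm: [410.0, 530.0]
  n_exp: null          # default: number of significant components
  weighted: true       # rSVs weighted by their singular values
  single_wavelength_nm: 485.0
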