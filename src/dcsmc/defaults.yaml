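# Default configuration for the DCS multi-layer Monte Carlo pipeline.
optics:
  # bulk properties assumed by the analytical (semi-infinite) fits
  analytical:
    wavelength_nm: 850.0
    mu_a: 0.015
    mu_sp: 0.85
    n: 1.37
  # per-wavelength sets (forehead); mu_s' scaled from 850 nm by a -1.5
  # power law, mu_a from tissue-composition literature
  table:
    forehead_767: {wavelength_nm: 767.0, mu_a: 0.018, mu_sp: 0.933, n: 1.37}
    forehead_785: {wavelength_nm: 785.0, mu_a: 0.016, mu_sp: 0.901, n: 1.37}
    forehead_850: {wavelength_nm: 850.0, mu_a: 0.020, mu_sp: 0.800, n: 1.37}
  scattering_power: -1.5

geometry:
  slab: {kind: slab, n_fine_layers: 21, fine_layer_thickness_mm: 1.0, mu_s: 0.85}
  shell: {kind: shell, n_fine_layers: 22, fine_layer_thickness_mm: 1.0, mu_s: 0.85,
          shell_outer_radius_mm: 80.0}
  annuli: [[5.0, 1.0], [25.0, 1.0], [30.0, 1.0]]
  # per-layer reduced scattering for the variable-scattering exploration
  # (scalp/skull/brain); requires a dedicated transport run
  variable_mu_s: [0.74, 0.81, 1.16]

fitting:
  fit_window_s: [1.0e-6, 1.0e-2]
  bfi_bounds: [1.0e-12, 1.0e-3]
  beta_bounds: [1.0e-3, 0.6]
  # fixed flows (mm^2/s) of the constrained layers
  skull_bfi: 2.0e-8
  csf_bfi: 5.0e-8
  # per-layer absorption (mm^-1) for scalp/skull/CSF/brain
  mu_a_layers: {scalp: 0.010, skull: 0.033, csf: 0.004, brain: 0.023}

selection:
  ratio_range: [3.0, 8.0]
  subsample_per_detector: 1500

screening:
  min_count_rate_hz: 5000.0
  max_baseline_cov: 0.25
  scalp_drift_pct: 20.0
  persist_s: 30.0

noise:
  sigma0: 0.01
  c: 0.05
  t_ref_s: 10.0

physio:
  lags_s: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  interval_s: [60.0, 250.0]
  etcd: {slope: 3.2, intercept: -0.4}
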