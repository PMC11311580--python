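# Full annotated pipeline configuration for `vaneedle simulate` / `vaneedle
# analyze`.  Every key is optional; omitted keys fall back to the defaults
# shown here.  Unknown keys are rejected.

seed: 20240805          # single global seed; per-recording RNGs are spawned
                        # counter-based from it, so results do not depend on
                        # execution order
out_dir: results        # default output directory
duration_s: null        # fixed recording length in seconds; null = sample
                        # uniformly from 5-15 s per insertion

# ---- synthetic cohort layout (used by `simulate`) -------------------------
cohort:
  - subject_id: Cadaver01
    n_insertions: 13     # total needle insertions for this subject
    n_cavity: 10         # how many reach the peritoneal cavity
    n_ph2_suppressed: 0  # cavity events without a discernible puncture burst

# ---- synthetic event model ------------------------------------------------
sim:
  fs: 16000.0                 # sampling rate, Hz
  noise_rms: 0.005            # stationary background noise RMS (amplitude)
  friction_band: [1800.0, 7000.0]  # inner/outer-core friction band, Hz
  friction_rms: 0.05          # friction RMS amplitude
  friction_logdur: [3.0, 0.6] # log-normal friction duration (log-ms mean, sd)
                              # -> median exp(3.0) ~ 20 ms
  friction_max_ms: 180.0      # truncation so the layout fits the window
  puncture_energy: 8.0        # burst sum-of-squares (sample^2 units)
  puncture_dur_ms: 3.0
  latency_ms: 3.5             # Ph2 onset -> Ph3 onset
  click_energy: 160.0         # click sum-of-squares -> E3/E2 = 20 by design
  click_tauE_fast_ms: 5.0     # bi-exponential energy-envelope constants
  click_tauE_slow_ms: 35.0
  click_weight_fast: 0.95     # fraction of decay energy in the fast term
  click_carrier_hz: [1200.0, 2700.0, 4100.0, 6300.0]
  attack_ms: 1.5              # broadband attack duration
  ph2_present: true
  window_ms: 400.0
  seed: 0                     # overridden by the top-level seed in cohorts

# ---- pre-processing -------------------------------------------------------
gate:                         # spectral-gating noise reduction
  frame_len: 1024             # STFT frame (power of two, >= 2*hop)
  hop: 256
  noise_percentile: 25.0      # per-band noise-floor percentile
  threshold_mult: 3.0         # gate threshold = mult x floor
  attenuation_db: 30.0        # maximum attenuation below threshold
  mask_smoothing: [3, 3]      # (time frames, frequency bins)
  floor_cap_mult: 10.0        # cap per-band floor at 10x the median floor

dwt:                          # wavelet band filter
  wavelet: db4
  levels: 10
  kept_scales: [1, 2, 3, 4, 5]  # detail levels kept (1 = fs/4..fs/2)
  keep_approximation: false

# ---- time-frequency analysis ----------------------------------------------
cwt:
  wavelet: cmor1.5-1.0        # analytic Morlet (bandwidth 1.5, centre 1.0)
  f_min: 100.0
  voices_per_octave: 12

# ---- excitation detection --------------------------------------------------
detector:
  frame_ms: 2.0               # short-time RMS frame
  hop_ms: 0.5
  k_mad: 8.0                  # threshold = median + k x MAD of the envelope
  mad_floor_frac: 0.2         # MAD floored at this fraction of the median
  refractory_ms: 300.0
  cavity_mult: 3.0            # cavity candidate must dominate by this factor
  min_decay_ms: 5.0           # and decay slower than a tissue transient

# ---- phase segmentation ----------------------------------------------------
segmentation:
  env_ms: 0.5                 # segmentation envelope (RMS window)
  ph2_env_ms: 1.0             # heavier smoothing for burst boundaries
  attack_frac: 0.05           # Ph3 onset = last rising 5 %-of-peak crossing
  attack_lookback_ms: 3.0
  recovery_fracs: [0.90, 0.98]  # Ph4/Ph5 and Ph5/Ph6 boundaries
  ph2_window_ms: 15.0
  ph2_guard_ms: 1.0
  ph2_noise_mult: 6.0
  ph2_local_mult: 3.0
  ph2_edge_frac: 0.25
  ph2_low_band: [100.0, 1000.0]  # sub-friction band for the broadband test
  ph2_lowband_mult: 3.0
  ph1_band: [1800.0, 7000.0]
  ph1_mult: 3.0
  ph1_sustain_ms: 5.0
  noise_k_mad: 8.0
  ph6_end_k_mad: 3.0
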