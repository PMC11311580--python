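# Methods

`vaneedle` analyses structure-borne vibroacoustic (VA) signals recorded at
the proximal end of a Veress needle during laparoscopic access.  When the
needle tip enters the peritoneal cavity, the spring-loaded inner stylet
snaps forward and the needle rings freely; tissue–tissue punctures on the
way in are damped almost immediately by the next layer.  That asymmetry is
what makes cavity entry detectable, and the fine phase structure of the
entry excitation is what this package quantifies.

## Signal model

A cavity-puncture excitation decomposes into six phases:

| phase | mechanism | signature |
|-------|-----------|-----------|
| Ph1 | friction between the needle's inner and outer cores | band-limited noise, 1800–7000 Hz, tens of ms |
| Ph2 | breakage of the peritoneum | short broadband burst (~3 ms) |
| Ph3 | attack of the spring-release click | rapid energy rise to the global peak |
| Ph4 | fast post-release decline | first part of the ring-down |
| Ph5 | slower release | second, slower ring-down |
| Ph6 | post-puncture settling | envelope returns to the noise floor |

Phase energies are sums of squared samples, `E = Σ x[n]²`.  The click
energy `E3` spans the whole excitation (attack through settling,
`[Ph3.onset, Ph6.offset)`): that is the quantity whose ratios against the
burst (`E3/E2 ≈ 20`) and the friction (`E3/E1 ≈ 200`) characterise the
event.  Defining `E3` as the 1.5 ms attack alone would make those ratios
meaningless (the attack holds under 10 % of the click energy).

The ring-down is bi-exponential in energy.  With `w` the fraction of decay
energy in the fast component, the squared-amplitude envelope is

    a²(t) ∝ (w/τ_f)·exp(−t/τ_f) + ((1−w)/τ_s)·exp(−t/τ_s)

so the cumulative post-peak energy fraction is exactly
`w(1−e^(−t/τ_f)) + (1−w)(1−e^(−t/τ_s))`.  The recovery time at fraction F
solves that expression for t; with the defaults (`w = 0.95`, `τ_f = 5 ms`,
`τ_s = 35 ms`) the closed forms are t(0.90) ≈ 13.3 ms, t(0.95) ≈ 19.1 ms,
t(0.98) ≈ 34.0 ms.  A single exponential cannot produce this 13/19/34
triple — the fast-then-slow structure is essential.  Note the weighting:
putting `w` directly on the envelope exponentials instead of the energy
densities (`w/τ`) yields cumulative weights `wτ_f : (1−w)τ_s` ≈ 0.73 : 0.27
and t(0.90) ≈ 35 ms — a parametrization that cannot reproduce the observed
recovery times.

## Synthetic data generator

Real recordings of cadaver insertions are not redistributable, so the
generator in `vaneedle.synthetic_data` emulates them with exactly
controlled ground truth.  Each component is rescaled after synthesis so
its sum of squares equals the configured energy; all defaults are the
study conditions:

* background: Gaussian noise, RMS 0.005 (full scale ±1);
* friction: Gaussian noise band-passed to 1800–7000 Hz (order-6
  Butterworth, zero-phase), RMS 0.05, duration log-normal with log-ms mean
  3.0 and sd 0.6 → median ≈ 20 ms with right-skewed dispersion, truncated
  at 180 ms so the layout always fits the 400 ms analysis window
  (untruncated exceedance ≈ 1e-4);
* burst: 3 ms of white noise, total energy 8;
* click: 1.5 ms broadband attack ramping to the decay's starting RMS,
  then four damped cosine carriers (1.2/2.7/4.1/6.3 kHz, random phases)
  under the bi-exponential envelope above, the whole click scaled to total
  energy 160;
* latency: Ph2 onset → Ph3 onset fixed at 3.5 ms (onset-to-onset);
* full recordings additionally carry 1–3 tissue transients (damped
  sinusoids, amplitude ≤ 0.15, amplitude decay constant ≤ 2 ms) and, iff
  the insertion reaches the cavity, one embedded event ≥ 1 s from the
  edges; the annotation instant is the true Ph2 onset.

With these energies the cohort medians are recoverable targets by
construction: E3/E2 = 20, E3/median(E1) = 160/(0.05²·20 ms·16 kHz) = 200.
Ph2-suppressed events (the non-discernible punctures, 13 of 154 in the
cohort layout) are generated with the burst amplitude zero and its energy
*not* reallocated.

What the generator does **not** emulate: insertion-speed-dependent,
non-stationary friction; colored or transient ambient noise; sensor and
coupling transfer functions; overlapping events; needle-model variation.
Passing tests therefore demonstrate that the pipeline recovers the phase
structure and statistics under the stated phenomenology, not that it
would do so on arbitrary clinical recordings.

All randomness flows from one integer seed through
`numpy.random.SeedSequence`; per-recording generators are spawned
counter-based (`[seed, subject, insertion]`) so cohorts are reproducible
independent of generation order.

## Pre-processing

1. **DC removal** — mean subtraction.
2. **Spectral gate** — STFT (hann 1024, hop 256 at 16 kHz), per-band noise
   floor = 25th percentile of the band's magnitude over time, threshold
   3× floor, bins below threshold attenuated 30 dB, gain mask box-smoothed
   over 3×3 (time × frequency) bins.  Two robustness choices beyond the
   basic rule: (a) each band's floor is capped at 10× the cross-band
   median floor — the percentile rule is self-referential for persistent
   narrowband content (a stationary in-band tone inflates its own floor
   and would be gated by ~27 dB; with the cap it passes within 1 dB);
   (b) gains are ≤ 1 everywhere, so no bin is ever amplified.  On
   stationary white noise the gate removes ≈ 12 dB.
3. **DWT band filter** — 10-level `db4` decomposition, symmetric
   extension; reconstruction keeps detail levels 1–5 (≈ 250 Hz–8 kHz at
   16 kHz) and discards the approximation, removing baseline trend and
   emphasising the high-frequency interaction dynamics.  The order (4)
   and the kept levels are declared defaults, both configurable.

**Two measurement tracks.**  Segmentation and detection run on the fully
preprocessed signal.  Phase *energies* and recovery times, however, are
quantified on a DC-removed + DWT-filtered track without the spectral
gate: friction sits only ~7× above the per-bin gate floor, so the mask
removes 8–10 % of its energy and would bias the cohort E3/E1 median by
~+10 %, while the ungated track adds only ~1 % noise energy to E1.  The
gate exists to make detection robust, not to define energies.

## Event analysis

* **Segment extraction** — a 400 ms window centred on the annotated
  instant (centering maximises pre/post context); annotations closer than
  200 ms to an edge are boundary errors, never padded.
* **Scalogram** — analytic Morlet CWT (`cmor1.5-1.0`), log-spaced grid
  from 100 Hz to Nyquist at 12 voices/octave, FFT-accelerated; a
  brute-force inner-product oracle on short signals pins down
  correctness in the tests.
* **Excitation detection** — short-time RMS envelope (2 ms frames,
  0.5 ms hop); threshold = median + 8·MAD with the MAD floored at 20 % of
  the median (heavily gated noise otherwise collapses the MAD and lets
  residual gating artifacts graze the threshold); local maxima above
  threshold with a 300 ms refractory period.  A peak is a *cavity
  candidate* when it dominates every other detected transient by ≥ 3×
  and its decay (time above a noise-referenced 20 % of peak) lasts
  ≥ 5 ms — tissue transients decay in ~2 ms, the free click ring-down in
  ~20 ms, so the margin is wide on both criteria.
* **Phase segmentation** (on a 0.5 ms RMS envelope; the 2 ms detection
  envelope cannot resolve the 0.5 ms gap between burst and attack):
  * attack peak = envelope argmax; segments whose peak stays within
    median + 8·MAD of the envelope raise a not-an-event error.  Envelope
    noise statistics use the 20th percentile (level) and the 20th→40th
    inter-percentile distance (spread): the click's slow tail occupies up
    to half the window and corrupts a plain median.
  * Ph3 onset = last rising crossing of 5 % of the peak, searched within
    a 3 ms lookback behind the attack's 50 %-rise point; if noise-
    reduction smearing fills the burst→attack gap above the 5 % level,
    the envelope minimum in the lookback stands in.  Without the
    lookback restriction the burst (33 % of peak) captures the crossing
    and the onset lands 3.5 ms early.
  * Ph4/Ph5 boundary = 90 % and Ph5/Ph6 boundary = 98 % post-peak
    cumulative energy; Ph6 ends when the envelope returns below
    noise + 3·MAD (or at the segment end — full settling typically
    outlasts the window).
  * Ph2 = supra-threshold run (1 ms envelope; threshold
    max(6× noise level, 3× window median — the second term keeps the
    friction plateau out)) in a 15 ms window before the Ph3 onset,
    bounds refined at 25 % of the run peak.  The *broadband*
    confirmation is time-domain: median 100–1000 Hz (sub-friction-band)
    envelope over the candidate ≥ 3× the window's own median in that
    band.  A scalogram-spread criterion was evaluated and rejected: at
    200 Hz the wavelet's time support is ~4 ms, so the click's
    low-frequency response floods any candidate abutting it, and the
    spectral gate pre-echoes click energy over the preceding ~10 ms;
    both effects turn pure-friction candidates "broadband".  On 924
    synthetic events across six seeds the final criterion makes 0
    false-positive and 0 false-negative Ph2 calls.
  * Ph1 = first sustained (≥ 5 ms at 80 % duty) crossing of the
    1800–7000 Hz band envelope above max(3× band floor, 50 % of the
    pre-burst friction plateau), searched before the Ph2 onset.  The
    plateau anchor guards against gate leakage, which restores
    full-level noise in whole STFT frames around the event.

## Cohort statistics

Quartiles use linear interpolation between order statistics; boxplot
whiskers are the most extreme points within 1.5×IQR, values beyond are
outliers.  Undefined metrics (latency and E2-derived quantities of
Ph2-absent events) are excluded from medians, never zero-filled.  Energy
ratios are reported both as percentages of E3 (boxplot convention) and as
fold changes E3/E1, E3/E2.

## Problem sizes

The reproduction script and the acceptance tests use cohorts of 154
insertions / 154 event segments (the study's cavity count) and a
100-event cohort for the energy ratios; property sweeps run 1000 random
events.  At these sizes the full reproduction completes in about half a
minute on one CPU.

## Known limitations

* The Ph1 onset rule misses very short friction phases (< ~5 ms,
  ≈ 1 % of log-normal draws) and can clip very long ones (> 180 ms,
  truncated by the generator anyway).
* Ph6's "cessation of vibration" usually falls outside the 400 ms
  window; total event duration therefore uses the 98 % recovery point,
  not full settling.
* The spectral gate trades ~0.9 dB of narrowband signal (hann-leakage
  bins straddling the mask edge) for its noise reduction; energy metrics
  avoid the gate entirely (two-track design above).
* Cohort counts in the analysis drivers take the annotation's
  reached-cavity flag as ground truth; mis-annotated recordings would
  propagate into the counts, as in any annotation-driven study.
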