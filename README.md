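# vaneedle

Vibroacoustic analysis of Veress-needle insertion signals: detection and
six-phase segmentation of peritoneum-puncture events, with a calibrated
synthetic-signal generator so the whole pipeline is testable end to end.

## The problem

Establishing laparoscopic access with a Veress needle relies on subjective
touch and audible cues; mis-placed insertions cause a large share of
laparoscopic complications.  A piezo element coupled to the needle's
proximal Luer-lock records the structure-borne vibroacoustic (VA) signal
of the tip–tissue interaction.  When the tip enters the peritoneal cavity
the spring-loaded inner stylet snaps forward and the needle rings freely —
a high-energy "click" that dwarfs the rapidly damped transients of
tissue–tissue punctures.  This package implements the signal-processing
side of that idea for engineers and researchers working on VA surgical
guidance: given 16 kHz mono WAVE recordings and per-recording annotations
of the approximate puncture instant, it detects cavity excitations and
quantifies the phase structure of each puncture event.

## Model and pipeline

A cavity-puncture excitation decomposes into six phases: inner/outer-core
friction (**Ph1**, band-limited to 1800–7000 Hz), peritoneum tissue
breakage (**Ph2**, a ~3 ms broadband burst), the click attack (**Ph3**),
fast and slow recovery (**Ph4**, **Ph5**) and post-puncture settling
(**Ph6**).  Phase energies are sums of squares, `E = Σ x[n]²`; the click
ring-down is bi-exponential in energy,

    a²(t) ∝ (w/τ_f) e^(−t/τ_f) + ((1−w)/τ_s) e^(−t/τ_s),

so the recovery time at energy fraction F solves
`w(1−e^(−t/τ_f)) + (1−w)(1−e^(−t/τ_s)) = F`.

The pipeline (all stages in `src/vaneedle/`):

1. `preprocessing` — DC removal, spectral-gating noise reduction,
   Daubechies DWT band filter;
2. `event_analysis` — 400 ms segment extraction around the annotation,
   Morlet CWT scalogram, short-time-RMS excitation detection, and
   envelope/cumulative-energy segmentation of Ph1–Ph6;
3. `metrics` — per-event energies E1–E3, energy ratios, friction
   duration, Ph2→Ph3 latency, 90/95/98 % recovery times, and cohort
   boxplot statistics;
4. `synthetic_data` — a generator producing insertion recordings with
   exact ground truth (component energies 160 / 8 / median 0.8 in
   sample² units, i.e. E3/E2 = 20× and E3/median(E1) = 200× by
   construction);
5. `signal_io`, `pipeline`, `cli` — WAVE/CSV I/O, YAML-configured runs,
   and the `vaneedle simulate | analyze | report` commands.

See `docs/methods.md` for the full model description, parameter tables
and design choices.

## Worked example

```python
from vaneedle import (simulate_event, preprocess, compute_cwt,
                      segment_phases, compute_event_metrics)
from vaneedle.preprocessing import remove_dc, dwt_filter

segment, truth = simulate_event(seed=1)       # one 400 ms cavity event
denoised = preprocess(segment)                # DC -> gate -> DWT
quant = dwt_filter(remove_dc(segment))        # energy-measurement track
bounds = segment_phases(denoised, compute_cwt(denoised))
m = compute_event_metrics(quant, bounds)
```

which prints, formatted:

```
Ph1 (friction):  175.3 -> 199.7 ms (duration 24.4 ms, true 24.7)
Ph2 (puncture):  onset 199.7 ms, E2 = 7.70
Ph3 (attack):    onset 203.6 ms, latency 3.94 ms
click energy E3 = 158.5;  E3/E2 = 20.6x, E3/E1 = 162x
recovery 90/95/98%: 13.6 / 19.3 / 35.1 ms
total event duration: 63.6 ms
```

Reading this: the needle's core friction ran for 24.4 ms before the
membrane broke (burst energy 7.70 ≈ the configured 8); the spring
released 3.94 ms after breakage; the click carried ~20× the burst energy;
90 % of the ring-down energy arrived within 13.6 ms; the whole event took
64 ms — faster than human perception, which is why automated detection
is useful.  (E3/E1 is 162× *for this event* because this friction phase
ran longer than the 20 ms median; the cohort median is ≈ 200×.)

## The analysis

`analysis/` holds numbered drivers that rebuild the study tables from
scratch (outputs under `results/`, bulky WAVE data under `scratch/`):

```bash
python analysis/01_simulate_cohort.py        # 193-insertion cohort as WAVE+CSV
python analysis/02_detection_completeness.py # detection rate on 154 cavity entries
python analysis/03_segment_cohort.py         # full pipeline over the WAVE cohort
python analysis/04_phase_statistics.py       # phase medians and boxplots
```

`03` prints the per-subject count table (insertions / cavity reached /
excitations / Ph1 / Ph2 / Ph3 present) with totals
193 / 154 / 154 / 154 / 141 / 154, and `04` the phase-metric medians.
The CLI exposes the same pipeline for arbitrary data:
`vaneedle analyze <wav_dir> --annotations <csv> --config examples/pipeline.yaml`.

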