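"""Event extraction, time–frequency analysis and six-phase segmentation.

A confirmed cavity-puncture excitation decomposes into six phases:

* **Ph1** — friction between the needle's inner and outer cores
  (band-limited, 1800–7000 Hz),
* **Ph2** — peritoneum tissue breakage (short broadband burst),
* **Ph3** — attack of the spring-release click (rapid energy rise),
* **Ph4** — fast decline after the release,
* **Ph5** — slower release phase,
* **Ph6** — post-puncture settling until needle vibration ceases.

Segmentation works on short-time RMS amplitude envelopes: the attack
peak is the envelope maximum, Ph3's onset is the last rising crossing of
5 % of the peak, the Ph4/Ph5 and Ph5/Ph6 boundaries are the 90 % and
98 % post-peak cumulative-energy points, Ph2 is a supra-threshold burst
in a short pre-attack window whose broadband nature is confirmed by
energy below the friction band, and Ph1 is sustained band-limited
(1800–7000 Hz) energy before the burst.  The CWT scalogram provides the
time–frequency view of the same phases for inspection and reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "EventSegment",
    "Scalogram",
    "PhaseInterval",
    "PhaseBounds",
    "CWTParams",
    "DetectorParams",
    "SegmentationParams",
    "Excitation",
    "NotAnEventError",
    "extract_segment",
    "compute_cwt",
    "detect_excitations",
    "segment_phases",
]


class NotAnEventError(ValueError):
    """Raised when a segment contains no excitation above the noise."""


@dataclass
class EventSegment:
    """A 400 ms analysis window around an annotated puncture instant."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0  # absolute start time within the parent recording, s
    annotation_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times (seconds in the parent recording)."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EventSegment":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class Scalogram:
    """CWT magnitude over a (frequency, time) grid."""

    magnitude: np.ndarray  # shape (n_freqs, n_times), all >= 0
    frequencies: np.ndarray  # Hz, monotone ascending
    times: np.ndarray  # seconds, aligned to the segment

    def __post_init__(self) -> None:
        assert self.magnitude.shape == (self.frequencies.size, self.times.size)


@dataclass(frozen=True)
class PhaseInterval:
    onset: float = math.nan
    offset: float = math.nan
    present: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset if self.present else math.nan


_ABSENT = PhaseInterval()


@dataclass
class PhaseBounds:
    """Onsets/offsets/presence of phases Ph1–Ph6 within a segment."""

    ph1: PhaseInterval = _ABSENT
    ph2: PhaseInterval = _ABSENT
    ph3: PhaseInterval = _ABSENT
    ph4: PhaseInterval = _ABSENT
    ph5: PhaseInterval = _ABSENT
    ph6: PhaseInterval = _ABSENT
    attack_peak_time: float = math.nan

    def phase(self, name: str) -> PhaseInterval:
        return getattr(self, name.lower())

    def validate(self) -> None:
        """Check the phase-ordering invariants among present phases."""
        for name in ("ph1", "ph2", "ph3", "ph4", "ph5", "ph6"):
            iv = self.phase(name)
            if iv.present and not iv.onset < iv.offset:
                raise AssertionError(f"{name}: onset !< offset ({iv})")
        chain = []
        if self.ph1.present:
            chain.append(("ph1.offset", self.ph1.offset))
        if self.ph2.present:
            chain.append(("ph2.onset", self.ph2.onset))
        if self.ph3.present:
            chain.append(("ph3.onset", self.ph3.onset))
            chain.append(("attack_peak", self.attack_peak_time))
        if self.ph4.present:
            chain.append(("ph4.onset", self.ph4.onset))
        for (na, a), (nb, b) in zip(chain, chain[1:]):
            if a > b + 1e-12:
                raise AssertionError(f"ordering violated: {na}={a} > {nb}={b}")
        if self.ph4.present and self.ph5.present:
            assert math.isclose(self.ph4.offset, self.ph5.onset)
        if self.ph5.present and self.ph6.present:
            assert math.isclose(self.ph5.offset, self.ph6.onset)


@dataclass
class CWTParams:
    """Analytic (Morlet-type) CWT on a log-spaced frequency grid."""

    wavelet: str = "cmor1.5-1.0"
    f_min: float = 100.0
    voices_per_octave: int = 12

    def frequency_grid(self, fs: float) -> np.ndarray:
        n_oct = math.log2((fs / 2) / self.f_min)
        k = np.arange(math.floor(n_oct * self.voices_per_octave) + 1)
        return self.f_min * 2.0 ** (k / self.voices_per_octave)


@dataclass
class DetectorParams:
    """Excitation detector settings (short-time RMS envelope)."""

    frame_ms: float = 2.0
    hop_ms: float = 0.5
    k_mad: float = 8.0
    refractory_ms: float = 300.0
    cavity_mult: float = 3.0
    min_decay_ms: float = 5.0
    #: floor on the MAD as a fraction of the median envelope; after heavy
    #: noise gating the raw MAD collapses and residual gating artifacts
    #: would otherwise graze the threshold.
    mad_floor_frac: float = 0.2


@dataclass
class SegmentationParams:
    """Phase-segmentation settings.

    The segmentation envelope is a centred sliding RMS of ``env_ms``
    (default 0.5 ms — fine enough to resolve the few-ms gap between the
    puncture burst and the click attack).
    """

    env_ms: float = 0.5
    ph2_env_ms: float = 1.0  # heavier smoothing for burst boundary refinement
    attack_frac: float = 0.05  # Ph3 onset = last rising crossing of this × peak
    attack_lookback_ms: float = 3.0  # onset search span behind the 50 % rise
    recovery_fracs: tuple[float, float] = (0.90, 0.98)  # Ph4/Ph5, Ph5/Ph6 bounds
    ph2_window_ms: float = 15.0
    ph2_guard_ms: float = 1.0
    ph2_noise_mult: float = 6.0
    ph2_local_mult: float = 3.0
    ph2_edge_frac: float = 0.25
    #: a candidate burst counts as broadband when it carries energy below
    #: the friction band: median 100-1000 Hz envelope >= mult x that
    #: band's floor.  (A scalogram-spread test is unreliable here: the
    #: click's low-frequency wavelet response smears several ms backwards
    #: over any interval that abuts it.)
    ph2_low_band: tuple[float, float] = (100.0, 1000.0)
    ph2_lowband_mult: float = 3.0
    ph1_band: tuple[float, float] = (1800.0, 7000.0)
    ph1_mult: float = 3.0
    ph1_sustain_ms: float = 5.0
    noise_k_mad: float = 8.0  # excitation-confirmation threshold
    ph6_end_k_mad: float = 3.0


@dataclass(frozen=True)
class Excitation:
    """One detected excitation in a recording."""

    time: float  # envelope-peak time, s
    peak_envelope: float
    is_cavity_candidate: bool
    decay_ms: float


def extract_segment(recording, t_annot: float, window_s: float = 0.4) -> EventSegment:
    """Extract the analysis window centred on the annotated instant.

    The window must fit entirely inside the recording; annotations within
    ``window_s / 2`` of either edge raise a boundary error (no padding).
    """
    fs = recording.fs
    n = recording.samples.size
    n_win = round(window_s * fs)
    i_center = round(t_annot * fs)
    i0 = i_center - n_win // 2
    i1 = i0 + n_win
    if i0 < 0 or i1 > n:
        raise ValueError(
            f"annotation at {t_annot} s too close to the edge for a "
            f"{window_s} s window (recording is {n / fs} s)"
        )
    return EventSegment(
        samples=recording.samples[i0:i1].copy(),
        fs=fs,
        t0=i0 / fs,
        annotation_time=t_annot,
    )


def compute_cwt(segment: EventSegment, params: CWTParams | None = None) -> Scalogram:
    """Morlet-type CWT magnitude on a log-spaced grid (≥ 12 voices/octave)."""
    params = params or CWTParams()
    x = segment.samples
    if x.size == 0:
        raise ValueError("empty segment")
    fs = segment.fs
    freqs = params.frequency_grid(fs)
    fc = pywt.central_frequency(params.wavelet)
    # row i of the coefficient matrix follows scales[i] = fc*fs/freqs[i],
    # so rows already align with the ascending frequency grid
    scales = fc * fs / freqs
    coefs, _ = pywt.cwt(x, scales, params.wavelet, sampling_period=1.0 / fs,
                        method="fft")
    return Scalogram(magnitude=np.abs(coefs), frequencies=freqs,
                     times=segment.times)


def _rms_envelope(x: np.ndarray, fs: float, win_ms: float) -> np.ndarray:
    n_win = max(1, round(win_ms * fs / 1000.0))
    # clip: the moving average of x**2 can go epsilon-negative by cancellation
    return np.sqrt(np.maximum(uniform_filter1d(x**2, size=n_win, mode="nearest"), 0.0))


def _frame_envelope(x: np.ndarray, fs: float, frame_ms: float, hop_ms: float):
    """Framed RMS envelope; returns (env, frame_centre_times)."""
    n_frame = max(1, round(frame_ms * fs / 1000.0))
    n_hop = max(1, round(hop_ms * fs / 1000.0))
    if x.size < n_frame:
        raise ValueError("signal shorter than one envelope frame")
    c = np.concatenate([[0.0], np.cumsum(x**2)])
    starts = np.arange(0, x.size - n_frame + 1, n_hop)
    env = np.sqrt((c[starts + n_frame] - c[starts]) / n_frame)
    times = (starts + n_frame / 2) / fs
    return env, times, n_hop, n_frame


def detect_excitations(
    recording, params: DetectorParams | None = None
) -> list[Excitation]:
    """Find excitation peaks in a (preprocessed) recording.

    The short-time RMS envelope is thresholded at ``median + k·MAD``;
    local maxima above threshold are kept with a refractory period.  A
    peak is a cavity candidate when its envelope dominates every other
    transient by ``cavity_mult`` × and its post-peak decay (time above
    20 % of the peak, noise-referenced) lasts at least ``min_decay_ms`` —
    tissue–tissue transients are damped much faster than the free
    oscillation after cavity entry.
    """
    params = params or DetectorParams()
    x, fs = np.asarray(recording.samples, float), recording.fs
    env, times, n_hop, _ = _frame_envelope(x, fs, params.frame_ms, params.hop_ms)
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    mad = max(mad, params.mad_floor_frac * med)
    thr = med + params.k_mad * mad
    min_dist = max(1, round(params.refractory_ms * fs / 1000.0 / n_hop))
    peaks, _props = find_peaks(env, height=thr, distance=min_dist)
    if peaks.size == 0:
        return []

    hop_ms = 1000.0 * n_hop / fs
    sub_thr_max = float(np.max(env[env < thr])) if np.any(env < thr) else med

    out: list[Excitation] = []
    for p in peaks:
        peak = float(env[p])
        # post-peak decay: frames until the envelope drops below
        # noise + 20 % of the peak elevation
        level = med + 0.2 * (peak - med)
        below = np.nonzero(env[p:] < level)[0]
        decay_ms = float(below[0] * hop_ms) if below.size else float(
            (env.size - p) * hop_ms
        )
        others = [float(env[q]) for q in peaks if q != p]
        ref = max(others) if others else sub_thr_max
        is_cavity = peak >= params.cavity_mult * ref and decay_ms >= params.min_decay_ms
        out.append(
            Excitation(
                time=float(times[p]),
                peak_envelope=peak,
                is_cavity_candidate=is_cavity,
                decay_ms=decay_ms,
            )
        )
    return out


def _band_envelope(x: np.ndarray, fs: float, band: tuple[float, float],
                   win_ms: float) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return _rms_envelope(sosfiltfilt(sos, x), fs, win_ms)


def _sustained_crossing(above: np.ndarray, n_sustain: int, min_frac: float = 0.8):
    """First index where ``above`` holds for >= min_frac of n_sustain samples."""
    if above.size == 0:
        return None
    frac = uniform_filter1d(above.astype(float), size=n_sustain, mode="nearest",
                            origin=-(n_sustain // 2))
    idx = np.nonzero(above & (frac >= min_frac))[0]
    return int(idx[0]) if idx.size else None


def segment_phases(
    segment: EventSegment,
    scalogram: Scalogram | None = None,
    params: SegmentationParams | None = None,
) -> PhaseBounds:
    """Segment a confirmed excitation into phases Ph1–Ph6.

    Raises :class:`NotAnEventError` when the envelope never exceeds the
    robust noise threshold.  ``scalogram`` is accepted for interface
    symmetry with the reporting path; the segmentation itself operates on
    time-domain envelopes (see :class:`SegmentationParams`).
    """
    params = params or SegmentationParams()
    x, fs = segment.samples, segment.fs
    n = x.size
    env = _rms_envelope(x, fs, params.env_ms)
    # Robust noise statistics: the click's slow tail can occupy a large
    # part of the window, so low percentiles of the envelope stand in for
    # the background level (20th) and spread (20th->40th distance).
    med, p40 = (float(v) for v in np.percentile(env, [20.0, 40.0]))
    mad = max(p40 - med, 1e-15)
    i_peak = int(np.argmax(env))
    peak = float(env[i_peak])
    if peak < med + params.noise_k_mad * mad or peak <= 0:
        raise NotAnEventError("no envelope peak above the noise threshold")

    def t(i: int) -> float:
        return segment.t0 + i / fs

    # --- Ph3: last rising crossing of attack_frac * peak before the peak.
    # The search is confined to a short lookback behind the attack's 50 %
    # rise point so that the preceding burst (whose envelope also exceeds
    # 5 % of the peak) cannot capture the onset; if the envelope never
    # dips below the 5 % level there (noise-reduction smearing can fill
    # the brief burst->attack gap), the envelope minimum stands in.
    a3 = params.attack_frac * peak
    half = np.nonzero(env[: i_peak + 1] < 0.5 * peak)[0]
    i_hi = int(half[-1]) if half.size else 0
    j0 = max(0, i_hi - round(params.attack_lookback_ms * fs / 1000.0))
    below = np.nonzero(env[j0: i_hi + 1] < a3)[0]
    if below.size:
        i3 = j0 + int(below[-1]) + 1
    else:
        i3 = j0 + int(np.argmin(env[j0: i_hi + 1]))
    i3 = min(i3, i_peak)
    attack_peak_time = t(i_peak)
    ph3 = PhaseInterval(onset=t(i3), offset=attack_peak_time, present=True)

    # --- post-peak cumulative energy -> Ph4/Ph5/Ph6 boundaries
    post = x[i_peak:] ** 2
    cum = np.cumsum(post)
    total = cum[-1]
    if total <= 0:
        raise NotAnEventError("zero post-peak energy")
    f_fast, f_slow = params.recovery_fracs
    i90 = i_peak + int(np.searchsorted(cum, f_fast * total))
    i98 = i_peak + int(np.searchsorted(cum, f_slow * total))
    i90 = max(i90, i_peak + 1)
    i98 = max(i98, i90 + 1)
    # Ph6 ends when the envelope returns below noise floor + k*MAD
    end_level = med + params.ph6_end_k_mad * mad
    tail_below = np.nonzero(env[i98:] < end_level)[0]
    i_end = i98 + int(tail_below[0]) if tail_below.size else n
    i_end = max(i_end, i98 + 1)
    ph4 = PhaseInterval(onset=t(i_peak), offset=t(i90), present=True)
    ph5 = PhaseInterval(onset=t(i90), offset=t(i98), present=True)
    ph6 = PhaseInterval(onset=t(i98), offset=t(min(i_end, n)), present=True)

    # --- Ph2: broadband burst in a short window before the Ph3 onset
    w0 = max(0, i3 - round(params.ph2_window_ms * fs / 1000.0))
    w1 = max(w0, i3 - round(params.ph2_guard_ms * fs / 1000.0))
    ph2 = _ABSENT
    if w1 - w0 > 2:
        env2 = _rms_envelope(x, fs, params.ph2_env_ms)
        win_env = env2[w0:w1]
        thr2 = max(
            params.ph2_noise_mult * max(med, 1e-12),
            params.ph2_local_mult * float(np.median(win_env)),
        )
        runs = _runs(win_env >= thr2)
        if runs:
            low_env = _band_envelope(x, fs, params.ph2_low_band, params.ph2_env_ms)
            # local floor: noise gating can pre-echo the click's low-band
            # energy over the last tens of ms, so the window's own median
            # is the only fair reference level
            low_floor = float(np.median(low_env[w0:w1]))
        best = None
        for r0, r1 in sorted(
            runs, key=lambda r: -float(np.max(win_env[r[0]: r[1]]))
        ):
            run_peak = float(np.max(win_env[r0:r1]))
            edge = params.ph2_edge_frac * run_peak
            # widen the run to its edge-fraction crossings
            below_lo = np.nonzero(env2[w0: w0 + r0] < edge)[0]
            lo = w0 + (int(below_lo[-1]) + 1 if below_lo.size else 0)
            # the offset may extend past the detection window up to the
            # Ph3 onset (the guard only shields candidate *detection*)
            above_hi = np.nonzero(env2[w0 + r1: i3] >= edge)[0]
            hi = w0 + r1 + (int(above_hi[-1]) + 1 if above_hi.size else 0)
            broadband = float(np.median(low_env[lo:hi])) >= (
                params.ph2_lowband_mult * max(low_floor, 1e-12)
            )
            if broadband:
                best = (lo, hi)
                break
        if best is not None:
            lo, hi = best
            ph2 = PhaseInterval(onset=t(lo), offset=t(min(hi, i3)), present=True)

    # --- Ph1: sustained band-limited energy before the burst (or attack)
    i_ph1_end = int(round((ph2.onset - segment.t0) * fs)) if ph2.present else i3
    ph1 = _ABSENT
    if i_ph1_end > 8:
        band_env = _band_envelope(x, fs, params.ph1_band, params.env_ms)
        # 20th percentile: robust to the event occupying up to ~half the window
        floor = float(np.percentile(band_env, 20.0))
        # friction plateau just before the burst; anchoring the onset
        # threshold to it guards against spectral-gate leakage, which
        # restores full-level noise in whole STFT frames around the event
        n_plat = max(1, round(5.0 * fs / 1000.0))
        plateau = float(np.median(band_env[max(0, i_ph1_end - n_plat): i_ph1_end]))
        thr1 = max(params.ph1_mult * max(floor, 1e-12), 0.5 * plateau)
        n_sus = max(1, round(params.ph1_sustain_ms * fs / 1000.0))
        region = band_env[:i_ph1_end]
        onset_i = _sustained_crossing(region >= thr1, n_sus)
        if onset_i is not None:
            above_i = np.nonzero(region[onset_i:] >= thr1)[0]
            off_i = onset_i + int(above_i[-1]) + 1 if above_i.size else i_ph1_end
            off_i = min(off_i, i_ph1_end)
            if off_i > onset_i:
                ph1 = PhaseInterval(onset=t(onset_i), offset=t(off_i), present=True)

    bounds = PhaseBounds(
        ph1=ph1, ph2=ph2, ph3=ph3, ph4=ph4, ph5=ph5, ph6=ph6,
        attack_peak_time=attack_peak_time,
    )
    bounds.validate()
    return bounds


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as [start, stop) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))
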