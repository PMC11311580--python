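"""Segment extraction, CWT scalogram, excitation detection, phase bounds."""


import numpy as np
import pytest
from scipy.signal import fftconvolve, find_peaks

from vaneedle.event_analysis import (
    EventSegment,
    NotAnEventError,
    compute_cwt,
    detect_excitations,
    extract_segment,
    segment_phases,
)
from vaneedle.preprocessing import preprocess
from vaneedle.signal_io import Recording
from vaneedle.synthetic_data import SimEventConfig, simulate_event, simulate_insertion

FS = 16000.0


def _segment(x, fs=FS):
    return EventSegment(samples=np.asarray(x, float), fs=fs)


class TestExtractSegment:
    def test_window_arithmetic(self):
        rec = Recording(samples=np.arange(160000) / 160000.0, fs=FS)
        seg = extract_segment(rec, t_annot=1.0, window_s=0.4)
        assert seg.samples.size == 6400
        assert seg.t0 == pytest.approx(0.8)
        # covers [0.8 s, 1.2 s)
        np.testing.assert_array_equal(seg.samples, rec.samples[12800:19200])

    def test_boundary_error_near_edges(self):
        rec = Recording(samples=np.zeros(160000), fs=FS)
        with pytest.raises(ValueError):
            extract_segment(rec, t_annot=0.1)
        with pytest.raises(ValueError):
            extract_segment(rec, t_annot=9.95)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        rec = Recording(samples=rng.normal(0, 0.1, 32000), fs=FS)
        a = extract_segment(rec, 1.0)
        b = extract_segment(rec, 1.0)
        np.testing.assert_array_equal(a.samples, b.samples)


def _brute_force_profile(x, fs, freqs, bandwidth=1.5, center=1.0):
    """Independent CWT oracle: direct inner products with sampled Morlet
    atoms, psi(u) = (pi*B)^(-1/2) exp(-u^2/B) exp(2j*pi*C*u)."""
    profile = []
    for f in freqs:
        a = center * fs / f  # scale in samples
        half = int(np.ceil(4 * a * np.sqrt(bandwidth)))
        u = np.arange(-half, half + 1) / a
        psi = (np.pi * bandwidth) ** -0.5 * np.exp(-(u**2) / bandwidth) * np.exp(
            2j * np.pi * center * u
        )
        w = fftconvolve(x, np.conj(psi[::-1]), mode="same") / np.sqrt(a)
        profile.append(np.mean(np.abs(w)))
    return np.asarray(profile)


class TestComputeCWT:
    def test_pure_tone_peak_frequency(self):
        t = np.arange(6400) / FS
        seg = _segment(0.2 * np.sin(2 * np.pi * 1000 * t))
        scal = compute_cwt(seg)
        f_peak = scal.frequencies[np.argmax(scal.magnitude.mean(axis=1))]
        assert abs(f_peak - 1000) / 1000 <= 0.05

    def test_impulse_localized_at_every_frequency(self):
        x = np.zeros(6400)
        x[3200] = 1.0
        scal = compute_cwt(_segment(x))
        t_max = scal.times[np.argmax(scal.magnitude, axis=1)]
        assert np.all(np.abs(t_max - 0.2) <= 2e-3)

    def test_two_tones_give_two_peaks_near_true_frequencies(self):
        t = np.arange(6400) / FS
        x = 0.2 * np.sin(2 * np.pi * 1000 * t) + 0.2 * np.sin(2 * np.pi * 5000 * t)
        scal = compute_cwt(_segment(x))
        profile = scal.magnitude.mean(axis=1)
        peaks, _ = find_peaks(profile, prominence=0.1 * profile.max())
        f_peaks = scal.frequencies[peaks]
        assert any(abs(f - 1000) / 1000 <= 0.05 for f in f_peaks)
        assert any(abs(f - 5000) / 5000 <= 0.05 for f in f_peaks)

    def test_agrees_with_brute_force_inner_products(self):
        """The FFT-accelerated implementation matches direct inner products
        with sampled wavelets (shape of the time-averaged spectrum)."""
        rng = np.random.default_rng(6)
        t = np.arange(1600) / FS
        x = (0.2 * np.sin(2 * np.pi * 700 * t)
             + 0.1 * np.sin(2 * np.pi * 3200 * t)
             + 0.01 * rng.normal(size=t.size))
        seg = _segment(x)
        scal = compute_cwt(seg)
        oracle = _brute_force_profile(x, FS, scal.frequencies)
        mine = scal.magnitude.mean(axis=1)
        r = np.corrcoef(mine / mine.max(), oracle / oracle.max())[0, 1]
        assert r >= 0.98

    def test_grid_and_invariants(self):
        seg, _ = simulate_event(seed=0)
        scal = compute_cwt(seg)
        assert np.all(scal.magnitude >= 0)
        assert np.all(np.diff(scal.frequencies) > 0)
        assert scal.frequencies[0] == pytest.approx(100.0)
        assert scal.frequencies[-1] <= FS / 2
        # >= 12 voices per octave
        ratio = scal.frequencies[1] / scal.frequencies[0]
        assert ratio <= 2 ** (1 / 12) + 1e-9

    def test_deterministic(self):
        seg, _ = simulate_event(seed=0)
        a = compute_cwt(seg).magnitude
        b = compute_cwt(seg).magnitude
        np.testing.assert_array_equal(a, b)


class TestDetectExcitations:
    def test_pure_noise_gives_empty_list(self, noise_only_recording):
        proc = preprocess(noise_only_recording)
        assert detect_excitations(proc) == []

    def test_cavity_insertion_yields_one_candidate_near_truth(
        self, cavity_insertion
    ):
        rec, _, truth = cavity_insertion
        proc = preprocess(rec)
        cands = [e for e in detect_excitations(proc) if e.is_cavity_candidate]
        assert len(cands) == 1
        assert abs(cands[0].time - truth.attack_peak) <= 10e-3

    def test_no_cavity_insertion_yields_zero_candidates(self):
        for seed in (11, 12, 13):
            rec, _, _ = simulate_insertion(seed=seed, reached_cavity=False,
                                           duration_s=6.0)
            proc = preprocess(rec)
            cands = [e for e in detect_excitations(proc) if e.is_cavity_candidate]
            assert cands == []


class TestSegmentPhases:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_onsets_within_2ms_of_ground_truth(self, seed):
        seg, truth = simulate_event(seed=seed)
        proc = preprocess(seg)
        bounds = segment_phases(proc, compute_cwt(proc))
        assert bounds.ph1.present and bounds.ph2.present and bounds.ph3.present
        assert abs(bounds.ph1.onset - truth.ph1_onset) <= 2e-3
        assert abs(bounds.ph2.onset - truth.ph2_onset) <= 2e-3
        assert abs(bounds.ph3.onset - truth.ph3_onset) <= 2e-3

    def test_suppressed_burst_gives_absent_ph2_but_ph1_ph3_found(self):
        cfg = SimEventConfig(ph2_present=False)
        for seed in (1, 2, 3):
            seg, truth = simulate_event(cfg, seed=seed)
            proc = preprocess(seg)
            bounds = segment_phases(proc, compute_cwt(proc))
            assert not bounds.ph2.present
            assert bounds.ph1.present and bounds.ph3.present
            assert abs(bounds.ph3.onset - truth.ph3_onset) <= 2e-3

    def test_phase_ordering_invariants_random_batch(self):
        """PhaseBounds.validate() passes on a batch of random events
        (the full 1000-event sweep runs in the acceptance suite)."""
        for k in range(40):
            cfg = SimEventConfig(ph2_present=(k % 5 != 0))
            seg, _ = simulate_event(cfg, seed=1000 + k)
            bounds = segment_phases(seg, None)
            bounds.validate()  # raises on violation

    def test_onset_bias_below_1ms_noise_free(self):
        """Noise-free events: mean absolute onset error under 1 ms."""
        cfg = SimEventConfig(noise_rms=1e-8)
        errs = {"ph1": [], "ph2": [], "ph3": []}
        for seed in range(8):
            seg, truth = simulate_event(cfg, seed=seed)
            bounds = segment_phases(seg, compute_cwt(seg))
            errs["ph1"].append(abs(bounds.ph1.onset - truth.ph1_onset))
            errs["ph2"].append(abs(bounds.ph2.onset - truth.ph2_onset))
            errs["ph3"].append(abs(bounds.ph3.onset - truth.ph3_onset))
        for name, es in errs.items():
            assert np.mean(es) <= 1e-3, f"{name} bias {np.mean(es)}"

    def test_noise_segment_raises_not_an_event(self):
        rng = np.random.default_rng(0)
        seg = _segment(rng.normal(0, 0.005, 6400))
        with pytest.raises(NotAnEventError):
            segment_phases(seg, None)

    def test_recovery_boundaries_consistent(self, segmented_event):
        seg, truth, bounds = segmented_event
        assert bounds.ph4.onset == pytest.approx(bounds.attack_peak_time)
        assert bounds.ph4.offset == pytest.approx(bounds.ph5.onset)
        assert bounds.ph5.offset == pytest.approx(bounds.ph6.onset)
        assert abs(bounds.attack_peak_time - truth.attack_peak) <= 2e-3
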