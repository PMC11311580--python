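"""Per-event metrics and cohort summaries against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaneedle.event_analysis import (
    EventSegment,
    PhaseBounds,
    PhaseInterval,
    compute_cwt,
    segment_phases,
)
from vaneedle.metrics import (
    MetricUndefinedError,
    boxplot_stats,
    compute_event_metrics,
    phase_energy,
    recovery_time,
    summarize_cohort,
)
from vaneedle.preprocessing import preprocess
from vaneedle.synthetic_data import SimEventConfig, simulate_event

FS = 16000.0


def _seg(x):
    return EventSegment(samples=np.asarray(x, float), fs=FS)


def _bounds(onset_s, offset_s):
    iv = PhaseInterval(onset=onset_s, offset=offset_s, present=True)
    return PhaseBounds(ph1=iv)


class TestPhaseEnergy:
    def test_zeros_give_zero(self):
        seg = _seg(np.zeros(1000))
        assert phase_energy(seg, _bounds(0.0, 0.05), "ph1") == 0.0

    def test_single_unit_sample(self):
        x = np.zeros(1000)
        x[100] = 1.0
        assert phase_energy(_seg(x), _bounds(0.0, 0.05), "ph1") == 1.0

    def test_constant_block(self):
        # 160 samples of amplitude 0.5 -> 160 * 0.25 = 40
        x = np.zeros(1000)
        x[:160] = 0.5
        assert phase_energy(_seg(x), _bounds(0.0, 0.01), "ph1") == pytest.approx(40.0)

    def test_absent_phase_raises_not_zero(self):
        seg = _seg(np.zeros(100))
        with pytest.raises(MetricUndefinedError):
            phase_energy(seg, PhaseBounds(), "ph2")


class TestRecoveryTime:
    def _exp_decay_segment(self, tau_ms=5.0, peak_s=0.0):
        # deterministic sqrt-of-exponential so sample energy follows
        # exp(-t/tau) exactly (no carrier)
        t = np.arange(3200) / FS
        return _seg(np.sqrt(np.exp(-t / (tau_ms / 1000.0))))

    def test_single_exponential_closed_form(self):
        """tauE=5 ms: t(0.90)=5 ln10=11.51 ms, t(0.95)=5 ln20=14.98 ms."""
        seg = self._exp_decay_segment()
        assert recovery_time(seg, 0.0, 0.90) == pytest.approx(11.51, abs=0.2)
        assert recovery_time(seg, 0.0, 0.95) == pytest.approx(14.98, abs=0.2)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_fraction_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        seg = _seg(rng.normal(0, 1, 400) ** 2 + 1e-9)
        r = [recovery_time(seg, 0.0, f) for f in (0.90, 0.95, 0.98)]
        assert r[0] <= r[1] <= r[2]

    def test_zero_post_peak_energy_is_undefined(self):
        with pytest.raises(MetricUndefinedError):
            recovery_time(_seg(np.zeros(100)), 0.0, 0.9)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            recovery_time(self._exp_decay_segment(), 0.0, 1.5)


class TestEventMetrics:
    def test_default_event_energy_ratios(self, segmented_event):
        """Generator energies 160/8/0.8: E3/E2 ~ 20 (ratio_pct_2 ~ 5 %) and
        E3/E1 of order 200 at the median friction duration."""
        seg, truth, bounds = segmented_event
        m = compute_event_metrics(seg, bounds)
        assert m.fold_e3_over_e2 == pytest.approx(20.0, rel=0.2)
        assert m.ratio_pct_2 == pytest.approx(5.0, rel=0.2)
        expected_fold_e1 = truth.e3 / truth.e1
        assert m.fold_e3_over_e1 == pytest.approx(expected_fold_e1, rel=0.25)

    def test_ph2_absent_latency_undefined_but_metrics_returned(self):
        cfg = SimEventConfig(ph2_present=False)
        seg, _ = simulate_event(cfg, seed=6)
        proc = preprocess(seg)
        bounds = segment_phases(proc, compute_cwt(proc))
        m = compute_event_metrics(proc, bounds)
        assert math.isnan(m.latency_ms) and math.isnan(m.e2)
        assert m.e3 > 0 and not math.isnan(m.friction_duration_ms)

    def test_energy_additivity(self, segmented_event):
        seg, _, bounds = segmented_event
        total = float(np.sum(seg.samples**2))
        phases = [p for p in ("ph1", "ph2", "ph3", "ph4", "ph5", "ph6")
                  if bounds.phase(p).present]
        assert sum(phase_energy(seg, bounds, p) for p in phases) <= total + 1e-9

    def test_recovery_map_nondecreasing(self, segmented_event):
        seg, _, bounds = segmented_event
        m = compute_event_metrics(seg, bounds)
        r = m.recovery_ms
        assert r[0.90] <= r[0.95] <= r[0.98]
        assert m.total_event_ms >= m.friction_duration_ms


def _brute_force_quartiles(values):
    """Sort-based linear-interpolation oracle, independent of numpy."""
    v = sorted(values)
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)


class TestBoxplotStats:
    def test_fixed_example_with_outlier(self):
        st_ = boxplot_stats([1, 2, 3, 4, 100])
        assert st_["median"] == 3 and st_["q1"] == 2 and st_["q3"] == 4
        assert st_["outliers"] == [100]
        assert st_["whisker_hi"] == 4 and st_["whisker_lo"] == 1

    def test_single_value(self):
        st_ = boxplot_stats([7.0])
        assert st_["median"] == 7.0 and st_["outliers"] == []

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_quartiles_match_brute_force_oracle(self, values):
        q1, med, q3 = _brute_force_quartiles(values)
        st_ = boxplot_stats(values)
        assert st_["q1"] == pytest.approx(q1, rel=1e-12, abs=1e-9)
        assert st_["median"] == pytest.approx(med, rel=1e-12, abs=1e-9)
        assert st_["q3"] == pytest.approx(q3, rel=1e-12, abs=1e-9)

    def test_nan_values_excluded(self):
        st_ = boxplot_stats([1.0, float("nan"), 3.0])
        assert st_["n"] == 2 and st_["median"] == 2.0


class TestSummarizeCohort:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_single_event(self, segmented_event):
        seg, truth, bounds = segmented_event
        m = compute_event_metrics(seg, bounds)
        summary = summarize_cohort([("S1", truth, bounds, m)])
        row = summary.counts.iloc[-1]
        assert row["insertions"] == 1 and row["cavity_reached"] == 1
        st_ = summary.metric_stats["friction_duration_ms"]
        assert st_["median"] == pytest.approx(m.friction_duration_ms)
        assert st_["outliers"] == []

    def test_six_column_counts_from_cohort_spec(self):
        """Counting over a ground-truth cohort mirroring the eight-subject
        layout reproduces the totals 193 / 154 / 154 / 154 / 141 / 154."""
        from vaneedle.synthetic_data import GroundTruth, reference_cohort_spec

        items = []
        for spec in reference_cohort_spec():
            for k in range(spec.n_insertions):
                reached = k < spec.n_cavity
                ph2 = reached and k >= spec.n_ph2_suppressed
                if reached:
                    truth = GroundTruth(
                        ph1_onset=0.1, ph1_offset=0.2, ph2_onset=0.2,
                        ph2_offset=0.203, ph3_onset=0.2035, attack_peak=0.205,
                        end_of_event=0.24, e1=0.8, e2=8.0 if ph2 else 0.0,
                        e3=160.0, ph2_present=ph2, reached_cavity=True,
                        friction_duration_ms=20.0,
                    )
                    bounds = PhaseBounds(
                        ph1=PhaseInterval(0.1, 0.2, True),
                        ph2=PhaseInterval(0.2, 0.203, ph2),
                        ph3=PhaseInterval(0.2035, 0.205, True),
                        attack_peak_time=0.205,
                    )
                else:
                    truth, bounds = (
                        GroundTruth(
                            ph1_onset=0.0, ph1_offset=0.0, ph2_onset=0.0,
                            ph2_offset=0.0, ph3_onset=0.0, attack_peak=0.0,
                            end_of_event=0.0, e1=0, e2=0, e3=0,
                            ph2_present=False, reached_cavity=False,
                            friction_duration_ms=0.0,
                        ),
                        None,
                    )
                items.append((spec.subject_id, truth, bounds, None))
        summary = summarize_cohort(items)
        total = summary.counts.iloc[-1]
        assert list(
            total[["insertions", "cavity_reached", "excitations",
                   "ph1_present", "ph2_present", "ph3_present"]]
        ) == [193, 154, 154, 154, 141, 154]
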