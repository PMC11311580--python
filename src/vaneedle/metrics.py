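"""Per-event statistics and cohort summaries.

Phase energies are sums of squared samples over the phase interval.  The
click energy E3 spans the whole click excitation — attack through
settling, [Ph3.onset, Ph6.offset) — which is the quantity the ×20 / ×200
comparisons against the puncture burst (E2) and friction (E1) refer to;
per-phase energies of Ph3–Ph6 individually remain available through
:func:`phase_energy`.  Energy ratios are reported both as percentages of
E3 (the boxplot convention) and as their reciprocals (the fold-change
phrasing).

Metrics that are undefined for an event (e.g. the Ph2→Ph3 latency when no
burst was discernible) raise :class:`MetricUndefinedError` at the
operation level and are stored as NaN in :class:`EventMetrics`; cohort
medians exclude them rather than zero-filling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_analysis import EventSegment, PhaseBounds

__all__ = [
    "MetricUndefinedError",
    "EventMetrics",
    "CohortSummary",
    "phase_energy",
    "recovery_time",
    "compute_event_metrics",
    "summarize_cohort",
    "boxplot_stats",
]

RECOVERY_FRACTIONS = (0.90, 0.95, 0.98)


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined for the given event."""


def _interval_indices(segment: EventSegment, onset: float, offset: float):
    i0 = int(round((onset - segment.t0) * segment.fs))
    i1 = int(round((offset - segment.t0) * segment.fs))
    i0 = max(i0, 0)
    i1 = min(i1, segment.samples.size)
    return i0, i1


def phase_energy(segment: EventSegment, bounds: PhaseBounds, phase: str) -> float:
    """Sum of squared samples over [onset, offset) of the given phase.

    Raises :class:`MetricUndefinedError` for an absent phase (absent is
    not the same as zero energy).
    """
    iv = bounds.phase(phase)
    if not iv.present:
        raise MetricUndefinedError(f"phase {phase} not present in this event")
    i0, i1 = _interval_indices(segment, iv.onset, iv.offset)
    return float(np.sum(segment.samples[i0:i1] ** 2))


def recovery_time(
    segment: EventSegment,
    attack_peak_time: float,
    fraction: float,
    end_time: float | None = None,
) -> float:
    """Time (ms) for the post-peak cumulative energy to reach ``fraction``.

    The post-peak window runs from the attack peak to ``end_time`` (the
    Ph6 onset boundary, typically) or the segment end.  Returns the
    smallest t with cumulative energy(t) >= fraction × total.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    i_peak = int(round((attack_peak_time - segment.t0) * segment.fs))
    if not 0 <= i_peak < segment.samples.size:
        raise ValueError("attack peak outside the segment")
    i_end = segment.samples.size
    if end_time is not None:
        i_end = min(i_end, int(round((end_time - segment.t0) * segment.fs)))
    post = segment.samples[i_peak:i_end] ** 2
    cum = np.cumsum(post)
    if cum.size == 0 or cum[-1] <= 0:
        raise MetricUndefinedError("zero post-peak energy")
    k = int(np.searchsorted(cum, fraction * cum[-1]))
    return 1000.0 * (k + 1) / segment.fs


@dataclass
class EventMetrics:
    """Per-event energies, ratios, durations (ms) and recovery times."""

    e1: float
    e2: float
    e3: float
    ratio_pct_1: float  # 100 * E1 / E3
    ratio_pct_2: float  # 100 * E2 / E3
    friction_duration_ms: float
    latency_ms: float  # Ph2 onset -> Ph3 onset; NaN when Ph2 absent
    recovery_ms: dict[float, float] = field(default_factory=dict)
    total_event_ms: float = math.nan  # Ph1 onset -> 98 % recovery point
    recording_id: str = ""

    @property
    def fold_e3_over_e2(self) -> float:
        return self.e3 / self.e2 if self.e2 > 0 else math.nan

    @property
    def fold_e3_over_e1(self) -> float:
        return self.e3 / self.e1 if self.e1 > 0 else math.nan

    def to_dict(self) -> dict:
        d = {
            "recording_id": self.recording_id,
            "e1": self.e1,
            "e2": self.e2,
            "e3": self.e3,
            "ratio_pct_1": self.ratio_pct_1,
            "ratio_pct_2": self.ratio_pct_2,
            "fold_e3_over_e1": self.fold_e3_over_e1,
            "fold_e3_over_e2": self.fold_e3_over_e2,
            "friction_duration_ms": self.friction_duration_ms,
            "latency_ms": self.latency_ms,
            "total_event_ms": self.total_event_ms,
        }
        for f, v in self.recovery_ms.items():
            d[f"recovery_ms_{int(round(100 * f))}"] = v
        return d


def compute_event_metrics(
    segment: EventSegment,
    bounds: PhaseBounds,
    fractions: tuple[float, ...] = RECOVERY_FRACTIONS,
) -> EventMetrics:
    """All per-event metrics from segmented phase bounds.

    Absent-Ph2 events get NaN latency and E2-derived fields; absent-Ph1
    events get NaN friction duration and E1-derived fields.  The event
    is still returned.
    """
    e3 = float(
        np.sum(
            segment.samples[
                slice(*_interval_indices(segment, bounds.ph3.onset, bounds.ph6.offset))
            ]
            ** 2
        )
    )
    if bounds.ph1.present:
        e1 = phase_energy(segment, bounds, "ph1")
        friction_ms = 1000.0 * bounds.ph1.duration
    else:
        e1, friction_ms = math.nan, math.nan
    if bounds.ph2.present:
        e2 = phase_energy(segment, bounds, "ph2")
        latency_ms = 1000.0 * (bounds.ph3.onset - bounds.ph2.onset)
    else:
        e2, latency_ms = math.nan, math.nan

    recovery = {
        f: recovery_time(segment, bounds.attack_peak_time, f)
        for f in fractions
    }
    total_ms = (
        1000.0 * (bounds.ph6.onset - bounds.ph1.onset)
        if bounds.ph1.present
        else math.nan
    )
    return EventMetrics(
        e1=e1,
        e2=e2,
        e3=e3,
        ratio_pct_1=100.0 * e1 / e3 if e3 > 0 else math.nan,
        ratio_pct_2=100.0 * e2 / e3 if e3 > 0 else math.nan,
        friction_duration_ms=friction_ms,
        latency_ms=latency_ms,
        recovery_ms=recovery,
        total_event_ms=total_ms,
    )


def boxplot_stats(values) -> dict:
    """Median, quartiles, 1.5×IQR whiskers and outliers.

    Quartiles use linear interpolation between order statistics.  NaNs
    (undefined metrics) are excluded.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {
            "n": 0, "median": math.nan, "q1": math.nan, "q3": math.nan,
            "whisker_lo": math.nan, "whisker_hi": math.nan, "outliers": [],
        }
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(np.min(inside)),
        "whisker_hi": float(np.max(inside)),
        "outliers": sorted(float(o) for o in v[(v < lo_fence) | (v > hi_fence)]),
    }


@dataclass
class CohortSummary:
    """Per-subject and total counts plus per-metric distribution stats."""

    counts: pd.DataFrame  # rows: subjects + Total row; six-column count layout
    metric_stats: dict[str, dict]

    def to_counts_csv(self, path) -> None:
        self.counts.to_csv(path, index=False)

    def metric_frame(self) -> pd.DataFrame:
        rows = []
        for name, st in self.metric_stats.items():
            row = {"metric": name, **{k: v for k, v in st.items() if k != "outliers"}}
            row["n_outliers"] = len(st["outliers"])
            rows.append(row)
        return pd.DataFrame(rows)


COUNT_COLUMNS = [
    "subject",
    "insertions",
    "cavity_reached",
    "excitations",
    "ph1_present",
    "ph2_present",
    "ph3_present",
]

_METRIC_KEYS = [
    "fold_e3_over_e2",
    "fold_e3_over_e1",
    "ratio_pct_1",
    "ratio_pct_2",
    "friction_duration_ms",
    "latency_ms",
    "recovery_ms_90",
    "recovery_ms_95",
    "recovery_ms_98",
    "total_event_ms",
]


def summarize_cohort(items) -> CohortSummary:
    """Summarise a cohort of analysed insertions.

    ``items`` is a non-empty list of ``(subject_id, reached, bounds_or_None,
    metrics_or_None)`` where ``reached`` is a :class:`GroundTruth`, a bare
    boolean (e.g. from an annotation) or None; ``bounds`` is None when no
    excitation was segmented.  Cavity counts use the ground truth /
    annotation where available, otherwise the detection outcome.
    """
    items = list(items)
    if not items:
        raise ValueError("empty cohort")
    per_subject: dict[str, dict] = {}
    metric_values: dict[str, list[float]] = {k: [] for k in _METRIC_KEYS}
    for subject, truth, bounds, metrics in items:
        row = per_subject.setdefault(
            subject,
            {c: 0 for c in COUNT_COLUMNS[1:]},
        )
        row["insertions"] += 1
        if truth is None:
            reached = bounds is not None
        elif isinstance(truth, bool):
            reached = truth
        else:
            reached = truth.reached_cavity
        row["cavity_reached"] += bool(reached)
        row["excitations"] += bounds is not None
        if bounds is not None:
            row["ph1_present"] += bounds.ph1.present
            row["ph2_present"] += bounds.ph2.present
            row["ph3_present"] += bounds.ph3.present
        if metrics is not None:
            d = metrics.to_dict()
            for k in _METRIC_KEYS:
                v = d.get(k, math.nan)
                if v is not None and np.isfinite(v):
                    metric_values[k].append(float(v))

    rows = [{"subject": s, **vals} for s, vals in per_subject.items()]
    total = {"subject": "Total"}
    for c in COUNT_COLUMNS[1:]:
        total[c] = sum(r[c] for r in rows)
    counts = pd.DataFrame(rows + [total], columns=COUNT_COLUMNS)
    stats = {k: boxplot_stats(v) for k, v in metric_values.items()}
    return CohortSummary(counts=counts, metric_stats=stats)
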