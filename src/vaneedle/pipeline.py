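"""Reproducible end-to-end pipeline with a file-based configuration.

A :class:`PipelineConfig` gathers every stage's parameter block plus the
global seed and output directory, round-trips losslessly through YAML and
rejects unknown keys.  :func:`run_simulate` writes a synthetic cohort
(float32 WAVEs + annotation and ground-truth CSVs); :func:`run_analyze`
runs preprocessing, detection, segmentation and metrics over a directory
of recordings and writes per-event and cohort CSVs plus a run manifest.

Per-recording randomness is spawned counter-based from the single seed,
so outputs are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .event_analysis import (
    CWTParams,
    DetectorParams,
    NotAnEventError,
    SegmentationParams,
    compute_cwt,
    detect_excitations,
    extract_segment,
    segment_phases,
)
from .metrics import compute_event_metrics, summarize_cohort
from .preprocessing import (
    DWTFilterParams,
    SpectralGateParams,
    dwt_filter,
    preprocess,
    remove_dc,
)
from .signal_io import read_annotations, read_wave, write_annotations, write_wave
from .synthetic_data import SimEventConfig, SubjectSpec, simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "run_simulate", "run_analyze"]


class ConfigError(ValueError):
    """Raised for malformed pipeline configuration."""


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {context!r}")
    # YAML gives lists; several params want tuples/frozensets
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = frozenset(v) if f.name == "kept_scales" else tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {context!r}: {exc}") from exc


@dataclass
class PipelineConfig:
    """All stage parameters, the global seed and the output directory."""

    seed: int = 0
    out_dir: str = "results"
    sim: SimEventConfig = field(default_factory=SimEventConfig)
    cohort: list[SubjectSpec] = field(default_factory=list)
    gate: SpectralGateParams = field(default_factory=SpectralGateParams)
    dwt: DWTFilterParams = field(default_factory=DWTFilterParams)
    cwt: CWTParams = field(default_factory=CWTParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    #: fixed duration for simulated recordings (None = sample 5-15 s)
    duration_s: float | None = None

    _SECTIONS = {
        "sim": SimEventConfig,
        "gate": SpectralGateParams,
        "dwt": DWTFilterParams,
        "cwt": CWTParams,
        "detector": DetectorParams,
        "segmentation": SegmentationParams,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("seed", "out_dir", "duration_s"):
            if key in data:
                kwargs[key] = data[key]
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data[name] or {}, name)
        if "cohort" in data:
            kwargs["cohort"] = [
                _from_mapping(SubjectSpec, row, f"cohort[{i}]")
                for i, row in enumerate(data["cohort"])
            ]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, frozenset)):
                return sorted(obj) if isinstance(obj, frozenset) else list(obj)
            return obj

        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "duration_s": self.duration_s,
            "sim": plain(self.sim),
            "cohort": [plain(s) for s in self.cohort],
            "gate": plain(self.gate),
            "dwt": plain(self.dwt),
            "cwt": plain(self.cwt),
            "detector": plain(self.detector),
            "segmentation": plain(self.segmentation),
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plot_scalogram(scal, segment, bounds, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.pcolormesh(scal.times, scal.frequencies,
                  20 * np.log10(scal.magnitude + 1e-12), shading="auto")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    for name, color in (("ph1", "w"), ("ph2", "r"), ("ph3", "y")):
        iv = bounds.phase(name)
        if iv.present:
            ax.axvline(iv.onset, color=color, ls=":", lw=1)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _write_manifest(out_dir: Path, config: PipelineConfig, timings: dict) -> None:
    manifest = {
        "package_version": __version__,
        "config_sha256_16": config.digest(),
        "seed": config.seed,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_simulate(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate the configured cohort and write WAVEs + CSVs.

    Returns a dict with the output paths and the cohort counts.
    """
    out = Path(out_dir or config.out_dir)
    wav_dir = out / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    recordings, annotations, truths = simulate_cohort(
        config.cohort, seed=config.seed, config=config.sim,
        duration_s=config.duration_s,
    )
    for rec in recordings:
        write_wave(rec, wav_dir / f"{rec.recording_id}.wav", encoding="float32")
    write_annotations(annotations, out / "annotations.csv")
    rows = []
    for rec, truth in zip(recordings, truths):
        row = {"recording_id": rec.recording_id, "subject_id": rec.subject_id}
        if truth is not None:
            row.update({k: getattr(truth, k) for k in (
                "ph1_onset", "ph2_onset", "ph3_onset", "attack_peak",
                "end_of_event", "e1", "e2", "e3", "ph2_present",
                "reached_cavity", "friction_duration_ms")})
        else:
            row["reached_cavity"] = False
        rows.append(row)
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "ground_truth.csv", index=False)
    counts = {
        "insertions": len(recordings),
        "cavity_reached": sum(t is not None for t in truths),
        "ph2_present": sum(t is not None and t.ph2_present for t in truths),
    }
    _write_manifest(out, config, {"simulate": time.perf_counter() - t0})
    log.info("simulated cohort: %s", counts)
    return {"wav_dir": wav_dir, "annotations": out / "annotations.csv",
            "ground_truth": out / "ground_truth.csv", "counts": counts}


def run_analyze(
    config: PipelineConfig,
    wav_dir: str | Path,
    annotations_path: str | Path,
    out_dir: str | Path | None = None,
    plot_scalograms: bool = False,
) -> dict:
    """Analyse every WAVE in a directory against its annotations.

    Per recording: preprocess -> detect excitations -> extract the 400 ms
    segment at the annotation -> CWT -> phase segmentation -> metrics.
    Recordings without an annotation are skipped with a warning.  With
    ``plot_scalograms`` a PNG of each event's scalogram is saved as well.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wav_paths = sorted(Path(wav_dir).glob("*.wav"))
    if not wav_paths:
        raise FileNotFoundError(f"no WAVE files in {wav_dir}")
    annotations = read_annotations(annotations_path)
    timings = {"preprocess": 0.0, "detect": 0.0, "segment": 0.0}

    event_rows = []
    cohort_items = []
    bounds_records = []
    for path in wav_paths:
        rec = read_wave(path)
        entries = annotations.for_recording(rec.recording_id)
        if not entries:
            log.warning("no annotation for %s; skipped", rec.recording_id)
            continue
        entry = entries[0]
        subject = rec.recording_id.rsplit("_", 1)[0]
        t0 = time.perf_counter()
        proc = preprocess(rec, config.gate, config.dwt)
        # quantification track: no spectral gate, whose mask biases the
        # energy of components near the noise floor
        quant = dwt_filter(remove_dc(rec), config.dwt)
        timings["preprocess"] += time.perf_counter() - t0
        t0 = time.perf_counter()
        excitations = detect_excitations(proc, config.detector)
        cavity = [e for e in excitations if e.is_cavity_candidate]
        timings["detect"] += time.perf_counter() - t0

        bounds = metrics = None
        if entry.reached_cavity:
            t0 = time.perf_counter()
            try:
                segment = extract_segment(proc, entry.t_puncture)
                scal = compute_cwt(segment, config.cwt)
                bounds = segment_phases(segment, scal, config.segmentation)
                quant_segment = extract_segment(quant, entry.t_puncture)
                metrics = compute_event_metrics(quant_segment, bounds)
                metrics.recording_id = rec.recording_id
                record = {"recording_id": rec.recording_id,
                          "attack_peak_time": bounds.attack_peak_time}
                for ph in ("ph1", "ph2", "ph3", "ph4", "ph5", "ph6"):
                    iv = bounds.phase(ph)
                    record[ph] = {"onset": iv.onset, "offset": iv.offset,
                                  "present": iv.present}
                bounds_records.append(record)
                if plot_scalograms:
                    _plot_scalogram(scal, segment, bounds,
                                    out / "scalograms" / f"{rec.recording_id}.png")
            except (ValueError, NotAnEventError) as exc:
                log.warning("%s: %s", rec.recording_id, exc)
            timings["segment"] += time.perf_counter() - t0
        row = {
            "recording_id": rec.recording_id,
            "subject_id": subject,
            "reached_cavity": entry.reached_cavity,
            "n_excitations": len(excitations),
            "n_cavity_candidates": len(cavity),
        }
        if bounds is not None:
            row.update(
                {
                    "ph1_present": bounds.ph1.present,
                    "ph2_present": bounds.ph2.present,
                    "ph3_present": bounds.ph3.present,
                    **metrics.to_dict(),
                }
            )
        event_rows.append(row)
        cohort_items.append((subject, entry.reached_cavity, bounds, metrics))

    if not cohort_items:
        raise ValueError("empty cohort: no annotated recordings analysed")
    import pandas as pd

    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    with open(out / "phase_bounds.jsonl", "w") as fh:
        for record in bounds_records:
            fh.write(json.dumps(record) + "\n")
    summary = summarize_cohort(cohort_items)
    summary.to_counts_csv(out / "cohort_counts.csv")
    summary.metric_frame().to_csv(out / "cohort_metrics.csv", index=False)
    _write_manifest(out, config, timings)
    return {
        "events": out / "events.csv",
        "cohort_counts": out / "cohort_counts.csv",
        "cohort_metrics": out / "cohort_metrics.csv",
        "summary": summary,
    }
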