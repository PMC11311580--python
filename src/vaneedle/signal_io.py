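"""Recording/annotation data model and WAVE + CSV I/O.

The acquisition device stores mono vibroacoustic signals as RIFF/WAVE at a
nominal 16 kHz sampling rate.  Internally amplitudes are floating point in
[-1, 1]; on disk both the 16-bit PCM and IEEE float32 dialects are supported
(PCM16 matches typical recorders, float32 is lossless for fixtures).

Annotations are delimited text with header ``recording_id,t_puncture_s,
reached_cavity``, times in seconds from the start of the recording.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "AnnotationEntry",
    "AnnotationSet",
    "WaveFormatError",
    "AnnotationSchemaError",
    "read_wave",
    "write_wave",
    "read_annotations",
    "write_annotations",
]

log = logging.getLogger(__name__)

DEFAULT_FS = 16_000

_PCM16_SCALE = 32768.0


class WaveFormatError(ValueError):
    """Raised for unreadable, corrupt or empty WAVE input."""


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file violates the expected schema."""


@dataclass
class Recording:
    """A sampled vibroacoustic signal.

    Parameters
    ----------
    samples : ndarray
        Real amplitudes, dimensionless, nominally in [-1, 1].
    fs : float
        Sampling rate in Hz (> 0; the acquisition prototype uses 16 kHz).
    recording_id, subject_id : str
        Identifiers of the insertion recording and the cadaver / simulation
        subject it belongs to.
    insertion_site : str or None
        Optional entry-point label (e.g. ``sub-umbilicus``, ``Lee-Huang``,
        ``Palmer``).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    recording_id: str = ""
    subject_id: str = ""
    insertion_site: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with replaced sample data."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class AnnotationEntry:
    recording_id: str
    t_puncture: float
    reached_cavity: bool


@dataclass
class AnnotationSet:
    """Per-recording annotations of the approximate puncture instant."""

    entries: list[AnnotationEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def for_recording(self, recording_id: str) -> list[AnnotationEntry]:
        return [e for e in self.entries if e.recording_id == recording_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recording_id": [e.recording_id for e in self.entries],
                "t_puncture_s": [e.t_puncture for e in self.entries],
                "reached_cavity": [e.reached_cavity for e in self.entries],
            }
        )

    def validate(self, catalogue: Iterable[Recording] | None = None) -> None:
        """Check invariants, optionally against a recording catalogue."""
        seen: set[tuple[str, float]] = set()
        durations = (
            {r.recording_id: r.duration for r in catalogue} if catalogue else {}
        )
        for e in self.entries:
            if not np.isfinite(e.t_puncture) or e.t_puncture < 0:
                raise AnnotationSchemaError(
                    f"t_puncture must be >= 0, got {e.t_puncture!r} "
                    f"for {e.recording_id!r}"
                )
            if e.recording_id in durations and e.t_puncture >= durations[e.recording_id]:
                raise AnnotationSchemaError(
                    f"t_puncture {e.t_puncture} s beyond end of "
                    f"{e.recording_id!r} ({durations[e.recording_id]} s)"
                )
            key = (e.recording_id, e.t_puncture)
            if key in seen:
                raise AnnotationSchemaError(f"duplicate annotation row {key}")
            seen.add(key)


def read_wave(path: str | Path) -> Recording:
    """Read a RIFF/WAVE file into a :class:`Recording`.

    Amplitudes are rescaled to [-1, 1] floats regardless of the on-disk
    encoding (16-bit PCM divides by 32768; 32-bit float passes through).
    Multichannel files use channel 0 with a warning — the sensing device is
    a single piezo element.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy chunk warnings
            fs, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header, unsupported format
        raise WaveFormatError(f"cannot read WAVE file {path}: {exc}") from exc
    if data.size == 0:
        raise WaveFormatError(f"zero-length audio in {path}")
    if data.ndim > 1:
        log.warning("%s has %d channels; using channel 0", path, data.shape[1])
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise WaveFormatError(f"unsupported sample format {data.dtype} in {path}")
    return Recording(samples=samples, fs=float(fs), recording_id=path.stem)


def write_wave(
    recording: Recording, path: str | Path, encoding: str = "pcm16"
) -> Path:
    """Write a recording to a WAVE file.

    ``encoding`` is ``"pcm16"`` (default; amplitudes outside [-1, 1] are
    clipped with a warning) or ``"float32"`` (lossless for float32-precision
    data).
    """
    path = Path(path)
    x = np.asarray(recording.samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot write non-finite samples")
    if encoding == "pcm16":
        if np.any(np.abs(x) > 1.0):
            log.warning(
                "%s: %d samples outside [-1, 1] clipped for PCM16",
                path,
                int(np.sum(np.abs(x) > 1.0)),
            )
        q = np.clip(np.round(x * _PCM16_SCALE), -32768, 32767).astype(np.int16)
        wavfile.write(path, int(round(recording.fs)), q)
    elif encoding == "float32":
        wavfile.write(path, int(round(recording.fs)), x.astype(np.float32))
    else:
        raise ValueError(f"unknown encoding {encoding!r}; use 'pcm16' or 'float32'")
    return path


_ANNOT_COLUMNS = ("recording_id", "t_puncture_s", "reached_cavity")

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s not in _BOOL_MAP:
        raise AnnotationSchemaError(f"cannot parse boolean {v!r}")
    return _BOOL_MAP[s]


def read_annotations(
    path: str | Path, catalogue: Sequence[Recording] | None = None
) -> AnnotationSet:
    """Parse an annotation CSV (``recording_id,t_puncture_s,reached_cavity``).

    Parsing uses the decimal point regardless of locale.  Invariants
    (non-negative times, uniqueness, containment in the catalogue if one is
    given) are enforced.
    """
    df = pd.read_csv(path, dtype={"recording_id": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationSchemaError(
            f"{path}: missing column(s) {missing}; expected {_ANNOT_COLUMNS}"
        )
    entries = []
    for _, row in df.iterrows():
        try:
            t = float(row["t_puncture_s"])
        except (TypeError, ValueError) as exc:
            raise AnnotationSchemaError(
                f"{path}: non-numeric t_puncture_s {row['t_puncture_s']!r}"
            ) from exc
        entries.append(
            AnnotationEntry(
                recording_id=str(row["recording_id"]),
                t_puncture=t,
                reached_cavity=_parse_bool(row["reached_cavity"]),
            )
        )
    aset = AnnotationSet(entries)
    aset.validate(catalogue)
    return aset


def write_annotations(annotations: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    annotations.to_frame().to_csv(path, index=False)
    return path
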