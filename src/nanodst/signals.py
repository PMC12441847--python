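"""Phase-annotated cantilever deflection recordings.

A nanomotion experiment is recorded as a single deflection channel sampled at
a fixed rate and annotated with up to three phases: a short *blank* phase
(bare functionalized cantilever), a *medium* phase (cells attached, no drug)
and a *drug* phase (after drug addition).  Deflection amplitudes are in
arbitrary units: the instrument is not calibrated to nanometres, so every
downstream statistic is either scale-invariant or explicitly documented as
scale-sensitive.

The recording clock used by all downstream analyses places t = 0 at the
start of the medium phase; the blank phase therefore lives at negative clock
times and is excluded from feature intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile


class Phase(str, Enum):
    BLANK = "blank"
    MEDIUM = "medium"
    DRUG = "drug"


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


_PHASE_ORDER = {Phase.BLANK: 0, Phase.MEDIUM: 1, Phase.DRUG: 2}


class ValidationError(ValueError):
    """A recording or annotation violates a structural invariant."""


class FormatError(ValueError):
    """A file is missing required structure (e.g. the sampling rate)."""


class DataError(ValueError):
    """Sample data itself is unusable (e.g. NaN deflections)."""


@dataclass(frozen=True)
class PhaseSpan:
    """One annotated phase, in seconds from the start of the file."""

    name: Phase
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", Phase(self.name))
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"phase {self.name.value}: start {self.start_s} must precede end {self.end_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class RecordingMeta:
    experiment_id: str = ""
    cell_line: str = ""
    drug: str = ""
    concentration_uM: float = 0.0
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", Label(self.label))
        if self.concentration_uM < 0:
            raise ValidationError("concentration_uM must be nonnegative")


@dataclass
class DeflectionRecording:
    """A sampled deflection time series with phase annotations and metadata.

    ``clock_zero_s`` is the file time (seconds from sample 0) of the
    recording-clock origin.  It defaults to the start of the medium phase so
    that sub-recordings produced by :func:`phase_segment` keep the original
    clock even when the medium span itself is sliced away.
    """

    samples: np.ndarray
    sampling_rate: float
    phases: list[PhaseSpan] = field(default_factory=list)
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    clock_zero_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise FormatError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("recording contains non-finite samples")
        self._validate_phases()
        if self.clock_zero_s is None:
            medium = self._find(Phase.MEDIUM)
            self.clock_zero_s = medium.start_s if medium is not None else 0.0

    def _validate_phases(self) -> None:
        seen: set[Phase] = set()
        for span in self.phases:
            if span.name in seen:
                raise ValidationError(f"duplicate phase {span.name.value}")
            seen.add(span.name)
            if span.start_s < 0 or span.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"phase {span.name.value} [{span.start_s}, {span.end_s}] s "
                    f"outside recording of {self.duration_s:.3f} s"
                )
        ordered = sorted(self.phases, key=lambda s: s.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if a.end_s > b.start_s + 1e-9:
                raise ValidationError(
                    f"phases {a.name.value} and {b.name.value} overlap"
                )
            if _PHASE_ORDER[a.name] >= _PHASE_ORDER[b.name]:
                raise ValidationError(
                    "phases must be ordered blank -> medium -> drug"
                )

    def _find(self, phase: Phase) -> PhaseSpan | None:
        for span in self.phases:
            if span.name == phase:
                return span
        return None

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def phase_span(self, phase: Phase | str) -> PhaseSpan:
        span = self._find(Phase(phase))
        if span is None:
            raise LookupError(f"phase {Phase(phase).value!r} not annotated")
        return span

    def clock_min(self, file_time_s: float) -> float:
        """Convert file time (s) to recording-clock minutes (0 = medium start)."""
        return (file_time_s - self.clock_zero_s) / 60.0


@dataclass(frozen=True)
class VarianceTrace:
    """Per-window population variance of the deflection signal (QC view).

    ``times_s`` are window start times in seconds from the start of the file;
    windows are contiguous, non-overlapping, and a trailing partial window is
    dropped.
    """

    window_s: float
    times_s: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.variances):
            raise ValidationError("times and variances must align")
        if np.any(np.asarray(self.variances) < 0):
            raise ValidationError("variances must be nonnegative")


def variance_trace(rec: DeflectionRecording, window_s: float = 8.0) -> VarianceTrace:
    """Variance of the deflection computed over non-overlapping windows.

    Uses the population (n-denominator) variance; at the default 8 s window
    the distinction from the n-1 form is negligible (hundreds of thousands of
    samples per window) but the population form is the documented convention.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * rec.sampling_rate))
    n_windows = rec.n_samples // win
    if n_windows == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than one {window_s} s window"
        )
    blocks = rec.samples[: n_windows * win].reshape(n_windows, win)
    variances = blocks.var(axis=1)  # population (ddof=0)
    times = np.arange(n_windows) * window_s
    return VarianceTrace(window_s=window_s, times_s=times, variances=variances)


def phase_segment(rec: DeflectionRecording, phase: Phase | str) -> DeflectionRecording:
    """Extract the sub-recording for one phase, preserving the recording clock."""
    span = rec.phase_span(phase)
    i0 = int(round(span.start_s * rec.sampling_rate))
    i1 = int(round(span.end_s * rec.sampling_rate))
    sub = rec.samples[i0:i1]
    new_span = PhaseSpan(span.name, 0.0, sub.size / rec.sampling_rate)
    return DeflectionRecording(
        samples=sub,
        sampling_rate=rec.sampling_rate,
        phases=[new_span],
        meta=rec.meta,
        clock_zero_s=rec.clock_zero_s - span.start_s,
    )


# ---------------------------------------------------------------------------
# I/O
#
# HDF5 layout: dataset /deflection (float64), attrs sampling_rate_hz,
# phases (JSON), meta (JSON), clock_zero_s.
# WAV dialect: IEEE-float32 mono, sampling rate in the header, plus a JSON
# sidecar <name>.json with phases/meta.
# ---------------------------------------------------------------------------

def _phases_to_json(rec: DeflectionRecording) -> str:
    return json.dumps(
        [
            {"name": s.name.value, "start_s": s.start_s, "end_s": s.end_s}
            for s in rec.phases
        ]
    )


def _meta_to_json(meta: RecordingMeta) -> str:
    return json.dumps(
        {
            "experiment_id": meta.experiment_id,
            "cell_line": meta.cell_line,
            "drug": meta.drug,
            "concentration_uM": meta.concentration_uM,
            "label": meta.label.value,
        }
    )


def _phases_from_json(text: str) -> list[PhaseSpan]:
    return [
        PhaseSpan(Phase(d["name"]), float(d["start_s"]), float(d["end_s"]))
        for d in json.loads(text)
    ]


def _meta_from_json(text: str) -> RecordingMeta:
    d = json.loads(text)
    return RecordingMeta(
        experiment_id=d.get("experiment_id", ""),
        cell_line=d.get("cell_line", ""),
        drug=d.get("drug", ""),
        concentration_uM=float(d.get("concentration_uM", 0.0)),
        label=Label(d.get("label", "unknown")),
    )


def write_recording(rec: DeflectionRecording, path: str | Path, format: str = "hdf5") -> Path:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("deflection", data=rec.samples, dtype="f8")
            f.attrs["sampling_rate_hz"] = float(rec.sampling_rate)
            f.attrs["phases"] = _phases_to_json(rec)
            f.attrs["meta"] = _meta_to_json(rec.meta)
            f.attrs["clock_zero_s"] = float(rec.clock_zero_s)
    elif format == "wav":
        wavfile.write(path, int(round(rec.sampling_rate)), rec.samples.astype(np.float32))
        sidecar = {
            "phases": json.loads(_phases_to_json(rec)),
            "meta": json.loads(_meta_to_json(rec.meta)),
            "clock_zero_s": float(rec.clock_zero_s),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> DeflectionRecording:
    """Read a recording; validation failures raise rather than pass silently."""
    path = Path(path)
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "hdf5"
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "sampling_rate_hz" not in f.attrs:
                raise FormatError(f"{path}: missing sampling_rate_hz attribute")
            samples = f["deflection"][:]
            rate = float(f.attrs["sampling_rate_hz"])
            phases = _phases_from_json(f.attrs.get("phases", "[]"))
            meta = _meta_from_json(f.attrs.get("meta", "{}"))
            clock = f.attrs.get("clock_zero_s")
            clock = float(clock) if clock is not None else None
        return DeflectionRecording(samples, rate, phases, meta, clock)
    if format == "wav":
        rate, samples = wavfile.read(path)
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
        sidecar = json.loads(sidecar_path.read_text())
        phases = [
            PhaseSpan(Phase(d["name"]), float(d["start_s"]), float(d["end_s"]))
            for d in sidecar.get("phases", [])
        ]
        meta = _meta_from_json(json.dumps(sidecar.get("meta", {})))
        clock = sidecar.get("clock_zero_s")
        return DeflectionRecording(
            np.asarray(samples, dtype=np.float64),
            float(rate),
            phases,
            meta,
            float(clock) if clock is not None else None,
        )
    raise ValueError(f"unknown format {format!r}")
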