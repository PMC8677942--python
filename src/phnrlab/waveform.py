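"""ERG recording data model and waveform table I/O.

A recording is an averaged photopic full-field ERG trace: by convention
430 samples spanning 220 ms with the flash delivered at 100 ms, exported
by the acquisition device after its internal filtering and averaging.
Sample *i* occurs at ``i * dt`` with ``dt = duration_ms / n_samples``
(0-based), so 11 consecutive samples span 11 * 220/430 = 5.63 ms.

Two on-disk dialects are supported: a long-form CSV (one row per sample,
metadata repeated per row) for interoperability, and a compact JSON form
(samples as an array) for fidelity.  Both round-trip exactly on the
textual float representation.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EYES",
    "LABELS",
    "EYE_CLASSES",
    "Covariates",
    "ERGRecording",
    "time_of_sample",
    "sample_at_time",
    "read_waveform_table",
    "write_waveform_table",
]

EYES = ("OD", "OS")
LABELS = ("ON_POS", "ON_NEG", "UNKNOWN")
EYE_CLASSES = (
    "on_acute",
    "on_chronic",
    "control_fellow",
    "control_patient",
    "control_healthy",
    "unknown",
)
_ON_CLASSES = {"on_acute", "on_chronic"}
_CONTROL_CLASSES = {"control_fellow", "control_patient", "control_healthy"}


class WaveformError(ValueError):
    """Raised for invalid recordings or malformed waveform tables."""


def time_of_sample(index: int, duration_ms: float = 220.0, n_samples: int = 430) -> float:
    """Time in ms of sample ``index`` under the i*dt convention."""
    if not 0 <= index < n_samples:
        raise WaveformError(f"sample index {index} out of range [0, {n_samples})")
    return index * (duration_ms / n_samples)

def sample_at_time(t_ms: float, duration_ms: float = 220.0, n_samples: int = 430) -> int:
    """Index of the sample nearest to ``t_ms``; ties go to the smaller index.

    ``t_ms`` may equal ``duration_ms``, in which case the last sample is
    returned (the nominal duration lies half a step beyond the final sample).
    """
    if not 0 <= t_ms <= duration_ms:
        raise WaveformError(f"time {t_ms} ms outside record [0, {duration_ms}]")
    dt = duration_ms / n_samples
    i = math.ceil(t_ms / dt - 0.5)  # round-half-down: ties toward smaller index
    return min(max(i, 0), n_samples - 1)


@dataclass(frozen=True)
class Covariates:
    """Optional per-eye clinical covariates; ``None`` marks an absent value."""

    age_years: float | None = None
    gender: str | None = None
    logmar: float | None = None
    hvf_md_db: float | None = None
    rnfl_um: float | None = None
    gclipl_um: float | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise WaveformError("age_years must be non-negative")
        for name in ("rnfl_um", "gclipl_um"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise WaveformError(f"{name} must be positive when present")


@dataclass(frozen=True)
class ERGRecording:
    """One averaged ERG waveform plus identifying metadata and label."""

    subject_id: str
    eye: str
    visit_index: int
    recording_index: int
    samples: tuple[float, ...]
    n_flashes: int = 100
    duration_ms: float = 220.0
    n_samples: int = 430
    stimulus_time_ms: float = 100.0
    label: str = "UNKNOWN"
    eye_class: str = "unknown"
    covariates: Covariates = field(default_factory=Covariates)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(float(v) for v in self.samples))
        self.validate()

    def validate(self) -> None:
        rid = self.record_id
        if self.eye not in EYES:
            raise WaveformError(f"{rid}: eye must be one of {EYES}, got {self.eye!r}")
        if self.label not in LABELS:
            raise WaveformError(f"{rid}: unknown label {self.label!r}")
        if self.eye_class not in EYE_CLASSES:
            raise WaveformError(f"{rid}: unknown eye_class {self.eye_class!r}")
        if self.visit_index < 0 or self.recording_index < 0:
            raise WaveformError(f"{rid}: visit/recording indices must be non-negative")
        if self.n_flashes <= 0:
            raise WaveformError(f"{rid}: n_flashes must be positive")
        if self.duration_ms <= 0 or self.n_samples <= 0:
            raise WaveformError(f"{rid}: duration and sample count must be positive")
        if not 0 <= self.stimulus_time_ms < self.duration_ms:
            raise WaveformError(
                f"{rid}: stimulus_time_ms {self.stimulus_time_ms} outside "
                f"[0, {self.duration_ms})"
            )
        if len(self.samples) != self.n_samples:
            raise WaveformError(
                f"{rid}: expected {self.n_samples} samples, got {len(self.samples)}"
            )
        if self.label == "ON_POS" and self.eye_class not in _ON_CLASSES | {"unknown"}:
            raise WaveformError(f"{rid}: ON_POS label requires an on_* eye_class")
        if self.label == "ON_NEG" and self.eye_class not in _CONTROL_CLASSES | {"unknown"}:
            raise WaveformError(f"{rid}: ON_NEG label requires a control_* eye_class")
        if self.label == "UNKNOWN" and self.eye_class != "unknown":
            raise WaveformError(f"{rid}: UNKNOWN label requires eye_class 'unknown'")

    @property
    def record_id(self) -> str:
        return f"{self.subject_id}/{self.eye}/v{self.visit_index}/r{self.recording_index}"

    @property
    def dt_ms(self) -> float:
        return self.duration_ms / self.n_samples

    @property
    def times_ms(self) -> tuple[float, ...]:
        return tuple(i * self.dt_ms for i in range(self.n_samples))

    def with_samples(self, samples: Sequence[float]) -> "ERGRecording":
        return replace(self, samples=tuple(float(v) for v in samples))


# ---------------------------------------------------------------------------
# Table I/O

_META_COLUMNS = [
    "subject_id", "eye", "visit_index", "recording_index", "n_flashes",
    "duration_ms", "n_samples", "stimulus_time_ms", "label", "eye_class",
]
_COV_COLUMNS = ["age_years", "gender", "logmar", "hvf_md_db", "rnfl_um", "gclipl_um"]
_CSV_COLUMNS = _META_COLUMNS[:8] + ["sample_index", "potential_uv"] + _META_COLUMNS[8:] + _COV_COLUMNS


def _fmt(value: float | int | str | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal
    return str(value)


def _opt_float(text: str) -> float | None:
    return float(text) if text not in ("", None) else None


def _record_meta(rec: ERGRecording) -> list[str]:
    cov = rec.covariates
    return (
        [rec.subject_id, rec.eye, str(rec.visit_index), str(rec.recording_index),
         str(rec.n_flashes), _fmt(rec.duration_ms), str(rec.n_samples),
         _fmt(rec.stimulus_time_ms)],
        [rec.label, rec.eye_class, _fmt(cov.age_years), _fmt(cov.gender),
         _fmt(cov.logmar), _fmt(cov.hvf_md_db), _fmt(cov.rnfl_um), _fmt(cov.gclipl_um)],
    )


def write_waveform_table(records: Iterable[ERGRecording], path: str | Path) -> None:
    """Write records to ``path``; dialect chosen by extension (.csv or .json)."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        payload = []
        for rec in records:
            cov = rec.covariates
            payload.append({
                "subject_id": rec.subject_id, "eye": rec.eye,
                "visit_index": rec.visit_index, "recording_index": rec.recording_index,
                "n_flashes": rec.n_flashes, "duration_ms": rec.duration_ms,
                "n_samples": rec.n_samples, "stimulus_time_ms": rec.stimulus_time_ms,
                "label": rec.label, "eye_class": rec.eye_class,
                "covariates": {k: getattr(cov, k) for k in _COV_COLUMNS},
                "samples": list(rec.samples),
            })
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            head, tail = _record_meta(rec)
            for i, v in enumerate(rec.samples):
                writer.writerow(head + [str(i), _fmt(v)] + tail)


def read_waveform_table(path: str | Path) -> list[ERGRecording]:
    """Read records from a waveform table written by :func:`write_waveform_table`."""
    path = Path(path)
    if not path.exists():
        raise WaveformError(f"no such waveform table: {path}")
    if path.suffix.lower() == ".json":
        return _read_json(path)
    return _read_csv(path)


def _make_record(meta: dict, samples: list[float], where: str) -> ERGRecording:
    try:
        return ERGRecording(
            subject_id=meta["subject_id"],
            eye=meta["eye"],
            visit_index=int(meta["visit_index"]),
            recording_index=int(meta["recording_index"]),
            n_flashes=int(meta["n_flashes"]),
            duration_ms=float(meta["duration_ms"]),
            n_samples=int(meta["n_samples"]),
            stimulus_time_ms=float(meta["stimulus_time_ms"]),
            label=meta["label"],
            eye_class=meta["eye_class"],
            covariates=Covariates(
                age_years=_opt_float(meta.get("age_years")),
                gender=meta.get("gender") or None,
                logmar=_opt_float(meta.get("logmar")),
                hvf_md_db=_opt_float(meta.get("hvf_md_db")),
                rnfl_um=_opt_float(meta.get("rnfl_um")),
                gclipl_um=_opt_float(meta.get("gclipl_um")),
            ),
            samples=tuple(samples),
        )
    except (WaveformError, KeyError, TypeError, ValueError) as exc:
        raise WaveformError(f"{where}: {exc}") from exc


def _read_csv(path: Path) -> list[ERGRecording]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise WaveformError(f"{path}: empty file")
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise WaveformError(f"{path}: missing required columns {sorted(missing)}")
        groups: dict[tuple, tuple[dict, list[float]]] = {}
        for lineno, row in enumerate(reader, start=2):
            key = (row["subject_id"], row["eye"], row["visit_index"], row["recording_index"])
            if key not in groups:
                groups[key] = (row, [])
            try:
                idx, val = int(row["sample_index"]), float(row["potential_uv"])
            except ValueError as exc:
                raise WaveformError(f"{path}:{lineno}: malformed sample row: {exc}") from exc
            samples = groups[key][1]
            if idx != len(samples):
                raise WaveformError(
                    f"{path}:{lineno}: record {'/'.join(key)} has non-contiguous "
                    f"sample_index {idx} (expected {len(samples)})"
                )
            samples.append(val)
    return [
        _make_record(meta, samples, f"{path}: record {'/'.join(key)}")
        for key, (meta, samples) in groups.items()
    ]


def _read_json(path: Path) -> list[ERGRecording]:
    payload = json.loads(path.read_text())
    records = []
    for i, obj in enumerate(payload):
        meta = {k: obj.get(k) for k in _META_COLUMNS}
        meta.update({k: v for k, v in (obj.get("covariates") or {}).items()})
        where = f"{path}: record #{i} ({obj.get('subject_id', '?')})"
        records.append(_make_record(meta, obj.get("samples", []), where))
    return records
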