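"""File I/O: CSV signals, CSV annotations, JSON reports, optional WFDB.

Conventions used everywhere: 0-based sample indices, durations in seconds,
one amplitude per CSV row, annotation files as (sample_index, label) pairs.
All writes are atomic (write to a temp file, then rename), so interrupted
runs never leave a corrupt output behind.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detector import DetectionResult
from .errors import FeatureUnavailableError, InputError
from .evaluation import EvalReport
from .metrics import RhythmSummary
from .preprocess import Signal

__all__ = [
    "AnnotationFile",
    "read_signal_csv",
    "write_signal_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_wfdb_record",
    "write_report",
    "atomic_write_text",
]


@dataclass(frozen=True)
class AnnotationFile:
    """Ordered (sample_index, label) beat annotations."""

    entries: tuple[tuple[int, str], ...]
    fs: float | None = None

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InputError("annotation indices must be strictly increasing")

    @property
    def indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.entries], dtype=int)


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def read_signal_csv(path: str | os.PathLike, fs: float, label: str = "") -> Signal:
    """One numeric amplitude per row; an optional non-numeric header line and
    blank lines are skipped.  A non-numeric row elsewhere is a parse error
    reported with its line number."""
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise InputError(f"{path}:{lineno}: not a number: {s!r}") from None
    if not values:
        raise InputError(f"{path}: no samples found")
    return Signal(samples=np.array(values), fs=fs, label=label or str(path))


def write_signal_csv(path: str | os.PathLike, sig: Signal) -> None:
    lines = ["amplitude"] + [repr(float(v)) for v in sig.samples]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_annotations_csv(path: str | os.PathLike) -> AnnotationFile:
    """(sample_index, label) CSV with an optional header row; a '# fs=...'
    comment line records the sampling frequency when present."""
    entries: list[tuple[int, str]] = []
    fs = None
    header_allowed = True
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            first = row[0].strip()
            if first.startswith("#"):
                if "fs=" in first:
                    fs = float(first.split("fs=")[1])
                continue
            try:
                idx = int(first)
            except ValueError:
                if header_allowed:  # one header row before any data
                    header_allowed = False
                    continue
                raise InputError(f"{path}:{lineno}: bad sample index {first!r}") from None
            header_allowed = False
            label = row[1].strip() if len(row) > 1 else "N"
            entries.append((idx, label))
    return AnnotationFile(entries=tuple(entries), fs=fs)


def write_annotations_csv(
    path: str | os.PathLike, indices: Sequence[int], labels: Sequence[str] | None = None, fs: float | None = None
) -> None:
    labels = labels or ["N"] * len(indices)
    lines = []
    if fs is not None:
        lines.append(f"# fs={fs}")
    lines.append("sample_index,label")
    lines += [f"{int(i)},{lab}" for i, lab in zip(indices, labels)]
    atomic_write_text(path, "\n".join(lines) + "\n")


# beat-type annotation codes kept when reading WFDB .atr files
_WFDB_BEAT_CODES = set("NLRBAaJSVrFejnE/fQ?")


def read_wfdb_record(record_path: str | os.PathLike):
    """Read a WFDB record (.hea/.dat, optional .atr) via the ``wfdb`` package.

    Returns (Signal, AnnotationFile or None) with the first channel in
    physical units.  Optional feature: requires the ``wfdb`` extra; the rest
    of the package works without it.
    """
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:
        raise FeatureUnavailableError(
            "WFDB support needs the optional 'wfdb' package (pip install qrsgram[wfdb])"
        ) from exc
    record_path = str(record_path)
    if not Path(record_path + ".hea").exists():
        raise InputError(f"no WFDB header at {record_path}.hea")
    rec = wfdb.rdrecord(record_path)
    sig = Signal(samples=np.asarray(rec.p_signal)[:, 0], fs=float(rec.fs), label=rec.record_name)
    ann = None
    if Path(record_path + ".atr").exists():
        a = wfdb.rdann(record_path, "atr")
        entries = tuple(
            (int(s), sym)
            for s, sym in zip(a.sample, a.symbol)
            if sym in _WFDB_BEAT_CODES
        )
        ann = AnnotationFile(entries=entries, fs=float(rec.fs))
    return sig, ann


def write_report(
    result: DetectionResult,
    summary: RhythmSummary,
    path: str | os.PathLike,
    evaluation: EvalReport | None = None,
) -> dict:
    """Versioned JSON report: beats, rhythm summary, config echo, and the
    evaluation block when a reference was scored (null otherwise)."""
    payload = result.to_dict()
    payload["schema"] = "qrsgram/report/1"
    payload["rhythm"] = summary.to_dict()
    payload["evaluation"] = evaluation.to_dict() if evaluation else None
    atomic_write_text(path, json.dumps(payload, indent=2) + "\n")
    return payload
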