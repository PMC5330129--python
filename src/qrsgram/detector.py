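"""QRS assembly: constraint labeling of tokens and grammar-driven beat parsing.

Two global thresholds separate narrow, high-variance QRS deflections from
broad, low-variance P/T waves:

- ``sigma1 = 0.1`` (dimensionless): a peak token must be steep, i.e. its
  population standard deviation must exceed the threshold (``sigma1`` for R
  and S, ``sigma1/2`` for the shallower Q);
- ``delta1 = 0.1`` s: a peak token must be short (``< delta1``); a rest token
  separating deflections must be very short (``< delta1/2``).

Labeled tokens are then parsed greedily left-to-right against the beat
grammar ``QRS = {Q}?{rest}?{R}{rest}?{S}``: an optional negative Q, an
optional rest, the mandatory positive R, an optional rest, and the mandatory
negative S (made optional only in the documented lenient mode).  Each token
is consumed by at most one beat, which structurally prevents duplicate
detections.  The R token's amplitude maximum is the beat fiducial used for
RR measurement.
"""

from __future__ import annotations

import csv
import enum
import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .lexer import (
    DEFAULT_PRECISION,
    SampleClass,
    SegmentStats,
    Token,
    token_stats,
    tokenize,
)
from .preprocess import FilterSpec, Signal, preprocess

__all__ = [
    "DetectorConfig",
    "TokenRole",
    "LabeledToken",
    "QRSComplex",
    "DetectionResult",
    "label_tokens",
    "assemble_qrs",
    "locate_r_peak",
    "detect",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the constraint step.

    sigma1 applies to R and S candidates, sigma1/2 to Q candidates; delta1
    bounds peak durations from above, delta1/2 bounds rest durations.
    ``strict_s`` keeps S mandatory as the grammar prints it; the lenient mode
    (R alone suffices) exists for morphologies lacking a distinct S wave.
    """

    sigma1: float = 0.1
    delta1: float = 0.1
    strict_s: bool = True

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0):
            raise ConfigurationError(f"sigma1 must be > 0, got {self.sigma1}")
        if not (self.delta1 > 0):
            raise ConfigurationError(f"delta1 must be > 0, got {self.delta1}")


class TokenRole(enum.Enum):
    R_CANDIDATE = "R"
    Q_CANDIDATE = "Q"
    S_CANDIDATE = "S"
    QS_CANDIDATE = "QS"  # negative token satisfying both thresholds
    REST = "rest"
    OTHER = "wave/other"


@dataclass(frozen=True)
class LabeledToken:
    token: Token
    stats: SegmentStats
    role: TokenRole

    @property
    def may_be_q(self) -> bool:
        return self.role in (TokenRole.Q_CANDIDATE, TokenRole.QS_CANDIDATE)

    @property
    def may_be_s(self) -> bool:
        return self.role in (TokenRole.S_CANDIDATE, TokenRole.QS_CANDIDATE)


@dataclass(frozen=True)
class QRSComplex:
    """One assembled beat.  Indices are 0-based samples; the span is
    [onset, offset) over the tokens the beat consumed."""

    r_token: Token
    fs: float
    q_token: Token | None = None
    s_token: Token | None = None
    rest_tokens: tuple[Token, ...] = ()
    r_peak_index: int = -1

    @property
    def onset(self) -> int:
        parts = [t for t in (self.q_token, *self.rest_tokens, self.r_token, self.s_token) if t]
        return min(t.start for t in parts)

    @property
    def offset(self) -> int:
        parts = [t for t in (self.q_token, *self.rest_tokens, self.r_token, self.s_token) if t]
        return max(t.end for t in parts)

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / self.fs


@dataclass(frozen=True)
class DetectionResult:
    """Ordered beats with their R fiducials and the configuration used."""

    beats: tuple[QRSComplex, ...]
    r_peaks: np.ndarray
    config: DetectorConfig
    fs: float
    label: str = ""

    @property
    def qrs_durations_s(self) -> np.ndarray:
        return np.array([b.duration_s for b in self.beats])

    def to_dict(self) -> dict:
        return {
            "schema": "qrsgram/detection/1",
            "label": self.label,
            "fs": self.fs,
            "config": {
                "sigma1": self.config.sigma1,
                "delta1": self.config.delta1,
                "strict_s": self.config.strict_s,
            },
            "n_beats": len(self.beats),
            "r_peaks": [int(i) for i in self.r_peaks],
            "beats": [
                {
                    "onset": b.onset,
                    "offset": b.offset,
                    "r_peak": int(b.r_peak_index),
                    "onset_s": b.onset / self.fs,
                    "offset_s": b.offset / self.fs,
                    "r_peak_s": b.r_peak_index / self.fs,
                    "duration_s": b.duration_s,
                    "has_q": b.q_token is not None,
                    "has_s": b.s_token is not None,
                }
                for b in self.beats
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def write_annotations_csv(self, path: str | os.PathLike) -> None:
        """2-column beat annotation file (sample_index, label 'N')."""
        tmp = f"{path}.tmp"
        with open(tmp, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_index", "label"])
            for i in self.r_peaks:
                w.writerow([int(i), "N"])
        os.replace(tmp, path)


def label_tokens(
    pairs: Sequence[tuple[Token, SegmentStats]], config: DetectorConfig | None = None
) -> list[LabeledToken]:
    """Apply the sigma/duration constraints to each token.

    POS tokens with sigma > sigma1 and duration < delta1 become R candidates;
    NEG tokens shorter than delta1 become Q candidates (sigma > sigma1/2),
    S candidates (sigma > sigma1), or both; REST tokens shorter than delta1/2
    become rest separators.  Everything else — in particular the broad P and
    T waves — is left as wave/other and never enters a beat.
    """
    config = config or DetectorConfig()
    out = []
    for token, stats in pairs:
        role = TokenRole.OTHER
        if token.cls is SampleClass.POS:
            if stats.sigma > config.sigma1 and stats.duration < config.delta1:
                role = TokenRole.R_CANDIDATE
        elif token.cls is SampleClass.NEG:
            if stats.duration < config.delta1:
                q_ok = stats.sigma > config.sigma1 / 2
                s_ok = stats.sigma > config.sigma1
                if q_ok and s_ok:
                    role = TokenRole.QS_CANDIDATE
                elif s_ok:
                    role = TokenRole.S_CANDIDATE
                elif q_ok:
                    role = TokenRole.Q_CANDIDATE
        else:  # REST
            if stats.duration < config.delta1 / 2:
                role = TokenRole.REST
        out.append(LabeledToken(token=token, stats=stats, role=role))
    return out


def assemble_qrs(
    labeled: Sequence[LabeledToken], config: DetectorConfig | None = None, fs: float = 360.0
) -> list[QRSComplex]:
    """Greedy left-to-right parse of the beat grammar over labeled tokens.

    At each R candidate the parser looks back for an adjacent optional rest
    and Q candidate (not yet consumed by the previous beat) and forward for an
    optional rest and the S candidate.  A negative token lying between two R
    candidates is consumed as the S of the left beat first, since the grammar
    finishes a complex with S before a new one may start.  In strict mode an
    R with no reachable S yields no beat.
    """
    config = config or DetectorConfig()
    beats: list[QRSComplex] = []
    consumed = -1  # highest token index used by an emitted beat
    i = 0
    n = len(labeled)
    while i < n:
        if labeled[i].role is not TokenRole.R_CANDIDATE:
            i += 1
            continue
        # forward: optional rest, then S
        j = i + 1
        rest_after = None
        if j < n and labeled[j].role is TokenRole.REST:
            rest_after = labeled[j].token
            j += 1
        s_token = None
        if j < n and labeled[j].may_be_s:
            s_token = labeled[j].token
        if s_token is None and config.strict_s:
            i += 1
            continue
        # backward: optional rest, then Q, over unconsumed tokens only
        k = i - 1
        rest_before = None
        if k > consumed and labeled[k].role is TokenRole.REST:
            rest_before = labeled[k].token
            k -= 1
        q_token = labeled[k].token if k > consumed and labeled[k].may_be_q else None
        if q_token is None:
            rest_before = None  # a dangling rest belongs to no beat
        rests = tuple(t for t in (rest_before, rest_after if s_token else None) if t)
        r_token = labeled[i].token
        beat = QRSComplex(
            r_token=r_token,
            fs=fs,
            q_token=q_token,
            s_token=s_token,
            rest_tokens=rests,
            r_peak_index=locate_r_peak_token(r_token),
        )
        beats.append(beat)
        consumed = j if s_token is not None else i
        i = consumed + 1
    return beats


def locate_r_peak_token(r_token: Token) -> int:
    """Sample index of the maximum amplitude inside the R token (earliest on
    ties)."""
    return r_token.start + int(np.argmax(r_token.samples))


def locate_r_peak(complex_: QRSComplex, sig: Signal | None = None) -> int:
    """Fiducial of a beat: argmax of the R token's amplitudes."""
    return locate_r_peak_token(complex_.r_token)


def detect(
    sig: Signal,
    filter_spec: FilterSpec | None = None,
    config: DetectorConfig | None = None,
    precision: int = DEFAULT_PRECISION,
) -> DetectionResult:
    """Full chain on a raw signal: preprocess, tokenize, label, assemble.

    Deterministic for fixed inputs and configuration.
    """
    config = config or DetectorConfig()
    norm = preprocess(sig, filter_spec)
    tokens = tokenize(norm, precision)
    pairs = [(t, token_stats(t, norm.fs)) for t in tokens]
    labeled = label_tokens(pairs, config)
    beats = assemble_qrs(labeled, config, fs=norm.fs)
    r_peaks = np.array([b.r_peak_index for b in beats], dtype=int)
    return DetectionResult(
        beats=tuple(beats), r_peaks=r_peaks, config=config, fs=norm.fs, label=sig.label
    )
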