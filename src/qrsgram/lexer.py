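"""Lexical analysis of the normalized amplitude stream.

A normalized ECG is read as text over the alphabet
``Σ = {0,1,2,3,4,5,6,7,8,9,-,.}``: each sample is serialized as a fixed-point
decimal and the stream is split into *tokens* — maximal runs of samples of the
same class:

- ``POS``  : rounded amplitude >= 0.1   (candidate R deflection)
- ``NEG``  : rounded amplitude <= -0.1  (candidate Q/S deflection)
- ``REST`` : |rounded amplitude| < 0.1  (near-isoelectric)

The 0.1 boundary is exactly the boundary drawn by the lexical patterns: a
peak sample reads ``0.[1-9][0-9]*`` or ``1`` (second character after the
point nonzero), a rest sample reads ``-?0.0[0-9]*``.  Classification is done
on the *rounded* value so the numeric view and the regex view can never
disagree.

Per token the detector needs three statistics: population standard deviation
sigma, mean amplitude, and duration k/fs seconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .preprocess import Signal

__all__ = [
    "ALPHABET",
    "SampleClass",
    "Token",
    "SegmentStats",
    "serialize_sample",
    "serialize_samples",
    "classify_sample",
    "tokenize",
    "token_stats",
    "DEFAULT_PRECISION",
]

#: every character that may appear in a serialized normalized amplitude
ALPHABET = frozenset("0123456789-.")

#: fractional digits used when serializing samples (decimal rounding, half-even)
DEFAULT_PRECISION = 3


class SampleClass(enum.Enum):
    """Lexical class of one normalized sample."""

    POS = "POS"
    NEG = "NEG"
    REST = "REST"


@dataclass(frozen=True)
class Token:
    """A maximal run of same-class samples: the half-open slice [start, end)."""

    cls: SampleClass
    start: int
    end: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(f"empty token [{self.start}, {self.end})")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def k(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentStats:
    """Per-token statistics: sigma (population std), mean, duration in s."""

    sigma: float
    mean: float
    duration: float


def _round(a: float, precision: int) -> float:
    # Python round(): correct decimal rounding of the double, ties to even.
    return round(float(a), precision)


def serialize_sample(a: float, precision: int = DEFAULT_PRECISION) -> str:
    """Serialize one normalized amplitude as a fixed-point decimal string.

    The values +-1 serialize as ``"1"`` / ``"-1"``; everything else carries
    exactly ``precision`` fractional digits.  Every character of the result
    belongs to the alphabet.
    """
    if not -1.0 <= a <= 1.0:
        raise InputError(f"amplitude {a} outside [-1, 1]; signal not normalized?")
    r = _round(a, precision)
    if r == 1.0:
        return "1"
    if r == -1.0:
        return "-1"
    if r == 0.0:  # avoid the "-0.000" spelling
        r = 0.0
    return f"{r:.{precision}f}"


def serialize_samples(samples: Iterable[float], precision: int = DEFAULT_PRECISION) -> str:
    """Concatenate the serializations of a sample sequence (no separator)."""
    return "".join(serialize_sample(a, precision) for a in samples)


def classify_sample(a: float, precision: int = DEFAULT_PRECISION) -> SampleClass:
    """Classify one sample by thresholding its rounded value at +-0.1."""
    if not -1.0 <= a <= 1.0:
        raise InputError(f"amplitude {a} outside [-1, 1]; signal not normalized?")
    r = _round(a, precision)
    if r >= 0.1:
        return SampleClass.POS
    if r <= -0.1:
        return SampleClass.NEG
    return SampleClass.REST


def tokenize(sig: Signal, precision: int = DEFAULT_PRECISION) -> list[Token]:
    """Partition a normalized signal into maximal same-class runs.

    The tokens tile the signal: their [start, end) ranges are disjoint and
    their union covers every sample, so concatenating token slices reproduces
    the signal exactly.
    """
    a = sig.samples
    if a.size and (np.abs(a).max() > 1.0):
        raise InputError("signal has |amplitude| > 1; run preprocess() first")
    r = np.round(a, precision)
    codes = np.zeros(a.size, dtype=np.int8)  # 0 = REST
    codes[r >= 0.1] = 1                      # POS
    codes[r <= -0.1] = -1                    # NEG
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [a.size]))
    lut = {1: SampleClass.POS, -1: SampleClass.NEG, 0: SampleClass.REST}
    return [
        Token(cls=lut[int(codes[s])], start=int(s), end=int(e), samples=a[s:e])
        for s, e in zip(starts, ends)
    ]


def token_stats(token: Token, fs: float) -> SegmentStats:
    """Population sigma, mean amplitude, and duration of one token.

    sigma uses the population form (divisor k); duration is exactly k/fs.
    """
    x = token.samples
    k = x.size
    if k == 0:
        raise InputError("cannot compute statistics of an empty token")
    mean = float(x.mean())
    sigma = float(math.sqrt(np.mean((x - mean) ** 2)))
    return SegmentStats(sigma=sigma, mean=mean, duration=k / fs)


def tokens_with_stats(
    tokens: Sequence[Token], fs: float
) -> list[tuple[Token, SegmentStats]]:
    """Convenience pairing used by the detector and the CLI token dump."""
    return [(t, token_stats(t, fs)) for t in tokens]
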