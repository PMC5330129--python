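"""Rhythm statistics: RR intervals, QRS durations, and regularity flags.

The RR interval is the time between two successive R-peak fiducials.  For a
record with n+1 beats there are n RR intervals and n+1 QRS durations.  Both
series are summarized by their mean and population standard deviation
(sigma_RR, sigma_QRS); a sigma below 0.1 s flags the series as regular, at or
above 0.1 s as irregular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "RhythmSummary",
    "rr_intervals",
    "summarize",
    "classify_regularity",
    "REGULARITY_THRESHOLD_S",
]

#: sigma below this (seconds) means the interval series is regular
REGULARITY_THRESHOLD_S = 0.1


@dataclass(frozen=True)
class RhythmSummary:
    """Means, population sigmas and regularity flags of the two series.

    All durations in seconds.  Fields are None for series too short to
    summarize (fewer than one interval / one duration).
    """

    rr: np.ndarray
    qrs_durations: np.ndarray
    rr_mean: float | None
    rr_sigma: float | None
    qrs_mean: float | None
    qrs_sigma: float | None
    rr_regular: bool | None
    qrs_regular: bool | None

    def to_dict(self) -> dict:
        return {
            "rr_mean": self.rr_mean,
            "rr_sigma": self.rr_sigma,
            "qrs_mean": self.qrs_mean,
            "qrs_sigma": self.qrs_sigma,
            "rr_regular": self.rr_regular,
            "qrs_regular": self.qrs_regular,
            "n_rr": int(self.rr.size),
            "n_qrs": int(self.qrs_durations.size),
        }


def rr_intervals(r_peaks, fs: float) -> np.ndarray:
    """RR series in seconds from fiducial sample indices.

    Fewer than two fiducials yield an empty series (with a warning), since no
    interval exists.
    """
    peaks = np.asarray(r_peaks, dtype=float)
    if peaks.size >= 2 and not np.all(np.diff(peaks) > 0):
        raise InputError("fiducial indices must be strictly increasing")
    if peaks.size < 2:
        warnings.warn("fewer than 2 fiducials: empty RR series", stacklevel=2)
        return np.array([])
    return np.diff(peaks) / fs


def _pop_sigma(x: np.ndarray) -> float:
    # population form: divisor n, squared deviations
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def summarize(rr, qrs_durations) -> RhythmSummary:
    """Mean and population sigma of both series, plus regularity flags.

    An empty series produces None statistics and a warning rather than an
    error, so partial records still yield a report.
    """
    rr = np.asarray(rr, dtype=float)
    qrs = np.asarray(qrs_durations, dtype=float)
    if np.any(rr <= 0) or np.any(qrs <= 0):
        raise InputError("intervals and durations must be positive")

    def stats(x: np.ndarray, name: str):
        if x.size == 0:
            warnings.warn(f"empty {name} series: summary fields are null", stacklevel=3)
            return None, None, None
        mean = float(x.mean())
        sigma = _pop_sigma(x)
        return mean, sigma, classify_regularity(sigma) == "regular"

    rr_mean, rr_sigma, rr_reg = stats(rr, "RR")
    qrs_mean, qrs_sigma, qrs_reg = stats(qrs, "QRS-duration")
    return RhythmSummary(
        rr=rr,
        qrs_durations=qrs,
        rr_mean=rr_mean,
        rr_sigma=rr_sigma,
        qrs_mean=qrs_mean,
        qrs_sigma=qrs_sigma,
        rr_regular=rr_reg,
        qrs_regular=qrs_reg,
    )


def classify_regularity(sigma: float, threshold: float = REGULARITY_THRESHOLD_S) -> str:
    """'regular' iff sigma < threshold (strict); the boundary is irregular."""
    if sigma < 0:
        raise InputError(f"sigma must be >= 0, got {sigma}")
    return "regular" if sigma < threshold else "irregular"
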