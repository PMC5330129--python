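"""Detection-quality scoring and SNR robustness sweeps.

Detected fiducials are matched one-to-one against reference annotations
within a time tolerance (default 150 ms); from the TP/FP/FN counts four
rates follow:

- sensitivity        Se  = TP/(TP+FN) x 100
- specificity        Sp  = TP/(TP+FP) x 100  (this is positive predictivity:
  the fraction of detections that are true beats — the term "specificity" is
  kept because that is what the rate is called in this method's report)
- false detection    FDR = FP/(TP+FP) x 100 = 100 - Sp
- false negative     FNR = FN/(TP+FN) x 100 = 100 - Se

For robustness studies, additive white Gaussian noise is injected at a
target SNR (power referenced to the centered signal) and the detector is
re-scored per SNR level and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .detector import DetectorConfig, detect
from .errors import InputError
from .preprocess import FilterSpec, Signal

__all__ = [
    "EvalReport",
    "NoiseSpec",
    "match_beats",
    "confusion_rates",
    "add_noise",
    "measured_snr_db",
    "snr_sweep",
    "DEFAULT_MATCH_TOLERANCE_S",
]

#: beat-matching window (seconds); a detection within +-150 ms of an
#: unmatched reference beat counts as that beat
DEFAULT_MATCH_TOLERANCE_S = 0.15


def _round2(x: float | None) -> float | None:
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalReport:
    """TP/FP/FN counts and the four derived rates (raw percentages).

    ``se_pct``/``sp_pct``/``fdr_pct``/``fnr_pct`` are unrounded; the
    ``*_2dp`` properties give the half-up 2-decimal display form.  Rates with
    a zero denominator are None (undefined), never silently 0.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise InputError("counts must be non-negative")

    @property
    def se_pct(self) -> float | None:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def sp_pct(self) -> float | None:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def fdr_pct(self) -> float | None:
        return 100.0 * self.fp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def fnr_pct(self) -> float | None:
        return 100.0 * self.fn / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def se_2dp(self) -> float | None:
        return _round2(self.se_pct)

    @property
    def sp_2dp(self) -> float | None:
        return _round2(self.sp_pct)

    @property
    def fdr_2dp(self) -> float | None:
        return _round2(self.fdr_pct)

    @property
    def fnr_2dp(self) -> float | None:
        return _round2(self.fnr_pct)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "se_pct": self.se_2dp,
            "sp_pct": self.sp_2dp,
            "fdr_pct": self.fdr_2dp,
            "fnr_pct": self.fnr_2dp,
            "raw": {
                "se_pct": self.se_pct,
                "sp_pct": self.sp_pct,
                "fdr_pct": self.fdr_pct,
                "fnr_pct": self.fnr_pct,
            },
        }


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a target SNR; the seed fixes the
    realization exactly."""

    snr_db: float
    seed: int = 0
    noise_kind: str = "awgn"

    def __post_init__(self) -> None:
        if self.noise_kind != "awgn":
            raise InputError(f"unsupported noise kind {self.noise_kind!r}")


def match_beats(
    detected: Sequence[int] | np.ndarray,
    reference: Sequence[int] | np.ndarray,
    tolerance_s: float,
    fs: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching in time order.

    Returns (tp, fp, fn) with tp + fn = len(reference) and
    tp + fp = len(detected).
    """
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    for name, arr in (("detected", det), ("reference", ref)):
        if arr.size >= 2 and not np.all(np.diff(arr) > 0):
            raise InputError(f"{name} fiducials must be strictly increasing")
    tol = tolerance_s * fs
    i = j = tp = 0
    while i < det.size and j < ref.size:
        d = det[i] - ref[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:  # detection too early to match this reference
            i += 1
        else:
            j += 1
    fp = det.size - tp
    fn = ref.size - tp
    return tp, int(fp), int(fn)


def confusion_rates(tp: int, fp: int, fn: int) -> EvalReport:
    """Se/Sp/FDR/FNR report from the three counts."""
    return EvalReport(tp=tp, fp=fp, fn=fn)


def measured_snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Re-measure the SNR of an injected-noise signal (diagnostic)."""
    c = np.asarray(clean, float)
    w = np.asarray(noisy, float) - c
    p_sig = np.mean((c - c.mean()) ** 2)
    p_noise = np.mean((w - w.mean()) ** 2)
    return 10.0 * np.log10(p_sig / p_noise)


def add_noise(sig: Signal, spec: NoiseSpec) -> Signal:
    """Inject white Gaussian noise at the target SNR.

    Signal power is the mean squared amplitude about the mean, so the dB
    values are reproducible regardless of any DC offset.
    """
    x = sig.samples
    p_sig = float(np.mean((x - x.mean()) ** 2))
    if p_sig == 0:
        raise InputError("cannot set an SNR against a zero-power signal")
    p_noise = p_sig / (10.0 ** (spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.seed)
    w = rng.normal(0.0, np.sqrt(p_noise), size=x.size)
    return sig.with_samples(x + w)


def snr_sweep(
    sig: Signal,
    reference: Sequence[int] | np.ndarray,
    snr_list: Sequence[float],
    seeds: Sequence[int],
    filter_spec: FilterSpec | None = None,
    config: DetectorConfig | None = None,
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> list[dict]:
    """Score the detector at each SNR level over several noise seeds.

    Returns one row per (snr_db, seed) with the counts and rates, ordered by
    the given SNR list then seed.  Sensitivity is expected to degrade as SNR
    falls, but the sweep measures — it does not enforce.
    """
    rows: list[dict] = []
    for snr_db in snr_list:
        for seed in seeds:
            noisy = add_noise(sig, NoiseSpec(snr_db=snr_db, seed=int(seed)))
            result = detect(noisy, filter_spec, config)
            tp, fp, fn = match_beats(result.r_peaks, reference, tolerance_s, sig.fs)
            report = confusion_rates(tp, fp, fn)
            rows.append(
                {
                    "snr_db": float(snr_db),
                    "seed": int(seed),
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "se_pct": report.se_pct,
                    "sp_pct": report.sp_pct,
                    "report": report,
                }
            )
    return rows
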