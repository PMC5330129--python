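"""Synthetic single-lead ECG with exact ground-truth beat positions.

Each beat is a sum of five Gaussian-shaped deflections — P, Q, R, S, T —
placed relative to the R peak, repeated at (optionally jittered) RR
intervals, with an optional sinusoidal baseline drift.  The morphology
defaults encode the structure the detector exploits:

- QRS deflections (Q, R, S) are narrow (extent < 0.1 s) and steep, so their
  tokens show a large standard deviation and a short duration;
- P and T waves are broad (extent > 0.1 s) and shallow, so their tokens fail
  the duration (and sigma) constraints and never form beats.

Amplitudes are fractions of the R deflection: R 1.0, S -0.45, Q -0.15,
T 0.25, P 0.1.  The generator is deterministic under a fixed seed and the
ground truth is exact by construction (R deflection centers are placed on
the sample grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .preprocess import Signal

__all__ = ["WaveSpec", "SynthConfig", "GroundTruth", "generate", "generate_tachycardia"]

#: a wave's extent is taken as +-2 standard deviations of its Gaussian
_EXTENT_SIGMAS = 4.0


@dataclass(frozen=True)
class WaveSpec:
    """One deflection: amplitude (fraction of R), Gaussian std width in
    seconds, and center offset from the R peak in seconds."""

    amplitude: float
    width_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (self.width_s > 0):
            raise ConfigurationError(f"wave width must be > 0, got {self.width_s}")

    @property
    def extent_s(self) -> float:
        return _EXTENT_SIGMAS * self.width_s


def _default_waves() -> dict[str, WaveSpec]:
    return {
        "P": WaveSpec(amplitude=0.10, width_s=0.030, offset_s=-0.200),
        "Q": WaveSpec(amplitude=-0.15, width_s=0.010, offset_s=-0.030),
        "R": WaveSpec(amplitude=1.00, width_s=0.012, offset_s=0.000),
        "S": WaveSpec(amplitude=-0.45, width_s=0.012, offset_s=0.030),
        "T": WaveSpec(amplitude=0.25, width_s=0.050, offset_s=0.300),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator conditions.

    Defaults: 360 Hz sampling, 0.8 s mean RR (75 bpm), no jitter, no drift.
    ``rr_jitter_s`` is the standard deviation of a truncated-normal RR
    perturbation (floor 0.3 s keeps beats separable).  The QRS deflections
    must stay narrower than 0.1 s and the P/T waves broader than 0.1 s, and
    the mean RR must exceed the summed wave extents, otherwise the
    configuration is rejected as infeasible.
    """

    fs: float = 360.0
    duration_s: float = 30.0
    mean_rr_s: float = 0.8
    rr_jitter_s: float = 0.0
    waves: dict[str, WaveSpec] = field(default_factory=_default_waves)
    baseline_drift_amp: float = 0.0
    baseline_drift_hz: float = 0.3
    seed: int = 0
    rr_floor_s: float = 0.3

    def __post_init__(self) -> None:
        if not (self.fs > 0):
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if not (self.duration_s > 0):
            raise ConfigurationError(f"duration must be > 0, got {self.duration_s}")
        if self.rr_jitter_s < 0:
            raise ConfigurationError("rr_jitter_s must be >= 0")
        for name in ("Q", "R", "S"):
            if name in self.waves and self.waves[name].extent_s >= 0.1:
                raise ConfigurationError(
                    f"{name} extent {self.waves[name].extent_s:.3f}s must be < 0.1 s"
                )
        for name in ("P", "T"):
            if name in self.waves and self.waves[name].extent_s <= 0.1:
                raise ConfigurationError(
                    f"{name} extent {self.waves[name].extent_s:.3f}s must be > 0.1 s"
                )
        total_extent = sum(w.extent_s for w in self.waves.values())
        if self.mean_rr_s <= total_extent:
            raise ConfigurationError(
                f"mean RR {self.mean_rr_s}s must exceed summed wave extents "
                f"{total_extent:.3f}s (waves would overlap across beats)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """True R-peak sample indices and the RR series they imply."""

    r_indices: np.ndarray
    rr_s: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.r_indices, dtype=int)
        if idx.size >= 2 and not np.all(np.diff(idx) > 0):
            raise ConfigurationError("ground-truth indices must be strictly increasing")
        object.__setattr__(self, "r_indices", idx)
        object.__setattr__(self, "rr_s", np.asarray(self.rr_s, dtype=float))


# margin (s) kept free of beats at both record edges, leaving room for the
# P wave before the first R and the T wave after the last
_EDGE_MARGIN_S = 0.4


def generate(config: SynthConfig | None = None) -> tuple[Signal, GroundTruth]:
    """Render a synthetic ECG and its exact beat annotations.

    R centers are quantized to the sample grid before rendering, so
    ``diff(r_indices)/fs`` equals the returned RR series exactly.
    """
    config = config or SynthConfig()
    fs = config.fs
    n = int(round(config.duration_s * fs))
    if n < 2:
        raise ConfigurationError(f"duration {config.duration_s}s yields {n} samples")
    rng = np.random.default_rng(config.seed)

    # place R peaks on the sample grid
    r_times = []
    t = _EDGE_MARGIN_S
    while t <= config.duration_s - _EDGE_MARGIN_S:
        r_times.append(t)
        rr = config.mean_rr_s
        if config.rr_jitter_s > 0:
            rr = rng.normal(config.mean_rr_s, config.rr_jitter_s)
        t += max(rr, config.rr_floor_s)
    if not r_times:
        raise ConfigurationError(
            f"duration {config.duration_s}s leaves no room for a beat"
        )
    r_indices = np.round(np.array(r_times) * fs).astype(int)
    r_indices = r_indices[r_indices < n]

    tt = np.arange(n) / fs
    x = np.zeros(n)
    for ridx in r_indices:
        t_r = ridx / fs
        for wave in config.waves.values():
            c = t_r + wave.offset_s
            # render only a +-5 sigma window around the wave center
            lo = max(0, int((c - 5 * wave.width_s) * fs))
            hi = min(n, int((c + 5 * wave.width_s) * fs) + 1)
            if lo < hi:
                seg = tt[lo:hi]
                x[lo:hi] += wave.amplitude * np.exp(
                    -0.5 * ((seg - c) / wave.width_s) ** 2
                )
    if config.baseline_drift_amp:
        x += config.baseline_drift_amp * np.sin(2 * np.pi * config.baseline_drift_hz * tt)

    rr_s = np.diff(r_indices) / fs
    sig = Signal(samples=x, fs=fs, label=f"synth(seed={config.seed})")
    return sig, GroundTruth(r_indices=r_indices, rr_s=rr_s, fs=fs)


def generate_tachycardia(
    config: SynthConfig | None = None, **overrides
) -> tuple[Signal, GroundTruth]:
    """A fast regular rhythm: mean RR 0.46 s (~130 bpm), no jitter."""
    base = config or SynthConfig()
    params = {"mean_rr_s": 0.46, "rr_jitter_s": 0.0, **overrides}
    return generate(replace(base, **params))
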