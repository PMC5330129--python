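# Methods

## Model

`qrsgram` is a syntactic beat detector. After preprocessing, a single-lead
ECG becomes a bounded, dimensionless amplitude stream in [-1, 1]; each sample
is serialized as a fixed-point decimal over `Σ = {0–9, '-', '.'}` and the
stream becomes a word in a regular language. Three per-sample lexical
classes partition the amplitude range:

- **POS** — serialization matches `0.[1-9][0-9]*|1`, i.e. rounded value ≥ 0.1;
- **NEG** — matches `-0.[1-9][0-9]*|-1`, i.e. rounded value ≤ −0.1;
- **REST** — matches `-?0.0[0-9]*`, i.e. |rounded value| < 0.1.

Maximal same-class runs are tokens. A token's population standard deviation
σ (divisor k), mean, and duration Δ = k/fs separate morphologies: QRS
deflections are steep and narrow (high σ, Δ < 0.1 s), P/T waves are shallow
and broad (low σ, Δ > 0.1 s). Labeled tokens are parsed against

```
QRS = {Q}? {rest}? {R} {rest}? {S}
```

greedily left to right; each emitted beat's R-token amplitude maximum is the
fiducial used for RR intervals.

### Assumptions

- Beats carry a dominant positive R deflection after band-pass filtering
  (the usual situation on a standard lead; entirely negative QRS
  morphologies are out of reach of this grammar).
- In strict mode (default) each beat must end in a distinct negative S
  token. The lenient mode (`strict_s=False`) accepts R alone for
  morphologies without a visible S, but is off by default because the
  grammar prints S as mandatory.
- Sampling is uniform; 360 Hz is the default, matching the standard
  arrhythmia benchmark format (360 Hz, gain 200, baseline 1024).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `sigma1` | 0.1 | dimensionless | minimum token σ for R and S peaks; Q uses σ₁/2 (Q is typically the shallowest deflection — the asymmetry is part of the method's constraint set) |
| `delta1` | 0.1 | s | maximum peak-token duration; rest tokens must be < Δ₁/2 |
| `FilterSpec.low_hz/high_hz` | 5 / 15 | Hz | pass-band that maximizes QRS energy against baseline wander and T waves |
| `FilterSpec.order` | 2 | — | Butterworth section order (doubled by the forward–backward pass) |
| `precision` | 3 | decimal digits | serialization precision; see below |
| `tolerance_s` | 0.15 | s | beat-matching window for scoring; a conventional choice that must be explicit for Se/Sp to be well defined (tests on synthetic data use the stricter 0.05 s) |
| regularity threshold | 0.1 | s | σ_RR (σ_QRS) < 0.1 strictly ⇒ regular; the boundary value counts as irregular |

## Numerical and design choices

**Filter realization.** The band-pass is a 2nd-order Butterworth applied
forward and backward (`sosfiltfilt`, reflective padding). Zero phase
protects fiducial timing: a symmetric pulse's peak moves at most one sample.
Reflective padding avoids spurious edge peaks entering the lexer.

**Normalization scale.** The centered signal is divided by its maximum
*absolute* deviation, not the maximum (signed) deviation — only the absolute
form bounds deep negative deflections to −1 and keeps the [-1, 1] contract
that the serialization alphabet assumes. Constant signals (and signals that
are constant up to filter round-off, scale ≤ 1e−12 relative) raise a
degenerate-input error rather than dividing by ~0.

**Serialization precision.** Source data quantization varies (11-bit ADCs
are typical), so the decimal precision is a package choice: 3 fractional
digits, decimal rounding with ties to even. Classification thresholds are
applied to the *rounded* value, which guarantees the numeric and regex views
agree (e.g. 0.0999 rounds to 0.100 → POS under both). The boundary is
inclusive: rounded 0.1 is POS, −0.1 is NEG. Values rounding to ±1 serialize
as `1`/`-1`.

**Automata engine.** The machines' transition tables include ε-moves
(realizing `+` repetitions and optional sections), so the engine is an
ε-NFA executed by ε-closure subset simulation — deterministic in outcome for
fixed machine and input. Digit-range shorthands (`0–9`, `1–9`) are expanded
per digit at build time; patterns are anchored to whole strings, with a
longest-prefix mode for diagnostics only. Each machine's contract is
language equality with its regular expression, enforced by tests against
the `re` engine on the full amplitude grid and on random strings.

Two transitions in the composite QRS machine deserve a call-out because
they are easy to lose when tabulating the machine by hand, and without them
the machine rejects words its regular expression generates (both are marked
in `automata.build_qrs_machine`): the digit loop `δ(15, 0–9) = 15`
completing `[0-9]*` in the embedded R pattern, and the ε-entry
`δ(0, ε) = 6` that lets a rest phase precede R when Q is absent. Duplicate
ε-entries are harmless under subset simulation and are kept.

**Q/S disambiguation.** The grammar gives Q and S the same lexical shape
with different σ thresholds and only an ordering rule (Q before R, S after).
Assignment is therefore positional around each R candidate, with the
role-specific σ threshold applied after placement. A NEG token between two R
candidates closes the left beat as its S — the grammar consumes S before a
new complex may start. Assembly is greedy, left-to-right, non-backtracking
across emitted beats; each token is consumed at most once, which prevents
duplicate beats structurally (no refractory period is added).

**Rhythm statistics.** σ_RR and σ_QRS are population standard deviations
with squared deviations — the ordinary definition, consistent with the
token σ. For n+1 beats there are n RR intervals and n+1 QRS durations; the
module uses however many beats were detected. Empty series yield null
summaries with a warning, never exceptions.

**Scoring.** Matching is greedy one-to-one in time order within
±tolerance; the identities tp+fn = |reference| and tp+fp = |detected| hold
by construction. "Specificity" is TP/(TP+FP) — positive predictivity — kept under the name
this family of grammar-based detectors traditionally reports it by. Displayed rates are rounded
half-up to 2 decimals; raw values are preserved. Zero-denominator rates are
reported as undefined (null), never as 0.

**Noise injection.** Additive white Gaussian noise, the standard first-order
robustness model; the target SNR references the power (mean square about the
mean) of the clean signal, so dB values are reproducible and independent of
DC offset. The realization is fixed by a seed.

## The synthetic generator

Each beat is a sum of five Gaussian deflections (P, Q, R, S, T) placed
relative to the R center, which is quantized to the sample grid so the
ground truth is exact. Defaults: amplitudes R 1.0, S −0.45, Q −0.15, T 0.25,
P 0.1 (fractions of R); Gaussian widths 12 ms (R), 10 ms (Q), 12 ms (S),
30 ms (P), 50 ms (T); offsets P −200 ms, Q −30 ms, S +30 ms, T +300 ms. With
extent taken as ±2 widths, QRS deflections stay under 0.1 s and P/T waves
over 0.1 s — the premise the σ/Δ constraints encode — and the configuration
is validated against it. RR jitter is a truncated normal (0.3 s floor keeps
beats separable); optional sinusoidal baseline drift (default off) exercises
the filter.

What the generator does **not** emulate: muscle/electrode artifact with
realistic spectra, ectopic morphologies (wide PVCs, bundle-branch-block
shapes), negative-R beats, ST-segment shifts, amplitude modulation from
respiration. Passing the synthetic closure therefore shows the pipeline is
correct *given the morphology assumptions*, not that it attains any
particular accuracy on clinical recordings; scoring on real annotated
records (via the optional WFDB path) remains the only test of that.

Problem sizes in the test and acceptance runs are chosen to estimate the
relevant statistics tightly while keeping runs quick: 5-minute records
(≈ 300–500 beats) for closure and regularity statistics, 2-minute records
for the SNR sweep, ten generator seeds for closure, five noise seeds per SNR
level.

## Known limitations

- Strict mode under-detects morphologies lacking a distinct S wave; lenient
  mode trades that for possible T-wave confusion on noisy records.
- The grammar has no refractory logic; pathological double-peaked R waves
  split by a NEG token can yield adjacent beats closer than physiology
  allows.
- Band-pass ringing turns a monophasic R into an R-with-side-lobes complex;
  this is what makes strict S workable, but it means the reported QRS
  duration reflects the *filtered* complex span (wider than the unfiltered
  deflection group).
- SNR robustness on synthetic fixtures is optimistic: white noise is heavily
  attenuated by the 5–15 Hz band, while real interference (muscle artifact,
  electrode motion) concentrates in-band.
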