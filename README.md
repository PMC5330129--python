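# qrsgram

Grammar-based QRS complex detection for single-lead ECG.

The QRS complex — the Q, R and S deflections of a heartbeat — is the anchor
of almost every ECG analysis: beat counting, RR-interval variability, rhythm
regularity. `qrsgram` detects it by treating the normalized signal as *text*:
every sample is serialized as a fixed-point decimal over the alphabet
`Σ = {0–9, '-', '.'}`, the stream is tokenized into maximal runs of
positive-peak, negative-peak and rest samples, and beats are parsed by finite
automata realizing the regular grammar

```
R    = (0.[1-9][0-9]* | 1)+           σ_R > σ₁,    Δ_R < Δ₁
Q, S = (-0.[1-9][0-9]* | -1)+         σ_Q > σ₁/2,  σ_S > σ₁,  Δ < Δ₁
rest = (-?0.0[0-9]*)+                 Δ_rest < Δ₁/2
QRS  = {Q}? {rest}? {R} {rest}? {S}
```

with the two global thresholds σ₁ = 0.1 (dimensionless) and Δ₁ = 0.1 s.
The constraints are what make the grammar clinical: QRS deflections are
narrow and steep (token standard deviation σ above threshold, duration Δ
below), while P and T waves are broad and shallow and never parse as peaks.
Per record the package reports beat fiducials, RR intervals and QRS
durations with their means and population standard deviations (σ_RR, σ_QRS;
values below 0.1 s flag a regular rhythm), beat-level detection quality
(Se, Sp, FDR, FNR), and SNR robustness sweeps. A synthetic ECG generator
with exact ground truth makes the whole pipeline testable offline.

Intended users: biomedical-signal researchers and students studying
syntactic/automata-based ECG analysis, and anyone needing a transparent,
fully deterministic QRS detector with an inspectable grammar.

## Worked example

Generate a 30 s, 75 bpm synthetic record with mild RR jitter, detect, and
score against the known ground truth:

```sh
$ qrsgram synth --bpm 75 --duration 30 --jitter 0.05 --seed 7 \
    --out ecg.csv --ann-out truth.csv
38 beats -> ecg.csv
$ qrsgram detect ecg.csv --fs 360 --out report.json --ann-out beats.csv
38 beats -> report.json
$ qrsgram eval beats.csv truth.csv --tolerance 0.05
TP=38 FP=0 FN=0 Se=100.0 Sp=100.0 FDR=0.0 FNR=0.0
```

All 38 true beats are recovered within 50 ms with no false detections
(Se = TP/(TP+FN), and Sp here is TP/(TP+FP), i.e. positive predictivity).
The report's rhythm block:

```json
{
  "rr_mean": 0.7783783783783784,
  "rr_sigma": 0.040707862914626816,
  "qrs_mean": 0.14166666666666666,
  "qrs_sigma": 0.0,
  "rr_regular": true,
  "qrs_regular": true
}
```

The mean RR of 0.778 s matches the configured 75 bpm (0.8 s) up to the
realized jitter; σ_RR ≈ 0.041 s < 0.1 s, so the rhythm is flagged regular —
exactly what 50 ms of configured jitter should produce. The same pipeline is
available in Python:

```python
from qrsgram import SynthConfig, generate, detect, match_beats

sig, truth = generate(SynthConfig(duration_s=30, mean_rr_s=0.8, seed=7))
result = detect(sig)
tp, fp, fn = match_beats(result.r_peaks, truth.r_indices, 0.05, sig.fs)
```

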