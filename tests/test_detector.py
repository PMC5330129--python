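import numpy as np
import pytest

from qrsgram import (
    DegenerateSignalError,
    DetectorConfig,
    SampleClass,
    SegmentStats,
    Signal,
    SynthConfig,
    Token,
    TokenRole,
    assemble_qrs,
    build_qrs_machine,
    detect,
    generate,
    label_tokens,
    locate_r_peak,
    match_beats,
    run_automaton,
    serialize_samples,
)
from qrsgram.detector import locate_r_peak_token


def _tok(cls, start, samples):
    arr = np.asarray(samples, dtype=float)
    return Token(cls, start, start + arr.size, arr)


def _pair(cls, start, samples, sigma, duration):
    tok = _tok(cls, start, samples)
    return tok, SegmentStats(sigma=sigma, mean=float(np.mean(samples)), duration=duration)


class TestLabeling:
    def test_steep_short_positive_is_r_candidate(self):
        pairs = [_pair(SampleClass.POS, 0, [0.2, 0.9, 0.3], sigma=0.42, duration=0.008)]
        assert label_tokens(pairs)[0].role is TokenRole.R_CANDIDATE

    def test_shallow_negative_is_q_only(self):
        # sigma 0.06 clears sigma1/2 = 0.05 but not sigma1 = 0.1
        pairs = [_pair(SampleClass.NEG, 0, [-0.15, -0.2], sigma=0.06, duration=0.02)]
        lab = label_tokens(pairs)[0]
        assert lab.role is TokenRole.Q_CANDIDATE
        assert lab.may_be_q and not lab.may_be_s

    def test_steep_negative_may_be_q_or_s(self):
        pairs = [_pair(SampleClass.NEG, 0, [-0.1, -0.9], sigma=0.4, duration=0.008)]
        lab = label_tokens(pairs)[0]
        assert lab.may_be_q and lab.may_be_s

    def test_long_rest_is_wave(self):
        pairs = [_pair(SampleClass.REST, 0, [0.0] * 72, sigma=0.0, duration=0.2)]
        assert label_tokens(pairs)[0].role is TokenRole.OTHER

    def test_short_rest_is_rest(self):
        pairs = [_pair(SampleClass.REST, 0, [0.0] * 10, sigma=0.0, duration=0.028)]
        assert label_tokens(pairs)[0].role is TokenRole.REST

    def test_broad_positive_wave_rejected_by_duration(self):
        # T-wave-like: high enough amplitude but too long
        pairs = [_pair(SampleClass.POS, 0, [0.3] * 58, sigma=0.15, duration=0.16)]
        assert label_tokens(pairs)[0].role is TokenRole.OTHER


def _labeled_sequence(spec):
    """Build a labeled token list from (role_char, sigma) shorthand."""
    pairs = []
    pos = 0
    for role in spec:
        if role == "R":
            pairs.append(_pair(SampleClass.POS, pos, [0.2, 1.0, 0.2], 0.38, 3 / 360))
        elif role == "Q":
            pairs.append(_pair(SampleClass.NEG, pos, [-0.12, -0.18], 0.06, 2 / 360))
        elif role == "S":
            pairs.append(_pair(SampleClass.NEG, pos, [-0.1, -0.5], 0.2, 2 / 360))
        elif role == "r":
            pairs.append(_pair(SampleClass.REST, pos, [0.0, 0.01], 0.005, 2 / 360))
        elif role == "W":
            pairs.append(_pair(SampleClass.REST, pos, [0.0] * 100, 0.01, 100 / 360))
        pos = pairs[-1][0].end
    return label_tokens(pairs)


class TestAssembly:
    def test_full_five_part_complex(self):
        beats = assemble_qrs(_labeled_sequence("QrRrS"), fs=360.0)
        assert len(beats) == 1
        b = beats[0]
        assert b.q_token is not None and b.s_token is not None
        assert len(b.rest_tokens) == 2
        assert b.onset == 0 and b.offset == b.s_token.end
        assert b.duration_s == pytest.approx((b.offset - b.onset) / 360.0)

    def test_bare_rs_complex(self):
        beats = assemble_qrs(_labeled_sequence("RS"), fs=360.0)
        assert len(beats) == 1
        assert beats[0].q_token is None

    def test_r_alone_strict_yields_nothing(self):
        assert assemble_qrs(_labeled_sequence("R"), fs=360.0) == []

    def test_r_alone_lenient_yields_beat(self):
        cfg = DetectorConfig(strict_s=False)
        beats = assemble_qrs(_labeled_sequence("R"), cfg, fs=360.0)
        assert len(beats) == 1 and beats[0].s_token is None

    def test_negative_between_two_r_goes_to_left_beat_as_s(self):
        # R S R S: the middle S must close the first beat, not open the second
        beats = assemble_qrs(_labeled_sequence("RSWRS"), fs=360.0)
        assert len(beats) == 2
        assert all(b.s_token is not None for b in beats)

    def test_no_overlap_and_strictly_increasing(self):
        beats = assemble_qrs(_labeled_sequence("QrRrSWQrRrSWRS"), fs=360.0)
        assert len(beats) == 3
        spans = [(b.onset, b.offset) for b in beats]
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_consumed_token_sequence_is_in_the_qrs_language(self):
        machine = build_qrs_machine()
        for spec in ("QrRrS", "RS", "QRS", "RrS"):
            for b in assemble_qrs(_labeled_sequence(spec), fs=360.0):
                parts = [t for t in (b.q_token, b.r_token, b.s_token, *b.rest_tokens) if t]
                parts.sort(key=lambda t: t.start)
                samples = np.concatenate([t.samples for t in parts])
                assert run_automaton(machine, serialize_samples(samples)).accepted


class TestFiducial:
    def test_argmax_and_tie_rule(self):
        tok = _tok(SampleClass.POS, 100, [0.2, 0.9, 0.3])
        assert locate_r_peak_token(tok) == 101
        plateau = _tok(SampleClass.POS, 200, [0.9, 0.9])
        assert locate_r_peak_token(plateau) == 200
        single = _tok(SampleClass.POS, 300, [0.5])
        assert locate_r_peak_token(single) == 300


class TestDetect:
    def test_clean_sixty_bpm_record(self):
        sig, truth = generate(SynthConfig(duration_s=30.0, mean_rr_s=1.0, seed=5))
        res = detect(sig)
        assert abs(len(res.beats) - 30) <= 1
        tp, fp, fn = match_beats(res.r_peaks, truth.r_indices, 0.05, sig.fs)
        assert fn == 0 and fp == 0

    def test_all_zero_signal_errors(self):
        with pytest.raises(DegenerateSignalError):
            detect(Signal(samples=np.zeros(5000), fs=360.0))

    def test_t_waves_produce_no_beats(self, clean_fixture):
        # T amplitude 0.3 and 0.16 s extent: rejected by the duration rule
        from dataclasses import replace
        from qrsgram import WaveSpec

        sig, truth = generate(
            SynthConfig(
                duration_s=30.0,
                seed=6,
                waves={
                    **SynthConfig().waves,
                    "T": WaveSpec(amplitude=0.3, width_s=0.04, offset_s=0.3),
                },
            )
        )
        res = detect(sig)
        tp, fp, fn = match_beats(res.r_peaks, truth.r_indices, 0.05, sig.fs)
        assert fp == 0 and fn == 0

    def test_threshold_monotonicity(self, clean_fixture):
        sig, _ = clean_fixture
        counts = [
            len(detect(sig, config=DetectorConfig(sigma1=s)).beats)
            for s in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_r_peaks_strictly_increasing(self, clean_fixture):
        sig, _ = clean_fixture
        res = detect(sig)
        assert np.all(np.diff(res.r_peaks) > 0)
        assert len(res.r_peaks) == len(res.beats)

    def test_determinism(self, clean_fixture):
        sig, _ = clean_fixture
        a, b = detect(sig), detect(sig)
        assert np.array_equal(a.r_peaks, b.r_peaks)
        assert a.to_dict() == b.to_dict()
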