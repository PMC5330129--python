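import itertools
import random

import pytest

from qrsgram import (
    DFADefinition,
    InputError,
    build_negative_peak_machine,
    build_positive_peak_machine,
    build_qrs_machine,
    build_rest_machine,
    matches_pattern,
    run_automaton,
    serialize_samples,
)
from qrsgram.automata import PATTERNS, build_machine

MACHINES = {
    "R": build_positive_peak_machine,
    "Qneg": build_negative_peak_machine,
    "rest": build_rest_machine,
    "QRS": build_qrs_machine,
}


class TestStructure:
    def test_positive_peak_shape(self):
        m = build_positive_peak_machine()
        assert m.states == frozenset(range(5))
        assert m.finals == frozenset({3, 4})
        assert m.start == 0

    def test_negative_peak_shape(self):
        m = build_negative_peak_machine()
        assert m.states == frozenset(range(6))
        assert m.finals == frozenset({4, 5})

    def test_rest_shape(self):
        m = build_rest_machine()
        assert m.states == frozenset(range(6))
        assert m.finals == frozenset({3})

    def test_qrs_shape(self):
        m = build_qrs_machine()
        assert m.states == frozenset(range(29))
        assert m.finals == frozenset({27, 28})

    def test_json_round_trip(self):
        for builder in MACHINES.values():
            m = builder()
            assert DFADefinition.from_json(m.to_json()) == m


class TestAcceptanceExamples:
    @pytest.mark.parametrize(
        "pid, text, expected",
        [
            ("R", "0.5", True),
            ("R", "1", True),
            ("R", "0.05", False),
            ("R", "0.30.4", True),   # two concatenated peak samples
            ("R", "11", True),
            ("R", "", False),
            ("Qneg", "-0.30", True),
            ("Qneg", "-1", True),
            ("Qneg", "0.30", False),
            ("rest", "0.00", True),
            ("rest", "-0.05", True),
            ("rest", "0.5", False),
            ("rest", "0.00.01", True),  # repetition of rest samples
            ("QRS", "", False),
        ],
    )
    def test_machine_and_regex_agree_on_examples(self, pid, text, expected):
        assert run_automaton(MACHINES[pid](), text).accepted is expected
        assert matches_pattern(pid, text) is expected

    def test_full_complex_forms(self):
        m = build_qrs_machine()
        full = serialize_samples([-0.3, 0.02, 0.9, 0.01, -0.4])
        bare = serialize_samples([0.9, -0.4])
        r_only = serialize_samples([0.9])
        assert run_automaton(m, full).accepted
        assert run_automaton(m, bare).accepted
        assert not run_automaton(m, r_only).accepted  # S is mandatory
        rest_no_q = serialize_samples([0.05, 0.9, -0.4])  # rest before R, Q absent
        assert run_automaton(m, rest_no_q).accepted

    def test_symbol_outside_alphabet_is_an_error(self):
        with pytest.raises(InputError):
            run_automaton(build_positive_peak_machine(), "0.x")

    def test_unknown_pattern_rejected(self):
        with pytest.raises(InputError):
            matches_pattern("T", "0.5")
        with pytest.raises(InputError):
            build_machine("T")


class TestEquivalence:
    @pytest.mark.parametrize("pid", sorted(MACHINES))
    def test_language_equals_regex_on_random_strings(self, pid):
        """Machine acceptance equals the regular expression on 10^4 random
        strings over the alphabet (length <= 12)."""
        m = MACHINES[pid]()
        rng = random.Random(20_000 + len(pid))
        for _ in range(10_000):
            s = "".join(rng.choice("0123456789-.") for _ in range(rng.randint(0, 12)))
            assert run_automaton(m, s).accepted == matches_pattern(pid, s), repr(s)

    @pytest.mark.parametrize("pid", sorted(MACHINES))
    def test_language_equals_regex_on_short_exhaustive(self, pid):
        m = MACHINES[pid]()
        for n in range(0, 4):
            for tup in itertools.product("01-.", repeat=n):
                s = "".join(tup)
                assert run_automaton(m, s).accepted == matches_pattern(pid, s), repr(s)

    def test_deterministic_outcome(self):
        m = build_qrs_machine()
        s = serialize_samples([-0.2, 0.9, -0.5])
        results = {run_automaton(m, s) for _ in range(5)}
        assert len(results) == 1

    def test_qrs_decomposition_oracle(self):
        """QRS acceptance iff the string splits into five consecutive parts —
        optional Q peaks, optional rest, mandatory R peaks, optional rest,
        mandatory S peaks — found by brute-force segmentation."""

        def decomposes(s: str) -> bool:
            n = len(s)
            cuts = [
                (a, b, c, d)
                for a in range(n + 1)
                for b in range(a, n + 1)
                for c in range(b + 1, n + 1)
                for d in range(c, n + 1)
            ]
            for a, b, c, d in cuts:
                q, r1, r, r2, sn = s[:a], s[a:b], s[b:c], s[c:d], s[d:]
                if (
                    (not q or matches_pattern("Qneg", q))
                    and (not r1 or matches_pattern("rest", r1))
                    and matches_pattern("R", r)
                    and (not r2 or matches_pattern("rest", r2))
                    and sn
                    and matches_pattern("Sneg", sn)
                ):
                    return True
            return False

        m = build_qrs_machine()
        rng = random.Random(7)
        pool = [-1.0, -0.4, -0.15, -0.05, 0.0, 0.05, 0.3, 0.9, 1.0]
        for _ in range(60):
            seq = [rng.choice(pool) for _ in range(rng.randint(1, 4))]
            s = serialize_samples(seq)
            assert run_automaton(m, s).accepted == decomposes(s), s

    def test_longest_prefix_mode(self):
        m = build_positive_peak_machine()
        res = run_automaton(m, "0.5-")
        assert not res.accepted
        assert res.consumed == 3  # "0.5" is the longest accepted prefix
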