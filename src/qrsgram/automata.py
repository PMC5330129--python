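"""Finite automata over serialized amplitude strings.

Four machines recognize the lexical building blocks of a beat:

- positive peak  ``R    = (0.[1-9][0-9]*|1)+``
- negative peak  ``Q/S  = (-0.[1-9][0-9]*|-1)+``
- rest phase     ``rest = (-?0.0[0-9]*)+``
- full complex   ``QRS  = {Q}?{rest}?{R}{rest}?{S}``

The transition tables carry epsilon-moves (realizing the ``+`` repetitions
and the optional parts), so the machines are epsilon-NFAs executed by
epsilon-closure subset simulation; for a fixed machine and input the outcome
is fully deterministic.  Each machine's contract is that its language equals
the regular expression above, and :func:`matches_pattern` (backed by the
``re`` engine) is kept as an independent oracle for exactly that equivalence.

Two transitions in the composite QRS table are easy to lose when tabulating
it by hand and are essential to the regex contract (see docs/methods.md):
the digit loop on the R-section state 15, and an epsilon entry into the
leading rest section so a rest phase may precede R when Q is absent.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping

from .errors import InputError

__all__ = [
    "EPSILON",
    "DFADefinition",
    "MatchResult",
    "run_automaton",
    "build_positive_peak_machine",
    "build_negative_peak_machine",
    "build_rest_machine",
    "build_qrs_machine",
    "matches_pattern",
    "PATTERNS",
]

EPSILON = "ε"

_DIGITS = "0123456789"
_NONZERO = "123456789"


@dataclass(frozen=True)
class DFADefinition:
    """The quadruple (Q, delta, q0, F) over the amplitude alphabet.

    ``transitions`` maps (state, symbol-or-epsilon) to the set of successor
    states; epsilon entries make the machine an epsilon-NFA in general.
    """

    states: frozenset[int]
    alphabet: frozenset[str]
    transitions: Mapping[tuple[int, str], frozenset[int]]
    start: int
    finals: frozenset[int]

    def __post_init__(self) -> None:
        if self.start not in self.states:
            raise InputError(f"start state {self.start} not in state set")
        if not self.finals <= self.states:
            raise InputError("final states must be a subset of the state set")
        for (src, sym), dsts in self.transitions.items():
            if src not in self.states or not dsts <= self.states:
                raise InputError(f"transition ({src},{sym!r}) leaves the state set")
            if sym != EPSILON and sym not in self.alphabet:
                raise InputError(f"transition symbol {sym!r} outside the alphabet")

    # -- JSON round-trip (inspection / documentation) -----------------------

    def to_json(self) -> str:
        payload = {
            "states": sorted(self.states),
            "alphabet": sorted(self.alphabet),
            "start": self.start,
            "finals": sorted(self.finals),
            "transitions": [
                {"from": src, "symbol": sym, "to": sorted(dsts)}
                for (src, sym), dsts in sorted(
                    self.transitions.items(), key=lambda kv: (kv[0][0], kv[0][1])
                )
            ],
        }
        return json.dumps(payload, ensure_ascii=False, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DFADefinition":
        d = json.loads(text)
        trans: dict[tuple[int, str], frozenset[int]] = {}
        for t in d["transitions"]:
            trans[(t["from"], t["symbol"])] = frozenset(t["to"])
        return cls(
            states=frozenset(d["states"]),
            alphabet=frozenset(d["alphabet"]),
            transitions=trans,
            start=d["start"],
            finals=frozenset(d["finals"]),
        )


@dataclass(frozen=True)
class MatchResult:
    """Outcome of running a machine: full-string acceptance plus the length
    of the longest accepted prefix (diagnostic longest-prefix mode)."""

    accepted: bool
    consumed: int


def _closure(machine: DFADefinition, states: frozenset[int]) -> frozenset[int]:
    stack = list(states)
    seen = set(states)
    while stack:
        q = stack.pop()
        for nxt in machine.transitions.get((q, EPSILON), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(seen)


def run_automaton(machine: DFADefinition, text: str) -> MatchResult:
    """Epsilon-closure subset simulation of ``machine`` on ``text``.

    Accepts iff some path consumes the whole input and ends in a final state.
    ``consumed`` records the longest prefix that would be accepted on its own.

    Raises
    ------
    InputError
        On a symbol outside the machine's alphabet (a serialization bug
        upstream, never a rejection).
    """
    current = _closure(machine, frozenset({machine.start}))
    longest = 0 if current & machine.finals else -1
    for i, sym in enumerate(text):
        if sym not in machine.alphabet:
            raise InputError(f"symbol {sym!r} at position {i} outside alphabet")
        nxt: set[int] = set()
        for q in current:
            nxt.update(machine.transitions.get((q, sym), ()))
        current = _closure(machine, frozenset(nxt))
        if not current:
            return MatchResult(accepted=False, consumed=max(longest, 0))
        if current & machine.finals:
            longest = i + 1
    return MatchResult(accepted=bool(current & machine.finals), consumed=max(longest, 0))


def _expand(table: list[tuple[int, str, int]]) -> dict[tuple[int, str], frozenset[int]]:
    """Expand digit-range shorthands and merge duplicate (state, symbol) rows."""
    out: dict[tuple[int, str], set[int]] = {}
    for src, sym, dst in table:
        if sym == "0-9":
            syms = _DIGITS
        elif sym == "1-9":
            syms = _NONZERO
        else:
            syms = sym
        for s in syms if sym in ("0-9", "1-9") else [sym]:
            out.setdefault((src, s), set()).add(dst)
    return {k: frozenset(v) for k, v in out.items()}


def _machine(table, states, start, finals) -> DFADefinition:
    return DFADefinition(
        states=frozenset(states),
        alphabet=frozenset("0123456789-."),
        transitions=_expand(table),
        start=start,
        finals=frozenset(finals),
    )


def build_positive_peak_machine() -> DFADefinition:
    """Machine for a run of positive-peak samples, (0.[1-9][0-9]*|1)+."""
    table = [
        (0, "0", 1),
        (1, ".", 2),
        (2, "1-9", 3),
        (3, "0-9", 3),
        (3, EPSILON, 0),
        (0, "1", 4),
        (4, EPSILON, 0),
    ]
    return _machine(table, range(5), 0, {3, 4})


def build_negative_peak_machine() -> DFADefinition:
    """Machine for a run of negative-peak samples, (-0.[1-9][0-9]*|-1)+."""
    table = [
        (0, "-", 1),
        (1, "0", 2),
        (2, ".", 3),
        (3, "1-9", 4),
        (4, "0-9", 4),
        (4, EPSILON, 0),
        (1, "1", 5),
        (5, EPSILON, 0),
    ]
    return _machine(table, range(6), 0, {4, 5})


def build_rest_machine() -> DFADefinition:
    """Machine for a run of near-isoelectric samples, (-?0.0[0-9]*)+."""
    table = [
        (0, "0", 1),
        (1, ".", 2),
        (2, "0", 3),
        (3, "0-9", 3),
        (3, EPSILON, 0),
        (0, "-", 4),
        (4, "0", 5),
        (5, ".", 2),
    ]
    return _machine(table, range(6), 0, {3})


def build_qrs_machine() -> DFADefinition:
    """Machine for a whole complex, {Q}?{rest}?{R}{rest}?{S}.

    States 0-5 recognize the optional Q run, 6-11 the optional leading rest,
    12-16 the mandatory R run, 17-22 the optional second rest, 23-28 the
    mandatory S run.  Epsilon moves realize the repetitions and the optional
    sections.
    """
    table = [
        # Q section: (-0.[1-9][0-9]*|-1)+, optional
        (0, "-", 1),
        (1, "0", 2),
        (2, ".", 3),
        (3, "1-9", 4),
        (4, "0-9", 4),
        (4, EPSILON, 6),
        (1, "1", 5),
        (4, EPSILON, 0),
        (5, EPSILON, 6),
        (5, EPSILON, 0),
        # first rest section: (-?0.0[0-9]*)+, optional
        (6, "0", 7),
        (7, ".", 8),
        (8, "0", 9),
        (6, "-", 10),
        (10, "0", 11),
        (11, ".", 8),
        (9, "0-9", 9),
        (9, EPSILON, 6),
        (6, EPSILON, 12),
        (0, EPSILON, 12),
        (0, EPSILON, 6),  # required: rest may precede R with Q absent
        (9, EPSILON, 12),
        # R section: (0.[1-9][0-9]*|1)+, mandatory
        (12, "0", 13),
        (13, ".", 14),
        (14, "1-9", 15),
        (15, "0-9", 15),  # required: [0-9]* digit loop after the first nonzero
        (15, EPSILON, 17),
        (15, EPSILON, 12),
        (12, "1", 16),
        (16, EPSILON, 12),
        (16, EPSILON, 17),
        # second rest section, optional
        (17, "0", 18),
        (18, ".", 19),
        (19, "0", 20),
        (20, "0-9", 20),
        (17, "-", 21),
        (21, "0", 22),
        (22, ".", 19),
        (20, EPSILON, 17),
        (17, EPSILON, 23),
        (20, EPSILON, 23),
        # S section: (-0.[1-9][0-9]*|-1)+, mandatory
        (23, "-", 24),
        (24, "0", 25),
        (25, ".", 26),
        (26, "1-9", 27),
        (27, EPSILON, 23),
        (27, "0-9", 27),
        (24, "1", 28),
        (28, EPSILON, 23),
    ]
    return _machine(table, range(29), 0, {27, 28})


# -- regex oracle -----------------------------------------------------------

_R_UNIT = r"(?:0\.[1-9][0-9]*|1)"
_NEG_UNIT = r"(?:-0\.[1-9][0-9]*|-1)"
_REST_UNIT = r"(?:-?0\.0[0-9]*)"

#: the regular-expression definitions of each lexical pattern (anchored)
PATTERNS: dict[str, re.Pattern[str]] = {
    "R": re.compile(rf"{_R_UNIT}+"),
    "Qneg": re.compile(rf"{_NEG_UNIT}+"),
    "Sneg": re.compile(rf"{_NEG_UNIT}+"),
    "rest": re.compile(rf"{_REST_UNIT}+"),
    "QRS": re.compile(
        rf"(?:{_NEG_UNIT}+)?(?:{_REST_UNIT}+)?{_R_UNIT}+(?:{_REST_UNIT}+)?{_NEG_UNIT}+"
    ),
}


def matches_pattern(pattern_id: str, text: str) -> bool:
    """Anchored match of ``text`` against one of the lexical patterns.

    Serves as the independent oracle the machines are tested against.
    """
    if pattern_id not in PATTERNS:
        raise InputError(f"unknown pattern {pattern_id!r}; choose from {sorted(PATTERNS)}")
    return PATTERNS[pattern_id].fullmatch(text) is not None


def build_machine(pattern_id: str) -> DFADefinition:
    """The machine corresponding to a pattern id."""
    builders = {
        "R": build_positive_peak_machine,
        "Qneg": build_negative_peak_machine,
        "Sneg": build_negative_peak_machine,
        "rest": build_rest_machine,
        "QRS": build_qrs_machine,
    }
    if pattern_id not in builders:
        raise InputError(f"unknown pattern {pattern_id!r}; choose from {sorted(builders)}")
    return builders[pattern_id]()
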