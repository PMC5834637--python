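"""Ground-count protocol and census precision classes.

The field protocol counts each sub-colony division three times; the three
counts must agree within 5% of their mean, otherwise the division is split
and the halves re-counted, recursively.  A total accepted this way carries
the 'N1' precision label; automated UAV counts carry 'N2' and rough
photographic counts 'N4' (relative half-widths 5%, 10% and 50%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import ObserverModel, simulate_observer_count

__all__ = [
    "PrecisionClass",
    "CountSession",
    "N1", "N2", "N4",
    "assess_agreement",
    "classify_precision",
    "protocol_count",
]

AGREEMENT_TOLERANCE = 0.05      # each count within 5% of the triple's mean


@dataclass(frozen=True)
class PrecisionClass:
    """Census precision label with its relative half-width."""

    label: str
    half_width: float

    _TABLE = {"N1": 0.05, "N2": 0.10, "N4": 0.50}

    def __post_init__(self):
        if self._TABLE.get(self.label) != self.half_width:
            raise ValueError(
                f"invalid precision class {self.label}={self.half_width}; "
                f"allowed: {self._TABLE}"
            )

    @classmethod
    def from_label(cls, label: str) -> "PrecisionClass":
        return cls(label, cls._TABLE[label])


N1 = PrecisionClass("N1", 0.05)
N2 = PrecisionClass("N2", 0.10)
N4 = PrecisionClass("N4", 0.50)


@dataclass(frozen=True)
class CountSession:
    """One counted division: its three counts and the protocol outcome."""

    unit_id: str
    counts: tuple[int, int, int]
    accepted: bool
    depth: int
    estimate: int
    unresolved: bool = False


def assess_agreement(counts) -> bool:
    """True iff each of three counts is within 5% of the triple's mean.

    The boundary is inclusive and an all-zero triple is accepted (every
    deviation is 0).
    """
    c = list(counts)
    if len(c) != 3:
        raise ValueError("exactly three counts required")
    if any(x < 0 for x in c):
        raise ValueError("counts must be non-negative")
    mean = sum(c) / 3.0
    return all(abs(x - mean) <= AGREEMENT_TOLERANCE * mean for x in c)


def classify_precision(relative_half_width: float) -> PrecisionClass:
    """Smallest N-class whose half-width bounds the given relative error."""
    if relative_half_width < 0:
        raise ValueError("relative half-width must be non-negative")
    if relative_half_width <= 0.05:
        return N1
    if relative_half_width <= 0.10:
        return N2
    if relative_half_width <= 0.50:
        return N4
    raise ValueError(
        f"relative half-width {relative_half_width} exceeds the N4 bound (0.50)"
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def protocol_count(
    true_units,
    observer: ObserverModel,
    max_depth: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[int, list[CountSession]]:
    """Simulate the triple-count / subdivide-until-agreement protocol.

    For each section (its true nest count given in ``true_units``) three
    observer counts are drawn.  If they agree within 5% of their mean, the
    section's estimate is that mean rounded half-up.  Otherwise the section
    is split into two halves (nests allocated binomially) and each half is
    counted recursively.  Sections still disagreeing at ``max_depth`` are
    flagged unresolved: their mean estimate is reported but they disqualify
    the total from an N1 label.

    Returns (total, sessions log).  With a noiseless observer (cv=0,
    bias=1) the total equals the true total exactly and no subdivision
    occurs.
    """
    rng = np.random.default_rng(seed)
    sessions: list[CountSession] = []

    def count_section(true_n: int, unit_id: str, depth: int) -> int:
        triple = tuple(
            simulate_observer_count(true_n, observer, rng) for _ in range(3)
        )
        ok = assess_agreement(triple)
        est = _round_half_up(sum(triple) / 3.0)
        if ok:
            sessions.append(CountSession(unit_id, triple, True, depth, est))
            return est
        if depth >= max_depth:
            sessions.append(
                CountSession(unit_id, triple, False, depth, est, unresolved=True)
            )
            return est
        sessions.append(CountSession(unit_id, triple, False, depth, est))
        left = int(rng.binomial(true_n, 0.5))
        right = true_n - left
        return (count_section(left, unit_id + ".a", depth + 1)
                + count_section(right, unit_id + ".b", depth + 1))

    total = 0
    for i, true_n in enumerate(true_units):
        if true_n < 0:
            raise ValueError("section sizes must be non-negative")
        total += count_section(int(true_n), f"u{i}", 0)
    return total, sessions
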