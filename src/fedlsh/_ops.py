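"""Scalar-multiplication (SM) accounting.

The protocol's cost unit is one real-number multiplication; additions are
ignored.  Core routines report their exact SM cost through a module-level
counter so that end-to-end runs can tabulate per-phase costs without the
counting machinery leaking into the numerical code paths.

Counting is opt-in: with no active counter every ``record`` call is a no-op.
"""

from __future__ import annotations

import contextlib
from collections import defaultdict
from dataclasses import dataclass, field


@dataclass
class OpCounter:
    """Accumulates scalar-multiplication counts keyed by protocol phase."""

    counts: dict[str, int] = field(default_factory=lambda: defaultdict(int))

    def add(self, phase: str, n: int) -> None:
        self.counts[phase] += int(n)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


_active_counter: OpCounter | None = None
_active_phase: str = "unphased"


@contextlib.contextmanager
def counting(counter: OpCounter):
    """Activate *counter* for the duration of the block."""
    global _active_counter
    prev = _active_counter
    _active_counter = counter
    try:
        yield counter
    finally:
        _active_counter = prev


@contextlib.contextmanager
def phase(name: str):
    """Attribute SM counts inside the block to phase *name*."""
    global _active_phase
    prev = _active_phase
    _active_phase = name
    try:
        yield
    finally:
        _active_phase = prev


def record(n: int) -> None:
    """Charge *n* scalar multiplications to the active counter, if any."""
    if _active_counter is not None:
        _active_counter.add(_active_phase, n)
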