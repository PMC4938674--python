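"""Copy-number state classification shared by depth- and ddPCR-based genotyping.

A measured copy number maps to an integer state in {0, 1, 2} using the
empirical ranges established for droplet-digital-PCR genotyping: two copies
1.7-2.3, one copy 0.7-1.3, and zero copies below ``zero_max`` (default 0.3,
symmetric with the gap below the one-copy range).  Values outside all ranges,
and undefined (NaN) values, are ambiguous (``None``).  One vocabulary serves
both modalities so a sequencing-derived and a ddPCR-derived genotype can never
diverge in semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AMBIGUOUS = None


@dataclass(frozen=True)
class StateRanges:
    """Inclusive copy-number ranges for the integer copy states."""

    two: tuple[float, float] = (1.7, 2.3)
    one: tuple[float, float] = (0.7, 1.3)
    zero_max: float = 0.3

    def __post_init__(self) -> None:
        if not (self.zero_max <= self.one[0] <= self.one[1] <= self.two[0] <= self.two[1]):
            raise ValueError("state ranges must be ordered and non-overlapping")


DEFAULT_RANGES = StateRanges()


def classify_cn(copy_number: float, ranges: StateRanges = DEFAULT_RANGES) -> int | None:
    """Map a copy-number estimate to a state in {0, 1, 2} or ambiguous (None).

    Total on [0, inf) and idempotent; boundaries are inclusive.  NaN (an
    undefined copy number, e.g. where the control lacks signal) is ambiguous.
    """
    if copy_number is None or math.isnan(copy_number):
        return AMBIGUOUS
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    if copy_number < ranges.zero_max:
        return 0
    if ranges.one[0] <= copy_number <= ranges.one[1]:
        return 1
    if ranges.two[0] <= copy_number <= ranges.two[1]:
        return 2
    return AMBIGUOUS
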