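"""Six-genotype deletion classification from region copy numbers.

With two deletion alleles, the smaller nested in the distal part of the
larger, the copy states of just two segments determine the diploid genotype
exhaustively:

    ==================  =============  =============
    genotype            Del1-unique    shared (Del2)
    ==================  =============  =============
    WT/WT               2              2
    Del1/WT             1              1
    Del2/WT             2              1
    Del1/Del1           0              0
    Del1/Del2           1              0
    Del2/Del2           2              0
    ==================  =============  =============

Any other state pair (states violating the nesting structure, or ambiguous
copy numbers) is reported as ``unresolved`` — a value, not an error.  The
same classifier serves sequencing-derived and ddPCR-derived copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .states import DEFAULT_RANGES, StateRanges, classify_cn


class Genotype(str, Enum):
    DEL1_DEL1 = "Del1/Del1"
    DEL1_DEL2 = "Del1/Del2"
    DEL2_DEL2 = "Del2/Del2"
    DEL1_WT = "Del1/WT"
    DEL2_WT = "Del2/WT"
    WT_WT = "WT/WT"
    UNRESOLVED = "unresolved"


AFFECTED = frozenset({Genotype.DEL1_DEL1, Genotype.DEL1_DEL2, Genotype.DEL2_DEL2})
CARRIERS = frozenset({Genotype.DEL1_WT, Genotype.DEL2_WT})

_STATE_TABLE: dict[tuple[int, int], Genotype] = {
    (2, 2): Genotype.WT_WT,
    (1, 1): Genotype.DEL1_WT,
    (2, 1): Genotype.DEL2_WT,
    (0, 0): Genotype.DEL1_DEL1,
    (1, 0): Genotype.DEL1_DEL2,
    (2, 0): Genotype.DEL2_DEL2,
}


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    genotype: Genotype
    unique_region_state: int | None
    shared_region_state: int | None
    unique_region_cn: float
    shared_region_cn: float
    affected: bool
    confidence: str = "high"


_PAIR_TO_GENOTYPE: dict[tuple[str, str], Genotype] = {
    ("Del1", "Del1"): Genotype.DEL1_DEL1,
    ("Del1", "Del2"): Genotype.DEL1_DEL2,
    ("Del2", "Del2"): Genotype.DEL2_DEL2,
    ("Del1", "WT"): Genotype.DEL1_WT,
    ("Del2", "WT"): Genotype.DEL2_WT,
    ("WT", "WT"): Genotype.WT_WT,
}


def genotype_of_pair(pair: tuple[str, str]) -> Genotype:
    """True genotype of an (unordered) haplotype pair."""
    return _PAIR_TO_GENOTYPE[tuple(sorted(pair))]


def genotype_from_states(unique_state: int | None, shared_state: int | None) -> Genotype:
    """Look up the genotype for a (Del1-unique, shared) copy-state pair."""
    return _STATE_TABLE.get((unique_state, shared_state), Genotype.UNRESOLVED)


def classify_genotype(
    unique_region_cn: float,
    shared_region_cn: float,
    ranges: StateRanges = DEFAULT_RANGES,
    sample_id: str = "",
    n_unique_windows: int | None = None,
    n_shared_windows: int | None = None,
    min_confident_windows: int = 3,
) -> GenotypeCall:
    """Classify a sample's deletion genotype from its two region copy numbers.

    A pure function of its inputs.  When window counts are supplied, calls
    resting on fewer than ``min_confident_windows`` windows in either region
    are flagged ``confidence="low"`` (a Del2/Del2 diagnosis, for example,
    hinges entirely on the shared region staying at zero while the unique
    region stays diploid).
    """
    us = classify_cn(unique_region_cn, ranges)
    ss = classify_cn(shared_region_cn, ranges)
    gt = genotype_from_states(us, ss)
    confidence = "high"
    for nw in (n_unique_windows, n_shared_windows):
        if nw is not None and nw < min_confident_windows:
            confidence = "low"
    if gt is Genotype.UNRESOLVED:
        confidence = "low"
    return GenotypeCall(
        sample_id=sample_id,
        genotype=gt,
        unique_region_state=us,
        shared_region_state=ss,
        unique_region_cn=float(unique_region_cn),
        shared_region_cn=float(shared_region_cn),
        affected=gt in AFFECTED,
        confidence=confidence,
    )


def summarize_region_cn(
    starts: np.ndarray, ends: np.ndarray, cns: np.ndarray, region: tuple[int, int]
) -> tuple[float, int]:
    """Mean copy number over windows fully contained in ``region``.

    Returns ``(mean_cn, n_windows)``; NaN windows are excluded from the mean.
    A region smaller than a single window has no fully contained window; it
    falls back to the windows overlapping it.  Raises only when no window
    overlaps the region at all.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    cns = np.asarray(cns, dtype=float)
    lo, hi = region
    inside = (starts >= lo) & (ends <= hi)
    if not inside.any():
        inside = (starts < hi) & (ends > lo)
    if not inside.any():
        raise ValueError(f"no window overlapping region [{lo}, {hi})")
    vals = cns[inside]
    n = int(inside.sum())
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), n
    return float(vals.mean()), n


def genotype_cohort(
    window_table: pd.DataFrame,
    sample_ids: list[str],
    del1_unique: tuple[int, int],
    shared: tuple[int, int],
    ranges: StateRanges = DEFAULT_RANGES,
) -> pd.DataFrame:
    """Genotype every sample from a windowed copy-number table.

    ``window_table`` is the output of :func:`shoxdel.windows.build_window_table`
    (one ``cn_<id>`` column per sample).
    """
    starts = window_table["start"].to_numpy()
    ends = window_table["end"].to_numpy()
    rows = []
    for sid in sample_ids:
        cns = window_table[f"cn_{sid}"].to_numpy()
        ucn, un = summarize_region_cn(starts, ends, cns, del1_unique)
        scn, sn = summarize_region_cn(starts, ends, cns, shared)
        call = classify_genotype(
            ucn, scn, ranges, sample_id=sid, n_unique_windows=un, n_shared_windows=sn
        )
        rows.append(
            {
                "sample_id": sid,
                "genotype": call.genotype.value,
                "unique_cn": call.unique_region_cn,
                "shared_cn": call.shared_region_cn,
                "affected": call.affected,
                "confidence": call.confidence,
            }
        )
    return pd.DataFrame(rows)
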