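"""Deletion segment calling, soft-clip breakpoint refinement, and tandem
repeat annotation.

Window copy numbers are classified into copy states (0/1/2/ambiguous) and
consecutive windows of the same non-diploid state are merged into deletion
calls, bridging short runs of ambiguous windows.  Breakpoints are refined by
scanning for windows where the soft-clipped read fraction exceeds the genome
background (clipped read ends pile up at structural-variant junctions), and
breakpoint flanks are annotated with perfect tandem motif runs (long TGGA
microsatellite runs flank both outer breakpoints of the real deletions and
are the likely mediators of the rearrangement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .states import DEFAULT_RANGES, StateRanges, classify_cn


@dataclass(frozen=True)
class DeletionCall:
    """A maximal run of windows in one deletion copy state."""

    start: int
    end: int
    state: int  # 0 or 1
    mean_cn: float
    n_windows: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call interval must be non-empty")


def call_segments(
    starts: np.ndarray,
    ends: np.ndarray,
    cns: np.ndarray,
    ranges: StateRanges = DEFAULT_RANGES,
    max_gap_windows: int = 2,
    min_windows: int = 3,
    sample_id: str = "",
) -> list[DeletionCall]:
    """Merge same-state deleted windows into segment calls.

    Each window is classified to a copy state via :func:`classify_cn`.  A
    segment collects consecutive windows of one state s in {0, 1}; up to
    ``max_gap_windows`` consecutive ambiguous/undefined windows may be
    bridged, but any window with a *different* definite state (including
    diploid) terminates the segment.  Segments supported by fewer than
    ``min_windows`` state-s windows are dropped.  The reported interval runs
    from the first to the last state-s window (bridged ambiguous tails are
    not included), with the mean copy number taken over the state-s windows.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    cns = np.asarray(cns, dtype=float)
    if not (len(starts) == len(ends) == len(cns)):
        raise ValueError("starts/ends/cns length mismatch")
    if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
        raise ValueError("windows must be sorted and non-overlapping")

    states = [classify_cn(c, ranges) for c in cns]
    calls: list[DeletionCall] = []
    open_state: int | None = None
    member_idx: list[int] = []
    gap = 0

    def flush() -> None:
        nonlocal open_state, member_idx, gap
        if open_state is not None and len(member_idx) >= min_windows:
            calls.append(
                DeletionCall(
                    start=int(starts[member_idx[0]]),
                    end=int(ends[member_idx[-1]]),
                    state=open_state,
                    mean_cn=float(np.mean(cns[member_idx])),
                    n_windows=len(member_idx),
                    sample_id=sample_id,
                )
            )
        open_state, member_idx, gap = None, [], 0

    for i, s in enumerate(states):
        if s in (0, 1):
            if open_state is None:
                open_state, member_idx, gap = s, [i], 0
            elif s == open_state and gap <= max_gap_windows:
                member_idx.append(i)
                gap = 0
            else:
                flush()
                open_state, member_idx, gap = s, [i], 0
        elif s is None:
            gap += 1
            if open_state is not None and gap > max_gap_windows:
                flush()
        else:  # definite diploid window terminates any open segment
            flush()
    flush()
    return calls


@dataclass(frozen=True)
class ClipPeak:
    """A locally maximal window of soft-clip enrichment."""

    position: int  # window centre
    start: int
    end: int
    clip_fraction: float
    p_value: float


def softclip_enrichment(
    clips: np.ndarray,
    depth: np.ndarray,
    background_clip_rate: float = 0.01,
    window_bp: int = 1_000,
    step_bp: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[ClipPeak]]:
    """Scan for windows where soft-clipping exceeds the background rate.

    In sliding windows (default step: half a window) the clipped read count is
    tested against Binomial(total depth, ``background_clip_rate``) with a
    one-sided upper tail; significance is Bonferroni-corrected over the number
    of windows.  Peaks are the best window within each contiguous run of
    significant windows.  Zero-depth windows are never significant; a track
    with no depth anywhere yields no peaks and no error.
    """
    clips = np.asarray(clips)
    depth = np.asarray(depth)
    if clips.shape != depth.shape:
        raise ValueError("clips and depth must have equal length")
    if np.any(clips > depth):
        raise ValueError("clip count cannot exceed depth")
    if not (0 < background_clip_rate < 1):
        raise ValueError("background_clip_rate must be in (0, 1)")
    step = step_bp or max(1, window_bp // 2)
    starts = np.arange(0, max(1, len(depth) - window_bp + step), step)
    ends = np.minimum(starts + window_bp, len(depth))
    cdep = np.concatenate([[0], np.cumsum(depth)])
    cclip = np.concatenate([[0], np.cumsum(clips)])
    n = cdep[ends] - cdep[starts]
    k = cclip[ends] - cclip[starts]
    pvals = np.where(n > 0, stats.binom.sf(k - 1, np.maximum(n, 1), background_clip_rate), 1.0)
    table = pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "depth": n,
            "clips": k,
            "clip_fraction": np.divide(k, n, out=np.zeros_like(pvals), where=n > 0),
            "p_value": pvals,
        }
    )
    threshold = alpha / len(starts)
    sig = pvals <= threshold
    peaks: list[ClipPeak] = []
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            best = i + int(np.argmin(pvals[i : j + 1]))
            peaks.append(
                ClipPeak(
                    position=int((starts[best] + ends[best]) // 2),
                    start=int(starts[best]),
                    end=int(ends[best]),
                    clip_fraction=float(table["clip_fraction"][best]),
                    p_value=float(pvals[best]),
                )
            )
            i = j + 1
        else:
            i += 1
    return table, peaks


def find_motif_runs(
    sequence: str, motif: str, min_run_length_bp: int = 1_000
) -> list[tuple[int, int, int]]:
    """Maximal perfect tandem runs of ``motif`` with span >= ``min_run_length_bp``.

    Runs are found greedily left to right and do not overlap: at each
    position the longest tandem extension of whole motif copies is taken,
    reported as ``(start, end, copies)`` if its span reaches the minimum, and
    scanning resumes after it.  The motif is matched in the given orientation
    only (no reverse complement).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(sequence)
    while i + m <= n:
        if sequence[i : i + m] == motif:
            k = 1
            while sequence[i + k * m : i + (k + 1) * m] == motif:
                k += 1
            if k * m >= min_run_length_bp:
                runs.append((i, i + k * m, k))
            i += k * m
        else:
            i += 1
    return runs
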