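"""Windowed read-depth normalization and copy-number estimation.

Depth is summarized as the mean per-base depth in fixed windows (1 kb by
default), normalized by each sample's genome-wide background mean, and turned
into a copy number relative to the control pool:

    normalized = window mean depth / genome background mean
    copy number = 2 x (case normalized / pool normalized)

The pool's own normalized depth is additionally expressed as a Z-score over
all windows, which flags regions where the pool itself deviates from the
genome-wide average (assembly artifacts, collapsed repeats).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import DepthTrack

DEFAULT_WINDOW = 1_000
DEFAULT_MIN_POOL_NORMALIZED = 0.2


def window_bounds(length: int, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open window boundaries tiling [0, length); the last may be short."""
    starts = np.arange(0, length, window_size)
    ends = np.minimum(starts + window_size, length)
    return starts, ends


def window_mean_depth(track: DepthTrack | np.ndarray, window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Mean per-position depth in consecutive half-open windows."""
    depth = track.depth if isinstance(track, DepthTrack) else np.asarray(track)
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if depth.size == 0:
        raise ValueError("empty depth track")
    starts, ends = window_bounds(depth.size, window_size)
    sums = np.add.reduceat(depth.astype(float), starts)
    return sums / (ends - starts)


def normalize(window_means: np.ndarray, background_mean: float) -> np.ndarray:
    """Window means divided by the sample's genome-wide background mean depth."""
    if background_mean <= 0:
        raise ValueError("background_mean must be > 0")
    return np.asarray(window_means, dtype=float) / background_mean


def copy_number(
    case_normalized: np.ndarray,
    pool_normalized: np.ndarray,
    min_pool_normalized: float = DEFAULT_MIN_POOL_NORMALIZED,
) -> np.ndarray:
    """Per-window copy number 2 x case/pool; NaN where the pool lacks signal.

    Windows where the pool's normalized depth falls below
    ``min_pool_normalized`` carry no usable reference signal; their copy
    number is undefined (NaN) rather than inflated.
    """
    case_normalized = np.asarray(case_normalized, dtype=float)
    pool_normalized = np.asarray(pool_normalized, dtype=float)
    if np.any(case_normalized < 0) or np.any(pool_normalized < 0):
        raise ValueError("normalized depths must be >= 0")
    ok = pool_normalized >= min_pool_normalized
    out = np.full(case_normalized.shape, np.nan)
    np.divide(2.0 * case_normalized, pool_normalized, out=out, where=ok)
    return out


def pool_zscore(pool_normalized: np.ndarray) -> np.ndarray:
    """Z-score of the pool's normalized depth against its all-window moments."""
    x = np.asarray(pool_normalized, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two windows for a Z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation across windows (degenerate input)")
    return (x - x.mean()) / sd


def build_window_table(
    tracks: Mapping[str, DepthTrack],
    pool_id: str,
    window_size: int = DEFAULT_WINDOW,
    min_pool_normalized: float = DEFAULT_MIN_POOL_NORMALIZED,
    chrom: str = "region",
) -> pd.DataFrame:
    """Windowed summary table for a cohort of depth tracks.

    Columns: ``chrom, start, end``; per sample ``raw_<id>`` and ``norm_<id>``;
    per non-pool sample ``cn_<id>`` (copy number relative to the pool);
    ``pool_z`` for the pool's Z-score.
    """
    if pool_id not in tracks:
        raise ValueError(f"pool sample {pool_id!r} not among tracks")
    lengths = {len(t) for t in tracks.values()}
    if len(lengths) != 1:
        raise ValueError("all tracks must cover the same region length")
    starts, ends = window_bounds(lengths.pop(), window_size)
    out = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
    norms = {}
    for sid, track in tracks.items():
        means = window_mean_depth(track, window_size)
        norms[sid] = normalize(means, track.background_mean)
        out[f"raw_{sid}"] = means
        out[f"norm_{sid}"] = norms[sid]
    for sid in tracks:
        if sid != pool_id:
            out[f"cn_{sid}"] = copy_number(norms[sid], norms[pool_id], min_pool_normalized)
    out["pool_z"] = pool_zscore(norms[pool_id])
    return out
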