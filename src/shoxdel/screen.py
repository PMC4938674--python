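"""Case-versus-pool fixed allele-frequency-difference screen.

For a recessive disorder, every case should be homozygous (or hemizygous) for
the causal haplotype, so the first-pass screen keeps SNP sites where every
covered case is fixed for the alternate allele while the control pool carries
only reference reads — an allele-frequency difference of 1.  Cases with no
reads at a site do not disqualify it: a homozygous deletion produces exactly
that pattern, and it was the mixture of fixed-alt and zero-depth cases that
pointed to the deletions in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def site_allele_frequency(ref_count: int, alt_count: int) -> float:
    """Alternate-allele read frequency at one site; NaN when depth is zero."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be >= 0")
    depth = ref_count + alt_count
    if depth == 0:
        return math.nan
    return alt_count / depth


@dataclass(frozen=True)
class ScreenResult:
    position: int
    case_alt_frequency: float  # pooled over covered cases; NaN if none covered
    pool_alt_frequency: float
    n_cases_covered: int
    passes: bool


def fixed_difference_screen(
    table: pd.DataFrame,
    case_ids: Sequence[str],
    pool_id: str,
    min_covered_cases: int = 1,
    min_case_depth: int = 1,
    max_discordant_reads: int = 0,
) -> pd.DataFrame:
    """Screen a SNP count table for case/pool fixed differences.

    A site passes iff (i) the pool has depth >= 1 and at most
    ``max_discordant_reads`` alternate reads (default 0: reference-fixed),
    (ii) every case covered at >= ``min_case_depth`` has at most
    ``max_discordant_reads`` reference reads (alt-fixed), and (iii) at least
    ``min_covered_cases`` cases are covered.  Uncovered cases are ignored.

    Parameters
    ----------
    table:
        Long-format count table with columns
        ``position, sample_id, ref_count, alt_count``.
    max_discordant_reads:
        Error tolerance for noisy inputs; 0 demands exact fixation.

    Returns
    -------
    One row per position with case/pool frequencies, the number of covered
    cases and the pass flag, sorted by position.
    """
    if len(case_ids) == 0:
        raise ValueError("need at least one case")
    known = set(table["sample_id"].unique())
    missing = [s for s in [*case_ids, pool_id] if s not in known]
    if missing:
        raise ValueError(f"sample ids not present in table: {missing}")

    ref = table.pivot_table(index="position", columns="sample_id", values="ref_count", aggfunc="sum")
    alt = table.pivot_table(index="position", columns="sample_id", values="alt_count", aggfunc="sum")
    ref = ref.fillna(0).astype(int)
    alt = alt.fillna(0).astype(int)

    case_ids = list(case_ids)
    cref = ref[case_ids].to_numpy()
    calt = alt[case_ids].to_numpy()
    pref = ref[pool_id].to_numpy()
    palt = alt[pool_id].to_numpy()

    covered = (cref + calt) >= min_case_depth
    n_covered = covered.sum(axis=1)
    case_fixed_alt = np.where(covered, cref <= max_discordant_reads, True).all(axis=1)
    pool_depth = pref + palt
    pool_fixed_ref = (pool_depth >= 1) & (palt <= max_discordant_reads)
    passes = pool_fixed_ref & case_fixed_alt & (n_covered >= min_covered_cases)

    cov_alt = np.where(covered, calt, 0).sum(axis=1)
    cov_depth = np.where(covered, cref + calt, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        case_af = np.where(cov_depth > 0, cov_alt / np.maximum(cov_depth, 1), np.nan)
        pool_af = np.where(pool_depth > 0, palt / np.maximum(pool_depth, 1), np.nan)

    return pd.DataFrame(
        {
            "position": ref.index.to_numpy(),
            "case_alt_frequency": case_af,
            "pool_alt_frequency": pool_af,
            "n_cases_covered": n_covered,
            "passes": passes,
        }
    ).sort_values("position", ignore_index=True)
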