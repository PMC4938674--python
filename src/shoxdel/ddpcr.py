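"""Droplet digital PCR copy-number quantification and genotyping.

A ddPCR reaction partitions template into ~15-20k droplets; template
molecules land in droplets as a Poisson process, so the concentration in
copies per droplet is recovered from the positive fraction f as

    lambda = -ln(1 - f)

and the copy number of a target locus is the lambda ratio against a two-copy
reference assay, scaled by the reference copy number (2).  Copy numbers are
classified to integer states with the empirical ranges (two copies 1.7-2.3,
one copy 0.7-1.3); multiple assays per deleted region are combined by
majority vote, and region states are mapped to the six deletion genotypes by
the shared classifier in :mod:`shoxdel.genotype`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genotype import AFFECTED, CARRIERS, Genotype, GenotypeCall, genotype_from_states
from .states import AMBIGUOUS, DEFAULT_RANGES, StateRanges, classify_cn

__all__ = [
    "poisson_lambda",
    "copy_number_ratio",
    "classify_cn",
    "multi_assay_consensus",
    "CopyNumberEstimate",
    "estimate_copy_numbers",
    "genotype_from_droplets",
    "StateRanges",
    "DEFAULT_RANGES",
]


def poisson_lambda(positive_droplets: int, total_droplets: int) -> float:
    """Template concentration in copies/droplet from droplet counts.

    Inverts Poisson occupancy: lambda = -ln(1 - positives/total).  A
    saturated well (every droplet positive) is unquantifiable and raises —
    the sample must be re-run diluted.
    """
    if total_droplets <= 0:
        raise ValueError("total_droplets must be > 0")
    if not (0 <= positive_droplets <= total_droplets):
        raise ValueError("positive_droplets outside [0, total_droplets]")
    if positive_droplets == total_droplets:
        raise ValueError("saturated well (all droplets positive): re-dilute and re-run")
    return -math.log1p(-positive_droplets / total_droplets)


def copy_number_ratio(
    lambda_target: float, lambda_reference: float, reference_copies: float = 2.0
) -> float:
    """Target copy number from the target/reference concentration ratio."""
    if lambda_target < 0:
        raise ValueError("lambda_target must be >= 0")
    if lambda_reference <= 0:
        raise ValueError("lambda_reference must be > 0")
    return reference_copies * lambda_target / lambda_reference


def multi_assay_consensus(states: Sequence[int | None]) -> int | None:
    """Majority copy state across assays; ties and ambiguous majorities stay ambiguous."""
    if len(states) == 0:
        raise ValueError("need at least one assay state")
    counts: dict[int | None, int] = {}
    for s in states:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    winners = [s for s, c in counts.items() if c == best]
    if len(winners) != 1 or winners[0] is AMBIGUOUS:
        return AMBIGUOUS
    return winners[0]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    assay_id: str
    lambda_target: float
    lambda_reference: float
    copy_number: float
    classified_state: int | None


def estimate_copy_numbers(
    droplets: pd.DataFrame,
    reference_assay: str,
    ranges: StateRanges = DEFAULT_RANGES,
) -> pd.DataFrame:
    """Per-sample, per-assay copy numbers from a droplet count table.

    ``droplets`` columns: ``sample_id, assay_id, assay_target,
    total_droplets, positive_droplets``.  Every sample must carry the
    reference assay.
    """
    required = {"sample_id", "assay_id", "assay_target", "total_droplets", "positive_droplets"}
    missing = required - set(droplets.columns)
    if missing:
        raise ValueError(f"droplet table missing columns: {sorted(missing)}")
    rows = []
    for sample_id, sub in droplets.groupby("sample_id", sort=False):
        ref_rows = sub[sub["assay_id"] == reference_assay]
        if ref_rows.empty:
            raise ValueError(f"sample {sample_id!r} lacks reference assay {reference_assay!r}")
        r = ref_rows.iloc[0]
        lam_ref = poisson_lambda(int(r["positive_droplets"]), int(r["total_droplets"]))
        for _, row in sub[sub["assay_id"] != reference_assay].iterrows():
            lam_t = poisson_lambda(int(row["positive_droplets"]), int(row["total_droplets"]))
            cn = copy_number_ratio(lam_t, lam_ref)
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay_id": row["assay_id"],
                    "assay_target": row["assay_target"],
                    "lambda_target": lam_t,
                    "lambda_reference": lam_ref,
                    "copy_number": cn,
                    "state": classify_cn(cn, ranges),
                }
            )
    return pd.DataFrame(rows)


def genotype_from_droplets(
    droplets: pd.DataFrame,
    reference_assay: str,
    del1_assays: Sequence[str],
    del2_assays: Sequence[str],
    ranges: StateRanges = DEFAULT_RANGES,
) -> pd.DataFrame:
    """End-to-end ddPCR genotyping: droplet counts to six-genotype calls.

    ``del1_assays`` target the Del1-unique segment, ``del2_assays`` the
    shared (Del2) segment; each region's state is the majority vote over its
    assays.  Returns one row per sample with region copy numbers, states,
    genotype, and carrier/affected flags.
    """
    est = estimate_copy_numbers(droplets, reference_assay, ranges)
    rows = []
    for sample_id, sub in est.groupby("sample_id", sort=False):
        by_assay = dict(zip(sub["assay_id"], zip(sub["state"], sub["copy_number"])))
        u_states = [by_assay[a][0] for a in del1_assays if a in by_assay]
        s_states = [by_assay[a][0] for a in del2_assays if a in by_assay]
        if not u_states or not s_states:
            raise ValueError(f"sample {sample_id!r} lacks assays for one of the regions")
        us = multi_assay_consensus(u_states)
        ss = multi_assay_consensus(s_states)
        gt = genotype_from_states(us, ss)
        u_cn = float(pd.Series([by_assay[a][1] for a in del1_assays if a in by_assay]).mean())
        s_cn = float(pd.Series([by_assay[a][1] for a in del2_assays if a in by_assay]).mean())
        rows.append(
            {
                "sample_id": sample_id,
                "genotype": gt.value,
                "unique_cn": u_cn,
                "shared_cn": s_cn,
                "unique_state": us,
                "shared_state": ss,
                "affected": gt in AFFECTED,
                "carrier": gt in CARRIERS,
            }
        )
    return pd.DataFrame(rows)


def call_from_row(row: pd.Series) -> GenotypeCall:
    """Convert one :func:`genotype_from_droplets` row to a GenotypeCall."""
    gt = Genotype(row["genotype"])
    return GenotypeCall(
        sample_id=row["sample_id"],
        genotype=gt,
        unique_region_state=row["unique_state"],
        shared_region_state=row["shared_state"],
        unique_region_cn=row["unique_cn"],
        shared_region_cn=row["shared_cn"],
        affected=gt in AFFECTED,
    )
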