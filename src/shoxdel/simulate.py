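"""Synthetic sequencing and ddPCR data with the statistical structure of a
case/pool deletion-mapping design.

Depth is Poisson per base, scaled by local haplotype copy number; pooled SNP
read counts are Poisson depth with binomial allele sampling from the exact
member haplotypes; droplet counts follow Poisson occupancy of droplets.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .region import DEL1, DEL2, WT, RegionModel, SampleSpec


@dataclass
class DepthTrack:
    """Per-position depth and soft-clip counts for one sample.

    ``background_mean`` stands in for the genome-wide average depth used for
    normalization (the simulated region is a negligible fraction of a genome,
    so the sample's target mean coverage is that average).
    """

    sample_id: str
    depth: np.ndarray
    softclip: np.ndarray
    background_mean: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.softclip = np.asarray(self.softclip)
        if self.depth.shape != self.softclip.shape:
            raise ValueError("depth and softclip must have equal length")
        if np.any(self.depth < 0):
            raise ValueError("depths must be >= 0")
        if np.any(self.softclip > self.depth):
            raise ValueError("soft-clip count cannot exceed depth")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class DropletAssay:
    """Droplet counts for one (sample, assay) well."""

    sample_id: str
    assay_id: str
    assay_target: str  # del1_unique_region | shared_region | reference
    total_droplets: int
    positive_droplets: int

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be > 0")
        if not (0 <= self.positive_droplets <= self.total_droplets):
            raise ValueError("positive_droplets outside [0, total_droplets]")


ASSAY_TARGETS = ("del1_unique_region", "shared_region", "reference")


def _expected_copy_number(model: RegionModel, spec: SampleSpec) -> np.ndarray:
    """Expected per-position copy number (mean over pool members)."""
    positions = np.arange(model.region_length)
    total = np.zeros(model.region_length, dtype=float)
    members = spec.member_genotypes
    for pair in members:
        total += model.copy_number(pair, positions)
    return total / len(members)


def simulate_depth(
    model: RegionModel,
    spec: SampleSpec,
    seed: int = 0,
    mapping_noise: float = 0.0,
    clip_background: float = 0.01,
    clip_enrichment: float = 10.0,
    breakpoint_halfwidth: int = 500,
) -> DepthTrack:
    """Simulate per-base depth and soft-clip counts for one sample.

    Depth at each base is Poisson(mean_coverage x local_copy_number / 2); for
    pools the expected copy number is averaged over the members' haplotypes.
    ``mapping_noise`` adds a small uniform Poisson background inside the
    deleted footprint (default 0: a clean deletion has no aligned reads).
    Soft clips occur at rate ``clip_background`` per aligned read, amplified
    ``clip_enrichment``-fold within +/-``breakpoint_halfwidth`` of every
    breakpoint at which the sample carries at least one intact junction.
    """
    rng = np.random.default_rng(seed)
    cn = _expected_copy_number(model, spec)
    lam = spec.mean_coverage * cn / 2.0
    if mapping_noise:
        d1s, d1e = model.del1
        lam[d1s:d1e] += mapping_noise
    depth = rng.poisson(lam)

    junctions: set[str] = set()
    for pair in spec.member_genotypes:
        junctions |= model.junction_breakpoints(pair)
    rate = np.full(model.region_length, clip_background)
    bps = model.breakpoints
    for label in junctions:
        pos = bps[label]
        lo = max(0, pos - breakpoint_halfwidth)
        hi = min(model.region_length, pos + breakpoint_halfwidth)
        rate[lo:hi] = min(1.0, clip_background * clip_enrichment)
    softclip = rng.binomial(depth, rate)

    return DepthTrack(
        sample_id=spec.sample_id,
        depth=depth,
        softclip=softclip,
        background_mean=spec.mean_coverage,
    )


def _member_haplotype_alleles(
    model: RegionModel, pair: Sequence[str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(present, alt) boolean arrays of shape (2, n_snps) for one member.

    Wild-type haplotypes draw their SNP alleles independently from the
    population frequencies; deletion haplotypes carry the shared founder
    alleles (identical by descent across carriers).
    """
    n = len(model.snp_positions)
    present = np.empty((2, n), dtype=bool)
    alt = np.empty((2, n), dtype=bool)
    for k, hap in enumerate(pair):
        present[k] = model.haplotype_present(hap, model.snp_positions)
        if hap == WT:
            alt[k] = rng.random(n) < model.snp_alt_freqs
        else:
            alt[k] = model.founder_alt.astype(bool)
    return present, alt


def simulate_pool_snp_counts(
    model: RegionModel,
    member_genotypes: Sequence[tuple[str, str]],
    coverage: float,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "pool",
) -> pd.DataFrame:
    """Simulate ref/alt read counts at every SNP site for an equimolar pool.

    Per-site depth is Poisson(coverage x mean member copy number / 2); the alt
    read count is Binomial(depth, p') where p is the fraction of present
    member haplotypes carrying the alternate allele and p' = p(1-e) + (1-p)e
    for sequencing error rate e.

    An individual is the special case of a one-member pool; see
    :func:`simulate_sample_snp_counts`.
    """
    if len(member_genotypes) == 0:
        raise ValueError("a pool needs at least one member")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    n = len(model.snp_positions)
    present_total = np.zeros(n)
    alt_total = np.zeros(n)
    for pair in member_genotypes:
        present, alt = _member_haplotype_alleles(model, pair, rng)
        present_total += present.sum(axis=0)
        alt_total += (present & alt).sum(axis=0)

    mean_member_cn = present_total / len(member_genotypes)
    depth = rng.poisson(coverage * mean_member_cn / 2.0)
    p = np.divide(alt_total, present_total, out=np.zeros(n), where=present_total > 0)
    p_err = p * (1 - error_rate) + (1 - p) * error_rate
    alt_count = rng.binomial(depth, p_err)
    return pd.DataFrame(
        {
            "position": model.snp_positions,
            "sample_id": sample_id,
            "ref_count": depth - alt_count,
            "alt_count": alt_count,
        }
    )


def simulate_sample_snp_counts(
    model: RegionModel, spec: SampleSpec, error_rate: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """SNP read counts for one library (individual or pool)."""
    return simulate_pool_snp_counts(
        model,
        spec.member_genotypes,
        coverage=spec.mean_coverage,
        error_rate=error_rate,
        seed=seed,
        sample_id=spec.sample_id,
    )


def simulate_cohort_snp_counts(
    model: RegionModel,
    specs: Sequence[SampleSpec],
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenated SNP count table for a cohort, one sub-seed per sample."""
    ss = np.random.SeedSequence(seed)
    frames = [
        simulate_sample_snp_counts(model, spec, error_rate=error_rate, seed=child)
        for spec, child in zip(specs, ss.generate_state(len(specs)) % (2**31))
    ]
    return pd.concat(frames, ignore_index=True)


def target_copy_number(pair: Sequence[str], assay_target: str) -> int:
    """Template copy number of a diploid genotype for one assay target.

    An amplicon in the Del1-unique segment is lost only on Del1 haplotypes;
    an amplicon in the shared segment is lost on both deletion haplotypes;
    a reference amplicon lies outside the region entirely.
    """
    if assay_target == "reference":
        return 2
    if assay_target == "del1_unique_region":
        return sum(1 for h in pair if h != DEL1)
    if assay_target == "shared_region":
        return sum(1 for h in pair if h == WT)
    raise ValueError(f"unknown assay target {assay_target!r}")


def simulate_ddpcr(
    genotype: tuple[str, str],
    assay_target: str,
    total_droplets: int = 15_000,
    mean_copies_per_droplet_ref: float = 1.0,
    seed: int = 0,
    false_positive_rate: float = 0.0,
    sample_id: str = "",
    assay_id: str = "",
) -> DropletAssay:
    """Simulate droplet counts for one well.

    The template load per droplet for the target is the reference load scaled
    by (copy number / 2); droplet positivity follows Poisson occupancy,
    P(positive) = 1 - exp(-load), optionally floored by a false-positive rate.
    """
    if total_droplets <= 0:
        raise ValueError("total_droplets must be > 0")
    if mean_copies_per_droplet_ref < 0:
        raise ValueError("template load must be >= 0")
    if not (0 <= false_positive_rate < 1):
        raise ValueError("false_positive_rate must be in [0, 1)")
    cn = target_copy_number(genotype, assay_target)
    load = mean_copies_per_droplet_ref * cn / 2.0
    p = 1.0 - np.exp(-load)
    p = p + (1.0 - p) * false_positive_rate
    rng = np.random.default_rng(seed)
    positives = int(rng.binomial(total_droplets, p))
    return DropletAssay(
        sample_id=sample_id,
        assay_id=assay_id or assay_target,
        assay_target=assay_target,
        total_droplets=total_droplets,
        positive_droplets=positives,
    )


def simulate_cohort_ddpcr(
    genotypes: dict[str, tuple[str, str]],
    assays: Sequence[tuple[str, str]],
    total_droplets: int = 15_000,
    mean_copies_per_droplet_ref: float = 1.0,
    seed: int = 0,
    false_positive_rate: float = 0.0,
) -> pd.DataFrame:
    """Droplet-count table for a cohort over a panel of (assay_id, target) wells."""
    ss = np.random.SeedSequence(seed)
    n_wells = len(genotypes) * len(assays)
    seeds = iter(ss.generate_state(n_wells) % (2**31))
    rows = []
    for sample_id, pair in genotypes.items():
        for assay_id, target in assays:
            a = simulate_ddpcr(
                pair,
                target,
                total_droplets=total_droplets,
                mean_copies_per_droplet_ref=mean_copies_per_droplet_ref,
                seed=int(next(seeds)),
                false_positive_rate=false_positive_rate,
                sample_id=sample_id,
                assay_id=assay_id,
            )
            rows.append(
                {
                    "sample_id": a.sample_id,
                    "assay_id": a.assay_id,
                    "assay_target": a.assay_target,
                    "total_droplets": a.total_droplets,
                    "positive_droplets": a.positive_droplets,
                }
            )
    return pd.DataFrame(rows)


def simulate_population(
    n_individuals: int,
    del1_freq: float,
    del2_freq: float,
    seed: int = 0,
    mean_coverage: float = 7.0,
) -> list[SampleSpec]:
    """Draw a Hardy-Weinberg population of individuals.

    Haplotypes are i.i.d. draws from {Del1, Del2, WT} at the given allele
    frequencies (wild type takes the remainder).
    """
    if not (0 <= del1_freq <= 1 and 0 <= del2_freq <= 1):
        raise ValueError("allele frequencies must be in [0, 1]")
    if del1_freq + del2_freq > 1:
        raise ValueError("del1_freq + del2_freq must be <= 1")
    rng = np.random.default_rng(seed)
    haps = rng.choice(
        [DEL1, DEL2, WT],
        size=(n_individuals, 2),
        p=[del1_freq, del2_freq, 1.0 - del1_freq - del2_freq],
    )
    return [
        SampleSpec(
            sample_id=f"ind{i:05d}",
            mean_coverage=mean_coverage,
            haplotypes=(str(h1), str(h2)),
        )
        for i, (h1, h2) in enumerate(haps)
    ]
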