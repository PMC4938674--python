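"""Region geometry for a pseudoautosomal locus carrying two nested deletions.

The model describes a diploid genomic region (diploid in both sexes, since the
pseudoautosomal region recombines on X and Y and escapes X-inactivation) with
two deletion alleles: a larger one (``Del1``) and a smaller one (``Del2``)
whose deleted interval coincides with the distal part of ``Del1``.  Every
individual carries two haplotypes drawn from ``{WT, Del1, Del2}``.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: The three haplotype alleles.
WT = "WT"
DEL1 = "Del1"
DEL2 = "Del2"
HAPLOTYPES = (WT, DEL1, DEL2)

#: Breakpoint labels: BP1 = proximal end of Del1, BP2 = proximal end of Del2,
#: BP3 = shared distal end of both deletions.
BP1 = "BP1"
BP2 = "BP2"
BP3 = "BP3"


@dataclass(frozen=True)
class RepeatRun:
    """A perfect tandem repeat run: ``copies`` copies of ``motif`` at ``start``."""

    start: int
    motif: str
    copies: int

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.copies


@dataclass(frozen=True)
class RegionModel:
    """Geometry and polymorphism content of the simulated region.

    Attributes
    ----------
    region_length:
        Length of the region in bp.
    del1, del2:
        Half-open deleted intervals of the two alleles.  ``del2`` must be
        strictly nested in ``del1`` and share its distal (right) end.
    snp_positions, snp_alt_freqs:
        Biallelic SNP sites (strictly increasing positions) and their
        population alternate-allele frequencies.
    founder_alt:
        Alternate-allele indicator of the deletion founder haplotype at each
        SNP site.  Both deletion alleles are modelled as arising on one shared
        haplotype background, so a hemizygous case exposes these alleles
        wherever its only remaining haplotype is the founder.
    repeat_runs:
        Tandem repeat runs placed in the region (TGGA microsatellites flank
        the outer breakpoints by default).
    """

    region_length: int
    del1: tuple[int, int]
    del2: tuple[int, int]
    snp_positions: np.ndarray
    snp_alt_freqs: np.ndarray
    founder_alt: np.ndarray
    repeat_runs: tuple[RepeatRun, ...] = ()

    def __post_init__(self) -> None:
        d1s, d1e = self.del1
        d2s, d2e = self.del2
        if not (0 <= d1s < d1e <= self.region_length):
            raise ValueError(f"del1 interval {self.del1} outside region [0, {self.region_length})")
        if not (d1s < d2s < d2e == d1e):
            raise ValueError(
                "del2 must be strictly nested in del1 and right-aligned to its distal end; "
                f"got del1={self.del1}, del2={self.del2}"
            )
        pos = np.asarray(self.snp_positions)
        if pos.size and not np.all(np.diff(pos) > 0):
            raise ValueError("snp positions must be strictly increasing")
        if pos.size and (pos[0] < 0 or pos[-1] >= self.region_length):
            raise ValueError("snp positions outside region")
        if len(self.snp_alt_freqs) != len(pos) or len(self.founder_alt) != len(pos):
            raise ValueError("snp_alt_freqs/founder_alt length mismatch with snp_positions")

    @property
    def breakpoints(self) -> dict[str, int]:
        return {BP1: self.del1[0], BP2: self.del2[0], BP3: self.del1[1]}

    @property
    def del1_unique(self) -> tuple[int, int]:
        """Segment deleted by Del1 only: ``[del1.start, del2.start)``."""
        return (self.del1[0], self.del2[0])

    @property
    def shared(self) -> tuple[int, int]:
        """Segment deleted by both alleles (the whole Del2 interval)."""
        return self.del2

    def deleted_interval(self, haplotype: str) -> tuple[int, int] | None:
        if haplotype == WT:
            return None
        if haplotype == DEL1:
            return self.del1
        if haplotype == DEL2:
            return self.del2
        raise ValueError(f"unknown haplotype allele {haplotype!r}")

    def haplotype_present(self, haplotype: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: is the haplotype's sequence present at each position?"""
        positions = np.asarray(positions)
        iv = self.deleted_interval(haplotype)
        if iv is None:
            return np.ones(positions.shape, dtype=bool)
        return (positions < iv[0]) | (positions >= iv[1])

    def copy_number(self, pair: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Diploid local copy number in {0, 1, 2} at each position."""
        h1, h2 = pair
        return (
            self.haplotype_present(h1, positions).astype(np.int64)
            + self.haplotype_present(h2, positions).astype(np.int64)
        )

    def junction_breakpoints(self, pair_or_haplotype) -> set[str]:
        """Breakpoint labels at which the sample carries an intact junction."""
        haps = (pair_or_haplotype,) if isinstance(pair_or_haplotype, str) else tuple(pair_or_haplotype)
        out: set[str] = set()
        for h in haps:
            if h == DEL1:
                out |= {BP1, BP3}
            elif h == DEL2:
                out |= {BP2, BP3}
        return out


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing library: an individual (haplotype pair) or an equimolar pool.

    A pool is described by the explicit genotypes of its members, so the
    effective allele dosage (e.g. 42 haplotypes for 21 diploid members) is
    exact by construction.  ``sex`` is metadata only: the region is diploid
    in both sexes.
    """

    sample_id: str
    mean_coverage: float
    haplotypes: tuple[str, str] | None = None
    is_pool: bool = False
    pool_members: tuple[tuple[str, str], ...] | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.is_pool:
            if not self.pool_members:
                raise ValueError("a pool needs at least one member genotype")
            if self.haplotypes is not None:
                raise ValueError("a pool carries member genotypes, not a single haplotype pair")
        else:
            if self.haplotypes is None:
                raise ValueError("an individual needs a haplotype pair")
            for h in self.haplotypes:
                if h not in HAPLOTYPES:
                    raise ValueError(f"unknown haplotype allele {h!r}")

    @property
    def member_genotypes(self) -> tuple[tuple[str, str], ...]:
        """Member genotypes: the pool's members, or the individual itself."""
        if self.is_pool:
            return tuple(self.pool_members)  # type: ignore[arg-type]
        return (self.haplotypes,)  # type: ignore[return-value]

    @property
    def pool_allele_dosage(self) -> int:
        return 2 * len(self.member_genotypes)


def _uniform_freq_sampler(low: float = 0.05, high: float = 0.95) -> Callable:
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return sample


def build_region_model(
    region_length: int = 300_000,
    del1_span: int = 170_000,
    del2_span: int = 70_000,
    n_snps: int = 200,
    snp_freq_sampler: Callable | None = None,
    seed: int = 0,
    repeat_motif: str = "TGGA",
    repeat_run_bp: int = 1200,
) -> RegionModel:
    """Build a region with nested deletions, breakpoint repeats and SNP sites.

    Del1 is placed centrally in the region; Del2 is right-aligned to Del1's
    distal end.  Tandem runs of ``repeat_motif`` of at least ``repeat_run_bp``
    (default 1.2 kb, i.e. above the 1 kb scale seen flanking real deletion
    breakpoints) are placed immediately distal of BP1 and BP3.  SNP sites are
    drawn uniformly outside the repeat runs; their population frequencies come
    from ``snp_freq_sampler(rng, n)`` (default Uniform(0.05, 0.95)), and the
    founder-haplotype allele at each site is a single Bernoulli draw from that
    frequency.
    """
    if not (0 < del2_span < del1_span < region_length):
        raise ValueError(
            "need 0 < del2_span < del1_span < region_length (Del2 strictly nested in Del1); "
            f"got region_length={region_length}, del1_span={del1_span}, del2_span={del2_span}"
        )
    rng = np.random.default_rng(seed)
    d1s = (region_length - del1_span) // 2
    d1e = d1s + del1_span
    d2s = d1e - del2_span
    del1 = (d1s, d1e)
    del2 = (d2s, d1e)

    copies = int(np.ceil(repeat_run_bp / len(repeat_motif)))
    runs = []
    for bp in (d1s, d1e):
        start = min(bp, region_length - copies * len(repeat_motif))
        runs.append(RepeatRun(start=start, motif=repeat_motif, copies=copies))

    sampler = snp_freq_sampler or _uniform_freq_sampler()
    in_run = np.zeros(region_length, dtype=bool)
    for r in runs:
        in_run[r.start : r.end] = True
    candidates = np.flatnonzero(~in_run)
    n_snps = min(n_snps, candidates.size)
    positions = np.sort(rng.choice(candidates, size=n_snps, replace=False))
    freqs = np.asarray(sampler(rng, n_snps), dtype=float)
    founder_alt = (rng.random(n_snps) < freqs).astype(np.int8)

    return RegionModel(
        region_length=region_length,
        del1=del1,
        del2=del2,
        snp_positions=positions,
        snp_alt_freqs=freqs,
        founder_alt=founder_alt,
        repeat_runs=tuple(runs),
    )
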