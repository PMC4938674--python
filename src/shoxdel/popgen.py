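"""Population summaries of deletion genotypes.

Allele frequencies by gene counting (every genotype is fully observed by the
copy-number assays, so no EM over unobserved phase is needed), carrier
fractions, and Hardy-Weinberg expectations for a recessive two-allele
deletion system where any two deletion alleles produce the phenotype.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import pandas as pd

from .genotype import CARRIERS, Genotype

#: Deletion-allele content of each resolvable genotype: (n_del1, n_del2, n_wt).
_ALLELE_CONTENT: dict[Genotype, tuple[int, int, int]] = {
    Genotype.DEL1_DEL1: (2, 0, 0),
    Genotype.DEL1_DEL2: (1, 1, 0),
    Genotype.DEL2_DEL2: (0, 2, 0),
    Genotype.DEL1_WT: (1, 0, 1),
    Genotype.DEL2_WT: (0, 1, 1),
    Genotype.WT_WT: (0, 0, 2),
}


def _normalize_counts(genotype_counts: Mapping) -> dict[Genotype, int]:
    out: dict[Genotype, int] = {}
    for g, n in genotype_counts.items():
        if int(n) < 0:
            raise ValueError("genotype counts must be >= 0")
        gt = Genotype(g)
        if gt is Genotype.UNRESOLVED:
            continue  # unresolved samples carry no allele information
        out[gt] = out.get(gt, 0) + int(n)
    return out


def allele_frequencies(genotype_counts: Mapping) -> tuple[float, float, float]:
    """Gene-counting allele frequencies ``(del1, del2, wt)``.

    Each heterozygote contributes one copy of each of its alleles, each
    homozygote two; frequencies are allele counts over 2n chromosomes.
    Affected genotypes, when present, are counted like any other.
    """
    counts = _normalize_counts(genotype_counts)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("need at least one resolved genotype")
    d1 = d2 = wt = 0
    for gt, c in counts.items():
        a1, a2, aw = _ALLELE_CONTENT[gt]
        d1 += a1 * c
        d2 += a2 * c
        wt += aw * c
    total = 2 * n
    return d1 / total, d2 / total, wt / total


def carrier_fraction(genotype_counts: Mapping) -> float:
    """Fraction of individuals heterozygous for either deletion allele."""
    counts = _normalize_counts(genotype_counts)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("need at least one resolved genotype")
    carriers = sum(c for gt, c in counts.items() if gt in CARRIERS)
    return carriers / n


def hwe_expectations(del1_freq: float, del2_freq: float) -> dict[str, float]:
    """Hardy-Weinberg genotype fractions for the three-allele system.

    The trinomial expansion of (p_wt + q1 + q2)^2; the expected affected
    fraction is q1^2 + 2 q1 q2 + q2^2 = (q1 + q2)^2, since every pairing of
    two deletion alleles manifests the recessive phenotype.
    """
    if del1_freq < 0 or del2_freq < 0:
        raise ValueError("allele frequencies must be >= 0")
    if del1_freq + del2_freq > 1:
        raise ValueError("allele frequencies must sum to <= 1")
    q1, q2 = del1_freq, del2_freq
    p = 1.0 - q1 - q2
    out = {
        Genotype.WT_WT.value: p * p,
        Genotype.DEL1_WT.value: 2 * p * q1,
        Genotype.DEL2_WT.value: 2 * p * q2,
        Genotype.DEL1_DEL1.value: q1 * q1,
        Genotype.DEL1_DEL2.value: 2 * q1 * q2,
        Genotype.DEL2_DEL2.value: q2 * q2,
    }
    out["carrier_fraction"] = 2 * p * (q1 + q2)
    out["affected_fraction"] = (q1 + q2) ** 2
    return out


@dataclass(frozen=True)
class PopulationSummary:
    n_individuals: int
    genotype_counts: dict[str, int]
    del1_freq: float
    del2_freq: float
    wt_freq: float
    carrier_fraction: float
    hwe_expected_affected_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_population(genotype_counts: Mapping) -> PopulationSummary:
    """Full population summary from a genotype count table."""
    counts = _normalize_counts(genotype_counts)
    d1, d2, wt = allele_frequencies(counts)
    return PopulationSummary(
        n_individuals=sum(counts.values()),
        genotype_counts={gt.value: c for gt, c in counts.items()},
        del1_freq=d1,
        del2_freq=d2,
        wt_freq=wt,
        carrier_fraction=carrier_fraction(counts),
        hwe_expected_affected_fraction=(d1 + d2) ** 2,
    )


def counts_from_calls(calls: pd.DataFrame) -> dict[str, int]:
    """Genotype counts from a per-sample call table with a ``genotype`` column."""
    return calls["genotype"].value_counts().to_dict()
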