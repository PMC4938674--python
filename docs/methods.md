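# Methods

`shoxdel` re-implements, as a reusable and tested pipeline, the analysis
chain used to map a recessive skeletal disorder to two overlapping large
deletions at a SHOX-like locus in the pseudoautosomal region (PAR): a pooled
case/control SNP screen, windowed read-depth copy-number analysis, deletion
segment calling with breakpoint annotation, droplet-digital-PCR (ddPCR)
copy-number genotyping, and population allele-frequency estimation. Because
the PAR recombines on both sex chromosomes and escapes X-inactivation, the
locus is treated as diploid in all individuals; sex is metadata only.

## Region model

A region of length `L` (default 300 kb) carries two deletion alleles:
`Del1` (default span 170 kb, placed centrally) and `Del2` (default 70 kb),
whose deleted interval is strictly nested in `Del1` and right-aligned to its
distal end — the structure in which every documented affected animal shares
the distal segment. The defaults put the true spans in the middle of the
plausible brackets for the real alleles (160–180 kb and 60–80 kb). Three
breakpoints follow: BP1 = `Del1` start, BP2 = `Del2` start, BP3 = the shared
distal end. Perfect TGGA tandem runs of 1.2 kb are stamped immediately
distal of BP1 and BP3, reflecting the >1 kb microsatellite stretches that
flank the real outer breakpoints and defeat short-read junction assembly.
Coordinates are 0-based half-open everywhere; 1-based conversion happens
only when writing samtools-style depth TSV and VCF.

SNP sites (default 200 in tests; configurable) are drawn uniformly outside
the repeat runs with population alternate-allele frequencies from
Uniform(0.05, 0.95). Both deletion alleles are modelled as arising on one
shared founder haplotype whose SNP alleles are a single Bernoulli draw from
the population frequencies. This is the mechanism that produces the
published screen signature endogenously: in the `Del1`-unique segment a
compound heterozygote retains only the founder haplotype, so any site where
the founder carries the alternate allele and the pool happens to be
reference-fixed shows cases fixed-alt / pool fixed-ref, while `Del1`
homozygotes simply have no reads there.

## Sequencing simulation

Depth at each base is Poisson(`coverage × c/2`) where `c` is the local copy
number in {0, 1, 2}; pools use the mean copy number over their members'
haplotypes, so a 21-member equimolar pool has an effective dosage of 42
haplotypes by construction. Default coverages follow the study design the
package emulates: 7X per individually sequenced case, 56X for the pool. An
optional `mapping_noise` Poisson background inside the deleted footprint
(default 0) lets thresholding be exercised; real deletions showed
essentially zero depth, hence the zero default. Soft-clipped reads occur at
a background rate of 0.01 per aligned read, amplified 10-fold within
±500 bp of every breakpoint at which the sample carries at least one intact
junction; samples without a junction get no enrichment anywhere.

Pooled SNP counts: per-site depth is Poisson(`coverage × mean member copy
number / 2`); the alternate count is Binomial(depth, p′) with p the fraction
of present member haplotypes carrying the alternate allele and
p′ = p(1−e) + (1−p)e for error rate `e` (default 0). An individual is
simulated as a one-member pool, so cases and pool share one code path.

The generator does not attempt read-level realism: no FASTQ, alignment,
base-quality, GC- or mappability-bias modelling, no multi-allelic sites,
and deletions are placed at exact coordinates rather than behind assembly
gaps. Passing tests therefore demonstrate the statistical machinery on an
idealized diploid region — they do not certify performance on a fragmented
assembly, where windows with poor pool signal would be flagged undefined
rather than genotyped.

## SNP screen

A site passes the fixed-difference screen iff the pool has depth ≥ 1 with
zero alternate reads, every covered case (depth ≥ `min_case_depth`,
default 1) has zero reference reads, and at least `min_covered_cases`
(default 1) cases are covered. Uncovered cases never disqualify a site —
a homozygous deletion *is* zero coverage. `max_discordant_reads`
(default 0, i.e. exact fixation) tolerates stray error reads when raised.
Count-level rules replace genotype-caller output deliberately: they are
transparent and reproduce the same signature. Note that raising
`min_case_depth` can both remove sites (coverage requirement) and admit
sites (a shallow discordant case drops out of the covered set); the screen
makes no monotonicity promise in that parameter.

## Windowed copy number

Window statistic is the mean per-base depth over 1-kb windows (the linear
statistic matching the Poisson expectation; the last window may be short).
Normalized depth divides by the sample's genome-wide background mean, which
includes deleted regions (they are a negligible genome fraction). Copy
number is 2 × case/pool normalized depth, reported as NaN (undefined, never
zero) where the pool's normalized depth is below `min_pool_normalized`
(default 0.2) — below that the pool itself lacks signal and a ratio would
be noise. The pool's per-window Z-score uses the all-window sample SD
(ddof 1); a zero-SD vector is rejected as degenerate rather than silently
returned as all-zero.

## Segment calling and breakpoints

Windows classify to copy states with one vocabulary shared with ddPCR
genotyping: two copies 1.7–2.3, one copy 0.7–1.3 (the empirically adjusted
ddPCR ranges), zero copies below 0.3 (chosen symmetric with the gap under
the one-copy range; no empirical outliers motivated a wider null range).
Consecutive windows of one deleted state merge into a call, bridging up to
`max_gap_windows` (default 2) ambiguous/undefined windows; any window with
a different definite state terminates the call; calls need ≥ `min_windows`
(default 3) supporting windows. The defaults are the smallest values robust
to single-window noise at 7X. Breakpoints are reported at window resolution
— base-exact breakpoints are not resolvable from depth, and the repeat
structure at the real locus defeated base-exact resolution by design.

Soft-clip refinement tests each sliding window (1 kb, step 500 bp) against
Binomial(depth, background rate) with a one-sided upper tail, Bonferroni-
corrected over windows (conservative by intent: this is peak calling, not
inference); peaks are the best window per contiguous significant run.
Tandem-repeat annotation reports maximal perfect runs of a motif (greedy
left-to-right, given orientation only) with span above a threshold
(default 1 kb).

## Genotyping

The copy states of two segments — the `Del1`-unique segment and the shared
(`Del2`) segment — determine all six genotypes exhaustively:
(2,2) WT/WT, (1,1) Del1/WT, (2,1) Del2/WT, (0,0) Del1/Del1,
(1,0) Del1/Del2, (2,0) Del2/Del2. State pairs violating the nesting
structure, or involving an ambiguous state, return `unresolved` — a value,
not an error; no cluster-rescue heuristics are attempted. A call resting on
fewer than 3 windows in either region is flagged low-confidence. Region
copy number is the mean over fully contained windows, falling back to
overlapping windows only when the region is smaller than one window.

## ddPCR

Concentration per droplet is recovered by Poisson occupancy,
λ = −ln(1 − positive fraction); a saturated well raises an error (re-dilute)
rather than returning infinity. Copy number is 2 × λ_target/λ_reference —
a dimensionless ratio, so no copies/µL conversion is needed or provided.
Per-assay states combine by majority vote across a region's assays; ties
and ambiguous majorities stay ambiguous. Simulated droplet loads default to
1.0 reference copies per droplet (the wet-lab load in ng is not translatable
to copies/droplet without fragment-size assumptions; at 15,000 droplets any
load in ~0.3–3 gives fully separated clusters, and the default sits in that
plateau). Fluorescence-amplitude clustering upstream of the counts is out
of scope; the pipeline starts at droplet counts.

## Population summaries

Allele frequencies use gene counting over fully observed genotypes (no EM
is needed — the assays observe both haplotypes); unresolved samples are
excluded from counting, affected samples are included. Carrier fraction is
heterozygotes over individuals. Hardy-Weinberg expectations come from the
trinomial expansion of (p + q₁ + q₂)²; the expected affected fraction is
(q₁ + q₂)², since any two deletion alleles manifest the phenotype. No
temporal stratification of sampling is modelled.

## Problem sizes and reproducibility

Tests and the acceptance script run the full 300-kb region with the study's
coverage design (7X cases, 56X/21-member pool), 20 replicates for the
stochastic end-to-end checks and 50 for breakpoint recovery; screen null
behaviour is checked on 10,000 neutral SNP sites. Every generator consumes
a `numpy` `SeedSequence`-derived seed, so fixed seeds give byte-identical
outputs. Convergence assertions use 3-standard-error bands computed from
the relevant closed forms (Poisson, binomial, delta-method for λ̂).

## Known limitations

- The simulator places both deletions on one founder SNP background; real
  alleles may sit on diverged backgrounds, which would only strengthen the
  screen signal.
- Depth-based genotyping assumes a usable control pool over the region of
  interest; regions failing `min_pool_normalized` genotype as unresolved.
- Assay placement is abstract (a target label, not primer coordinates);
  assay failure modes other than count-level noise (polymorphic primer
  sites, partial digestion) are not modelled.
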