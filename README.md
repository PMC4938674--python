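# shoxdel

Deletion mapping at a SHOX-like pseudoautosomal locus: a tested, reusable
implementation of the analysis chain that identifies two overlapping large
deletions behind a recessive skeletal disorder from case/pool whole-genome
resequencing, and genotypes them by droplet digital PCR.

The package is aimed at genome scientists who want the statistical core of
that analysis — not the upstream alignment — as library functions and small
shell tools:

- **Synthetic data** (`shoxdel.region`, `shoxdel.simulate`): a diploid
  region (the pseudoautosomal region is diploid in both sexes) carrying two
  deletion alleles, `Del1` (~170 kb) and `Del2` (~70 kb) nested in `Del1`'s
  distal part; Poisson per-base depth scaled by haplotype copy number
  (7X cases, 56X 21-member equimolar pool by default); SNP read counts;
  soft-clip enrichment and TGGA repeat runs at breakpoints; droplet counts.
- **SNP screen** (`shoxdel.screen`): sites where every covered case is
  fixed for the alternate allele while the control pool carries only
  reference reads (allele-frequency difference of 1); cases without reads
  do not disqualify a site — homozygous deletions look exactly like that.
- **Depth windows** (`shoxdel.windows`): 1-kb window means, normalization
  by genome background depth, copy number `CN = 2 · (case/pool normalized
  depth)`, and pool Z-scores.
- **Deletion calling** (`shoxdel.segments`): merge deleted-state windows
  into segment calls, refine breakpoints by binomial soft-clip enrichment,
  annotate tandem motif runs.
- **Genotyping** (`shoxdel.genotype`): the copy states of the
  `Del1`-unique and shared segments map exhaustively to six genotypes
  (`WT/WT`, `Del1/WT`, `Del2/WT`, `Del1/Del1`, `Del1/Del2`, `Del2/Del2`);
  anything else is `unresolved`.
- **ddPCR** (`shoxdel.ddpcr`): Poisson occupancy `λ = −ln(1 − f)`, copy
  number `2 · λ_target/λ_ref`, classification with the empirical ranges
  (two copies 1.7–2.3, one copy 0.7–1.3), multi-assay majority consensus.
- **Population genetics** (`shoxdel.popgen`): gene-counting allele
  frequencies, carrier fraction, Hardy–Weinberg expectations with affected
  fraction `(q₁+q₂)²`.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate the sequencing design — two affected animals, one carrier, and the
21-member wild-type control pool — and genotype everyone from windowed
read depth:

```python
from shoxdel import build_region_model, simulate_depth, build_window_table
from shoxdel.region import SampleSpec
from shoxdel.genotype import genotype_cohort
from shoxdel.popgen import summarize_population

model = build_region_model(seed=1)           # 300 kb, Del1 170 kb, Del2 70 kb
cases = {"case1": ("Del1", "Del1"), "case2": ("Del1", "Del2"),
         "carrier": ("Del1", "WT")}
pool = SampleSpec("pool", 56.0, is_pool=True, pool_members=(("WT", "WT"),) * 21)
tracks = {sid: simulate_depth(model, SampleSpec(sid, 7.0, haplotypes=pair), seed=i)
          for i, (sid, pair) in enumerate(cases.items())}
tracks["pool"] = simulate_depth(model, pool, seed=99)

table = build_window_table(tracks, pool_id="pool")   # 1-kb windows
calls = genotype_cohort(table, list(cases), model.del1_unique, model.shared)
print(calls.to_string(index=False))

summary = summarize_population({"Del1/WT": 9, "Del2/WT": 2, "WT/WT": 83})
print(f"Del1 {summary.del1_freq:.2%}  Del2 {summary.del2_freq:.2%}  "
      f"carriers {summary.carrier_fraction:.1%}  "
      f"expected affected {summary.hwe_expected_affected_fraction:.2%}")
```

Output:

```
sample_id  genotype  unique_cn  shared_cn  affected confidence
    case1 Del1/Del1   0.000000   0.000000      True       high
    case2 Del1/Del2   1.001887   0.000000      True       high
  carrier   Del1/WT   1.001854   1.001963     False       high
Del1 4.79%  Del2 1.06%  carriers 11.7%  expected affected 0.34%
```

The homozygote has no reads over the whole deletion (copy number 0 in both
segments); the compound heterozygote keeps one copy of the `Del1`-unique
segment but none of the shared segment; the carrier keeps one copy of both.
The population summary is the gene-counting arithmetic for a random set of
94 animals with 9 + 2 heterozygous carriers: allele frequencies 4.79% and
1.06%, carrier fraction 11.7%, and an expected affected birth fraction of
0.34% under Hardy–Weinberg.

The same steps are available from the shell (`shoxdel simulate`,
`shoxdel screen-snps`, `shoxdel depth-windows`, `shoxdel call-deletions`,
`shoxdel annotate-breakpoints`, `shoxdel genotype`, `shoxdel ddpcr`,
`shoxdel popstats`); run `shoxdel --help`.

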