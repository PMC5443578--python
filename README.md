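# uvhotspots

Analysis toolkit for a question at the heart of non-coding cancer genomics:
when the same promoter base is mutated in tumor after tumor, is that
selection for a driver, or just a position that is unusually easy to mutate?
In UV-exposed cancers such as melanoma, recurrent promoter mutations cluster
at cytosines at the 5' end of the ETS-like element **CTTCCG**, and their
behavior — recurrence tracking total mutation load, elevation only near
active transcription start sites (TSSs) — is what one expects from an
*extended context-specific mutational signature* rather than from positive
selection. This package implements that analysis chain as a tested,
reusable library for anyone who wants to run it on their own cohorts or on
fully synthetic data.

## What it computes

The central statistic is the context-specific mutation probability

```
P(context) = mutations(context) / (instances(context) x n_tumors)
```

i.e. the number of observed substitutions whose pyrimidine-strand sequence
context matches a pattern, divided by the number of genomic occurrences of
that pattern and by the cohort size. Comparing `P` for extended
CTTCCG-related contexts against the matched trinucleotide contexts —
genome-wide versus within ±500 bp of TSSs, split by gene-expression tier —
quantifies the position-specific vulnerability of the motif's 5' cytosines.

Around that core the package provides:

- **genome / annotation** — FASTA access, pyrimidine-strand normalization,
  exact motif scanning with N wildcards, TSS derivation (5'-most transcript
  start), expression tiers, TSS-window masks with template/non-template
  strand resolution;
- **hotspot detection** — per-position recurrence across tumors, promoter
  hotspot calling, NCTTCCGN overlap classification and offset histograms,
  recurrence vs TSS distance per expression tier, and a two-sided Wilcoxon
  rank-sum test for expression differences between mutated and non-mutated
  tumors (exact for small groups);
- **burden correlation** — per-tumor hotspot-position count vs genome-wide
  load, with Spearman's rank correlation (exact permutation p for n ≤ 8);
- **synthetic data** — genomes with planted CTTCCG elements near TSSs of
  each expression tier, a UV-like trinucleotide signature (C>T at
  dipyrimidines, occasional CC>TT), log-uniform per-tumor loads, and a
  multiplicative vulnerability factor *f* at motif 5' cytosines near
  active TSSs, with full ground truth;
- **amplicon consensus** — barcode-family grouping of ultra-deep amplicon
  reads, consensus acceptance (families of ≥ 20 reads with ≥ 90% identical
  members), raw vs error-corrected variant frequencies, and a matched
  library simulator with PCR-lineage and per-read sequencing errors.

## Worked example

Simulate a cohort and analyze it, all from the shell:

```
uvhotspots simulate --outdir demo --seed 1 --genome-length 2000000 \
    --load-min 200 --load-max 20000
uvhotspots report --genome demo/genome.fa --annotation demo/genes.tsv \
    --variants demo/variants.tsv --expression demo/expression.tsv \
    --outdir demo/run --min-recurrence 5
```

or from Python:

```python
from uvhotspots import SimulationConfig, generate_reference, simulate_tumors
from uvhotspots import MotifIndex, call_hotspots, vulnerability_ratio
from uvhotspots.annotation import nearest_tier_masks

cfg = SimulationConfig(seed=42)          # 10 Mb, 38 tumors, f = 50
bundle = generate_reference(cfg)
cohort, truth = simulate_tumors(cfg, bundle)

masks = nearest_tier_masks(bundle.index, bundle.genome.lengths)
tier3 = vulnerability_ratio(cohort, bundle.genome, masks[3])
gw = vulnerability_ratio(cohort, bundle.genome, None)
print(f"top-tier TSS ratio {tier3.ratio:.1f}, genome-wide {gw.ratio:.1f}")
```

prints

```
top-tier TSS ratio 51.9, genome-wide 2.1
```

meaning: near the TSSs of highly expressed genes, the mutation probability
of motif 5' cytosines is ~52x the matched trinucleotide baseline —
recovering the planted 50-fold vulnerability — while genome-wide the same
contexts are barely elevated, because most motif instances lie far from
active promoters. In the heavy-load regime (`load_range=(1000, 100000)`),
individual motif positions recur in ≥ 5 of 38 tumors, every called promoter
hotspot overlaps NCTTCCGN, and the per-tumor hotspot count tracks total
mutation load (Spearman ρ ≈ 0.88-0.99 depending on seed) — the signature
of mutational vulnerability, not selection.

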