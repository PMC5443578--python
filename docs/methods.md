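# Methods

## The probability model

Every substitution is reported on its pyrimidine strand: the strand on
which the mutated base is C or T, the standard orientation for mutational
signatures. For a sequence context — a pattern over {A,C,G,T,N} with a
designated mutated index — the mutation probability in a genomic stratum is

    P = mutations / (instances x n_tumors)

where *mutations* counts substitution events (one per tumor and position;
ingestion deduplicates) whose pyrimidine-strand context matches the pattern
and whose position falls in the stratum, *instances* counts genomic
occurrences of the pattern in the stratum on either strand (each strand's
pyrimidine is an independent target, so a pattern present on both strands
at overlapping coordinates contributes once per strand), and *n_tumors* is
the declared cohort size including tumors with zero variants. The three
factors are reported in every output row, so any probability can be
recomputed exactly; rows with zero instances carry an undefined value
serialized as `NA`, never a division result.

Coordinates are 1-based inclusive at the interfaces (VCF convention) and
0-based half-open in internal interval masks. Windows that cross a contig
edge are padded with N: edge mutations are retained but can never match a
context, which keeps counts conservative.

## Strata

* *genome-wide*: no mask.
* *TSS ± 500 by expression tier*: genes are ranked by mean expression and
  cut into three tiers of near-equal size (remainders go to the lower
  tiers; expression ties break by gene id, so the assignment is invariant
  under input order). Both mutations and instance denominators are
  assigned to the tier of the **nearest** gene among positions within 500
  bp of any TSS, so the three tier strata partition the TSS-proximal
  territory exactly. The per-gene window masks (a position near two TSSs
  belongs to both genes) remain available for analyses that need them.
* *upstream 500, top tier, by strand*: transcriptionally upstream windows
  of top-tier genes, with mutations assigned by whether the chromosomal
  strand carrying the pyrimidine is the template or non-template strand of
  the downstream gene, and instances by the strand carrying the pattern.
  A position in the upstream windows of two opposite-strand genes is
  counted once per gene (logged).

## Motif geometry

The extended element is N-CTTCCG-N read on the motif-bearing strand,
offsets 0..7 with offset 0 at the leading N; offset −1 (one base upstream
of the leading N) is reported for context but not counted as overlap.
Minus-strand occurrences mirror plus-strand ones after the strand flip.
"Adjacent" in the recurrence-vs-distance analysis means within 1 bp of the
CTTCCG boundary, which is exactly the two flanking N positions.

## The vulnerability-ratio estimator

The headline quantity pools the motif's two 5'-end cytosines (the first C
of CTTCCG, plus the leading flank base when it is a C) and divides their
pooled probability by the pooled marginal matched trinucleotides (NCT and
NCC) in the same stratum. The baseline **excludes** positions overlapping
any N-CTTCCG-N element: in compact synthetic genomes the planted motifs
are a material fraction of the matched trinucleotide rows inside the small
promoter masks, and leaving them in would bias the ratio toward 1. (In a
gigabase genome the contamination is negligible and inclusive and
exclusive baselines coincide.) The paper-style inclusive rows are still
what `trinucleotide_panel` and `motif_panel` emit.

## Rank statistics

The Wilcoxon rank-sum test (expression of mutated vs non-mutated tumors)
enumerates all group assignments with midranks when both groups have ≤ 10
observations and otherwise uses the normal approximation with tie and
continuity correction (scipy's Mann-Whitney machinery). Spearman's ρ uses
midranks; its p-value is an exhaustive permutation enumeration for n ≤ 8
and the t-approximation with n − 2 degrees of freedom otherwise. A
constant vector yields an undefined ρ, not an error.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes and
supplies ground truth for parameter recovery:

* **Genome**: i.i.d. bases (default uniform composition, 2 × 5 Mb), with
  CTTCCG elements written at recorded coordinates/strands near the TSSs of
  genes in each tier (default 60 per tier within ±450 bp). A placement is
  re-drawn whenever the insertion would create an unintended extra
  occurrence adjacent to the planted one, so the manifest is an exact
  subset of a genome-wide scan. Chance background occurrences (~5,000 per
  10 Mb at uniform composition) are kept and treated identically to
  planted ones by every rule downstream.
* **Genes**: 300 genes at jittered even spacing, random strand, 1–3
  transcript starts of which the 5'-most is the TSS, log-normal mean
  expression (log-mean 1, log-sd 2, arbitrary units) from which tiers are
  derived with the same code the analysis uses.
* **Signature**: relative weights per (pyrimidine trinucleotide, class).
  The UV-like default puts weight 1.0 on C>T at dipyrimidine cytosines
  (5' neighbor T or C), 0.05 on other C>T, 0.02 on C transversions, and
  small weights on T mutations — a deliberately simple photoproduct-
  dominated spectrum, not a fitted catalog signature.
* **Vulnerability**: motif instances within 500 bp of a top-tier TSS have
  their 5'-cytosine weights multiplied by *f* (default 50) and their
  central-CC weights by a smaller factor (default 5). The factor is
  phenomenological — agnostic between enhanced lesion formation and
  blocked repair.
* **Tumors**: 38 per cohort. Each draws a load log-uniformly and then
  samples that many *distinct* positions with probability proportional to
  weight (weighted reservoir keys), so a site mutates at most once per
  tumor and the emitted count equals the drawn load exactly. Drawn C>T
  mutations at motif CC pairs extend to the adjacent cytosine with
  probability 0.1 (the CC>TT channel); each extension displaces one
  unprotected drawn mutation so the load invariant holds.

### Load regimes

Per-site per-tumor inclusion under exact-load sampling is approximately
1 − exp(−load · w / W), which saturates once load · f · w / W approaches 1.
Two regimes therefore matter:

* the **linear regime** (default loads log-uniform 10²–10⁴ per 10 Mb, two
  orders of magnitude): per-site probabilities stay ≲ 0.15 even at
  vulnerable sites, so the probability-ratio estimator recovers the
  multiplicative factor *f* — this is where parameter-recovery checks run;
* the **saturated regime** (loads 10³–10⁵ per 10 Mb): vulnerable sites
  approach one mutation per tumor, individual positions recur in ≥ 5 of 38
  tumors, and hotspot emergence and the burden-load correlation are
  studied here. Probability ratios in this regime are compressed below
  *f* by construction; that compression is a property of the estimand,
  not an estimator defect.

The cohort-scale choices (38 tumors, loads spanning orders of magnitude,
three expression tiers, ±500 bp windows, recurrence thresholds of 5/38 ≈
13% for "highly recurrent" and ≥ 3 for the established-hotspot set) mirror
the melanoma study design this pipeline is built around; loads are scaled
from gigabase tumors to the megabase synthetic genome so that recurrence
is reachable at all.

### What the generator does not emulate

No replication timing, chromatin state, or regional rate covariates; no
mechanistic repair model; no indels; i.i.d. background sequence rather
than real promoter composition. Passing tests on this generator show the
estimators are correct under the stated model — they do not show that real
promoter hotspots are fully explained by it, and real-data contamination
(mappability, germline leakage, driver selection at loci like the TERT
promoter) is out of scope beyond the position blacklist.

## Barcode consensus

Reads are grouped by exact barcode (no barcode-error clustering); member
reads are the trimmed amplicon portions. A family yields a consensus only
when it has ≥ 20 reads of which ≥ 90% are exactly identical (whole-read
equality — the most literal reading of the protocol); the consensus is the
modal read, and a tie rejects the family as ambiguous. A per-position
majority mode exists behind a flag for sensitivity analysis. Raw
frequencies are over all retained reads, corrected frequencies over
accepted consensus reads; the accepted count and reads-per-consensus ratio
are always reported. The library simulator draws molecules carrying true
variants per their fractions, log-normal family sizes (median ≈ 37), PCR
errors per molecule lineage propagating to an early-cycle fraction (1/2,
1/4 or 1/8) of the family, and per-read sequencing errors. At the 0.5%
per-base sequencing error used in the stress test, only a few percent of
49 bp families clear the 90% identity bar — acceptance rates are
deliberately pessimistic there, and the corrected estimate remains
unbiased because errors are strand- and site-symmetric.

## Numerical and degenerate-input choices

Distance ties in nearest-TSS queries break toward the lower genomic
coordinate. A hotspot overlapping several motif occurrences reports the
occurrence that covers it most centrally. Multi-allelic records and indels
are dropped at ingestion (counted); the variant-allele-fraction filter
(≥ 0.2, as used for repair-deficient tumor data) exists but is off by
default; the position blacklist removes all alleles at a position unless
an allele is specified. Probabilities are never formed with a zero
denominator. All randomness flows through numpy Generators seeded from a
single integer; identical seed and configuration reproduce every output
byte for byte.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full chain on a 10 Mb
genome for parameter recovery and burden analysis, twenty 2 Mb replicate
cohorts for null calibration, 100 kb genomes for brute-force enumeration
oracles, and amplicon libraries of 2,000–10,000 molecules — sizes at which
every quantity of interest is measurable with comfortable margins on a
single CPU.
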