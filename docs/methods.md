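# Methods

## Scope and model

`nucspec` re-implements, at desk scale, the analysis chain of a
nuclease-specificity campaign: select DNA-binding proteins that discriminate
a target from a close homologue (dual-reporter fluorescence readout), profile
their binding preference in vitro (SELEX), measure editing outcomes at
candidate loci (amplicon deep sequencing), and discover off-target cut sites
genome-wide without prior hypotheses (IDLV capture). Every stage consumes
plain-text interchange formats (FASTA/FASTQ/BED6/TSV/YAML) and can be fed by
the synthetic-data generator, which plants known truth so each stage's
estimator can be checked quantitatively.

## Synthetic-data generator

The generator emulates the study designs, not sequencing physics:

- **Capture integrations.** Each treated replicate draws
  Poisson(`intensity`) integrations per planted site at
  `center + sign · Geometric(1/scale)` (default scale 50 bp: integrations
  concentrate within tens of bp of the break, with occasional distal
  capture); all replicates receive a uniform background (default
  10 integrations/Mb/replicate). Controls carry background only.
- **Amplicon reads.** A read is the reference; with probability
  `indel_rate` a single insertion or deletion (length from a configurable
  distribution, default 1–10 bp skewed short) is anchored uniformly inside
  the cut interval, then i.i.d. substitution noise (default 0.1%/base) is
  applied. One lesion per read suffices because reads are scored binary
  (indel-positive or not).
- **SELEX pools.** `flank5 + core + flank3` with the core sampled
  column-wise from a generating probability matrix; a contaminant fraction
  is truncated or flank-mutated to exercise the exact-match filter. The
  default flanks are the published 24-nt library flanks around a 22-nt
  randomized core (read length 70).
- **FACS events.** A mixture of bivariate log-normal populations;
  20,000 events by default, the standard acquisition floor for
  mean-fluorescence estimation.

Not emulated: per-cycle quality/error profiles, PCR duplicates, real LTR/
adapter structure, chimeric reads, spillover between channels. Passing tests
demonstrate estimator correctness under the planted model, not robustness to
those artifacts.

All draws descend from `SimConfig.seed` through fixed per-operation salts,
so a fixed config reproduces byte-identical files.

## Reporter assays

Gates are the per-channel empirical percentile of a negative control
(default 99.5%), defined as the order statistic at index `ceil(p·n) − 1`;
an event is channel-positive iff strictly above the threshold, so boundary
equality counts as background. Quadrants: Q1 GFP−/mCherry+, Q2 +/+,
Q3 −/−, Q4 +/−. Channel means are arithmetic means of linear-scale
intensities. Doubling time is `1/slope` of a least-squares fit of
`log2(OD − blank)` against time restricted to blanked OD ∈ [0.02, 0.4]
(below culture saturation, above the lag/noise floor); slopes under
10⁻⁹ doublings/min are reported as "no growth" rather than astronomically
long doubling times.

## SELEX analysis

Because the library's fixed flanks pin the register of the variable region,
the position frequency matrix is built by direct column counting with
additive smoothing (default pseudocount 0.5) instead of de novo motif
discovery — with a fixed register, discovery would only re-estimate the
same frequencies with extra variance. The alignment step is kept: the score
of placing the matrix at `(offset, strand)` is the summed frequency of the
target base in each overlapped column (the simplest monotone match score);
all offsets and both strands are searched, ties resolve forward-then-
leftmost, and the matrix is trimmed to the target's columns, reverse-strand
hits being reported in target orientation. Subsampling to 200 reads is
uniform without replacement and seeded.

## Amplicon indel calling

Reads are aligned globally with affine gaps (match +1, mismatch −2, gap
open −6, gap extend −1; a gap of length L costs 6 + (L−1)). The Gotoh
three-matrix recurrence is evaluated exactly (numba kernel); traceback is
deterministic with ties preferring diagonal, then vertical (extra read
base), then horizontal, and gap closure preferred over extension on equal
score. Scores are integer-valued in float64, so equality comparisons in the
traceback are exact. A read is indel-positive iff a gap overlaps
`[cut_start − pad, cut_end + pad)` (default pad 10 bp; lesions centre on
the break). Zero-width insertions count when the junction falls inside or
on either edge of the window. Reads under 60% identity over non-gap
columns (or shorter than 20 bp) are discarded as unscorable rather than
counted as negative.

The treated-vs-control comparison is a one-sided Fisher's exact test
(upper hypergeometric tail with margins fixed), adopted as the exact,
assumption-free test for 2×2 counts; the original study cites an external
test without reproducing it, so this is a documented substitution.
Bonferroni correction is `min(1, m·p)` with `m` the number of candidate
loci in the batch. A locus is *active* iff adjusted p < α (default 0.05)
and its frequency exceeds the cognate control's. Aggregate off-target
activity is the sum of active frequencies; the fold change versus a
comparator aggregate is reported rounded to the nearest integer, matching
how such fold decreases are quoted. On:off ratios with a zero off-target
frequency are reported as a lower bound against the batch's background
floor (default 0.1%, a GFP-control-scale frequency) rather than as
infinite.

## Off-target discovery

"Within 1 kb of each other" is implemented as single-linkage (transitive)
merging: two integrations share a cluster iff connected by a chain of
same-chromosome gaps each ≤ 1 kb; strand is ignored because capture can
insert in either orientation at one break. "Unique integration" means a
distinct (chromosome, position, strand) within one sample; read-level
multiplicity is retained as metadata only. The replicate filter keeps
clusters present in ≥ 2 of 3 treated and ≤ 1 of 3 control replicates
(both thresholds configurable). Ranking is a strict total order: total
unique treated integrations, then treated replicates present, then
treated:control ratio (zero control ⇒ ∞, ranked first), then coordinates —
so repeated runs and permuted inputs produce identical orderings. Dimer
annotation scans cluster ± 250 bp exhaustively for half-site A (+ strand) +
spacer ∈ [4, 7] bp + half-site B (− strand) in both half-site orders,
counting Hamming mismatches per half-site (default ≤ 3); 4–7 bp is the
standard obligate-dimer nuclease geometry.

A scaling property worth knowing: the expected number of coincidental
background clusters passing the replicate filter grows as
(per-bp density)² × genome size × merge distance. At genome scale
(~10³ integrations in 3 × 10⁹ bp) such coincidences are rare, but a
megabase toy at the same *count* is ~10³ times denser per bp and produces
~1 spurious candidate per run. Tests of background behaviour therefore fix
the per-bp density, not the count; spurious candidates in planted runs are
benign because planted sites outrank them.

## Orchestrated run

`run_full` chains discovery and validation on one synthetic study: each
candidate locus gets simulated treated reads at the locus's true planted
rate (0 for spurious clusters) and control reads at the background lesion
rate (default 0.1%), then indel calling, Fisher tests, Bonferroni over the
candidate batch, and the specificity report. Validation depth defaults to
5,000 reads per locus — realistic amplicon depth, and enough power to
separate a 0.4% lesion from a 0.1% background after correction. Every
artifact is listed in a manifest with SHA-256 checksums, the seed and a
hash of the study parameters (the output path is excluded from the hash),
making a rerun byte-identical.

## Problem sizes

The test suite and acceptance script use: 2–16-Mb toy genomes; 3 + 3
replicates with five planted sites at intensity 5 over ~960 background
integrations (20 seeds) for recovery; 5,000 reads per locus for indel
calibration at planted rates {0, 0.4, 30, 60}%; 200 sampled SELEX reads
from 3,000-read pools with 20% contaminants; exhaustive Fisher checks over
all 2×2 tables with row totals ≤ 50; and 1,000 random clustering instances
of ≤ 200 integrations against a transitive-closure oracle.

## Known limitations

Junction mapping is exact-match on a toy genome; real screens should map
with a production aligner and enter the pipeline as BED. The Fisher test
treats reads as independent draws (no overdispersion across PCR
replicates). The indel caller scores presence/absence only — no allele
spectrum, no HDR. PFM alignment assumes the matrix is at least as long as
the target. Percentile gates assume single-mode background fluorescence;
no compensation/spillover correction is attempted.
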