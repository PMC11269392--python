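# Methods

This note documents the models, parameter defaults, numerical choices
and known limitations of `cnsmeth`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Low-pass nanopore whole-genome sequencing of tumor tissue (~0.5X)
produces two usable signals: per-CpG methylation fractions (beta values)
at whichever CpG sites the reads happened to cover, and genome-wide read
depth. The first drives methylation-based tumor classification against a
reference atlas of binary CpG profiles with a class taxonomy grouped
into families; the second drives binned copy-number profiling and, when
the tumor carries numerical chromosomal alterations, purity estimation.
The defining difficulty on the classification side is extreme, run-
dependent missingness: a case may cover under 1% or over 80% of the
atlas sites, so the classifier must be trained to be indifferent to
which subset it sees.

## Feature stage

* Beta values are binarized at **0.6, boundary methylated** (beta of
  exactly 0.6 counts as methylated).
* Zero-variance atlas columns (constant across all reference samples)
  are removed before training; the filter preserves column order and is
  idempotent.
* CpG identity is `(chrom, start)` on **0-based half-open** coordinates
  throughout (bedGraph/BED dialect). Atlas and case files must share the
  dialect; the parser validates coordinates and rejects duplicate sites
  as errors rather than keeping the last record, because duplicates
  indicate an upstream merge bug.
* QC: a case must overlap the atlas at **≥ 1,000 CpGs** (inclusive,
  configurable). Failure is a warning gate — the clinical remediation is
  an additional sequencing run — so classification is still attempted
  and marked low-confidence.

## Masked-feature network

The atlas gives fully observed binary training vectors; deployment
vectors are mostly missing. Training therefore re-masks every sample
each epoch: a per-sample mask rate is drawn uniformly from
**[0.3, 0.99]** (spanning realistic sparsity) and that fraction of
features is hidden. Hidden and missing features share one encoding —
the value channel is set to 0 and a parallel binary observed-indicator
channel is set to 0 — so "unmethylated" (value 0, observed 1) remains
distinguishable from "unobserved" (0, 0). With a mask-rate range of
[0, 0] the procedure reduces to standard supervised training.

Architecture and schedule (all config-exposed): one hidden layer of 256
ReLU units, softmax output over classes, cross-entropy loss, Adam
(lr 1e-3, weight decay 1e-5), 30 epochs, batch size 16, stratified 80/20
train/validation split. The network is implemented directly in numpy;
it is small enough that a deep-learning framework would add nothing but
a dependency. All randomness flows from a single seeded generator, so
identical seeds give identical models. Non-finite losses abort training
with diagnostics; a held-out accuracy below the configured target (0.9)
raises a convergence warning rather than failing silently.

Scores: logits are divided by a temperature fitted by minimizing
held-out negative log-likelihood (the held-out samples are replicated
under the training-time masking distribution so calibration matches
deployment sparsity), then softmaxed. Family scores are exact sums of
member class scores — a linear partition operation, so they conserve
probability mass and are invariant to class order. Top calls break ties
lexicographically and flag them; the top class and top family are
independent calls and may disagree.

## Cutoff calibration

Passing is **strictly greater than** the cutoff. Two sensitivity
conventions are computed side by side: the operational tp/n (fraction of
all cases that pass and are correct — the convention behind the bundled
cohort's 15/19 → 79% with 100% specificity) and the conventional
tp/(tp+fn). Both are reported; they differ whenever concordant cases
fall below the cutoff. Cutoff selection sweeps the distinct-score
intervals (confusion is piecewise constant under the strict rule),
maximizes operational sensitivity subject to 100% specificity, and
returns the midpoint of the optimal interval together with its
endpoints, because a finite cohort only ever pins the cutoff to an
interval — on 19 cases no single value is canonical, and a fixed 0.2
override is available.

## Copy number

* **Binning**: fixed-width tiling (default 1,000 kbp, matched to
  low-pass depth); input intervals are assigned to the bin containing
  their midpoint; bins below a count floor (default floor 10 for
  normal-reference profiles, no floor for tumors) and zero-count bins
  are masked.
* **Normalization**: log2 of count over the unmasked autosomal median.
  GC/mappability correction is omitted by default — the synthetic data
  carry no GC bias — and would slot in between binning and
  normalization.
* **Reference subtraction** is done in log space (the difference of
  log2 ratios), chosen over count space for symmetry and scale
  invariance; masked bins propagate.
* **Segmentation**: recursive binary splitting. At each step the
  breakpoint maximizing the pooled two-sample t statistic is accepted if
  its within-segment permutation p-value (default 200 permutations,
  fixed seed) is below alpha (default 0.01), then both halves recurse;
  minimum segment length 5 bins. Maximizing |t| is algebraically
  equivalent to minimizing the two-segment squared error, which is what
  the brute-force oracle in the tests checks. An off-scale statistic
  from a zero-variance (noiseless) step is accepted at the resolution
  floor of the permutation test. Segments are contiguous per chromosome;
  masked bins are carried but do not contribute to means.
* **Focal events**: segments no wider than 10 Mb whose mean deviates
  from the length-weighted mean of their flanking segments by ≥ 0.15
  log2 are reported with overlapping BED annotations; whole-chromosome
  changes are excluded by the width filter.

## Purity

For cellularity α and tumor ploidy P (grid default: α 0.05–1.00 step
0.01, P fixed at 2; an extended ploidy grid is available with
lowest-ploidy tie-breaking), a segment of integer copy n has expected
log2 ratio `log2((αn + 2(1−α)) / (αP + 2(1−α)))`. The fit error is the
length-weighted mean squared distance of segment means to their nearest
integer state in 0..8, and the estimate is the grid argmin.

Two numerical guards matter:

1. **Half-cellularity degeneracy.** Any fit at α is reproduced exactly
   at α/2 with copy offsets doubled (n → 2n − 2), so the error landscape
   is self-similar and the bare argmin is decided by floating-point or
   sampling noise. Exact near-ties are broken toward the lowest ploidy,
   then the *highest* cellularity (the parsimonious branch). In
   addition, copy number 0 is disallowed for segments wider than 30 Mb:
   a homozygous deletion spanning tens of megabases is not compatible
   with cell viability, and that state is precisely what the spurious
   half-branch needs to absorb whole-chromosome losses. Without this
   guard the half-branch occasionally wins when small spurious segments
   fit its denser copy-state lattice.
2. **Identifiability.** Estimation requires numerical chromosomal
   alterations. The fit is declared unidentifiable — cellularity absent,
   not defaulted — when the aneuploid genome fraction (length with
   |log2| ≥ 0.1) is below 5%, or when the error profile is flat across
   the cellularity grid. Near-diploid tumors (e.g. most pilocytic
   astrocytomas) land here by design.

## Synthetic data

The generator emulates the three data layers with known ground truth:

* **Reference atlas**: binary CpG × sample matrix; each class has a
  disjoint signature block (default 100 CpGs of a 5,000-CpG atlas, 8
  classes × 20 samples) methylated with probability 0.9 against a 0.1
  background. Disjoint blocks make the Bayes error effectively zero, so
  classifier accuracy targets are analytic; a `signature_overlap`
  parameter makes the task harder when needed. Classes partition
  contiguously into families (default 3).
* **Sparse observations**: n CpGs sampled uniformly without replacement;
  beta = clamp(state + N(0, sd), 0, 1). The truncated-Gaussian noise is
  the simplest model that exercises the 0.6 binarization boundary. Real
  atlases are built from beta-valued array data whose pre-binarization
  distribution is bimodal rather than two-point; the generator models
  binary states plus noise only.
* **Bin counts**: expected count per bin is
  `mean_count · (α·CN + 2(1−α)) / 2` over a configurable toy genome
  (default 2 chromosomes × 50 Mb; hg19 sizes bundled for realistic
  runs), drawn negative-binomially with variance μ + φμ², exactly
  Poisson at φ = 0.

Study conditions used by the tests and the acceptance script: the
classifier suite runs on the default 8 × 20 × 5,000 cohort; the purity
suite uses a 1,000-bin genome (10 × 100 Mb) with CN 1 on one chromosome,
CN 3 on another and CN 1 on 40% of a third (~24% aneuploid fraction),
cellularities {0.25, 0.40, 0.65}, mean 800 reads per bin with dispersion
0.002 (per-bin log2 noise ≈ 0.06, the regime the recovery property
targets), 20 replicates per cellularity. These sizes keep the whole
suite in tens of seconds on one CPU.

What passing these tests shows — and does not. The synthetic cohort has
no batch effects, no covariate shift between reference and cases, no
correlated missingness (real nanopore coverage clusters along the
genome), no GC bias and a clean class structure. Green properties here
validate the machinery (encoding, masking, aggregation, segmentation,
grid fit), not clinical performance on real specimens.

## Bundled cohort table

`data/ua_cohort.tsv` transcribes a published 19-case pediatric
ultrasonic-aspirate cohort (demographics, reference diagnoses,
microarray and nanopore MC/MCF calls with scores). Its `concordant`
column follows the source's accounting: equality with the microarray
class where available, compatibility with the reference diagnosis for
the two cases without microarray results — 17/19 concordant, with the
two discordant cases scoring 0.07 and 0.08. Plain string equality of the
two call columns would give 15/19 (it cannot count the two
microarray-N/A cases); `summarize_cohort` works from explicit
`ScoredCase` inputs so either convention can be passed in. One
source-internal inconsistency is preserved as printed: the table rows
contain 6 male patients while the source text reports 7.

## Known limitations

* The classifier's "normalization function" before the softmax is
  realized as temperature scaling; depth, width, masking distribution
  and schedule are package choices where the underlying method left them
  open, and are all config-exposed.
* Segmentation is recursive binary splitting, not full circular binary
  segmentation; on profiles whose breakpoint signal is weak (short
  interior segments at borderline amplitude) a split can be missed at
  the default alpha.
* Purity fitting assumes a diploid admixture and, by default, tumor
  ploidy 2; whole-genome doubling is only addressable through the
  extended ploidy grid and remains underdetermined on toy genomes.
* The pipeline starts at methylation calls and binned counts;
  basecalling, alignment and methylation calling are out of scope, as
  are t-SNE visualization and microarray processing.
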