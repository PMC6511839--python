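# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `onecell-dge`, and what the simulation-based tests do and
do not demonstrate about real data.

## Multiplex index design and decoding

Indexes are fixed-length DNA words (default L = 8) whose minimum
pairwise Hamming distance d guarantees correction of up to
⌊(d−1)/2⌋ substitutions. The designer is a deterministic greedy
lexicographic scan: enumerate all 4^L words in alphabetical order
(A < C < G < T) and retain each word whose distance to every previously
retained word is ≥ d. At (L = 8, d = 3) the exhaustive scan retains
1024 words — far more than the ~100 a multiplexed experiment needs —
and the greedy construction is reproducible by anyone from the
description alone, which is why it was preferred over table lookup or
randomised search. An optional homopolymer filter rejects candidates
with runs ≥ k before the distance check.

Decoding returns the unique index within `max_correct` (default 1)
substitutions of the observed word. Two policies are deliberate:

* **ties are never guessed** — if two indexes tie at the minimal
  qualifying distance the read is unassigned, because mis-assigning a
  read to the wrong cell is worse than losing it;
* **N bases mismatch everything**, so an index read with more than
  `max_correct` Ns is necessarily unassigned.

Demultiplexing may decode on a prefix of the stored index
(`effective_index_len`, e.g. 6 of 8 bases). The truncated set's own
minimum pairwise distance then governs its error tolerance, which the
`IndexSet.truncated` constructor recomputes and records; 6-base
prefixes of a distance-3 set may correct nothing, and the package makes
that explicit rather than silently assuming single-error correction.

## Read processing

The 20-nt index read is trimmed to 18 nt from the 3′ end, split into
index (first 8) and UMI (last 10) — the layout is a flag because some
protocols reverse it — and the UMI is appended to the read1 name as
`<id>_UMI:<umi>`, using the first whitespace token only so the name
survives the SAM QNAME round trip.

Read1 trimming mirrors common short-read practice: optional 3′ adapter
clipping (full internal occurrence, or a terminal adapter prefix of at
least 7 bases — a simplification of palindromic adapter trimming that
keeps the minimum-overlap semantics), removal of 3′ bases below Q20,
truncation at the first 4-base window with mean quality below 15, and
discarding reads shorter than 30 nt. Quality trimming is idempotent and
never lengthens a read; the demultiplexing report accounts every input
pair as assigned-and-written, assigned-but-dropped, or unassigned, so
`Σ assigned + unassigned = total` always holds.

Reads whose UMI contains N are kept at demultiplexing (flagged in the
report) and discarded at unification, where grouping them would be
ambiguous.

## Gene assignment and UMI unification

Alignments against a transcript reference (SAM; any aligner) are
resolved to genes via a many-to-one transcript→gene map. Multiple hits
to transcripts of the same gene collapse to one assignment. Reads
hitting more than one gene follow a policy, default **discard**:
without a probabilistic multi-mapping model, dropping such reads is the
conservative choice and is tallied explicitly. Positions are recorded
1-based per the SAM convention but are *not* part of the unification
key.

Unification counts distinct UMIs per gene within a sample. The key is
(gene, UMI) exactly: no Hamming-1 UMI merging is performed, a fidelity
choice that keeps counting transparent; the simulation tests document
the resulting known bias (UMI sequencing errors can only inflate
counts). A representative read per (gene, UMI) group is chosen
uniformly at random under a seed — mirroring "pick one read per
duplicate group" — and the counts are provably independent of that
seed.

The per-sample statistics are mapped reads, mapping rate, UMI counts
(column sum), detected genes (counts ≥ 1), and the UMI-unified rate
(mapped − UMI)/mapped — the fraction of mapped reads removed as
duplicates. The central invariant, verified end-to-end in the tests, is
**duplication invariance**: replicating every molecule's reads m-fold
leaves the count matrix bit-identical while multiplying mapped reads by
m.

A toy aligner (exact first-31-mer seed, leftmost occurrence, secondary
records for additional hits) makes the pipeline self-contained at test
scale. It is not a general mapper: no mismatches, no indels, no
quality awareness. Real libraries should be aligned externally and fed
in as SAM.

## Saturation

Detected genes and the UMI-unified rate are recomputed on uniform
without-replacement subsamples of a sample's gene-assigned reads
(sampling *mapped* reads, since both statistics are defined relative to
mapped reads), at a grid of depths with replicate draws from a spawned
seed sequence. Both statistics are monotone non-decreasing in
expectation; the full-depth row is computed on the identity subset and
therefore reproduces the unsubsampled statistics exactly. Only
interpolation is offered — extrapolating library complexity beyond the
observed depth is a different estimation problem and is out of scope.

## QC screen

The screen uses the four standard configured quantities — maximum
false-positive rate (0.05), TPM cutoff (1), Spearman and Pearson test
p-value thresholds (0.001) — with an explicitly simplified rule, since
the original screening program's internal algorithm is not public in a
reimplementable form:

* per sample, compute detected genes at TPM ≥ cutoff, the mapping rate,
  and the best-partner Spearman ρ and Pearson r (on log2(TPM+1), each
  against its most-correlated other sample) with t-approximation
  p-values;
* a sample is a **failure candidate** when both correlation tests are
  non-significant at the thresholds — even its best partner looks
  unrelated;
* at most ⌊max_fpr · n⌋ candidates fail, worst best-partner ρ first.
  The cap bounds the number of flags at the nominal false-positive
  budget under an exchangeable null;
* technical metrics (detected genes, mapping rate) are reported with a
  lower-tail warning flag but never fail a sample alone: a genuinely
  uncorrelated sample can have unremarkable technical metrics, and
  conditioning failure on a technical lower tail would let it evade the
  screen.

TPM uses per-gene effective lengths where supplied and a default of
1000 otherwise — tag counts are 3′-anchored, so length normalisation is
a mild correction, not a model commitment. All QC-facing correlations
and fits use log2(x + 1); the pseudocount convention is stated so every
R² in the outputs is reproducible. Replicate concordance is the R² of
an OLS fit in that log space over genes detected in either replicate.
Spike-in linearity regresses log2(UMI + 1) on log2(nominal
concentration) over ERCC-named rows, keeping zero-count species as
pseudocount points and additionally reporting the fit with them
excluded; proportional capture gives slope 1 and library-size scaling
moves only the intercept.

## Normalisation and differential expression

**TMM.** For each sample against a reference column (auto-chosen by the
upper-quartile rule), M = log2 ratio and A = mean log2 abundance of
library-size-normalised counts are computed over genes positive in
both; the 30%/30% extreme M and 5%/5% extreme A ranks are trimmed; the
factor is 2 to the weighted mean of the surviving M values with
inverse-asymptotic-variance weights; factors are rescaled to geometric
mean 1. The implementation was cross-checked against the Bioconductor
reference implementation on a fixture and agrees to 6 decimals (frozen
in the test suite).

**Exact NB test.** Counts are moment-match scaled to the geometric-mean
effective library size and rounded (full quantile matching was judged
not worth the added opacity at tag-count depths); per gene the group-A
total given the overall total follows a negative hypergeometric law
when per-sample counts are NB with common dispersion φ (sizes n/φ and a
shared probability parameter that cancels on conditioning). The
two-sided p-value sums all splits with conditional probability ≤ that
of the observed one (minimum-likelihood rule, tie mass included, with a
1e-10 relative tolerance against floating-point ties). φ = 0
degenerates to the conditional binomial split. The dispersion is a
user parameter (default 0.1); tagwise/trended empirical-Bayes
estimation is deliberately not reimplemented — the test's calibration
under a known common dispersion is what the package guarantees
(simulated null type-I error at α = 0.05 stays within [0.03, 0.07]).

**iDEGES.** The iterative DEG-exclusion strategy runs, per iteration:
TMM on the current gene set → exact test of all genes → mark putative
DEGs at q < 0.1, or the top 5% by p-value when fewer qualify
(floor rule) → recompute TMM on the complement, expressing subset
factors against full library sizes and re-centring to geometric mean 1.
Three iterations by default; zero iterations is exactly plain TMM. On
simulations with 20% one-sided 4-fold DEGs the looped factors land
closer to the true depth ratio than plain TMM in ≥ 80% of runs.

**DEG calling.** Final q-values are Benjamini–Hochberg (step-up with
monotonicity, via statsmodels); genes pass at q < 0.01 by default.
m = log2 fold change of mean normalised CPM (prior 0.5 per group to
keep zero means finite), a = mean log2 abundance; the ranking is a
total order by (q, p, |m| descending), ties broken deterministically by
the row order of the input matrix. All-zero genes are reported NA and
never tested.

## Hoeffding's D

D is computed from the classical rank formula
`D = 30·((n−2)(n−3)D1 + D2 − 2(n−2)D3) / (n(n−1)(n−2)(n−3)(n−4))`
with midranks and tie-weighted bivariate ranks (strictly-below pairs
count 1, single-coordinate ties ½, double ties ¼) — the ×30 scaling
puts the population maximum at 1, matching the convention of the
widely used R implementation, with the finite-sample range roughly
[−0.5, 1]. The implementation agrees with a definition-level O(n²)
brute-force oracle to 1e-12 including ties. p-values are by
permutation of y (default, add-one estimator) or by the asymptotic
null law of n·D/30 — a centred weighted sum of χ²(1) variables with
weights 1/(π⁴ j² k²) — evaluated by Gil–Pelaez characteristic-function
inversion truncated at j, k ≤ 50; the two agree to within Monte-Carlo
error at moderate n.

## qPCR utilities

Plasmid copy numbers use mass / (bp × 615 Da/bp / N_A) with the exact
SI Avogadro constant; the molar mass per base pair is the conventional
double-stranded value for these calibrations. Standard curves are OLS
of Cp on log10 concentration (≥ 3 points, positive concentrations,
non-degenerate design) and invert analytically; the implied
amplification efficiency 10^(−1/slope) − 1 is exposed. Missing
transcript-level values are imputed per transcript as one tenth of the
observed minimum. A sample-standard-deviation helper (n − 1
denominator) supports per-gene variability summaries.

## Synthetic data generator

The simulator emulates a shallow multiplexed single-cell tag-counting
experiment:

* per-gene level λ_g ~ LogNormal(μ, σ) drawn once (a fixed expression
  profile shared by all cells); per cell, true molecules ~ Poisson(λ_g)
  and captured molecules ~ Binomial(true, capture_rate);
* each captured molecule gets a uniform random 10-nt UMI; UMI
  collisions are real events the truth table records (distinct
  (gene, UMI) pairs per cell × gene is the quantity counting can
  recover, and E[distinct] = U(1 − (1 − 1/U)^m) for m molecules,
  U = 4^10, is verified against simulation);
* reads per molecule ~ Geometric(p_dup) on {1, 2, …} (mean 1/p_dup):
  one parameter with a heavy tail stands in for the unknown
  amplification-cycle distribution; p_dup = 1 means no duplication;
* read1 is an 80-nt fragment at a uniform start within the transcript
  (no positional bias by default); the index read is
  index + UMI + 2 random bases with independent per-base substitution
  rates for the three segments, zero by default;
* spike-in species (`ERCC-*`) follow a 2-fold concentration ladder and
  bypass the expression model (molecules ~ Poisson(conc × spike_scale),
  thinned by capture).

Defaults — 10 cells, 200 genes of length 500, μ = ln 25, σ = 1,
capture 0.6 (≈ 5000 captured molecules per cell in expectation),
p_dup = 0.3, error-free reads — describe the regime the package's
guarantees address: a small multiplexed run deep enough for heavy PCR
duplication. The acceptance-scale end-to-end checks (~150 000 reads)
run in seconds on one core; these problem sizes are the package's own
test design, chosen to exercise every code path at interactive speed.

What the simulator does **not** model — and what passing tests
therefore do not establish about real data: cycle-dependent base-quality
profiles and indel errors, 3′-positional bias of oligo(dT) priming,
chimeric/template-switching artifacts, cross-cell index hopping,
transcript-level ambiguity beyond exact k-mer sharing, and empirical
dispersion structure of real biological replicates. The error-free
exactness results are statements about the counting algebra, not about
aligner or chemistry robustness.

## Known limitations

* No UMI error correction: counts inflate under UMI sequencing errors
  (quantified in the tests); graph-based merging is deliberately out of
  scope.
* Multigene reads are discarded by default rather than probabilistically
  resolved; transcript-level (isoform) abundance estimation is not
  provided.
* The QC screen is a documented simplification, not a reimplementation
  of any published screening program's internals.
* The exact test's common dispersion is supplied, not estimated; with
  badly misspecified φ the type-I calibration degrades.
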