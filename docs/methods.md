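# Methods

## Model and procedure

`circmotif` infers how a circular RNA (circRNA) regulates gene expression
from knockdown experiments, in six coupled stages.

**Gene ranking.** Each knockdown experiment is summarised per gene by a
DESeq2-style table (log2 fold change, p, adjusted p). The signed DE score is
s = −log10(p) · sgn(log2FC); log2FC = 0 yields s = 0 (the direction function
is undefined there) and p is floored at 1e−300 so scores stay finite when
upstream tools emit p = 0. Genes are classified down / up / notDE by
adjusted p < 0.1 (Benjamini–Hochberg; adjusted values supplied in the table
are used verbatim, recomputation is opt-in). A `fold_change` ranking mode
exists for public knockdown compendia whose per-gene p-values are not a
usable ranking.

**k-mer scoring.** Circular k-mer enumeration produces exactly L windows
for a circle of length L (wrap-around across the backsplice junction),
L − k + 1 for a linear sequence. For each unique circRNA 7-mer, genes whose
3′UTR contains it at least once (exact match; presence, not counts) are
compared to the remaining genes by a two-sided Wilcoxon rank-sum test on
the DE score; the motif score is −log10(p) with a negative sign when the
carrier group's mean rank lies toward down-regulation. The statistic is a
deliberate, documented stand-in for Markov-chain-based motif–expression
correlation machinery: it preserves the sign semantics and the ranking
behaviour while being exactly testable; its absolute values are not
comparable to that machinery's scores, and whether such tools use presence
or counts is not specified in our sources, so presence was chosen and fixed.
The carrier/non-carrier test uses a tie-corrected normal approximation
computed from a single precomputed rank vector (needed to score ~10^3
k-mers over 10^4 genes quickly); universes below 50 untied genes use exact
enumeration. The universe is always the intersection of DE-table genes and
UTR records, and is logged. A gene-label permutation null (add-one
estimator, minimum p = 1/(n_perm+1), seeded) calibrates the statistic;
k-mer groups below `min_genes` (default 10) are flagged NA with a reason
rather than scored.

**Consensus assembly.** The top-N (default 10) most negative 7-mers are
aligned greedily: the best-scoring k-mer anchors the consensus; remaining
k-mers are placed at the offset minimising mismatches against the column
base sets observed so far, requiring at least k − 1 aligned columns (a
one-base shift — the tightest overlap among genuinely shifted k-mers; an
unconstrained offset range would let an unrelated k-mer "place" on a 1-nt
overlap). Placement is mismatch-tiered and multi-pass: all zero-mismatch
placements are exhausted (repeating until stable, so a k-mer two shifts
from the anchor joins once the consensus has grown toward it) before any
one-mismatch placement is admitted — otherwise a mid-motif anchor can trap
a k-mer in a wrong one-shift placement. Ties break toward fewer mismatches,
then smaller |offset|. K-mers that never fit the budget (default 1) are
reported unplaced, never dropped. Columns with more than one observed base
become IUPAC degenerate codes. Terminal columns that are degenerate are
trimmed iteratively: they arise when k-mers extending past the true motif
boundary drag in heterogeneous flanking bases (a real phenomenon — a
boundary 7-mer shares 6 informative bases with the motif and is genuinely,
if more weakly, enriched), and a terminal position with conflicting
single-pass support carries no consensus information. A degenerate position
that is *internal* (like the W of `AGGCCCCCWGC`) is never trimmed. Known
limitation: a truly degenerate terminal motif position, or a boundary
extension supported by only one k-mer (hence non-degenerate), would survive
or perish incorrectly; both require evidence this procedure does not model.

**Scanning and enrichment.** The consensus is scanned over 3′UTRs allowing
up to 2 substitutions; a base matching a degenerate letter's IUPAC set
contributes zero mismatches; overlapping matches are all reported; scanning
is single-strand; coordinates are 0-based half-open throughout (BED
convention); RNA input is normalised U→T once on ingestion. Presence is
cross-tabulated against DE classes with Pearson's chi-square (1 df,
uncorrected by default — it equals the closed form n(ad−bc)²/∏margins,
which the tests exploit; Yates is a flag, and at the group sizes involved
the difference is negligible). A zero margin triggers an automatic,
logged Fisher fallback. Gene-set overlaps use the one-sided hypergeometric
(Fisher) tail. The bipartite recognition element `CTCAC-(N10–15)-WGGW`
(the KH34-domain high-affinity element of the IGF2BP family, RNA alphabet
mapped to DNA) is scanned by explicit spacer-length enumeration so every
valid spacer is reported.

**CLIP corroboration.** Peaks are kept when linear fold-enrichment over the
size-matched input is ≥ 8 ("at least" read as boundary-inclusive; the
threshold is applied to the log2 column as ≥ 3) and peak length ≥ 4 nt. A
gene counts as bound by an RBP when a kept peak overlaps one of its 3′UTR
intervals by ≥ 4 nt on the same strand. Interval overlap uses a sorted
two-pointer sweep, cross-checked against the naive all-pairs oracle in the
tests. Peak–motif overlap requires ≥ 1 nt (configurable; no minimum width
is defined by the protocol descriptions we follow). Cross-knockdown
concordance tabulates, for genes down (resp. up) in experiment A, the
fraction down/up/notDE in experiment B over the shared gene universe.

**Sponge control and stoichiometry.** Seed sites are exact 7-mer matches
(overlapping occurrences counted at every start); per-miRNA down-vs-up
enrichment is BH-corrected across miRNAs at 0.1, and "no sponge evidence"
is emitted iff no miRNA passes. The miRNA-vs-non-miRNA k-mer score
comparison reports the rank-biserial effect magnitude |2·AUC − 1|. qPCR:
Ct is regressed on log10(copies) (≥ 3 dilution points required); efficiency
E = 10^(−1/slope) with a (1, 2.2] sanity band (warn only); sample copies
are 10^((Ct − intercept)/slope), divided by cell-equivalents
(n_cells × assayed fraction — "0.033%" is treated as the single assayed
fraction 3.3e−4, giving 264 cell-equivalents for 0.8e6 cells). Replicates
are averaged on the copy scale, not the Ct scale, because copies are the
quantity of interest and Ct is logarithmic; the CI is a t-interval over
replicate copy estimates (a choice of ours — only point values are
conventionally reported). Densitometry inverts a linear intensity-vs-mass
calibration, converts ng → molecules via a user-supplied molecular weight
(never a bundled constant) and Avogadro's number; negative back-computed
masses clamp to 0 with a warning. X0 relative levels are E^(−Ct) ratios.
The molar-ratio verdict flags 1:1 ceRNA sequestration as implausible above
a 100-fold protein excess (configurable).

## Synthetic data: what it emulates and what it does not

The generator plants a degenerate 11-mer (`AGGCCCCCWGC`, W resolved A/T per
instance) into a random circRNA (both variants, so the circle's k-mer set
covers the degeneracy) and into 8% of 10,000 gene UTRs (one instance each,
uniform position). UTR lengths are log-normal (mean 500 nt, sd 300 nt,
floor 50 nt) with GC 0.45, typical of human 3′UTRs. Experiment A shifts
motif-gene log2FC by −0.8, experiment B by +0.8 (the anti-correlated
knockdown pair); per-gene noise is N(0, 0.3) and p-values follow
p = 2Φ(−|log2FC|/0.25), a smooth Wald-like stand-in whose ranking is all
that matters downstream. CLIP peaks cover planted instances with
probability 0.75 (padding 0–14 nt per side, log2 fold-enrichment
3 + Exp(1), i.e. always past the 8-fold filter); 800 decoy peaks are placed
uniformly. Half the simulated miRNA seeds are drawn from the circRNA's own
7-mers (mirroring that a fraction of circRNA k-mers coincide with real seed
sites), none with a planted class association. Calibration panels use truth
45 circRNA copies/cell (E = 1.95, Ct noise 0.15, triplicates, dilutions
from 2.5e7 molecules/reaction) and 216,000 protein copies/cell (66 kDa
stand-in MW, 1e6 cells/lane, 5–100 ng ladder). Identical config + seed
reproduces byte-identical files; truth lives in a JSON sidecar.

Not emulated: read-level noise (no FASTQ/counts), gene–gene correlation,
dispersion structure, multiple instances per UTR, secondary-structure
effects on binding, genomic (multi-exon) UTR coordinates, or miRNA
expression levels. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability under the planted model, not
performance on real knockdown data, where effect sizes are smaller, noise
is heavier-tailed, and motif instances cluster non-uniformly.

## Numerical choices

- p-value floors: 1e−300 before log10 in DE scores; rank-sum p floored at
  the smallest positive double only to avoid −log10(0).
- Chi-square is refused (Fisher fallback) on zero margins; groups must be
  disjoint and nonempty.
- BH adjustment delegates to statsmodels; a brute-force step-up oracle
  guards it in the tests.
- Scanning is vectorised per sequence (per-position boolean lookup tables
  over an ASCII-encoded array), identical by construction and by test to
  the O(L·k) sliding Hamming oracle.
- Degenerate inputs error early with the offending column/row named:
  k > L, empty k-mer lists, mixed k, malformed intervals, invalid
  proportions, ≤ 2 dilution points, non-positive calibration slopes.
- Problem sizes: the shipped study conditions (10,000 genes, ~1,000 unique
  circRNA 7-mers, 1,000-permutation nulls over 200 k-mers) keep a full
  pipeline run under ~10 s and the whole test suite under a minute on one
  CPU.

## Open design points, resolved

- The expressed-gene pre-filter used upstream of DE analysis operates on
  raw counts this package does not model; an expressed-gene whitelist can
  be imposed by subsetting the DE table before classification.
- Whether the 8-fold eCLIP filter applies to the linear or log2 column of
  released peak files is ambiguous in the protocols we follow; the filter
  is defined on the linear scale and the input scale is declared by the
  reader (log2 in the BED6+2 extra column).
- The CLI exists as a thin wrapper because the pipeline is also a
  reasonable shell tool; the library API is the primary surface, and the
  examples are the reference usage.
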