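# Methods

`bromoscreen` implements the computational chain for asking whether a tumor
type is preferentially sensitive to bromodomain (BRD) versus histone-
acetyltransferase (HAT) domain inhibition of EP300/CBP. The chain has three
legs: comparative dose-response screen analytics, spike-in-anchored RNA-seq
normalization and differential expression, and integration of drug-
downregulated genes with CRISPR dependency and interaction-network data.
Every stage consumes plain-text inputs and is exercised against synthetic
data with known ground truth.

## Screen analytics

**Model.** Each cell line x compound viability curve is summarized by a
normalized trapezoidal AUC over log10(dose):

    AUC = ( ∫ v(log10 d) d log10 d ) / (log10 d_max − log10 d_min)

so an unaffected line scores exactly 1 and a fully killed line 0. Viability
(fraction of control) is clipped to [0, 1.2] before integration; the cap
bounds growth-stimulation artifacts and is configurable. The trapezoid was
chosen over a 4PL-fit AUC because it is parameter-free, monotone in
viability, and makes the flat-curve identities exact.

Per compound, AUCs are median-normalized across all lines in the analyzed
table (the normalized vector has median exactly 1; even-length medians are
the mean of the two central order statistics). The comparative statistic is
the per-line ratio

    ratio = norm_AUC(BRD inhibitor) / norm_AUC(HAT inhibitor),

with strict thresholds: ratio < 0.8 calls the line BRD-preferential (the
BRD inhibitor suppressed growth relatively more), ratio > 1.2 calls it
HAT-preferential, boundary values are neutral. Median normalization makes
the ratio invariant to rescaling either compound's raw AUCs, which is the
point: the two screens need not have been run simultaneously or at matched
potency. Lineage summaries report the per-lineage median ratio and drop
lineages with fewer than 3 lines. Normalization is always within the table
provided to the call; a small validation panel is therefore normalized
against itself, not against an external screen.

**Parameters.** `hi`/`lo` thresholds (1.2/0.8), viability cap (1.2),
`min_n` per lineage (3). Dose grids are molar and strictly increasing;
curves need at least 2 doses.

## Spike-in-anchored expression normalization

**Lengths and TPM.** Gene length is the union of all exon intervals across
all isoforms (GTF is read 1-based inclusive and converted to 0-based
half-open; strand is ignored for length). TPM per sample is

    rate_g = count_g · read_length / length_g,
    TPM_g  = rate_g · 1e6 / Σ_g rate_g,

with spike-in rows included in the normalizing sum. The read length (default
100 bp) cancels within a sample and is kept only because the quantity is
conventionally written that way; column sums are exactly 1e6.

**Loess normalization.** Samples are made comparable with an MA-style loess
fitted *only* on spike-in rows. The reference is the per-row geometric mean
of TPM across samples. For each sample, M = log2(sample) − log2(reference)
is regressed on A = (log2(sample) + log2(reference))/2 over the spike-ins,
using locally weighted linear regression (span 0.5, 4 robustifying
iterations, `statsmodels` lowess); the fitted trend is evaluated at every
row's A value — constant extension beyond the spike-in A range — subtracted
from all rows, and the matrix back-transformed. A pseudocount of 0.5 TPM is
added before the log and removed afterwards (output clipped at 0).

Because spike-ins are added per cell at fixed abundance, this removes
technical between-sample trends while *preserving* genuine global shifts of
the endogenous transcriptome — the transcriptional-amplification signature
that ordinary library-size normalization silently erases. A planted global
x2 shift of one sample is flattened on the spike-ins (mean |M| ≈ 0.01 in the
noise-free planted-shift construction), while an endogenous-only x2 shift
survives normalization (median recovered ratio within 10% of 2). On noisy
data the per-spike-in counting scatter dominates |M| (~0.25 at the
low-abundance end), so flatness there is a statement about the fitted trend
(per-sample mean M), not about individual spike-ins. The procedure is
idempotent to ~1e-3 log2 units on rows well above the pseudocount; rows near
zero relax this slightly because of back-transform curvature.

**Requirements.** At least 8 spike-ins with positive TPM per sample; the
reference-based (rather than pairwise-cyclic) fit keeps the output
independent of sample ordering.

## Control-gene negative-binomial differential expression

A compact DESeq2-style engine with spike-in-anchored size factors. It
approximates DESeq2's behaviour on simulated data; it does not reproduce its
exact numerics (no MAP dispersion estimator, no Cook's distance, no LFC
shrinkage, no independent filtering).

**Size factors.** Median-of-ratios restricted to control rows (spike-ins):
factor_s = median over controls g of count_gs / geomean_g, computed over
controls with no zero in any sample, rescaled to geometric mean 1. At least
8 eligible controls are required. Scaling one sample's counts by c scales
its factor by c relative to the others.

**Dispersions.** Per gene, a method-of-moments estimate on size-factor-
normalized counts, alpha_hat = (s² − mu)/mu², with the variance pooled
within conditions so real fold changes are not absorbed into dispersion. A
trend alpha(mu) = a0 + a1/mu is fit by non-negative least squares over genes
with mu ≥ 5 using the raw (unfloored) moment estimates, so floor censoring
does not bias it. The final value blends gene and trend estimates
geometrically (weight 0.5); genes whose moment estimate falls at or below
the floor (1e-8) carry no usable overdispersion information at small n and
take the trend value. This last rule matters: at 3 vs 3 roughly half of all
null genes have sample variance below their mean, and treating them as
near-Poisson would inflate the Wald type-I error severalfold. As
implemented, the null type-I error at alpha = 0.05 measures 0.047–0.065
across seeds (2000 genes, 3 vs 3).

**Wald test.** Per gene, NB GLM with log link, design intercept + condition,
offset log(size factor). The two-group structure gives closed-form 2x2
normal equations, solved by IRLS vectorized across genes; the standard error
comes from the expected Fisher information (Var(beta1) = 1/w_control +
1/w_treated with weights w = mu/(1 + alpha·mu)). log2FC = beta1/ln 2;
two-sided normal p. Genes with all-zero counts, or non-converged fits (eta
clipped at ±30; tolerance 1e-8; 100 iterations), get NA p-values and are
excluded from the Benjamini–Hochberg multiplicity count. Coefficients and
standard errors agree with per-gene `statsmodels` NB GLM fits to ~1e-4, and
planted log2FCs agree with `pydeseq2` to a median absolute difference below
0.25.

**Adjusted p and gene sets.** Benjamini–Hochberg step-up (the default of the
tool being emulated). High-confidence per-treatment sets require padj <
alpha with concordant direction in *every* cell line analyzed (≥ 2);
discordant or partially significant genes are excluded. Mismatched gene
universes are intersected with a warning.

## Dependency and network integration

Dependencies are genes with a Chronos-style effect score strictly below
−0.5 in at least 3 cell lines of the panel (the "more than 2 of 7" rule for
a seven-line panel; NA scores are ignored per line). The call is monotone in
the threshold. Drug-downregulated sets are intersected with the dependency
set; the overlap fraction |query ∩ dependency| / |query| is kept with its
2x2 counts, and fractions from two treatments are compared by two-sided
Fisher's exact test under the probability-ordering definition (all tables
with the observed margins whose probability does not exceed the observed
table's; `scipy.stats.fisher_exact`, verified exhaustively against full
enumeration for every table with N ≤ 30). Zero-margin tables return p = 1
with a warning.

Interaction networks are supplied as confidence-weighted edge lists (edges
below 0.4 — the "medium confidence" cut — are dropped; no remote service is
queried). For a gene set, the induced subgraph's edge count, mean degree,
connected fraction and largest-component fraction are reported, plus a
seeded permutation z-score of the edge count against size-matched random
node sets (degree matching is not attempted; a degree-preserving null is a
possible extension).

## Clustering and enrichment

**Elbow k-means.** For each k, best-of-restarts k-means (k-means++
initialization, fixed seed) records the within-cluster sum of squares; the
chosen k maximizes the distance from the min-max-normalized WSS curve to
the chord joining its endpoints (kneedle-style). Fully degenerate curves
(WSS ≈ 0 or flat within 1e-9) return the smallest k. Rows are standardized
(mean 0, sd 1) by default, the usual convention for fold-change heatmaps.
Two limitations are inherent to the scale-free elbow: a single noisy blob
still produces *some* elbow (only the exactly degenerate case returns
k = 1), and when planted clusters have very unequal separations the elbow
can prefer merging the closest pair. The planted-cluster test condition
therefore uses equidistant centers 10 noise-sd from the origin along random
orthonormal directions.

**Gene-set enrichment.** Exact hypergeometric upper tail,
p = P(X ≥ overlap) with X ~ Hypergeom(|universe|, |set|, |query|), BH across
sets — a self-contained over-representation test standing in for remote
enrichment services, and identical to the one-sided Fisher tail on the
corresponding 2x2 table (cross-checked in tests).

**Motif statistics.** Promoter sequences are scanned for an IUPAC consensus
(default CACGTG, the MYC/MAX E-box) with overlapping windows; with
both-strand scanning, positions matching the reverse complement are added
but a position matching on both strands — as every palindrome occurrence
does — counts once. Enrichment dichotomizes promoters as motif-positive
(≥ 1 match) and applies the two-sided Fisher test query vs background
(query sequences are removed from the background). Promoter window and
background choice are the caller's inputs. Under equal motif rates the
exact p-values are valid but discrete and conservative: they are
super-uniform, not uniform, so calibration is checked as
P(p < alpha) ≤ alpha (+ binomial slack), not as a two-sided uniformity fit.

## Synthetic data: what it emulates, and what it does not

All inputs can be generated with known ground truth; every generator is
seed-deterministic (identical config + seed gives bitwise-identical output).

* **Screen** — Hill-curve viability, v(d) = floor + (1−floor)/(1+(d/IC50)^h),
  over a 10-point log-spaced grid (1 nM–10 µM), with multiplicative
  lognormal noise (screen readouts are positive and heteroskedastic;
  default sigma 0.05, chosen for test power — pooled-screen noise magnitude
  is not a published quantity). Planted BRD-preferential lines have a
  100-fold lower IC50 for the BRD compound; base IC50s are lognormal around
  1 µM, slopes near 1, floors uniform on [0, 0.3].
* **Counts** — NB counts with dispersion trend alpha(mu) = 0.02 + 2/mu,
  lognormal baseline means (ln-mean 3.0, ln-sd 1.8), optional planted
  log2FCs (random sign) and a condition-level global multiplier on
  endogenous means only. A 92-member synthetic spike-in panel with
  log-uniform abundances over 2^0–2^15 (mimicking the dynamic range of a
  commercial mix without redistributing vendor data) has fixed per-cell
  abundance across conditions; per-sample technical depth (lognormal,
  sigma 0.1) multiplies all rows including spike-ins. Global shifts act on
  means before sampling. No read-level data or alignment is simulated.
* **Dependency** — Gaussian effect scores, planted genes around −1.0
  (sd 0.2), background around 0; the 7-line default uses the
  medulloblastoma panel names.
* **Graph** — planted dense module (edge probability 0.8 within, 0.02
  background), confidences uniform on [0.4, 1].
* **Promoters** — i.i.d. ACGT sequences; a configured fraction receives one
  planted motif insertion (chance occurrences remain, as in real promoters).

Passing tests on these data demonstrate that the statistics recover planted
truth under the stated generative models; they do not demonstrate
robustness to features the generators lack — batch structure, GC/length
bias, correlated genes, degree-structured networks, outlier samples, or
non-lognormal screen noise.

## Problem sizes and numerical choices

The test and acceptance workloads use 100-line screens, 1000–2000-gene
count matrices at 3 replicates per condition, 500-gene dependency matrices
over 7 lines, 200-node graphs with 200 permutations, and 100 query vs 1000
background promoters — sizes at which every planted effect is comfortably
detectable and the full suite runs in well under a minute per stage.
Numerical details: even-count medians are the mean of the central pair;
Fisher probability ties are compared with 1e-7 relative tolerance; IRLS eta
is clipped at ±30 (a group with all-zero counts drifts to the bound and is
reported, conservatively, with an enormous standard error or flagged
non-converged); lowess extrapolates constantly beyond the spike-in A-range;
k-means uses Euclidean distance with seed-fixed restarts.
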