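# Methods

## Scope and model of the data

`xdosage` analyses allele-resolved count data from an F1 hybrid cross
(*Mus musculus* 129 × *M. castaneus*), in which strain SNPs assign a
fraction of sequencing reads to the maternal ("Mus") or paternal ("Cast")
allele.  Two data shapes share one container (`AllelicCountMatrix`):
bulk allelic ATAC-seq (regions × timepoint replicates) and Smart-seq2-style
allelic scRNA-seq (genes × cells).  Three raw integer layers are carried:
Mus reads, Cast reads, and total reads including allele-unassignable ones;
the package never infers counts upstream of these matrices (alignment,
read splitting and peak calling are out of scope).

The biology being quantified: in female somatic cells one X is inactivated
(XCI) and the single active X is transcriptionally upregulated (XCU) so
that one X allele matches the output of two autosomal alleles.
Reprogramming to pluripotency reactivates the inactive X (XCR) and
concurrently erases XCU ("XCD"); X loss in XX iPSCs (XO cells)
re-establishes XCU on the remaining allele.  Every estimator in the
package measures some aspect of that program.

## Core statistics

**Normalization.** Each layer value x becomes `log1p(scale·x / L_s)` with
`L_s` the total-layer column sum of the sample and scale = 10,000.  The
divisor is deliberately the *total* library (not the allelic sub-library),
so Mus, Cast and total values of a sample are commensurable.  The log base
is natural; it is configurable since only monotonicity matters for the
rank statistics.

**X/A fold (`x_autosome_fold`).** Per feature, the linear (de-logged)
normalized value averaged over the selected samples; the fold is the
median over chrX features divided by the median over pooled autosomal
features (chrY/chrM always excluded), with a two-sided rank-sum p-value on
the two feature-level distributions.  Folds are computed on the linear
scale because a ratio of medians of log-values is not the accessibility or
expression fold being reported; p-values are unaffected by the monotone
log.  A per-chromosome-median variant (median of the 19 autosomal medians)
is available behind a flag; the pooled default matches the feature-level
rank-sum test.

**Per-cell X/A ratio.** Per cell, only expressed genes (allelic read sum
> 0) enter; the ratio is median(X genes)/median(autosomal genes) of linear
normalized values of one allele, with a mean variant behind a flag.  A
fully silenced X gives ratio 0 by convention (empty X median → 0), and a
cell without expressed autosomal genes gives a logged NaN.

**Filters.** ATAC regions need ≥ 10 allelic reads (Mus+Cast) within a
timepoint group to be informative *in that group*; cross-timepoint
analyses intersect groups, and the trajectory analyses use the stricter
"≥ 9 in every timepoint" rule.  Genes need ≥ 4 covering SNPs.  Entries
with total reads but zero allelic reads are *missing*, not zero
(`apply_missing_convention`); entries with no reads at all are true zeros.
Thresholds are inclusive; 25% expression-change and allelic-bias
classifications likewise count exactly-25% as changed/biased.

## Accessibility dynamics

The allelic ratio r = Mus/(Mus+Cast) of group-summed counts partitions
into Cast-monoallelic (r < 0.15), biallelic (0.15 ≤ r ≤ 0.85) and
Mus-monoallelic (r > 0.85); both boundaries belong to the biallelic band.
Trajectories over the six timepoints (d0, d8, d9, d10, d12, iPSC) are
clustered by k-means (k-means++ initialization, 25 restarts, Euclidean
distance on the raw ratio vectors — they are bounded and commensurate, so
no scaling) and clusters are named automatically by first-crossing rules:
a cluster mean starting Mus-monoallelic is "mus_mono_to_bi", one never
leaving the Cast-mono band is "cast_monoallelic", one starting at or above
0.15 is "escapee", and otherwise the first timepoint entering the
biallelic band names it early (d8), intermediate (d9), late (d10) or
very_late (d12; a first crossing only at iPSC is also very_late).  Published analyses of this system grouped such clusters into these
categories by visual inspection; the crossing rule is a deterministic
restatement of that grouping.

**Opening time.** Per region, a Gaussian GLM with log link relates the
ratio to the numeric day ({d0:0, d8:8, d9:9, d10:10, d12:12, iPSC:16};
the iPSC day is a convention and configurable) and the opening time is the
day the fitted curve crosses 0.15 — 0 if already open at day 0, NaN
(logged) if the fit fails or never crosses within the observed range.
Class means (enhancer vs promoter) summarize.

**Distance to day-0 biallelic regions.** Gap between closest interval
edges on the same chromosome (0-based half-open; any overlap → 0;
adjacent intervals → 0), computed per chromosome with sorted-edge
searches and verified against an all-pairs oracle in tests.

## Pseudotime kinetics

Per-gene curves are fitted by loess — local weighted polynomial
regression with tricube weights, degree 2, span 0.75, evaluated at 100
equally spaced pseudotime points; span, degree and grid size are
configurable since published analyses state none of them.  The
implementation is local least squares (degree 2 is not offered by the
usual lowess routines); linear data is reproduced exactly for any span,
which the tests pin down.  XCR-mode fits smooth the per-cell raw-count
allelic ratio (the per-cell library factor cancels in the ratio) clipped
to [0,1]; XCD-mode fits smooth linear normalized expression of the active
allele.  Cells lacking allelic signal for a gene are missing for that
gene's fit; genes with < 20 informative cells are skipped and logged.

Classification clusters the fitted curves (k-means as above) and then
names clusters *only from curve shape*, so labels are invariant to
k-means index permutation: for XCR (k=5), clusters whose fitted starting
ratio is ≥ 0.15 are escapees and the rest are ordered early /
intermediate / late / very_late by half-reactivation pseudotime (first
grid point reaching (start+end)/2, ties to the earliest point); for XCD
(k=3), the 25% rule applied to cluster-mean endpoints names decreased /
stable / increased.  Degenerate inputs (fewer than k distinct clusters)
raise an error with guidance rather than returning arbitrary labels.

## Two-state transcription model

Transcription is modeled by the telegraph process: a promoter switches
ON↔OFF at rates k_on and k_off and transcribes at rate k_syn while ON;
with mRNA degradation rate set to 1 (all rates in degradation units), the
steady-state copy number is the Poisson-beta mixture
n ~ Poisson(k_syn·p), p ~ Beta(k_on, k_off).  Burst frequency is k_on and
burst size k_syn/k_off.  Closed forms used throughout and verified
against the pmf and a sampling oracle: mean = k_syn·k_on/(k_on+k_off);
variance = mean + k_syn²·k_on·k_off / ((k_on+k_off)²(k_on+k_off+1)).

**Likelihood.** The pmf is evaluated by 50-node Gauss-Jacobi quadrature
over the Beta density with log-domain accumulation; the rule integrates
the Beta density exactly, so the pmf normalizes to machine precision up to
truncation.  Numerical regimes: k_on or k_off < 0.05 (boundary-singular
density) uses adaptive quadrature in the public pmf; k_on + k_off > 800
with both rates ≥ 1 (concentrated, near-Gaussian Beta) uses Gauss-Legendre
over a ±10 sd window; the asymmetric singular corner uses generalized
Gauss-Laguerre in the Gamma-limit variable.  These branches exist because
the Jacobi weight computation overflows for very large parameter sums.

**MLE.** Per gene: missing (NaN) cells dropped, values rounded to
integers, unique-value weighting, L-BFGS-B in log-parameter space with
bounds k_on, k_off ∈ [1e-3, 1e3], k_syn ∈ [1e-2, 1e4], started from the
Peccoud-Ycart factorial-moment solution; two deterministically jittered
restarts run only if the first fit fails or sits on a bound (the
k_off–k_syn likelihood ridge makes unconditional restarts ~3× more
expensive for no accuracy gain).  A fit is `converged` only with optimizer
success and an interior optimum; all-zero genes and genes with > 90%
missing cells are reported unconverged with a reason.  Only k_on and
k_syn/k_off are well identified at realistic depths — k_off and k_syn
individually ride a flat likelihood ridge — which is why comparisons are
made on burst frequency and burst size.  Default fits use raw allelic
counts; rounding RPKM-normalized values (provided via `rpkm_normalize`)
is possible but mixes library depth into the rate units, so it is not the
default.

**Comparison.** `compare_burst` reports X/A folds of median burst
frequency and median burst size over converged genes (≥ 20 per side
required) with two-sided rank-sum p-values.

## Synthetic data: what it emulates, and what it does not

The generators provide the study conditions with full ground truth.
Counts for both alleles are direct Beta-then-Poisson draws from per-gene
telegraph parameters.

* **Reprogramming scRNA** (`simulate_reprogramming_scrna`): 500 cells on a
  0–100 pseudotime (cell groups C0–C5 by sextile), 2,000 autosomal +
  300 X genes (440 in the expression-fold preset, the scale at which X-linked genes
  are typically allelically quantifiable in such experiments), 10%
  escapees, remaining X genes split over reactivation classes at
  pseudotimes {early 25, intermediate 45, late 65, very_late 85} with
  logistic slope 4.  The silenced (Mus) allele's k_on carries a 0.01
  baseline multiplier (leaky, so escape-like signal is representable)
  rising logistically at the gene's class time; the active (Cast) allele
  carries `xa_fold` decaying to 1 around pseudotime 45, coupling
  upregulation erasure to reactivation.  A `snapshot` mode freezes all
  cells in the somatic (C0) or pluripotent (C5) state.
* **ATAC timecourse** (`simulate_atac_timepoints`): 50,000 autosomal +
  5,000 X regions (the real repertoire is ~224k/5.4k; X is kept at full
  scale because X-median precision limits every fold estimator), 2
  replicates per timepoint, region baselines lognormal (median 30
  reads/allele, σ 0.5), closed-state multiplier 0.02, category mix
  {early .20, intermediate .15, late .20, very_late .15, escapee .15,
  mus_mono_to_bi .10, cast_monoallelic .05}.  Earlier-opening regions are
  planted genomically closer to escapee anchors.  Snapshot presets
  (female MEF, male mESC, XX iPSC) describe the active-allele peak
  repertoire and therefore omit the Xa-closed-at-d0 category.
* **XO iPSCs** (`simulate_xo_ipscs`): XX cells express both X alleles at
  autosomal levels; XO cells zero every X count of the lost allele —
  escapees included, mirroring how X loss is called from loss of biallelic
  escapee expression — and upregulate the retained allele by `xa_fold`.
* **Pure burst experiment** (`simulate_burst_dataset`): genes × cells
  counts drawn exactly from the Poisson-beta model, no depth variation or
  unassignable reads, with k_on and burst-size multipliers on X genes.

Design choices worth calling out:

* **XCU acts on burst frequency.**  `xa_fold` multiplies k_on (the
  mechanism under study), with the per-gene multiplier solved so the
  *mean* scales exactly by `xa_fold` — a raw k_on multiplier f scales the
  mean by f(k_on+k_off)/(f·k_on+k_off) < f.  A k_syn mode exists to test
  whether the pipeline distinguishes mechanisms.  One consequence: a
  burst-frequency increase also de-skews the count distribution, so the
  *median* of per-cell values rises more than the mean; the expression
  fold is therefore recovered with the feature-level statistic (median
  over genes of per-gene mean expression), not the per-cell
  median-over-genes ratio, which over-states a mean fold by construction.
* **Stratified baselines.**  Feature-level parameters are drawn by
  scrambled-quantile (stratified) lognormal sampling, separately within
  the X and autosomal sets: marginals are identical to i.i.d. draws, but
  the feature-set medians that every fold estimator divides by are pinned,
  as is standard in parameter-recovery designs.  Stratified samples are
  not exchangeable, so the null-calibration experiment (uniformity of
  rank-sum p-values) switches to i.i.d. draws via `stratified=False`;
  fold-band calibration holds either way.
* **Technical noise.**  Per-cell/sample depth is lognormal (σ 0.3);
  allele-unassignable reads inflate the total layer by a factor 1/0.10
  (≈ 10% of reads allele-assignable, the scale typical of such crosses),
  added as Poisson counts on top of the allelic layers so the
  mus+cast ≤ total invariant holds.
* **Determinism.**  All generators are bit-reproducible given (config,
  seed) via a single `numpy` Generator.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: mappability and SNP-density variation along the
genome, reference bias in allelic assignment, cell-cycle and cell-size
covariation, mRNA half-life differences (degradation is the unit of
time), UMI-less amplification noise beyond Poisson, correlated bursting
between alleles or neighbouring genes, and real pseudotime estimation
error (pseudotime is always an input here).

## Problem sizes and tolerances used by the shipped experiments

The recovery experiments in `tests/test_acceptance.py` and
`scripts/acceptance.py` run at: 55,000 ATAC regions × 1 timepoint for
accessibility folds (±0.05 bands); 2,440 genes × 500 cells for the
expression fold (±0.05); 1,800 genes × 1,000 cells for burst-fold
recovery (±0.10); 300–800 features for kinetic-class recovery (≥ 90%
agreement); 200 genes × 1,000 cells for MLE error (< 20% median relative
error); 200 replicates of 25,000 regions for null calibration (folds in
[0.95, 1.05], Kolmogorov–Smirnov uniformity of p at α = 0.01).  These
sizes keep the whole suite within a few minutes on one core while leaving
each estimator's sampling error several times smaller than its tolerance.

## Known limitations

* The k-means category naming reproduces the published grouping logic
  only up to its deterministic restatement; borderline clusters near the
  0.15 threshold can flip categories between seeds.
* The telegraph MLE assumes steady state and independent cells;
  population structure along pseudotime violates this, so burst inference
  should be run within cell states (as the comparisons here do).
* Gaussian GLM opening times extrapolate an exponential mean curve; for
  regions opening abruptly late, the crossing day is interpolated from a
  misspecified curve and carries no uncertainty estimate.
* RPKM-mode burst fitting (rounding normalized values) is exposed for
  compatibility but changes the meaning of the rate units; raw counts are
  the default and the recommendation.
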