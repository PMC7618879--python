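# Methods

This note documents the statistical models behind each module, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Paired differential-translation model (`polysome_rank`)

**Model.** For each gene, counts from matched polysomal and sub-polysomal
fractions across conditions and replicates follow a negative-binomial GLM
with log link and variance mu + alpha*mu^2:

    log mu = log(sf) + condition + condition:replicate + condition:fraction

with the sub-polysomal fraction as the reference level. The
condition:fraction coefficient of a condition is therefore its average
polysomal/sub-polysomal log2 fold change — a translation-efficiency
estimate that respects replicate pairing. Because the design contains no
main fraction or replicate terms shared between conditions, the model is
block-diagonal: each condition block (intercept + R−1 replicate dummies +
fraction dummy, 2R observations) is fitted independently. Internally all
fits use natural logs; coefficients and SEs are converted to log2 at the
interface.

**Fitting.** Per-gene fits use iteratively reweighted least squares,
vectorized across genes (shared design matrix, per-gene weights, batched
5×5 solves). The per-gene fit is exactly the GLM a reference
implementation produces — the test suite checks coefficients and SEs
against `statsmodels` GLM fits gene by gene — but runs three orders of
magnitude faster at desk scale. Non-convergent genes are flagged in
`EffectTable.converged`, never dropped silently.

**Size factors.** Median-of-ratios with a geometric-mean pseudo-reference
over genes positive in all samples; user-supplied factors are accepted
(`sample_size_factors`), which the noise-free exactness tests use.

**Dispersion.** Per-gene: a method-of-moments start pooled over
condition×fraction replicate groups of normalized counts (floor 1e-8),
refined by maximizing the Cox–Reid-adjusted profile likelihood in alpha on
a 41-point log grid with quadratic interpolation. The profile is taken
against condition×fraction group means (24 residual df at R = 4) rather
than the 20-parameter fitted design: with only 3 residual df per condition
block a per-gene dispersion is far too unstable for Wald inference, and
the group-mean profile also absorbs replicate-offset variability, which
keeps Wald intervals honest at small R. No dispersion–mean trend and no
empirical-Bayes moderation across genes are applied; parameter-recovery
tests (not coefficient-exact equivalence with any particular framework)
define correctness here.

**Contrasts.** Delta_log2FC = coef(reference) − coef(other); because
blocks are independent, SE = sqrt(SE_ref² + SE_other²); two-sided Wald
p-values (normal quantiles), floored at 1e-300.

**Adaptive shrinkage.** Empirical-Bayes normal-mixture prior
pi0·delta(0) + sum_k pi_k·N(0, sigma_k²) on a geometric grid (ratio
sqrt 2) spanning [SE_min/10, 2·max|value|]; weights fitted by EM on the
marginal likelihood of the (estimate, SE) pairs; posterior means returned.
Every component shrinks toward zero, so |shrunken| ≤ |raw| gene-wise and
the ranking of equal-SE genes is preserved. The uniform and half-uniform
prior components of the full adaptive-shrinkage family are not
implemented.

**Ranking metrics.** TRM = −Delta_log2FC(shrunken) × log10(p);
RM = −log2FC × log10(p) on total-RNA contrasts (unshrunken by default —
the shrinkage step is defined for the polysome contrast; a flag allows
shrinking first); RM_adj multiplies by X_max (below). p ≤ 0 is floored at
1e-300 (configurable) with a warning so metrics stay finite. Ranked lists
order ties by gene identifier, making downstream GSEA deterministic.

**Expression filters.** Polysome mode drops a gene when any
condition×fraction group has zeros in ≥ ceil(3R/4) of R replicates
(3-of-4 at R = 4); total mode pools fractions per replicate and drops at
≥ ceil(R/2) zero replicates per condition (2-of-4 at R = 4). Both are
idempotent and leave the sample set unchanged.

## Pre-ranked GSEA and term scoring (`enrichment`)

**ES.** Classic weighted KS running sum, weight exponent 1: hits add
|metric|/sum(|metric| over hits), misses subtract 1/(N−N_hits); ES is the
extreme deviation. All-hit lists give ES = 1; zero-metric hits fall back
to uniform increments. Exhaustive brute-force oracles in the tests pin the
implementation to 1e-12.

**Significance.** Gene-label permutation: the null for a set of size k is
the ES of random k-subsets of the ranked list. The null depends only on k
given the metric, so null distributions are cached per size. Nominal
p = (1 + #{same-sign null with |ES'| ≥ |ES|})/(1 + #same-sign null);
NES = ES / mean|same-sign null ES|; BH FDR across all tested sets. The
adaptive multilevel p-refinement of fast reference implementations is
deliberately not reproduced: same estimand, far simpler, adequate at desk
scale (`n_perm` configurable, default 10000). Sets are filtered to 3–1500
members counted over genes present in the ranked list; zero-overlap sets
are skipped with a recorded reason.

**Term scores.** Set names are split on underscores, upper-cased, and
counted once per set. RP = rank percentile rounded up to the next 0.1%
multiple, computed with integer ceiling arithmetic
(`ceil(1000·rank/total)/10`) so the 1–1000 score range is exact at both
ends; per-set score = 100/RP; a term's overall score is the mean over the
sets containing it; the top 100 terms are reported after removing stop
terms (prepositions, conjunctions, and generic vocabulary — WITH, VIA,
THROUGH, AND, OR, GENE, PATHWAY, REGULATION, TARGET, and similar). The RP
denominator defaults to all sets supplied; a `positive_only` switch
restricts the ranking to positively enriched sets, since either reading of
"the ranking of their associated gene set" is defensible.

## Ambient-RNA correction and single-cell ranking (`sc_ambient`)

**Soup model.** Observed = endogenous + ambient, with the ambient profile
b_g shared across droplets of a sample. The profile is the normalized sum
of barcodes with ≤ `empty_umi_max` (default 100) total UMIs.

**Automatic contamination estimate.** Candidate "soup-explainable" genes
are those whose pseudo-bulk expression fraction across cells does not
exceed their soup fraction (no evidence of endogenous expression). Each
cell then yields a Poisson MLE of its contamination from those genes;
ρ_auto is the lower decile (`cell_quantile = 0.10`) of the per-cell
estimates, not their mean: in real data a candidate gene genuinely
expressed in some cells inflates those cells' estimates, and a robust
lower envelope must not mistake expression for soup. The cost of that
robustness is systematic underestimation — the documented behavior of
automatic soup estimators — which is exactly what the next step
compensates.

**The two modifications.** (1) ρ_adj = 2·ρ_auto, always. (2) Instead of
one fraction for all cells, ρ_c = min(ρ_max, ρ_adj·mean(N)/N_c) with
ρ_max = 0.5 — the unique rule making the expected subtracted total
S = ρ_adj·mean(N) identical for every cell, which is the stated goal of
the per-cell adaptation ("uniform distribution of subtracted counts").
ρ_max guards tiny cells from degenerate full subtraction. The original
modification's exact formula is unpublished; only its stated objective is
implementable.

**Subtraction.** Deterministic, not stochastic: expected soup counts
e_gc = ρ_c·N_c·b_g are apportioned by the largest-remainder method
(floor, then one count per gene in fractional-remainder order), capped at
observed counts; cap-induced shortfall is redistributed proportionally to
b_g over genes with remaining counts (≤ 10 passes). Output counts are
integers in [0, observed]; per-cell subtracted totals equal their targets
whenever counts suffice, giving the uniform-subtraction property directly
(CV from rounding only).

**QC.** Keep a cell iff mito fraction ≤ 0.10 and total UMIs ≥ 800 and
detected genes ≥ 200 (both boundaries inclusive on the keep side exactly
as stated); genes expressed in no surviving cell are dropped. Idempotent.

**HVGs.** Counts scaled per cell to the median library size; dispersion =
variance/mean; departure = z-score of dispersion within 20
equal-occupancy bins of mean expression (a binned stand-in for the
dispersion-versus-mean trend — no functional form is prescribed anywhere,
so none is fitted); genes on the exclusion lists (mitochondrial,
ribosomal, cell-cycle — user-supplied, since no canonical list is defined)
or with mean normalized expression ≤ 0.01 are never selected; top 1000 by
departure returned.

**RM_adj ranking.** Two-sided Wilcoxon rank-sum p per gene on log1p
normalized expression (asymptotic with tie correction, no continuity
correction, so identical groups give p = 1 exactly);
log2FC = log2((mean_a + 1e-9)/(mean_b + 1e-9)) of normalized expression;
X_max = larger expressing-cell fraction of the two groups;
metric = −log2FC × log10(p) × X_max. Normalization scales to the median
library by default (the common 10⁴ constant is available by argument).

## Calcium-trace quantification (`calcium_quant`)

Traces are background-corrected fluorescence per cell at one frame per
second (a time column overrides the 1 Hz assumption). The schedule lists
treatments in order of addition — glycine first (NMDA-receptor
co-agonist), ionomycin last. Pipeline: (1) one baseline window of 20
consecutive frames shared by all cells, chosen before the first treatment
of interest by exhaustively scanning candidate windows and minimizing the
summed within-window variance across cells ("high signal stability" is
not otherwise quantified, so a minimum-variance scan realizes it);
F_C0 = per-cell median over the window. (2) Δ(F/F₀) = F/F₀ − 1.
(3) Amplitude of treatment T = max of Δ(F/F₀) in [t_T, t_{T+1}), last
window to trace end. (4) Everything divided by the cell's own ionomycin
amplitude; values above 1 or below 0 are genuine high/low responders and
are kept. (5) Exclusions: ionomycin amplitude < 0.1 ΔF/F₀ units →
`no_ionomycin_response`; for any earlier treatment, if the normalized
trace between that treatment's peak and the next addition never falls
below 0.2 × its amplitude → `no_return_to_baseline`. Both thresholds are
configurable defaults — the rules are stated without numbers anywhere,
and only ~1% of cells are affected in practice. The return check applies
only to amplitudes above 0.05 (ionomycin-normalized) so that noise on a
non-responding window is not read as a plateau. (6) Sample trace =
per-frame mean ± s.e.m. over kept cells; since normalization is per cell,
the average does not generally reach 1 at the ionomycin peak.

Quantification is invariant to per-cell gain (any positive rescaling of a
raw trace), which the tests assert directly.

## Birefringence and IF quantification (`histology_quant`)

RGB → HSB with all channels on 0–255 (hue circle mapped linearly,
H = round(hue°·255/360); brightness = max channel). Class boxes,
inclusive: red-orange H 2–27, yellow 28–47, green 48–140, all with S
0–255 and B 140–255 (the printed interval notation is read as inclusive
ranges, the ImageJ convention; the literal reading is empty). Grey pixels
(S = 0) are classified by H and B alone since S spans the full range.
Relative areas are percentages of tissue ∩ ¬excluded pixels; excluded
regions (vessels, lung rim) appear in neither numerator nor denominator.
When no tissue mask is supplied, tissue defaults to brightness ≥ 10
(near-black background excluded); per-metastasis reporting is achieved by
passing one mask per metastasis. IF collagen intensity = total signal /
nucleus count, nuclei from a DAPI channel by Otsu threshold + connected
components with a 20-pixel minimum size, or supplied directly.

## Isotopologue correction (`isotope`)

The natural-abundance matrix has entries
M[j,i] = C(n−i, j−i)·a^(j−i)·(1−a)^(n−j) (a = 0.0107), the probability
that an M+i species is measured as M+j via natural ¹³C at unlabeled
positions; columns sum to 1. Correction solves M·x = measured by
non-negative least squares — direct inversion can return small negative
abundances on noisy data — renormalizes, and reports fractional
enrichment sum_i i·x_i/n. Only the carbon backbone is corrected;
derivatization atoms (Si/H/O) are out of model, and a full user-supplied
matrix is accepted for derivatized fragments.

## Synthetic data (`synthdata`)

Each generator is a pure function of seed and parameters and stores the
exact ground truth its downstream stage estimates.

* **Polysome counts.** mu = sf·baseline·2^rep_offset·2^(effect·poly);
  NB sampling with per-gene alpha (variance mu + alpha·mu²).
  dispersion = 0 is the deterministic noise-free limit
  (counts = round(mu)) used by exactness tests; an NB draw at small alpha
  is still Poisson-noisy, so the limit is implemented as exact.
  Defaults: baseline log-normal (log-mean 5, log-sd 1 — typical RNA-seq
  depth for an expressed gene), replicate offsets N(0, 0.1) in log2,
  size factors log-normal(0, 0.1). `study_fraction_effects` plants
  Δlog₂FC ∈ {0, ±1.5} (80/10/10%) on the reference condition so the true
  between-condition delta is known exactly.
* **Soup.** Observed library N_c log-normal around 2000 UMIs; soup total
  Binomial(N_c, ρ); endogenous counts multinomial from the cell profile;
  soup counts multinomial from the ambient profile; observed = true +
  soup, so the expected soup per cell is ρ·N_c. The ambient profile
  places 30% of its mass on a 5% block of ambient-specific genes the
  cells never express (the hemoglobin-like transcripts that make ambient
  contamination estimable in real data) and follows the cell profile
  elsewhere. Pure-soup empty droplets (~50 UMIs each) are appended for
  profile estimation. A Dirichlet-multinomial overdispersion layer is
  deliberately omitted — multinomial draws suffice for recovery tests.
* **Calcium.** Transients rise instantaneously at addition and decay
  exponentially (tau = 8 s), truncated at the next addition, so the
  window maximum equals the set amplitude exactly and responders return
  to baseline; only amplitudes are specified by the quantification rules,
  so any kernel with that window-maximum property is valid. Designed
  non-responders get ionomycin amplitude 0; designed non-returners hold a
  plateau through subsequent additions. Noise is Gaussian with s.d.
  proportional to baseline. Default amplitudes (ΔF/F₀): glycine 0.05,
  glutamate 0.1, aspartate 0.5, ionomycin 2.0 — aspartate a clear
  sub-maximal response, ionomycin the per-cell maximum.
* **Fiber images.** Planted pixels receive HSB values inside per-class
  sub-boxes with 2-unit hue margins and a saturation floor of 80, so
  8-bit RGB round-trips cannot move a pixel across a class boundary;
  remaining tissue is dim (B < 140), non-tissue near-black. Truth masks
  are stored per class, making exact pixel-count recovery testable.
* **MIDs.** Forward convolution with the same binomial kernel the
  corrector inverts (round-trip identity within 1e-6 is a test).

What the generators do **not** emulate: transcriptome-scale biology (GC
and length bias, expression correlation structure, batch effects),
droplet cell calling and doublets, calcium kinetics beyond amplitudes,
optical blur/chromatic noise in histology, and measurement noise in MIDs
(supported but off by default). Passing recovery tests therefore
demonstrates estimator correctness under the stated generative models,
not robustness to every artifact of real data.

## Problem sizes

Simulation-backed tests run at desk scale, chosen so the full suite
completes in a few minutes on one CPU while keeping Monte-Carlo noise
well below the tolerances being asserted: 2000 genes × 32 samples for the
NB-recovery checks (three seeds pooled, ~1200 effect genes), 200 null
gene sets × 2000 permutations for GSEA calibration, 400 cells × 250 genes
× 50 seeds for ambient correction (contamination 0.10, a typical droplet
level), 200 cells for calcium cohorts, and 150×200 px fiber images.

## Known limitations

* Wald inference with per-gene dispersions is slightly anti-conservative
  at very small replicate numbers; the group-mean dispersion profile
  compensates at R = 4 (the tested design) but R = 2 designs should be
  interpreted cautiously.
* The ambient model assumes one shared soup profile per sample; channel
  mixing across samples is out of scope.
* The per-cell contamination rule implements the stated uniformity
  objective; whatever caps or smoothing the original unpublished
  modification applied beyond that are unknowable from the description.
* Gene identifiers are opaque case-sensitive strings; cross-species or
  symbol/ID mapping is the caller's responsibility.
* The GSEA permutation null is gene-label based; sample-label permutation
  (which preserves gene–gene correlation) is not implemented.
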