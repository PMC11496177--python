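# Methods

## Model and estimands

The package operates entirely on GWAS summary statistics.  For each SNP j and
each trait, the input is the marginal per-allele effect estimate β̂ with
standard error σ, a p-value, and allele metadata.  Under the standard
instrumental-variable assumptions (relevance, independence from confounders,
exclusion restriction), the per-SNP Wald ratio β̂_Yj/β̂_Xj estimates the
causal effect of exposure X on outcome Y, and the estimators below combine
the ratios:

- **IVW** is the zero-intercept weighted least-squares fit of β̂_Y on β̂_X
  with weights 1/σ_Y², equivalent to the inverse-variance-weighted mean of
  the Wald ratios.  The default SE model is multiplicative random effects:
  the fixed-effect SE is inflated by max(1, √(Q/(k−1))), where Q is
  Cochran's statistic, so heterogeneity widens intervals but can never
  shrink them below the fixed-effect SE.  This matches the de-facto default
  of the widely used R tooling; the fixed-effect variant is a config switch.
- **MR-Egger** adds a free intercept (after re-orienting rows so β̂_X ≥ 0).
  The slope is consistent under InSiDE even with directional pleiotropy;
  the intercept estimates the average direct (pleiotropic) effect and is
  the basis of the pleiotropy test.  Inference uses t(k−2), and the residual
  scale is likewise floored at 1.
- **Weighted median**: the 50th percentile of the ratio distribution under
  inverse-variance weights, interpolated linearly across centered cumulative
  weights; consistent when valid instruments carry ≥50% of the weight.
- **Weighted/simple mode**: argmax of a normal-kernel density over the
  ratios (inverse-variance or uniform weights).  Bandwidth is
  `bandwidth_factor` × 0.9·min(SD, normalized MAD)·k^(−1/5); the argmax is
  taken on a dense grid spanning the ratio range ±3 bandwidths.
- Median and mode SEs come from a parametric bootstrap (default 1,000
  draws of each β̂ from N(β̂, σ²)), with a mandatory explicit seed recorded
  in the output.

p-values use the normal reference for IVW/median/mode and t(k−2) for Egger.
Binary-outcome effects are log odds ratios; OR-scale output is
OR = exp(β), CI = exp(β ± 1.96·SE).

## Instrument selection and harmonization

Defaults: association screen p < 1e-5; greedy clumping (smallest p first,
ties broken by position then SNP id, making results order-independent)
discarding SNPs within ±10,000 kb of a kept index SNP at r² ≥ 0.001;
per-SNP strength F = (β/σ)² with F < 10 dropped.  An eaf-based variance
explained (2·MAF·(1−MAF)·β², F = R²(n−2)/(1−R²)) is available for the power
calculator's R² input.

Harmonization joins on SNP id (instruments absent from the outcome are
dropped and counted), sign-flips the outcome effect when its effect allele
matches the exposure's other allele directly or as a strand complement, and
handles palindromic (A/T, C/G) SNPs by policy: `drop` (default,
conservative) or `infer_by_eaf`, which keeps a palindrome only when both
effect-allele frequencies fall outside [0.42, 0.58] and infers the strand
from the minor-allele side.  Every drop reason is tallied, and stage counts
satisfy in = kept + dropped at each step.

## Sensitivity diagnostics

Cochran's Q uses first-order ratio weights (w_j = β̂²_Xj/σ²_Yj) around the
fixed-effect IVW estimate, referred to χ²(k−1); by construction
Q/(k−1) is exactly the squared residual scale of the random-effects IVW SE.
Leave-one-out refits IVW k times and flags fits whose 95% CI changes the
sign conclusion.  MR-PRESSO is re-implemented from its published algorithm:
the observed RSS uses leave-one-out expected outcome effects; the global p
is the upper-tail proportion over parametric simulations under no
pleiotropy (default 1,000, p floored at 1/(n_sim+1)); the per-SNP outlier
test compares each observed contribution to its simulated distribution with
Bonferroni correction; the distortion test compares the outlier-corrected
IVW slope against slopes from removing random subsets of the same size.
Outlier correction is surfaced in the report, never silently substituted
for the headline estimate.

## Mediation

β(A) (exposure→mediator), β(B) (mediator→outcome) and the total effect are
all IVW fits by default (the primary estimator; the choice is recorded in
the output).  The mediated effect is the exact product β(A)·β(B); the
direct effect is stored as total − mediated, so the decomposition identity
holds to within one floating-point rounding.  The product variance is the
first-order Sobel form β(B)²σ_A² + β(A)²σ_B² (second-order term by flag),
assuming independent legs — justified by the two-sample design in which
each leg comes from a different GWAS cohort.  The proportion CI uses the
independence delta form (m/t)²(σ_m²/m² + σ_t²/t²); an opposite-sign
mediated/total pair is flagged `inconsistent` rather than reported as an
absolute value.  First-order delta intervals are approximate: empirical
coverage is 93–97% at moderate effect sizes (verified by simulation), and
degrades when the total effect is weakly estimated or near zero.

Multiple testing uses Benjamini–Hochberg within each screening family
(exposures and mediators separately), with the three evidence tiers
FDR < 0.05 (causal), p < 0.05 (suggestive), otherwise none.  The scan
screens families at `screen_alpha` (default 0.01) and tests
exposure→mediator legs singly at `leg_alpha` (default 0.05, no family
correction) — the legs are confirmatory tests of an already-screened pair,
and both knobs are configurable.  Reverse-direction ("bidirectional")
analysis is an exposure/outcome swap with identical thresholds; no distinct
reverse methodology is defined.

Power for a binary outcome uses the standard non-centrality approximation
power = Φ(−z_{1−α/2} + |log OR|·√(n·R²·K·(1−K))) with case fraction K.

## Synthetic-data generator

The generator emulates the study conditions the pipeline targets, directly
on the summary-statistic scale (no individual-level genotypes): a small
exposure GWAS (n = 3,757, the immune-phenotype cohort scale), a mid-size
mediator GWAS (n = 8,299, the plasma-metabolite cohort scale), and a large
binary outcome GWAS (n = 977,323 with 47,309 cases, the heart-failure
cohort).  Default true effects are β(A) = 0.05, β(B) = 0.15 and total
θ = 0.039 log-odds (OR ≈ 1.04 per SD), i.e. a planted mediated share of
19.2% — magnitudes matching the effect sizes such a study reports.
Exposure instruments draw γ_j ~ N(0, 0.25²) truncated at |γ| ≥ 0.15, giving
uniformly strong instruments (F ≫ 10) so parameter-recovery runs are not
confounded by winner's curse; the mediator has its own instrument set of
the same form; 120 null SNPs carry no effects.  SEs follow the large-sample
form 1/√(2·MAF·(1−MAF)·n), divided by √(K(1−K)) for the binary outcome;
observed effects add N(0, σ²) noise and p-values are two-sided Wald.
Pleiotropy (none/balanced/directional) adds α_j to the outcome effects of
exposure instruments, independent of γ so InSiDE holds.

LD panels are block-structured: each instrument heads a block of null proxy
SNPs at a declared within-block r² (default 0.8), blocks separated by more
than the clump window.  The panel drives clumping only — observed
statistics are drawn independently per SNP, so the generator does not model
correlated sampling noise between linked SNPs, sample overlap, winner's
curse, allele-frequency drift between cohorts, or realistic LD decay.
Passing tests therefore demonstrate correctness of the selection,
harmonization, estimation and mediation machinery under the stated
sampling model, not robustness to those real-data complications.
Outcome tables randomly swap allele orientation (and strand, for
non-palindromic SNPs) to exercise harmonization; a config switch injects
palindromic SNPs.

## Numerical and design choices

- Clump tie-breaks (p, then position, then id) make output independent of
  row order.  Coordinates are 1-based; the window is ±window_kb.
- Wald ratio requires β̂_X ≠ 0 (exact zero raises); bootstrap draws landing
  on zero are perturbed by 1e-300 to avoid division faults.
- All-identical ratios short-circuit the mode estimator (point mass,
  SE 0); a zero MAD falls back to the SD for bandwidth.
- Empirical p-values (MR-PRESSO) are floored at 1/(n_sim+1), never 0.
- Every stochastic routine takes an explicit seed; the pipeline derives
  per-task seeds from the root seed by hashing the task's label path, so
  adding or removing one analysis never perturbs another's stream.
- Files are plain TSV; floats round-trip at full precision
  (`float_precision="round_trip"` on read, `repr` on write).

## Problem sizes used in checks

Replicate counts are chosen to keep the default verification runs fast
while leaving Monte-Carlo error well below the tolerances asserted:
calibration tests use 1,000 null replicates (type-I error bands of ±3
Monte-Carlo SE), delta-CI coverage uses 2,000–5,000 replicates, and
pipeline-level parameter recovery uses 300 replicate studies in the
acceptance script and 500 in the test suite.  The planted-path scan uses 4
exposures × 4 mediators (one true path among decoys).

## Known limitations

- First-order delta intervals (Wald ratio, Sobel, proportion) are
  asymptotic; they are anti-conservative for weak instruments or
  near-null totals.
- MR-PRESSO's distortion p is a permutation approximation and is only
  computed when outliers are detected.
- The proportion is reported signed; values outside [0, 100]% arise
  naturally from sampling noise and from inconsistent mediation.
- No proxy-SNP lookup: instruments missing from the outcome GWAS are
  dropped (and counted), which loses power relative to r²-based proxying.
- Multi-allelic variants and indels are excluded at read time.
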