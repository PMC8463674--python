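# Methods

## Model and estimators

Let T be a standardized complex trait and E the standardized expression of
one gene. The package works under the linear structural model

    T = α_fwd · E + q_T · U + ε_T
    E = α_rev · T + q_E · U + ε_E

with a shared confounder U ~ N(0,1) independent of the mutually
independent residuals ε_T, ε_E. With E, T, U standardized,

    corr(E, T) = (α_fwd + α_rev + q_T·q_E) / (1 + α_fwd·α_rev).     (†)

Only the product q_T·q_E is identified from (†); the individual loadings
are not, and the package never reports them separately.

### Two-sample MR estimates of α_rev and α_fwd

The reverse direction (trait → expression) instruments the trait with
LD-independent (r² < 0.01), genome-wide-significant (p < 5e-8) GWAS SNPs
and takes their standardized *trans*-eQTL effects as outcomes; the forward
direction swaps the roles. The IVW estimate is

    α̂ = (β̂ᵀ C⁻¹ β̂)⁻¹ (β̂ᵀ C⁻¹ γ̂),

with C the instrument LD matrix. Instruments are assumed pre-pruned;
C defaults to the identity, in which case α̂ = Σβ̂γ̂/Σβ̂², the no-intercept
least-squares slope of outcome on exposure effects. The variance is the
first-order delta expansion with analytic gradients ∂α̂/∂γ_j = β_j/Σβ²
and ∂α̂/∂β_j = (γ_j − 2αβ_j)/Σβ², and cov(β̂, γ̂) = 0 because the two
sets of effects come from non-overlapping studies. Z = α̂/SE(α̂) is
referred to the standard normal (two-sided); p-values are also kept as
log10 so transcriptome-scale results below the smallest positive double
survive serialization.

Harmonization aligns the eQTL effect to the GWAS effect allele
(sign-flipping on swapped or strand-complemented codings), removes
strand-ambiguous A/T and C/G SNPs unconditionally (no frequency rescue),
and drops irreconcilable allele pairs with a warning. The selection
filters keep exposure associations at p < 5e-8 and remove SNPs with
|γ̂| > |β̂| (larger outcome than exposure effect — likely reverse
causation or confounding). Standardization, when needed, is
β_std = z/√n, SE = 1/√n, which preserves the z-score.

### Pleiotropy filter

For each instrument, d_i = γ̂_i − α̂β̂_i, with variance (as-printed form,
the default)

    var(d_i) = var(γ̂_i) + β_i²·var(α̂) + var(γ̂_i)·α² + var(β̂_i)·var(α̂).

The third term is dimensionally odd — a first-order expansion of α̂β̂_i
gives α²·var(β̂_i) instead — so a "corrected" form with that replacement
is selectable (`variance="corrected"`); the two coincide whenever
var(β̂_i) = var(γ̂_i). T_i = d_i²/var(d_i) is referred to χ²₁. While any
SNP fails at p < 1e-4 the SNP with the largest |d_i| is removed (ties
broken by smallest snp_id, logged) and α̂ re-estimated, stopping at a
configurable floor (default 2 instruments, below which convergence is
flagged false). The global Q (sum of final T_i, df = n−1) is reported as
a diagnostic.

Calibration: at the global null the T_i tail matches χ²₁ to within the
O(1/n) leverage of each SNP on α̂. With a nonzero causal effect the
as-printed variance's var(γ̂)·α² term inflates the denominator by a
factor ≈ 1 + α², making the test mildly conservative (at α = 0.1 the
1e-4 tail rate drops to ≈ 0.9e-4); the corrected form removes this.

Power: a directional direct effect of magnitude 5× the outcome SE gives a
per-SNP noncentrality of at most 25, i.e. a ceiling of
P(χ²₁(25) > 15.14) ≈ 0.87 at the 1e-4 threshold; leverage shrinkage of
d_i and contamination of α̂ by the outliers bring realized removal power
to ≈ 0.65–0.70 in the simulation study. Bias of α̂, by contrast, is cut
by well over half because the largest outliers are removed first.

### Robust estimators

Per-SNP ratio estimates r_j = γ̂_j/β̂_j with first-order weights
w_j = β̂_j²/SE(γ̂_j)² feed the weighted median (50th weighted percentile,
cumulative weights interpolated linearly; consistent when valid
instruments carry a majority of weight) and the weighted mode (argmax of
a weighted normal-kernel density with a modified Silverman bandwidth
0.9·min(sd, IQR/1.349)·n^{−1/5}, scaled by a bandwidth factor, evaluated
on a 2048-point grid; consistent when the largest ratio cluster is
valid). Both report a seeded parametric-bootstrap SE (default 1000
draws). SNPs with β̂_j = 0 are excluded with a warning.

### Decomposition and binned meta-analysis

Per gene, the forward share is α̂_fwd/r, the reverse share α̂_rev/r, the
confounder share the complement — using (†) with the denominator set to 1,
since |α_fwd·α_rev| is negligible at realistic effect sizes (< 1%
difference whenever |α_fwd·α_rev| < 0.01; the exact denominator is
selectable). Share SEs treat r as fixed (its SE at replication-cohort
scale is an order of magnitude below the MR SEs; a delta-method variant
including var(r) is selectable). Shares are signed and never clipped: a
causal estimate opposing the sign of r legitimately yields a negative
share. Within half-open |r| bins (default width 0.02 up to 0.1 plus a
terminal open bin) each share is combined by fixed-effect
inverse-variance meta-analysis; because per-gene weights are close to
proportional across the three shares, binned shares sum to 1 only up to
that proportionality (per-gene shares sum to 1 exactly).

The dilution adjustment divides the observed Pearson correlation between
two per-gene estimate vectors by
√(1 − ΣSE_α²/Σα̂²) · √(1 − ΣSE_r²/Σr̂²), the attenuation implied by
independent additive estimation noise; it is undefined (and raises) when
noise dominates either vector. Its 95% CI maps the Fisher-z interval of
the observed correlation through the same factor.

### Cohort correlations and trait-pair correlation

Cohort-level observational correlations apply the rank-based inverse
normal transform (Blom offset 3/8, average ranks on ties) to phenotype
and expression, residualize both on covariates (sex, age, age²;
expression additionally on technical covariates) by OLS, and take the
Pearson correlation with SE √((1−r²)/(n−2)). Cohorts are combined by
fixed-effect meta-analysis on the Fisher-z scale with var(z) = 1/(n−3).
The trait-pair "perturbation correlation" is the Pearson correlation of
two traits' per-gene causal-effect vectors over a caller-supplied
independent gene panel (pairwise-complete, ≥ 3 genes), with two-sided
t-tests and Benjamini–Hochberg FDR across pairs.

## The simulator

`simulate_summary_stats` draws, per gene, true instrument effects
|β| ~ N(0, σ_β²) truncated so every instrument passes genome-wide
significance at the GWAS sample size before estimation noise — so the
selection filter is exercised non-trivially — and oriented positive
(effects reported on the trait-increasing allele, the usual convention
for instrument lists). Trans effects are γ = α_rev·β plus, for a
Bernoulli(pleiotropy_fraction) mask, a direct effect of fixed magnitude
pleiotropy_scale × SE(γ̂) with a common positive sign: directional
uncorrelated pleiotropy, the worst case for IVW and the case the Q-scan
is designed to catch (correlated pleiotropy is out of scope). Estimation
noise is N(0, 1/n) at each study's sample size. Defaults: 50 instruments
per gene, n_GWAS = 300,000 (biobank-scale GWAS), n_eQTL = 30,000
(consortium-scale whole-blood trans-eQTLs), σ_β = 0.02. The GWAS scale
matters: at n_GWAS in the tens of thousands, the noise in β̂ inflates
Σβ̂² enough to attenuate α̂ by ~1–2% (classical errors-in-variables),
visible against the 3-SE recovery bands; at 300,000 it is negligible.
Forward-direction instruments are a disjoint, cis-like set with larger
effect scale (σ = 0.1) on expression.

`simulate_cohort` draws individual-level data from the exact reduced
forms of the structural model, with residual scales σ_T, σ_E solved from
the unit-variance constraints var(E) = var(T) = 1 (so (†) holds exactly
in the population). Single-gene configurations use the full bidirectional
forms; multi-gene panels share one trait and one confounder realization
across genes and therefore require α_fwd = 0 — one trait cannot receive
feedback from thousands of genes simultaneously. Age and sex covariates
load additively on both variables and are removed by the adjustment step.
Regeneration from the same seed is bit-identical.

What the simulator does not emulate: LD between instruments (instruments
are exactly independent; real pruning at r² < 0.01 leaves residual
correlation), correlated pleiotropy (direct effects independent of
instrument strength), sample overlap between GWAS and eQTL studies,
winner's-curse in the discovery of instruments beyond the truncation
device, non-normal expression distributions, and shared eQTL noise across
genes. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to these real-data
violations.

## Simulation studies (`revtwmr.evaluation`)

All studies are seeded; sizes were chosen as the smallest that make the
assertions statistically meaningful. Oracle agreement and identity-LD
equivalence use 1,000 random instances; the delta-method check compares
20 instances against 1e5 Monte-Carlo resamples (first-order accuracy
requires SE(β̂)/|β| ≲ a few percent, the regime of genome-wide-significant
instruments); calibration of the deviation test uses 1e6 SNP-tests
(1,000 genes × 1,000 SNPs) at the global null; the outlier study uses 500
replicates of 20 instruments with 10% planted directional pleiotropy at
5× the outcome SE; the decomposition recovery runs 10,000 genes with a
generating 85%/15%/0% confounder/reverse/forward split, observational
correlations from three cohorts of 488, 609 and 991 individuals
(meta-analyzed on the Fisher-z scale) and 50 instruments per gene per
direction. In that study each gene's (trait, expression, confounder)
triple is drawn independently, because the binned meta-analysis SE
assumes independent genes; with a shared trait realization the SE
understates the true scatter several-fold — a caveat that applies equally
to real single-cohort data. Dilution coverage uses 500 replicates of
1,000 genes with true correlation 0.35; the perturbation-correlation
study 1,000 replicates at the 2,974-gene panel size; the null FDR study
500 independent 11-trait panels.

## Numerical choices and degenerate inputs

Ties in |d_i| break lexicographically by snp_id (deterministic given
input order). Zero exposure-effect vectors raise a degenerate-instruments
error; an LD matrix with condition number > 1e12 raises with the
condition number reported. r = 0 makes decomposition shares undefined and
raises. Constant vectors are rejected by the INT; collinear covariates
raise naming the offending columns. Weighted-percentile interpolation
clamps outside the cumulative-weight range to the extreme ratios. The
minimum-instrument warning threshold (3) and the outlier-scan floor (2)
are configurable.

## Known limitations

Multivariable MR, genome-wide latent-confounder models, LD-aware
instrument pruning from genotypes, and separate identification of q_T and
q_E are out of scope. The as-printed deviation variance makes the
pleiotropy scan conservative for large |α|. Binned decomposition shares
inherit a small errors-in-variables attenuation from noise in r̂ (genes
are binned and divided by the same noisy estimate); at replication-cohort
precision this stays within the combined-SE bands but grows as cohorts
shrink.
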