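# Methods

## Model and assumptions

A separation experiment splits each RNA sample into input, eluate
(modified) and supernatant (unmodified) fractions, each sequenced. For
gene *g* with log expression μ_g and modification log-odds γ_g
(α_g = 1/(1+e^{−γ_g})), the expected relative abundances are e^{μ_g},
e^{μ_g}·α_g and e^{μ_g}·(1−α_g); eluate and supernatant sum to the input
by construction, which encodes the core assumptions: complete pull-down of
modified molecules and negligible cross-fraction contamination. Counts are
negative binomial with mean d_s·x_{f(s)}·m_{gs} and shared size θ
(variance m + m²/θ). Fitting is on the logit scale: γ is unbounded, keeps
gene parameters on a common logarithmic scale, and α is a derived
quantity; a box of ±20 on γ (α within ~2·10⁻⁹ of {0,1}) keeps the MLE
finite when a gene has zero counts in one fraction.

Working on the logit scale has a reporting cost: intervals transformed to
the α scale are asymmetric near 0 and 1. That is intended — symmetric
α-scale intervals would leave (0, 1).

## Identifiability and normalization

Two multiplicative layers are separated deliberately:

* **Depth factors d_s** — median-of-ratios within each fraction
  (geometric-mean reference per gene over that fraction's samples, genes
  with any zero excluded from the reference), rescaled to geometric mean 1
  per fraction and then held fixed. They capture replicate-to-replicate
  depth only; nothing about d is comparable across fractions.
* **Fraction factors x_f** — one scale per fraction, shared across all
  genes, carrying the entire between-fraction scale. Shared-ness is what
  makes the model identifiable. Without spike-ins, x_input ≡ 1 and
  (x_eluate, x_supernatant) are fitted. With post-IP equal-amount
  spike-ins, x_supernatant ≡ 1 and x_eluate is the geometric mean over
  qualifying spike-ins of depth-normalized eluate/supernatant counts — no
  fitting, and the input fraction drops out of the likelihood entirely.

The factor convention throughout is *mean multiplier*: predicted mean =
depth × x_fraction × fraction mean. Under this convention the spike-derived
x_eluate equals 2^R of the ratio method, and the model's α̂ coincides
exactly with E/(E + S·2^R) on single-pair data — the two routes are the
same algebra, which the tests exploit as a cross-check.

Because fitted depth factors are geometric-mean-1 within fractions, the
identifiable fraction factor on simulated data is the generative x_f times
the ratio of true depth geometric means (fraction vs input); recovery tests
compare against that quantity.

## Fitting

Block coordinate ascent over three blocks: (1) per-gene (μ, γ) by bounded
L-BFGS-B with analytic gradients; (2) fraction factors by 2-D bounded
quasi-Newton on the log scale (≥2 genes required, otherwise an
identifiability error); (3) θ by bounded Brent search on log θ ∈
[log 10⁻³, log 10¹²], boundary solutions flagged. Each block starts from
the previous optimum and is guarded never to return a worse value, so the
total log-likelihood trace is non-decreasing — asserted in the tests.
The likelihood surface has a shallow ridge between the shared factors and
the gene parameters; each outer iteration therefore runs a few (default 4)
gene/factor relaxation sweeps before updating θ, which cuts typical outer
iteration counts from ~55 to ~15. Convergence: relative change in total
log-likelihood below 10⁻⁸, at most 50 outer iterations; non-convergence
returns a flagged result with a warning rather than an exception.

Initialization follows the moment structure: μ₀ is the log mean
depth-normalized reference count (input; or eluate+supernatant in spike-in
mode), γ₀ the logit of the eluate share e/(e+s) clipped to the box, x₀ = 1,
θ₀ = 100. Genes with all-zero counts are reported at μ = MU_MIN with γ = 0,
converged = False and an at-bound flag; genes with zero counts in a single
fraction land on the γ box bound and are flagged rather than reported
infinite.

θ̂ from a full fit is biased upward (each gene's three fraction means are
fitted from few replicates, absorbing part of the variance — the classic
MLE dispersion bias; at 6 samples and θ = 100 the fitted value is ~140–160).
Point estimates of α are insensitive to this, and interval calibration is
tested with θ fixed, matching how the intervals are defined.

## Numerical details

The NB log-pmf is evaluated in the Γ-function form for θ < 10⁶ and via a
Stirling-difference form for larger θ: the difference
lnΓ(k+θ) − lnΓ(θ) is expanded as k·lnθ + (θ+k−½)·log1p(k/θ) − k + O(1/θ),
and the k·lnθ term cancels analytically against the mean term. Direct
gammaln differencing loses ~10⁻² absolute at θ = 10¹²; the stable form
agrees with the Poisson limit to <10⁻⁶ per observation for counts within
~10³ of the mean, so "Poisson-like" data (θ at the upper search bound)
are handled without a special case. Sampling uses the Gamma–Poisson
mixture, switching to pure Poisson above θ = 10¹⁰.

## Confidence intervals

Profile likelihood: for an interval on γ the gene log-likelihood is
maximized over μ at each fixed γ (bounded Brent), with normalization
factors and θ frozen at their fitted values — their uncertainty is
deliberately ignored, so intervals are conditional on the normalization.
Bounds solve 2(ℓ_max − ℓ_profile(γ)) = χ²₁(level) by stepping outward from
γ̂ with doubling steps and Brent root-finding in the bracketing interval
(deviance matched to ~10⁻⁶ at interior bounds). A side that reaches the γ
box bound before crossing the cutoff is reported at the bound and flagged
one-sided — the typical outcome for genes with zero counts in one
fraction. α-scale bounds are the logistic transform of the γ bounds.
Intervals for μ profile over γ symmetrically.

Empirical coverage of the 95% γ intervals on data simulated under the
model (500 genes, 2 replicates/fraction, θ = 100, true factors fixed) is
~95% (the acceptance script recomputes this; a binomial band of roughly
[92, 98] is the meaningful tolerance at 500 genes).

## Ratio baseline

`laicseq_R` estimates the log2 cross-fraction offset from spike-ins. The
default dialect fixes the slope to 1 (paired mean of log2 E/S), because
only then does 2^R carry the exact scale-factor meaning the formula
α = E/(E+S·2^R) requires; a free-slope OLS dialect is available for
comparison and records its fitted slope. Spike-ins qualify with at least
100 counts (inclusive), unlike the strict >100 gene expression filter. R
is estimated per eluate/supernatant pair, matched by condition and
replicate, and per-pair α columns are reported alongside their mean.
Geometric-mean aggregation (rather than a totals ratio) keeps one dominant
spike-in from controlling the factor; on simulated data the two differ by
well under 5%.

## Synthetic data

The generator emits exactly the structure the model assumes: NB counts
around depth·scale·fraction means, shared θ, spike-ins present only
post-IP with equal expected depth-scaled abundance in eluate and
supernatant and zero rows in the input. Defaults (500 genes, 2 replicates,
θ = 100, expression 100–10000 expected input counts, α uniform on
(0.02, 0.98), depths log-uniform on [0.5, 2], unit fraction scales) are a
desk-scale rendering of a two-replicate LAIC-seq-style experiment and run
in seconds. What it does *not* emulate — cross-fraction contamination,
gene-specific dispersion, isoform mixtures, mappability and coverage
biases, spike-in pipetting error beyond NB noise — bounds what passing
tests show: they validate the estimator under its own assumptions, not
robustness to their violation on real libraries.

## Problem sizes

Test and acceptance runs use 40–1000 genes and 1–2 replicates per
fraction. These sizes give stable statistics (e.g. binomial coverage at
500 genes, factor recovery at 1000 genes) while keeping a full suite run
to a few minutes; the estimator itself scales linearly in genes and has
been exercised to thousands.

## Known limitations

* Shared θ: genes with atypical dispersion get mis-calibrated intervals.
* Interval coverage is conditional on fitted normalization; with few
  replicates the extra variability of fitted factors is unaccounted.
* The full-fit θ̂ bias noted above; a REML-style correction is out of scope.
* Conditions are fitted independently; no formal between-condition test of
  modification differences is provided (overlapping intervals are only an
  informal screen).
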