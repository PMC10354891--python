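# Methods

## Model

Two-sample summary-data MR works from per-variant association estimates.
For instrument j, the exposure GWAS reports β_Xj (SE se_Xj) and the
outcome GWAS — from a non-overlapping cohort — reports β_Yj (SE se_Yj).
Under the instrumental-variable assumptions, the true effects satisfy
Γⱼ = θ·γⱼ + αⱼ, where γⱼ is the variant's effect on the exposure, θ the
causal effect of interest, and αⱼ a direct (horizontally pleiotropic)
effect on the outcome that is zero for a valid instrument.

Estimators in `mrkit.estimators`:

* **Wald ratio** θ̂ⱼ = β_Yⱼ/β_Xⱼ with first-order SE se_Yⱼ/|β_Xⱼ|.  The
  first-order form ignores exposure-side noise; it is the convention when
  instruments are strong, and a second-order correction (adding
  β_Yⱼ²se_Xⱼ²/β_Xⱼ⁴) is available behind a flag.
* **IVW** θ̂ = Σwⱼβ_Xⱼβ_Yⱼ / Σwⱼβ_Xⱼ², wⱼ = se_Yⱼ⁻² — identically the
  zero-intercept weighted least-squares slope of β_Y on β_X.  Fixed-effect
  SE (Σwⱼβ_Xⱼ²)^{-1/2}; the multiplicative random-effects variant (the
  default reported alongside fixed) inflates it by max(1, √(Q/(J−1))), so
  over-dispersion can widen but never narrow the interval.  Normal
  inference.  A single-instrument set degrades to the Wald ratio.
* **MR-Egger**: weighted regression β_Y = α + θβ_X after orienting all
  instruments to β_X ≥ 0 (signs of both effects flipped together; the
  input set is not mutated).  Both coefficient SEs carry the
  multiplicative scale max(1, RSS_w/(J−2)); p-values and CIs use t with
  J−2 df — honest small-J inference when an intercept is estimated.  The
  intercept estimates the mean directional pleiotropic effect; the slope
  is consistent under InSIDE (instrument strength independent of direct
  effects).
* **Weighted median**: order the Wald ratios, normalize the first-order
  inverse-variance weights wⱼ = β_Xⱼ²/se_Yⱼ², form the cumulative
  midpoints sⱼ = Σ_{k≤j}w_k − wⱼ/2, and interpolate θ across s at 1/2.
  Consistent while instruments carrying <50% of the weight are invalid.
  The SE is the standard deviation of the estimate over a parametric
  bootstrap (β_Xⱼ, β_Yⱼ redrawn from normals with their reported SEs);
  the bootstrap is the package's only stochastic estimator, so its seed
  is mandatory and `n_boot=0` gives a point estimate only (used inside
  large simulation studies).

Diagnostics in `mrkit.sensitivity`:

* **Cochran's Q** = Σ wⱼ(θ̂ⱼ − θ̂_IVW)² with wⱼ = β_Xⱼ²/se_Yⱼ², referred to
  χ²(J−1).  With these weights Q equals the weighted residual sum of the
  zero-intercept regression, keeping the heterogeneity statistic
  consistent with the IVW weighting.
* **Egger intercept test**: two-sided t test (J−2 df) of α̂ against zero.
* **MR-PRESSO global test**: RSS_obs = Σ wⱼ(β_Yⱼ − θ̂₍₋ⱼ₎β_Xⱼ)², with
  θ̂₍₋ⱼ₎ the leave-one-out IVW slope, compared against a parametric null:
  each replicate redraws β*_X ~ N(β_X, se_X²) and β*_Y ~ N(θ̂₍₋ⱼ₎β_X, se_Y²)
  and recomputes the same statistic (leave-one-out slopes re-estimated on
  the replicate).  p = (1 + #{RSS* ≥ RSS_obs})/(n_sim + 1), a valid
  Monte-Carlo p-value with floor 1/(n_sim+1).  Default n_sim = 2000
  (p resolution 5×10⁻⁴); fewer than 100 draws is allowed but flagged.
  The optional outlier/distortion follow-ups of the MR-PRESSO framework
  are out of scope; the global test is the tested surface.

## Instrument selection

The cascade runs in a fixed order — p-value filter, LD clumping, proxy
substitution, F screen, confounder pruning — with a per-stage audit count
so attrition is always monotone and inspectable.  Inequality conventions:
the p filter is strict (<); clumping removes at r² ≥ the threshold (so
retained pairs satisfy r² < 0.001 as usually quoted); proxies require
r² strictly > 0.8; the F screen keeps F ≥ 10.  "Window" means ±window
around the index variant.  Determinism everywhere: candidate ordering is
p ascending with variant-id tiebreak, making clumping invariant to input
order.  Variants absent from the LD reference are treated as independent
and a warning is recorded — this mirrors reference-panel dropout and
keeps the operation total.  Proxy records adopt the proxy's own
effects/alleles from both datasets; no imputation.  The confounder filter
removes a variant iff it carries at least one annotation in a configured
category with p below the (configurable, default 5×10⁻⁸) threshold; both
"remove" and "retain" policies for any category are expressible because
the category list is part of the configuration.

## Harmonization

The exposure labelling is the reference.  Identical allele pairs pass;
swapped pairs flip the outcome beta sign and EAF; strand (complement)
comparison is attempted only after direct and swapped comparisons fail,
minimizing spurious complement matches.  Palindromic variants are kept
and aligned by frequency agreement only when both EAFs fall outside the
ambiguity window (default (0.42, 0.58), the common tooling default; a
drop-all-palindromes switch exists); missing EAF on either side drops a
palindrome.  Flips are involutive, and kept + dropped always equals the
id-intersection size.

## Decision rules

A pair is *nominally significant* iff the IVW p-value is below 0.05 and
IVW, weighted median, and Egger slope all share a sign (a zero estimate
or an uncomputable method fails the rule).  Family-wise significance
replaces 0.05 by a Bonferroni threshold α/n; n defaults to the number of
pairs actually analyzed and can be overridden to a pre-specified family
size (e.g. 468 for a six-exposure × 78-trait screen).  The override
changes only the flags, never the estimates.  Per-pair seeds are derived
from SHA-256 of (master seed, exposure name, outcome name), so grid
results are reproducible and independent of execution order.

## Synthetic data generator

`mrkit.synth` draws γⱼ from a truncated normal |γ| ≥ γ_min (default
N(0, 0.08²), γ_min = 0.05), oriented positive by default — the convention
of reporting instruments on the exposure-increasing allele, which is also
what makes directional pleiotropy meaningful.  Per-SNP SEs are log-normal:
exposure median 0.004 (σ_log = 0.3), outcome median 0.01 (σ_log = 0.4),
emulating a very large (≈10⁶-sample) exposure GWAS against a mid-sized
(≈5×10⁴) outcome GWAS.  Under these defaults the per-SNP F = (β_X/se_X)²
spans roughly 25 to above 10⁴.  The floor is deliberate: instruments are
meant to look like *post-selection* variants — anything passing a
p < 10⁻⁵ filter necessarily has F ≳ 20 — and it keeps IVW's
weak-instrument dilution an order of magnitude below the Monte-Carlo
resolution of the recovery studies.  Observed effects add sampling noise
from two independent substreams (no sample overlap, matching the
two-sample design).  Pleiotropy laws: none, balanced (zero-mean),
directional (InSIDE holds), correlated with γ (InSIDE violated), and
contaminated (a fraction of instruments invalid).  Optional background
null SNPs, block-diagonal LD, a 10% palindromic-allele fraction, and
confounder annotations exercise the selection and harmonization stages.
`simulate_grid` gives each exposure its own variant namespace so null
cells of an exposure × outcome grid are genuinely null.

Canonical scenarios (`scenario_suite`): NULL (θ = 0, valid instruments),
CAUSAL (θ = 0.1, J = 100), BALANCED_PLEIOTROPY (σ_α = 0.01, constant SEs
so the intercept test's t reference is exact), DIRECTIONAL_PLEIOTROPY
(μ_α = 0.02), INSIDE_VIOLATED (ρ = 0.7), MINORITY_INVALID (30% invalid,
μ_α = 0.05) and MAJORITY_INVALID (60% — the median's guarantee is void
there, which is documented rather than asserted).

What the generator does *not* emulate: realistic human LD maps, winner's
curse from in-sample instrument discovery, sample overlap between the two
GWAS, binary-exposure selection effects, or allele-frequency-dependent
effect sizes.  Passing the simulation suites therefore demonstrates
correctness of the estimators and calibration under the stated model, not
robustness to those real-data complications.

## Numerical conventions

* p-values are clamped to (0, 1]: a numerically underflowing normal tail
  reports the smallest positive double rather than 0.
* CI identity ci = θ ∓ q·se holds exactly (q = z₀.₉₇₅ for normal methods,
  t₀.₉₇₅,J−₂ for Egger).
* Degenerate inputs are typed errors, not NaNs: β_X = 0 for a Wald ratio,
  all-zero exposure effects for IVW, J < 3 for Egger/median, J < 4 for
  the MR-PRESSO global test.  Inside `run_all_methods` and the grid these
  become structured `not_computed` entries so a screen never aborts.
* TSV dialect everywhere: tab-separated, `.` decimal, `NA` missing;
  floats written at %.17g so read∘write is the identity to ≤1e-12.
* Validation problem sizes (1000 replicates for type-I rates, 500 for
  recovery and bias orderings, 200 runs for the Monte-Carlo-p uniformity
  check, n_sim = 1000 for the planted-outlier test) were chosen so each
  check has clear resolution at desk scale: Monte-Carlo SE ≈ 0.007 on a
  5% rejection rate and ≈3 Monte-Carlo SEs of headroom on recovery bias.

## Known limitations

* The MR-PRESSO implementation covers the global test only.
* No Steiger directionality filtering, multivariable MR, MR-RAPS, or
  mode-based estimators.
* LD handling is lookup-based (a user-supplied r² reference); there is no
  genotype-panel clumping, and multi-allelic variants are out of scope.
* The weighted-median SE is bootstrap-only; no analytic alternative is
  offered.
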