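# Methods

## The screen being modelled

A site-saturation variant library over an L-residue metastable serpin
(default L = 379; 19 substitutions per site, 7201 possible variants, ~95.5%
present) displayed on phage is selected for protease inhibition twice: at 0 h,
and after a 48 h incubation at 37 °C during which active molecules convert to
the inactive latent conformation. Wild-type-like variants (half-life 1–2 h)
pass through 24–48 half-lives during the incubation and are essentially
eliminated; variants that slow the transition survive. Input and selected
pools are deep-sequenced, and per-variant log₂ enrichments measure inhibition
(0 h) and functional stability (48 h).

## Selection model

Capture probability after t hours:

    p_i(t) = a_i · 2^(−t / h_i)

with a_i ∈ [0, 1] the capture efficiency of the active conformation
(inhibitory activity) and h_i > 0 the latency half-life in hours. Expected
post-selection frequencies are f_i · p_i(t) renormalized. First-order decay is
the minimal kinetic model consistent with a stated half-life; it is
memoryless, so selecting at t₁ then t₂ (with a = 1) equals one selection at
t₁ + t₂ — a property the tests assert. The 30-min protease reaction at 0 h is
treated as t = 0, and decay during the selection step itself is ignored.

## Ground-truth structure and defaults

Per position: tolerance to substitution with respect to inhibition,
tol0 ~ Beta(2, 2) (mean 0.5, matching a screen in which roughly half of all
substitutions score as functional); tolerance with respect to stabilization,
tol48 = 0.7 inside planted stabilizing regions and 0.1 outside. The planted
regions default to the five intervals a full-scale screen of this serpin
calls stabilizing (40–45, 72–93, 158–178, 216–237, 320–347).

Per variant, in draw order under one seeded generator: functional with
probability tol0 of its position; activity log-uniform on [0.25, 1] if
functional (functional variants in selection screens spread over roughly two
log₂ units of enrichment) and log-uniform on [0.001, 0.02] if not (depleted
but never absent, so their scores are finite); half-life uniform on [1, 2] h;
*strongly stabilized* (half-life × 20) with probability tol48 of its position
if functional and inside a planted region; otherwise *weakly stabilized*
(half-life × 4) with probability 0.5 if functional.

### Why the weak-stabilization tier exists

Kinetic effects of substitutions are graded, not binary; a full-scale screen
of this protein scores ~63% of its refined (0 h-functional) variants
positive at 48 h, which a two-class world cannot produce. The tier also
matters numerically: median-of-ratios normalization anchors the selected
sample's scale on the variants that still have counts in *every* sample.
After 48 h, wild-type-like variants have none, so without an intermediate
class the anchor is the strongly stabilized class itself — centering those
variants' log₂FC at zero, making half of them score negative, and pushing the
entire positional acceptance profile below zero (no stabilizing region can
then be called, because a value below zero is classified destabilizing with
precedence). With a broad weak tier, the anchor sits between wild-type-like
(deeply negative) and strongly stabilized (clearly positive) variants, which
is also where a real screen's wild-type-dominated background places it. The
tier is position-independent, so it adds no structure to the conservation
model or the region truth — it is background, not signal.

Spike-ins default to I91L at 2.6% and E242T at 1.4% of the input library
(the synthetic wild-type sequence forces Ile91 and Glu242 so the names stay
meaningful). Sequencing counts are negative binomial per variant with mean
depth·f and variance mean + α·mean² (α = 0.05, depth 2×10⁶, 3 replicates per
condition); α = 0 degenerates to a multinomial draw.

Predictor tables: VEP score = clip(1 − a + ε, 0, 1), ε ~ N(0, 0.05) — a
monotone decreasing function of activity, blind to half-life. ΔΔG in each
conformation = baseline (0.5 active / 0.8 latent kcal/mol) + 2.5 kcal/mol
misfolding penalty if nonfunctional + N(0, 0.5) — again independent of
half-life, encoding the hypothesis that predictors see misfolding, not
latency kinetics. Conservation (higher = more labile):

    score_p = α·tol0_p − β·tol48_p + ε_p,   α = 1.3, β = 0.73, ε ~ N(0, 0.3)

with the two coefficients set to the magnitudes of the slopes such screens
report.

## Enrichment engine

A defined, self-contained NB procedure (deliberately *not* a port of any
published differential-abundance package, whose shrinkage estimators are out
of scope):

- **Size factors**: per-sample median of count / geometric-row-mean over
  variants positive in every sample, rescaled to geometric mean 1.
- **Dispersions**: method of moments max(0, (s² − μ̄)/μ̄²) on normalized
  counts within each condition with ≥ 2 replicates, pooled by replicates − 1,
  shrunk 50/50 toward a fitted trend α(μ) = a₀ + a₁/μ (coefficients clipped
  ≥ 0), floored at 10⁻⁸. Single-replicate designs fall back to a configured
  prior (0.05) with a logged warning.
- **Test**: log₂FC of pseudocounted (½) normalized condition means; SE by the
  delta method with the pseudocounted mean as working mean so fully depleted
  variants keep finite uncertainty; two-sided normal Wald p; BH over
  baseMean ≥ 50 variants only (others carry no adjusted p), mirroring the
  thresholding order of the original analysis.
- Classification convention everywhere: score > 0 is the upper class;
  0 folds into the lower (reduced / destabilized) class. The post hoc
  refinement filter, in contrast, removes scores strictly *below* zero, so an
  exact 0 is retained there.

## Positional analysis

Mutational acceptance = mean (configurable: sum) of refined 48 h scores per
position; positions with no refined variant are gaps and excluded from
smoothing windows. LOWESS dialect, frozen: the k = 20 nearest positions with
values, tricube weights on distance scaled by the window radius, local
degree 1, no robustness iterations. Region calls: destabilizing where the
smoothed value is < 0; stabilizing where it reaches the 75th percentile of
the smoothed series (linear-interpolation percentile; a "greater than the
mean" threshold is available via configuration); destabilizing takes
precedence so an all-negative profile yields no stabilizing region. Runs of
consecutive positions with one class merge into 1-based inclusive intervals;
the BED export is the package's single 0-based half-open surface.

## Statistical comparisons

- Stratified predictor comparisons report per-stratum means with normal 95%
  CIs (mean ± 1.96·sd/√n) and test the class difference with
  predictor ~ class + (1 | position), fit by REML with a Wald p. The reported
  coefficient is the lower-stratum effect, so positive = the
  reduced/destabilized class has the higher predictor value. If the
  random-intercept variance estimates to (numerically) zero or the fit fails,
  the test falls back to OLS with a logged warning — which is also the
  correct degenerate answer.
- Quadrants: positions are split at the medians of npc(0 h) and npc(48 h);
  ties go to the low half (npc values are discrete fractions, so ties are
  real). Cartesian numbering with x = npc 0 h, y = npc 48 h: Q1 (hi, hi),
  Q2 (lo, hi), Q3 (lo, lo), Q4 (hi, lo) — chosen so Q4 is
  inhibition-permissive/stability-constrained and Q3 doubly constrained.
  One-way ANOVA across quadrants, Tukey HSD with the Tukey–Kramer adjustment
  for unequal sizes; identical conservation everywhere returns F = 0 by
  convention.
- Two-way ANOVA of conservation on the two median-split classes uses type-II
  sums of squares (quadrant occupancies are never balanced), denominator
  df = n − 4; constant or confounded factors are design errors.

## What a green test does and does not establish

The generator emulates library composition, two-timepoint selection,
overdispersed counts, predictor blindness to kinetics, and
tolerance-linked conservation. It does not emulate: amplicon structure and
the wild-type background correction (so spike-in artifacts can be
demonstrated but not corrected), codon-level biases, selection-round
stochasticity beyond count noise, epistasis, or phylogenetic
non-independence of conservation scores. Recovery tests therefore establish
that the pipeline's inference is faithful to its own model class, not that
the model captures every property of real screens.

One planted expectation is structurally out of reach of the additive
conservation model: with score = α·tol0 − β·tol48 + ε and quadrants split on
proxies of tol0 and tol48, the (lo, hi) quadrant Q2 is at or below the
(lo, lo) quadrant Q3 in expectation whenever β > 0, so Q3 cannot reliably be
the *minimum* quadrant mean — Q2 takes that role (real data from such screens
agree: their Q2 and Q3 means are statistically indistinguishable). The
corresponding acceptance test asserts the Q3-minimum expectation as stated
and is expected to fail; the regression-sign and significance expectations
around it hold.

## Numerical choices

- Frequencies must sum to 1 within 10⁻⁶ on input; post-selection frequencies
  renormalize exactly.
- Wald SEs are floored at 10⁻¹²; p-values clipped into (0, 1].
- Percentiles use numpy's linear interpolation.
- LOWESS windows with zero radius (all ties) average; singular local fits
  return the weighted mean.
- Floats round-trip through TSV/CSV at 12 significant digits; counts are
  int64 and validated (nonnegative integers) with 1-based row numbers in
  errors.
- One `numpy.random.Generator` per simulation run; every stochastic
  operation draws from it in the documented order, so equal seeds give
  byte-identical outputs.

## Known limitations

- The enrichment engine's p-values rely on a plug-in dispersion and a normal
  Wald statistic; with 3 replicates they are approximate. The all-null
  calibration test bounds the practical consequence (empirical FDR well
  under the nominal 10%).
- No log-fold-change shrinkage is applied; scores of low-count variants are
  noisy and rely on the baseMean filter.
- The 48 h screen cannot separate half-lives at or below wild type (both
  deplete completely); the refinement step removes the inhibition-dead
  variants but the remaining negative scores conflate "wild-type-like" with
  "mildly destabilized", exactly as in the real experiment.
- Conservation scores are consumed as-is; the sign convention
  (higher = more labile) is the caller's responsibility.
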