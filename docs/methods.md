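# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `oakselect`, in the
spirit of a model-documentation page rather than a tutorial.

## Variance components and heritability

For each trait, population and garden, the model is a one-way
family-random-effects linear mixed model with garden block as a fixed
effect:

    y = X beta + Z u + e,   u ~ N(0, V_g I),   e ~ N(0, V_e I)

Maternal families grown from open-pollinated acorns of a single mother are
treated as *full siblings*; under that reading the family variance
component is reported directly as the genetic variance V_g (no ×2/×4
sib-covariance conversion) and broad-sense heritability is
H² = V_g/(V_g + V_e). Full-sib family variance in truth confounds additive,
dominance and maternal-environment contributions; with unknown fathers
these cannot be separated, which is why the broad-sense label is used.

**Estimation.** Restricted maximum likelihood, chosen because family sizes
are unbalanced after field mortality and because REML removes the bias from
estimating the block fixed effects. The covariance matrix is block diagonal
by family and each block V_e I + V_g J has closed-form inverse and
determinant (Sherman–Morrison), so the restricted likelihood is evaluated
exactly in O(n). The likelihood is profiled over the ratio
λ = V_g/V_e: a log-spaced grid (10⁻⁶–10³, 55 points, plus λ = 0) locates
the basin and Brent's bounded method polishes it (`xatol = 1e-12`). V_g is
constrained non-negative; the boundary λ = 0 is always compared against the
interior optimum. The response is centered before fitting (REML is location
invariant; centering avoids catastrophic cancellation in the quadratic
form) and the intercept is restored afterwards. On balanced one-way data
this machinery reproduces the ANOVA method-of-moments estimators to < 1e-6,
which the test-suite uses as an independent oracle; on unbalanced data it
matches `statsmodels.MixedLM` to ~1e-4.

**Inference.** Evidence for V_g > 0 is the likelihood-ratio statistic
−2(L₀ − L_max) referred to χ² with 1 df. Because the null places V_g on the
boundary of its parameter space, the asymptotic null is actually the
mixture ½χ²₀ + ½χ²₁, so the plain χ²₁ reference is conservative
(true size ≈ 0.025 at nominal 0.05); the χ²₁ convention is retained
deliberately as the field-standard reporting choice, and the null
calibration test verifies the conservatism empirically. Standard errors of
(V_g, V_e) are square roots of the diagonal of the inverse observed
information, computed by central finite differences of the restricted
log-likelihood at the optimum (relative step 1e-5); at a boundary optimum
the V_g curvature is one-sided and the SE may be reported as NaN.

Only univariate (per-trait) components are estimated. Multi-trait REML
would additionally yield genetic covariances, but per-trait variances are
what heritability and the breeder's equation consume; the trivariate
generalization is a documented non-goal.

## Two-node fitness model

Lifetime fitness is approximated by a minimal life-history graph:
two-year survival s ~ Bernoulli(p), logit p linear in the predictors, and
final height h | s = 1 ~ N(μ, σ²), μ linear in the same predictors. The
predictors are maternal family, height at initial planting (to absorb
early maternal provisioning), and block — all fixed effects with
reference-level coding. The joint likelihood

    L = Π Bern(s_i; p_i) · [N(h_i; μ_i, σ²)]^{s_i}

is maximized by damped Newton–Raphson on the full parameter vector
(analytic gradient and Hessian; the Hessian is block diagonal across
nodes because the parameters are disjoint). That same disjointness means
the joint MLE coincides with a two-stage fit (logistic regression, then
least squares on survivors), which the test-suite exploits as an
independent oracle: agreement is verified to 1e-8 on every simulated
dataset without separation. σ² is the MLE (RSS/n_survivors).

Complete separation in the survival node (the fitted linear predictor
perfectly orders outcomes, so no stationary point exists) is detected on
non-convergence and raised as an error recommending a penalized fit.
Families in which every tree survived drive their survival coefficient to
a large saturated value; the fit still converges by gradient norm and the
predictions are unaffected (p̂ → 1), so this is tolerated, matching
standard GLM practice.

Expected fitness is the unconditional terminal-node mean Ŵ = p̂·μ̂ (cm).
Individuals observed dead still receive a model-based expected fitness, so
downstream selection analysis accounts for mortality differences rather
than conditioning on survival. Because both nodes share one design matrix,
the MLE satisfies Σ(s − p̂)ᵀXc = 0 for the height coefficients c, giving the
exact balance mean(Ŵ) = mean(s·h) — a property the tests check to 1e-6.
Negative μ̂ at extreme covariates is possible and is not truncated. Whether
block enters is decided per garden by an omnibus LRT across both nodes
(df = twice the number of block contrasts).

## Selection analysis

Relative fitness is w = W/W̄ within garden (mean 1 by construction);
traits are z-scored within garden (sample SD). A configuration switch
allows within-(garden × population) standardization for the
population-level models; within-garden is the default because the
garden-level and population-level analyses then share one scale.

* **β** — partial regression coefficients of w on the standardized traits,
  from linear mixed models with random intercepts for block and (at garden
  level) population, fit by REML (`statsmodels` MixedLM with variance
  components on a single dummy group, which accommodates the crossed
  structure). Significance is a two-tailed t-test with residual degrees of
  freedom n − k. If the mixed fit fails to converge — common when the
  random-effect variances are at zero — the fit falls back to OLS with a
  loud warning; with no random structure the two coincide exactly, and
  β = P⁻¹S (P the trait covariance matrix) holds to numerical precision.
* **S** — sample covariance of w with each standardized trait
  (ddof = 1), total selection including indirect paths through correlated
  traits.
* **γ** — coefficients of the *pure squared* standardized trait terms in a
  separate quadratic regression that retains all linear terms.
  Cross-product (correlational) terms are not fit. γ is reported as the
  raw regression coefficient — the doubling convention that converts it to
  the curvature of the individual selection surface is documented here but
  intentionally off, matching the extraction convention of the analyses
  this package mirrors. Negative γ is labeled stabilizing, positive
  disruptive.
* **Collinearity** — variance inflation factors 1/(1 − R²) computed by
  regressing each candidate on the others; predictors with VIF > 5 are
  dropped iteratively, worst first, recomputing after each drop.
* **Response** — breeder's equation R = H²·S per trait, population and
  garden, interpreted as the predicted one-generation shift of the
  standardized trait mean.

## Synthetic-data generator

The generator is first-class, tested code, and its defaults *are* the
study conditions: 3 gardens × 3 populations × 20 maternal families × 10
individuals per family per garden (600 per garden, 1800 total), 6 blocks
with block SD 0.1, per-trait V_g = 0.3 and V_e = 0.7 (H² = 0.3, typical of
field heritabilities for growth and physiology traits). Family effects are
drawn once per family and shared across gardens — the same genotype pool
is planted everywhere, as in a reciprocal transplant; garden-by-genotype
interaction can be injected through garden-specific variance overrides.

The fitness stage draws survival from a logit-linear surface and survivor
height from a linear (optionally quadratic) surface in the standardized
trait deviations and standardized initial height. Garden survival
intercepts default to logits 1.8/2.2/0.4 (≈ 86/90/60% survival), encoding
the north-to-south mortality gradient of the motivating field design, and
garden height intercepts 60/80/70 cm put the central garden tallest.
Directional selection defaults to height_beta = {RGR: 2 cm/SD}. For purely
linear surfaces the implied Lande–Arnold gradient of the surface,
β_j = E[W z_j]/E[W], is computed by reducing the multi-dimensional
expectation to one-dimensional Gauss–Hermite quadrature over the survival
linear predictor (conditioning the Gaussian inputs on it); the test-suite
verifies this oracle against brute-force Monte Carlo to < 0.003.

Spectra are phenomenological: a sigmoidal red-edge baseline minus Gaussian
absorption features at 531/645 nm (pigments), 970/1400/1900 nm (water) and
a broadband NIR term (LMA), with depths modulated by the trait deviations,
plus optional population-specific Gaussian offsets (for classifier
testing), an optional step at 990 nm (for splice testing), and white
noise (SD 0.002). They exercise splicing, index extraction and
classification but are *not* radiative-transfer physics: real leaf spectra
have correlated band noise, nonlinear pigment responses and specular
effects the generator omits, so passing classification tests here
demonstrates correctness of the algorithms, not field-level accuracy.
`spectral_trait_coupling = 0` switches the trait-driven variation off
entirely, giving the single-informative-band construction used by the
planted-signal tests (with coupling on, large-variance water bands
legitimately dominate the variance-weighted loading ranking even when the
class signal sits elsewhere).

Randomness derives from one master seed via `numpy.random.SeedSequence`
spawning, so each stage is independently reproducible.

## Spectral preprocessing

Sensor splicing treats the lower-wavelength detector as the reference: for
each splice point p with window width w, reflectance strictly inside
[p, p + w] is replaced by the straight line between the nearest grid
points outside the window. The two field recipes (990/1100 nm with 5/1 nm
windows; 990/1900 nm for transmittance work) are both expressible —
neither is hard-coded. The operation is idempotent and leaves an already
continuous spectrum unchanged to machine precision. Resampling is linear
interpolation with extrapolation forbidden; band extraction interpolates
linearly when the requested wavelength is off-grid (on a 10 nm analysis
grid the standard bands 700/900/1400 nm are on-grid, so interpolation only
makes the operation total). Raw spectra with reflectance outside [0, 1]
are excluded with a QC report rather than clipped, since clipping would
silently distort indices.

## PLSDA

The SIMPLS algorithm (successive weight vectors from the SVD of the
deflated cross-product matrix X'Y, deflation in the loading space)
regresses the column-centered one-hot class indicator on centered
predictors. At full rank its fitted values equal the OLS fit of the
indicator matrix, and for a single response column it coincides with
NIPALS PLS — both serve as test oracles (the latter against
scikit-learn). Class posteriors are Gaussian class-conditionals on the
score space with pooled within-class covariance and empirical class priors
(the "Bayes" option of the reference workflow names the prior handling
but not the density; pooled-covariance Gaussians are the standard
realization and keep prediction deterministic). Component count is chosen
by bootstrap out-of-bag Cohen's kappa: stratified resampling within class,
Tukey's HSD across candidate counts, and the smallest count not
significantly below the best mean — a parsimony reading of "maximal
plateau", since the plateau rule itself is underdetermined. The default
bootstrap size is 200; the tests and pipeline default use 10–50 for
turnaround, a scaled-down choice recorded in the pipeline configuration.
Wavelengths are ranked by maximum absolute loading across components
(sign- and component-permutation invariant).

## Problem sizes in the test-suite and acceptance script

The statistical checks use: 200 replicates of the 20 × 10 balanced family
design for variance-component recovery; 500 null replicates for LRT
calibration; 200 replicates of 600 trees for linear-gradient recovery and
200 × 600 for quadratic recovery; bootstrap size 50 for the planted-signal
classification checks. The acceptance script uses 100–200 replicates per
quantity. These sizes put Monte-Carlo error well inside the assertion
bands while keeping a full run in tens of seconds.

## Known limitations

* Family variance is reported as V_g under the full-sib assumption; if
  families contain half-sibs the genetic variance is underestimated, and
  maternal-environment effects inflate it. Neither is separable without
  paternity data.
* The χ²₁ LRT reference is conservative at the boundary (see above).
* Aster-style fitness prediction transmits trait signal only through
  family membership and initial height, so selection gradients estimated
  from model-predicted fitness are attenuated toward the between-family
  component of selection; gradient-recovery tests therefore use realized
  fitness (survival × height), whose conditional expectation is exactly
  the generating surface.
* Correlational selection (γ_ij, i ≠ j) and spline fitness surfaces are
  out of scope; the quadratic model measures curvature one trait at a
  time.
* The spectral forward model is non-physical (see above); no
  radiative-transfer inversion is provided.
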