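# Methods

## Force model

The axial puncture force is the sum of three depth-dependent components.
All interfaces use millimetres, newtons, seconds and degrees; angles are
converted to radians only inside trigonometric calls.

**Cutting.** The default model is a saturating exponential
`f_c(z) = f_max (1 − e^{−λz})`: near the surface it rises linearly as
`f_max λ z` (within 1% for `z ≤ 0.01/λ`), and it approaches the rupture
limit `f_max` at depth, reflecting that tissue fracture resistance does
not grow without bound. A constant model `f_c = Γ·w₀` is available for
the stable cutting phase; it requires the `gamma_w0` parameter and is
depth-independent.

**Stiffness.** `f_s(z) = k₀ e^{αz} z sin θ`, the product of an
exponentially growing equivalent stiffness `k(z) = k₀ e^{αz}` and the
effective compression `δ(z) = z sin θ`. The puncture angle θ is the
inclination between needle shaft and tissue surface, valid on (0°, 90°];
90° is perpendicular insertion and maximizes compression. Values above
90° are rejected rather than reflected — the convention tops out at
perpendicular. The same depth variable drives both the exponential and
the linear factor: the derivation evaluates every term at the current
needle-tip depth.

**Friction.** A modified Coulomb model: the shaft friction is the
integral of the friction coefficient times the stiffness-derived normal
stress over the inserted length, giving the closed form
`f_f(d) = μ₀ k₀ sin θ [e^{αd}(αd − 1) + 1]/α²`. The needle radius cancels
between the contact-area and normal-stress expressions and does not
appear; `NeedleSpec` stores it for provenance only. At `α = 0` the
expression is a removable singularity with limit `μ₀ k₀ sin θ d²/2`; the
implementation switches to the limit below `α = 1e−6 mm⁻¹`, where the
direct formula would suffer catastrophic cancellation. An adaptive-
quadrature evaluation of the integrand (`friction_force_quadrature`)
serves as an independent oracle for the closed form; the two agree to
better than 1e−8 relative across the tested (d, α, θ) grid.

Reference parameter sets are bundled: liver (f_max 1.68 N, λ 0.12 mm⁻¹,
k₀ 0.05 N/mm, α 0.21 mm⁻¹) and renal (1.12, 0.15, 0.08, 0.25), both with
μ₀ = 0.2.

A caveat on extrapolation: with α ≈ 0.2 mm⁻¹ the exponential stiffness
term grows by e⁸ ≈ 3000 over a 40 mm stroke, so the reference parameters
produce physically implausible forces at the deep end of the default
synthetic protocol. Parameter recovery is unaffected (the estimator is
scale-free in the response), but users modelling deep strokes should
treat α as valid only over the depth range it was identified on.

## Viscoelastic law

Rate dependence for renal tissue uses the additive law
`σ(t) = E ε(t) + η dε/dt`. Although this form is commonly introduced next
to a spring–dashpot-in-series sketch, the equation as written is
algebraically the parallel (Kelvin–Voigt) arrangement; it is implemented
exactly as stated and no series ODE is substituted. The strain rate is
computed with central differences at interior samples and one-sided
differences at the ends (`numpy.gradient`), second-order accurate on
uniform interior grids; on a sampled constant-rate ramp the response
matches the closed form `E·r·t + η·r` to machine precision at interior
points, and halving the step at least halves the interior error on
smooth strains. The law can optionally feed the renal generator as an
additive correction scaled by a coupling factor (default off, because no
explicit coupling between stress relaxation and the measured axial force
is defined); strain is then proxied by normalized depth.

## Lateral perturbation

Robot-arm micro-vibration is modelled as a transverse displacement
`u_x(t) = A sin(2πft)`, operating point A = 0.05 mm, f = 1000 Hz. The
tabulation utility discretizes the signal into the two-column
time–displacement table an explicit-dynamics solver ingests as a remote
displacement boundary condition (default step 1/(20f), twenty samples
per period; a Nyquist warning fires for coarser steps).

How lateral displacement maps into the *measured axial force* is not
observable at desk scale, so `apply_perturbation` emulates it with a
linear coupling coefficient (default 0.1 N/mm, configurable): the axial
ripple is `coupling · u_x(t)`, optionally with a seeded random phase
jitter. Consequences worth knowing:

- the amplitude sweep reproduces the qualitative monotone
  accuracy-vs-amplitude trend, not absolute error levels;
- with jitter off the sweep is exactly linear (doubling A doubles RMSE);
- a force curve sampled below the disturbance's Nyquist rate cannot
  resolve the ripple — sampling a 1 kHz sine on a 10 Hz grid hits its
  zeros stroboscopically — so the code warns and sweep demonstrations
  use short, fast-sampled base curves.

Default sweep amplitudes {0, 0.025, 0.05, 0.1} mm bracket the operating
point.

## Synthetic trials

The generator produces the statistical structure the downstream analyses
assume, in place of undeposited experimental data.

- **Kinematics.** depth(t) = v·t up to `max_depth` at the configured
  sample rate; retraction appends samples with depth returning to zero
  and force decaying exponentially from the final insertion value (rate
  chosen so the force falls to 5% of peak over the retraction unless
  overridden). The model is depth-driven; speed enters through the
  time–depth map, plus an optional rate multiplier (default 1) for users
  who want to emulate the empirically observed speed effect.
- **Noise.** Additive i.i.d. Gaussian on force, default sd 0.02 N
  (roughly 1–2% of typical liver peak forces), seeded.
- **Layers.** A `LayerProfile` is an ordered contiguous stack of
  segments, each with its own parameters. Within segment i the model is
  evaluated at the local depth `z − start_i` and added to the force
  carried in from the previous segment, so cutting and stiffness restart
  at each interface while the total stays continuous; adjacent segments
  blend through a logistic weight over `transition_width` (default
  0.5 mm) which smooths the slope change without moving the boundary.
  The default renal fixture (cortex 0–10 mm, medulla 10–25 mm, calyx
  25–40 mm; medulla stiffest, calyx softest and friction-dominated)
  reproduces the slow/steep/slow gradient signature of a layered renal
  puncture; its depths and parameters are package conventions, not
  measured values.
- **Factorials.** `generate_experiment` builds one trial per
  speed × angle × repeat cell (defaults: speeds 0.5/1.5/2.5 mm/s, 5
  repeats; angle studies use 15°/30°/45°). Per-trial seeds are derived
  from the master seed by hashing the condition tuple, giving bit-exact
  reproducibility with mutually independent trials.

What the generator deliberately does not emulate: within-layer
heterogeneity and anisotropy, stick-slip/rate-dependent friction,
discrete rupture events, and the empirically reported *inverse* angle
trend (peak forces highest at shallow angles due to longer paths through
stiff superficial layers). The analytic model scales as sin θ and the
generator follows the model; emulating the path-length effect would
require capsule geometry the model does not contain. Passing tests
therefore demonstrate correctness of the pipeline on model-consistent
data, not fidelity to every feature of real tissue.

## Parameter identification

`fit_model` minimizes the sum of squared residuals (equivalently RMSE)
between the analytic model and the insertion-phase samples — retraction
is never fitted, as the model has no retraction equation. The optimizer
is `scipy.optimize.least_squares` with the trust-region reflective
method: Levenberg–Marquardt-style damped Gauss–Newton steps with smooth
handling of box bounds (default (1e−4, 100) in each parameter's natural
units). Tolerances default to 1e−10 (cost, step, gradient), max 500
iterations.

Free parameters default to {f_max, λ, k₀, α} with μ₀ fixed at 0.2: at
fixed α, μ₀ and k₀ enter the friction term only through their product,
so freeing both is weakly identified. The degeneracy is surfaced rather
than hidden — `FitResult.jacobian_cond` is the condition number of the
*column-normalized* Jacobian (normalization removes unit-scale
disparities so the number measures collinearity), and a friction-
dominated fit with both μ₀ and k₀ free shows a condition number orders
of magnitude above a standard fit.

When no initial guess is supplied, a data-driven heuristic is used:
f_max starts at 80% of the observed peak, λ at 3/max_depth, and k₀, α
from a log-linear fit of the late-depth force gradient (which the
exponential stiffness term dominates). Optional multi-start (seeded
log-uniform jitter of the init, best cost kept) is available for noisy
data. Non-convergence returns the best iterate flagged
`converged=False`; a singular Jacobian leaves the covariance `None`.
`recovery_report` summarizes repeated fits per parameter: bias, relative
error quantiles, and coverage of approximate 95% normal intervals from
the Jacobian covariance.

On the reference scenario (0.5 mm/s, 40 mm, 10 Hz) recovery is exact to
~1e−11 relative on noiseless data from ±20%-perturbed starts, and the
median per-parameter error stays well under 5% at 0.02 N noise.

## Evaluation

RMSE, R² (1 − SS_res/SS_tot about the observed mean; an explicit error
for constant observations) and maximum absolute error, cross-checked
against direct-loop oracles. The unified error z-scores each metric
across conditions (population sd; R² sign-flipped so larger always means
worse), then takes a weighted mean with weights normalized to sum to one
(equal by default); zero-variance metrics contribute zeros with a
warning. The construction is invariant to affine rescaling of any single
metric.

Segmentation locates layer interfaces as the strongest slope changes of
the force–depth curve: moving-average smoothing (default 9 samples),
depth-gradient, then the n−1 largest well-separated peaks of the
absolute gradient change. Two numerical details matter. Box smoothing
flattens a sharp slope break into a curvature plateau whose argmax can
sit at an edge, so each peak is refined to the local curvature centroid
— on the noiseless renal fixture this recovers both boundaries exactly.
And a homogeneous exponential curve has smoothly growing curvature that
can produce spurious "peaks"; a detection is flagged `low_contrast`
unless the peak stands clear of both the global median curvature and the
local curvature two windows away. The method is deterministic and
invariant to force rescaling. With 0.02 N noise at 10 Hz the curvature of
the noise dominates the layer signal and the flag fires — boundary
recovery is only claimed for clean or strongly averaged curves.

## Statistics

One-way ANOVA via the standard between/within decomposition (p from the
F distribution), and Tukey HSD in the Tukey–Kramer form
`se = sqrt(MS_within/2 (1/n_i + 1/n_j))`, which reduces to the balanced
formula for equal n. Quantiles and adjusted p-values come from the
studentized range distribution evaluated numerically
(`scipy.stats.studentized_range`); critical values are cached per
(α, k, df). Each row reports meandiff (first group mean minus second),
p_adj, CI bounds and a reject flag; reject ⇔ p_adj < α ⇔ CI excludes
zero, by construction. A `compute_p=False` fast path decides from the
interval alone (identical decisions, ~100× faster), used for the
2000-replicate null simulation that confirms the family-wise error rate
≈ 0.05. The per-trial response feeding the factorial reports is
configurable; peak force is the default. α is fixed at 0.05 unless
overridden.

## Files, configuration, determinism

Curve files are '#'-commented CSV (`t_s, depth_mm, force_N, phase`) with
full `repr` float precision: write→read round trips are bit-exact, and
malformed rows are reported with their line numbers. Run configurations
are YAML with unknown keys rejected. Every CLI artifact embeds a short
SHA-256 hash of its producing configuration; the `stats` command hashes
manifest *content* rather than paths so identical data yields identical
reports wherever it lives. No timestamps enter output files, so a rerun
of `synth → fit → stats` from one master seed is byte-identical.

## Problem sizes

Defaults used throughout the tests and the acceptance script: 801-sample
curves (40 mm at 0.5 mm/s, 10 Hz), 20 replicate fits for the noisy
recovery study, 50 datasets for the reference cross-check, 2000
simulations for the null family-wise error, and a 2001-sample 20 kHz
base curve for the perturbation sweep. The whole acceptance run takes a
few seconds on one core.
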