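# Methods

## Model and assumptions

The artery of interest is modelled as a rigid, axisymmetric lumen: an
arclength coordinate `s` (mm), a 3D centerline, and a radius profile
`r(s)` (mm). Flow is steady, laminar and Newtonian (dynamic viscosity
μ = 0.0035 Pa·s, density ρ = 1056 kg/m³ — standard blood analogue values);
there is no pulsatility, no fluid–structure interaction, no side-branch
outflow and no gravitational correction of the measured pressures.
Pressures are prescribed at the reconstruction inlet (Pa) and outlet (Pd),
both in mmHg (1 mmHg = 133.322 Pa); flows are reported in ml/min and
resistances in Wood units (mmHg·min/L), with the factor 1000 converting
ml/min to L/min in `CMVR = 1000·Pd/Q`.

### Two-view reconstruction

Synthetic angiographic views are orthographic projections of the
centerline with the local silhouette half-width; under axisymmetry the
half-width equals the local radius in every view. Reconstruction requires
the two view lines to be at least 30° apart (the acute angle between the
projection directions; antiparallel orthographic views carry identical
information). Correspondence between the two polylines is by normalized
arclength; each 3D centerline point is the least-squares intersection of
the four back-projection constraints, and the radius is the arithmetic
mean of the two half-widths, which is unbiased under axisymmetry. The
recovered radius profile is lightly smoothed with a Savitzky–Golay filter
(polynomial order 2, window of about n/14 samples, minimum 5): a
second-order filter is exact for locally quadratic profiles, so smooth
stenoses are essentially unaffected while half-width measurement noise is
attenuated by roughly the square root of the window length. Epipolar
consistency is not used for correspondence (the phantoms are straight-axis
tubes, for which normalized-arclength correspondence is exact); it would
be the natural extension for curved vessels.

### Reduced-order flow model (default backend)

The pressure drop across the lumen is `ΔP = a·Q + b·Q²` with

* `a = ∫ 8μ / (π r(s)⁴) ds` (trapezoidal quadrature) — the lubrication
  (locally Poiseuille) viscous resistance, exact for a constant-radius
  tube;
* `b = K_e · ρ/2 · (1/A_min − 1/A_out)²` — a Young–Tsai-type separation
  loss at the stenosis throat, with the classical empirical coefficient
  K_e = 1.52 (configurable) and A_min, A_out the minimal and distal
  cross-sectional areas; `b = 0` for an unstenosed tube.

Given Pa > Pd the flow is the unique positive root of the quadratic,
evaluated in the cancellation-free form `Q = 2ΔP/(a + √(a² + 4bΔP))` so
the defining equation is satisfied to ~1e-15 relative even when `b` is
tiny.

### Axisymmetric Navier–Stokes backend (internal oracle)

The steady incompressible equations are solved in stream-function /
vorticity form on a body-fitted grid (ξ = x, η = ρ/R(x), default 128×32
cells). Continuity is satisfied identically by the Stokes stream function;
the azimuthal vorticity transport equation is discretized with
second-order central differences, convection blending smoothly from
central to first-order upwind as the local cell Péclet number grows
(the blend θ = Pe²/(1+Pe²) is continuous in the velocity field, which
keeps the Picard iteration free of switching limit cycles). The flow rate
enters through the stream-function wall value (ψ_wall = Q/2π); no-slip and
the axis condition are exact, wall vorticity uses Jensen's second-order
one-sided formula. The Picard iteration applies implicit (diagonal-boost)
under-relaxation of the vorticity solve (factor 0.65) and explicit
relaxation of the wall vorticity (0.2); once the residual falls below 50×
the tolerance the iteration latches onto heavier damping (0.3 / 0.05) to
suppress a marginally damped oscillatory mode that otherwise sustains a
small residual floor in separated flows, and it restarts from the
developed-flow initial guess with halved factors if it ever blows up.
Convergence is declared when the relative change in vorticity falls below
the configured tolerance (default 1e-6, at most 10,000 iterations);
non-convergence is a first-class logged outcome, not a crash.

The pressure drop at a given Q is recovered from the discrete mechanical
energy balance, `ΔP·Q = Φ + KĖ_out − KĖ_in`, where Φ is the volume
integral of the viscous dissipation function and KĖ the kinetic-energy
fluxes through the end faces (face viscous work vanishes for developed
end profiles). An outer secant iteration on Q then matches the prescribed
Pa − Pd; warm-started inner solves make this converge in a handful of
evaluations. Prescribing pressures this way is equivalent to pressure
boundary conditions for a steady rigid-lumen problem.

On a straight tube the solver reproduces the parabolic profile
(u_max/u_mean = 2.00 within 0.5% at 64×16) and the Poiseuille flow with
monotone second-order grid convergence (0.6% at 32×8, 0.08% at 128×32).

### Where the two backends agree — and where they should not

The reduced model's K_e = 1.52 was calibrated on abrupt (blunt-plug)
stenoses, where the post-throat jet dissipates with essentially no
pressure recovery. For smooth cosine-shaped stenoses at throat Reynolds
numbers above ~100 the divergent segment acts as a partial diffuser: the
axisymmetric solution recovers a substantial fraction of the jet's kinetic
energy, so the reduced model overestimates the separation loss (observed:
the effective loss coefficient of a 6 mm cosine bump at Re ≈ 150 is about
half of 1.52). The backends therefore agree within 10% on absolute flow
only where viscous losses dominate (separation share of the pressure drop
below ~20%, throat Re below ~100); the cross-backend test pins exactly
such a configuration and records the Reynolds number it runs at. This is a
documented limitation of the quadratic loss model, not a defect of either
solver.

## Physiological indices and exclusion taxonomy

FFR is the hyperaemic Pd/Pa; CMVR uses each state's own Pd with that
state's computed flow; CFR is the ratio of the two flows bit-for-bit as
solved. Every submitted case receives exactly one consort entry:

* `inadequate_gradient` — hyperaemic Pa − Pd below 2 mmHg (configurable).
  The threshold is a design choice: below typical pressure-wire drift the
  flow is unidentifiable. This rule also fires on unstenosed vessels.
* `reconstruction_failure` — view separation below 30°, or unmatched
  polyline extents.
* `meshing_failure` — the reconstructed lumen violates geometric
  invariants (e.g. non-positive radius), so no solver grid can be built.
* `convergence_failure` — the iterative backend exhausted its budget.

Baseline CMVR below hyperaemic CMVR is physiologically unusual (failed
vasodilation); it is logged as a warning, not enforced or excluded.

## Synthetic cohort generator

The generator defines the study conditions and emulates:

* **Sex-specific hyperaemic CMVR**: lognormal with medians 680 WU (male)
  and 860 WU (female). Lognormal is chosen because resistance is positive
  and right-skewed with asymmetric interquartile ranges; the log-scale
  standard deviations (0.38 male, 0.46 female) are calibrated from the
  observed IQR ratios via `q75/q25 = exp(2·0.6745·σ)` (865/520 → 0.377;
  1205/650 → 0.458) and verified by Monte-Carlo in the test suite.
* **Baseline CMVR** = hyperaemic × 2.0 (consistent with the observed
  baseline medians) × per-case lognormal noise (σ = 0.10; set to 0 to make
  baseline ≥ hyperaemic a hard guarantee).
* **Aortic pressure** Pa ~ Normal(92, 10) mmHg truncated at 60, drawn per
  state (hyperaemic aortic drop ignored).
* **Anatomy**: severity ~ Normal(60, 15)% diameter reduction truncated to
  [10, 90] (IQR ≈ 50–70%), reference radius ~ Normal(1.5, 0.25) mm
  truncated to [0.8, 2.5], vessel length 30 mm, raised-cosine stenosis of
  length U(6, 14) mm centred in the middle third. Severity is *diameter*
  reduction, matching visual angiographic grading.
* **Self-consistent pressures**: Pd solves the series circuit
  `Pa − aQ − bQ² = Pd = CMVR·Q/1000` in closed form, so recomputing CMVR
  from (Pd, Q) reproduces the hidden truth to round-off — the defining
  identity the pipeline must recover.
* **Covariates** at the recruited-cohort prevalences (e.g. 76% male, 63%
  smokers, 65% hypertension); arteries at the observed six-level
  frequencies (LAD, RCA, LCx, Dx, OM, LMS).
  No covariate except sex influences CMVR, so subgroup analyses double as
  type-I-error fixtures.
* **Projections**: two views (−30°, 0°) and (30°, 20°) (62° apart) with
  additive Gaussian half-width noise, default σ_w = 0.05 mm. Centerline
  noise is not modelled.
* **Failure injection** at configurable per-category rates, realised as
  genuinely failing inputs (near-zero gradient; 10°-apart views; a band of
  non-physical silhouette widths) except for convergence failures, which
  tag the case so the runner executes the iterative backend with a
  one-iteration budget.

All randomness flows from one seed through per-case `SeedSequence`
substreams: cohorts are byte-identical under a fixed seed, any case subset
is reproducible independently of cohort size, and the first draw of each
case stream is the hyperaemic CMVR, which external Monte-Carlo oracles
re-draw directly (common random numbers).

What passing tests do *not* show about real data: there is no real
angiographic imaging (no vesselness filtering, calibration, foreshortening
or table panning), no centerline reconstruction error, no curved vessels,
no within-patient correlation across multiple arteries (one artery per
patient; the clinical analogue analysed 203 arteries from 144 patients
without modelling clustering either), and the noise model touches
half-widths only.

## Statistics

Shapiro–Wilk (3 ≤ n ≤ 5000) gates parametric vs rank-based procedures:
normal groups are summarised as mean ± sd and compared by Welch's t
(pooled-variance t available for the F = t² identity); otherwise
median [IQR] and Mann–Whitney U. The Mann–Whitney Z uses the tie-corrected
variance **with** continuity correction (a flag disables it for
sensitivity checks); for pooled n ≤ 12 an exact permutation p is computed
by full enumeration. Sign convention (the clinical reports are
inconsistent here, so it is fixed explicitly): the first group is the
reference, and Z > 0 means the comparison group tends to larger values.
Three-level artery comparisons (LAD+Dx vs LCx+OM vs RCA; left-main-only
cases are not assignable to a branch territory and are omitted from this
row) use tie-corrected Kruskal–Wallis; left- vs right-origin is a binary
row; continuous covariates use Pearson correlation. Categorical tables use
the Pearson chi-square without Yates correction. Effect sizes are Cohen's
d on the pooled sd and Hedges' g = d·(1 − 3/(4·df − 1)), df = n₁+n₂−2.
All tests are two-tailed at α = 0.05 with no multiple-testing correction
across report rows; the Markdown report states the nominal-α caveat.

## Calibration and power checks

* Type-I error: 1000 null cohorts (equal medians, 50+50) give an empirical
  sex-rejection rate of ~0.05.
* Power consistency: 500 study-size cohorts (109 M / 35 F at the default
  medians) are analysed through the full pipeline and compared with a
  direct Monte-Carlo oracle on the generator's distributions using common
  random numbers; both give ~0.81. These replicates use gradient-safe
  anatomy (severity 65 ± 5%, r0 1.2 ± 0.15 mm) so that every generated
  case is analyzable. Under the default anatomy the low-gradient exclusion
  rule removes ~2–3% of cases *preferentially at high CMVR* — and
  therefore disproportionately women — which truncates the female upper
  tail and costs roughly 10 percentage points of power (0.71 vs 0.81 in a
  500-replicate experiment). This selection effect of gradient-based
  exclusion is a real property of the measurement design, worth keeping in
  mind when interpreting cohorts assembled under such rules.

## Problem sizes

Phantoms use 128 arclength samples; the axisymmetric oracle runs at 128×32
cells (grid-convergence checks at 32×8 and 64×16); recovery experiments
use 100-case cohorts; calibration and power experiments use 1000 and 500
replicates of 100- and 144-case cohorts on the fast reduced-order path.
These sizes make the full suite and the acceptance script each run in a
few minutes on a single CPU while leaving all statistical checks
well-powered.

## Known limitations

Rigid straight-axis lumens only; the reduced model's fixed K_e
overestimates separation losses for smooth stenoses at Re ≳ 100 (see
above); the axisymmetric backend's energy-balance pressure recovery is
slightly (~1–2%) low on under-resolved separated shear layers; exact
Mann–Whitney enumeration is limited to pooled n ≤ 12; no DICOM ingestion
or real-image segmentation.
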