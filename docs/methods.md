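# Methods

This note records the models petkin implements, the numerical choices
behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.  It states no empirical result that
the test suite does not itself compute.

## Compartment models and forward computation

The one- and two-tissue compartment models are linear systems driven by
the metabolite-corrected arterial plasma concentration Cp(t).  Their
tissue impulse response is a sum of exponentials; for the two-tissue
model the decay rates are

    θ₁,₂ = [(k2 + k3 + k4) ± √((k2 + k3 + k4)² − 4·k2·k4)] / 2

with partial-fraction amplitudes summing to K1 and impulse-response
integral K1/k2·(1 + k3/k4) = V_T.  The discriminant is a sum of squares
of positive terms, so the decomposition exists for all admissible rates;
the θ₁ → θ₂ degenerate direction (k3 → 0 with k2 → k4) collapses
smoothly onto the one-tissue response.

The tissue curve is computed by exact convolution on the 1-s input grid
under a piecewise-linear interpolation of Cp: each exponential term
becomes a first-order IIR recursion

    y[n] = e^(−θΔ)·y[n−1] + b₀·Cp[n] + b₁·Cp[n−1]

whose coefficients are the exact integrals of the kernel against a
linear segment (θ → 0 handled by its series limit).  This keeps short
grids exact, unlike FFT convolution, and costs ~0.1 ms per curve.  The
measured model adds the blood signal as (1 − V_B)·C_T + V_B·C_blood —
the (1 − V_B) convention is a declared choice, stated here because the
operational equation is often left unprinted — and shifts both input
curves by t_bolus (zero-padded before arrival, linear interpolation for
fractional shifts, edge-held at the far end of the grid).  Frame values
are time-averages over each frame, since PET frames integrate counts;
midpoint sampling is available behind a flag for sensitivity checks.
Rate constants are per minute at every interface and converted to per
second exactly once, inside the convolution.

An independent verification path (`ode_oracle`) integrates the state
equations directly.  Its default realisation propagates the augmented
4×4 linear system (two states, plus the locally linear input modelled
as u' = v, v' = 0) with one matrix exponential per 1-s segment — exact
for the same piecewise-linear input assumption, but sharing no numerics
with the convolution path.  An adaptive stiff solver (LSODA,
max_step = 10 s so that steps respect the input grid's derivative
kinks) is available as a second, slower cross-check.  The oracle has
its own frame-averaging code and is used only in tests.

## Arterial input function

The plasma input is assembled as

    Cp(t) = D_τ[blood](t) · ratio(t) · pf(t)

on a 1-s grid: the whole-blood curve joined from the automated early
sampling system (ABSS) and the later manual samples, dispersion-
corrected, multiplied by a linear fit to the manual plasma/blood ratio
(clipped non-negative) and by the Hill parent-fraction model

    pf(t) = 1 − α·t^β / (t^β + γ),

which satisfies pf(0) = 1 and declines sigmoidally to 1 − α.  The Hill
fit runs in (α, β, log γ) for conditioning, since γ is on the scale of
t^β; a degenerate metabolite-free dataset snaps exactly to α = 0.

Joining rule: ABSS values verbatim on their window; a monotone
piecewise-cubic (PCHIP) through the manual whole-blood samples after
it.  "Smoothing factor zero" is read as interpolation through the
points.  Where both are defined the curves cross-fade over 10 s; a gap
of up to 60 s (the manual schedule starts at the next frame midpoint,
shortly after the ABSS ends) is bridged linearly; larger gaps error
unless extrapolation is explicitly allowed.  Beyond the last manual
sample the curve continues as a monoexponential fitted log-linearly to
the last three samples.

Dispersion correction defaults to an exact discrete deconvolution of
the monoexponential catheter kernel (1/τ)e^(−t/τ): the forward
convolution under piecewise-linear inputs is a stable first-order IIR
filter, and its inverse (run with a steady-state initial condition, so
constants are fixed points) recovers the pre-dispersion curve to
machine precision, including across the sharp bolus onset.  The classic
first-order correction g + τ·dg/dt, with the derivative taken by
central differences after a 5-point moving average, is retained as
`method="derivative"`: the exact inverse amplifies high-frequency
content by roughly 2/(1 − e^(−Δ/τ)) (~15× at τ = 2.5 s, Δ = 1 s), which
is unacceptable on noisy measured 1-Hz counting data, whereas the
derivative form is noise-tolerant but leaves an error of order
τ²·g″/2 — up to ~10% over the few seconds surrounding a bolus-onset
kink.  Since the package's data path is synthetic and noise-free in
blood, exactness was preferred as the default.  τ defaults to 2.5 s, a
typical arterial-line constant, and is configurable; the true value for
any given sampling rig must be calibrated.

## Fitting

All fits are bounded trust-region least squares (scipy `least_squares`,
numeric Jacobian) on weighted residuals, from the fixed initial values
K1 = 0.5, k2 = 0.1, k3 = 0.5, k4 = 0.5 with all rate constants
constrained to (0, 0.9] min⁻¹ (the bound is applied to K1 as well; the
text this emulates does not distinguish).  Convergence tolerances are
1e-12; on solver failure the fit restarts from up to five log-uniform
(×10^U(−0.5, 0.5)) perturbations of the initials under a fixed seed and
keeps the best residual; a still-unconverged fit is returned flagged
rather than raised.  Standard errors come from the weighted Jacobian at
the solution (pseudo-inverse of JᵀJ scaled by RSS/dof).

Weights default to frame duration, normalised to sum to the number of
frames; uniform and duration²/activity schemes are selectable and
recorded in every result.  Decay-based weighting is deliberately absent
because every curve in the pipeline is decay-corrected.

The six-parameter whole-brain fit frees V_B ∈ [0, 1] and
t_bolus ∈ [−60, 60] s alongside the four rate constants; its V_B and
t_bolus are then frozen for all regional fits of that scan.  On
blood-free data V_B and t_bolus are nearly flat directions, so they
land near (not exactly on) zero — the regional consistency check uses
the recovery tolerances, not equality.

The coupled fit shares one K1/k2 ratio across regions with per-region
(k2, k3, k4); K1 is reconstructed as ratio·k2.  The shared ratio is
bounded in (0, 10], because observed ratios reach ~0.6 and a 0.9 cap on
a ratio has no basis.  The two-session protocol couples grey-matter
regions plus a designated "typical grey matter" region first, then
white-matter regions with the same typical-GM region; the typical-GM
parameters retained in the output are those of the first session.  When
tissue classes truly differ in K1/k2, the second session's shared ratio
is a weighted compromise pulled slightly toward the typical-GM value —
a structural property of the protocol, asserted as such in the tests.

### Identifiability under noise

Zero-noise recovery of all parameters is exact to ~1e-13·truth.  Under
counting-statistics noise SD = s·√(C/duration) scaled to ~5% CV in the
late 300-s frames, the early 20-s frames carry ~14% CV, and the
linearised Cramér–Rao bound at the grey-matter group-mean parameters
already implies relative standard deviations of roughly 10% (K1), 21%
(k2), 35% (k3) and 38% (k4) even with optimal inverse-variance
weighting: k2 and k3 trade off strongly for a tracer whose slow
eigenvalue (~0.023 min⁻¹) equilibrates on the scan's own timescale.
The recovery property test therefore asserts median errors within
12/25/35/40% — what the information content supports — rather than
tighter figures.  In occasional noise draws the global minimum pins k4
to its lower bound, making BP_ND unbounded; such fits are flagged
(`at_bounds` / `degenerate`) and are the reason the cohort default
noise is set below the stress-test level (below).

## Logan graphical analysis

The transform y(T) = ∫₀ᵀCt/Ct(T) against x(T) = ∫₀ᵀCp/Ct(T) is
evaluated at frame ends, where the tissue integral is exact: a frame
value is the frame average, so value×duration is the frame's integral
and the cumulative sum needs no quadrature.  (Midpoint-trapezoid
integration was tried and rejected: quadrature error from the bolus
peak breaks the equilibrium identity Ct = V·Cp → slope V, which the
frame-end form satisfies to machine precision.)  The plasma integral
uses the trapezoid rule on the 1-s grid; the regression is ordinary
(unweighted) least squares over frames starting at or after t* (default
480 s); non-positive tissue frames are excluded with a warning.  The
noise-induced negative bias of Logan regression is not corrected, and
no multilinear variant is provided.

### Logan bias

For this tracer's kinetics the finite-window Logan slope is *not* an
unbiased estimate of the compartmental V_T: with the calibrated
synthetic input and grey-matter group-mean parameters the noiseless
slope at t* = 8 min is ~16% below K1/k2(1+k3/k4), rising monotonically
toward it as t* grows (~12% low at 15 min, ~6% low at 25 min).  This
matches the magnitude of the discrepancy between graphical and
compartmental V_T reported for the tracer this package models, and is a
property of slow equilibration, not of the regression.  The acceptance
test asserting 3% agreement at t* = 8 min is retained verbatim and
fails by design; the monotone-convergence and slope ≤ V_T properties
are asserted separately and pass.

## Synthetic data generator

The generator emulates a six-subject, two-scan (≈6 weeks apart)
test–retest study: 25 frames over 46 min (the listed frame sequence is
used verbatim even though the protocol prose announces 29 frames and
60 min — an inconsistency documented, not resolved), injected dose
302 ± 33 MBq, whole-brain uptake peaking near 2.5 %ID at about one
minute and declining toward ~1.3–1.5 %ID late in the scan, parent
fraction 0.70 at 60 min, grey-/white-matter two-tissue truths at the
published test-scan group means, fractional blood volume 0.06 ± 0.009,
bolus delay 10 ± 3 s.

The plasma-parent truth is the Feng bolus form (linear rise times a
fast exponential plus two slower exponentials).  Its default
coefficients were calibrated once against the uptake conditions above —
peak %ID, late %ID, and an end-of-scan brain-to-plasma ratio inside the
reported 0.5–2 band — and then frozen; they are parameters of the
emulated study, not tuning knobs.  The whole-blood fixture is
back-computed (plasma ÷ ratio line ÷ parent fraction, then convolved
with the dispersion kernel) so that `build_input_function` applied to
the emitted samples reconstructs the generating truth to within
interpolation error (<2%; verified ~0.4% max over the curve above 1% of
peak).  Manual samples sit at the frame midpoints after the 5-min ABSS
window; parent fractions at the standard 4–50-min metabolite draws.

Cohort structure: per-subject parameter truths are mean-preserving
log-normal perturbations of the region truths with between-subject CVs
defaulting to the published test-scan CV column (K1 25%, k2 8%, k3 25%,
k4 38%); per-scan within-subject perturbations default to 5% CV; frame
noise follows SD = noise_scale·√(C/duration).  Seeds are hierarchical
(master → subject → scan → region noise), so any sub-fixture is
bitwise reproducible in isolation.  The default noise_scale of 0.5
(~1.7% late-frame CV) reflects the data quality the emulated study
evidently had — uniformly finite estimates with ~20% test–retest error
SDs in large regions — while the stress tests use 1.5 (~5% late-frame
CV) explicitly.  Inadmissible draws are redrawn up to ten times, then
error.

Not emulated: scanner resolution and partial-volume effects, subject
motion, noise on the blood measurements, input-function variability
between scans, and radioactive decay (all curves are decay-corrected by
construction).  Passing tests on this generator therefore demonstrate
correctness of the estimation chain under the stated statistical model,
not robustness to the full error structure of measured PET data.

## Statistics

AIC uses the Gaussian least-squares form n·ln(RSS/n) + 2(p + 1),
counting the noise variance as a parameter; only differences between
models fitted to the same data and weights are meaningful, and the
comparison refuses mismatched weighting schemes.  The nested F test is
one-tailed (right); a noise-driven RSS increase under the larger model
reports p = 1 with a warning.  The two-tissue model is "preferred" only
when the AIC is lower *and* p < 0.05.  No multiple-testing correction
is applied (a flat α = 0.05), matching the analysis this emulates.

Test–retest error is 100·(test − retest)/mean(test, retest) — the
symmetric convention, declared here because the source never prints its
formula; a test-denominator variant is selectable.  CV% is the SD over
the group mean per occasion.  The ICC is the one-way form
(MS_BS − MS_WS)/(MS_BS + (n−1)·MS_WS) with n = 2, equal to
(F − 1)/(F + 1) for the one-way ANOVA F with subjects as groups (the
identity used as an independent oracle in tests); it is defined as 1
when MS_WS = 0 and may be negative when within-subject scatter
dominates.  Subjects with incomplete pairs are dropped per region with
a warning.

## Worked-example verification

`verify_worked_examples` recomputes the arithmetic identities implied
by the published study's tables from the embedded printed values:
binding-potential ratios for the internally consistent grey-matter test
rows (subjects 1 and 4), K1/k2 ratios, six-subject group means,
test–retest averages, and the reported BP_ND range.  Entries that are
internally inconsistent as printed — subject 2's grey-matter test
BP_ND (0.058/0.026 = 2.23 vs printed 1.86, and similarly subjects 3 and
6), the grey-matter k4 test mean (printed 0.029, arithmetic 0.036), the
white-matter BP_ND mean (1.91 vs 1.93), and the putamen test–retest
average (1.35 vs 1.38) — are reported as documented discrepancies and
never silently reconciled.  Comparisons use half-a-printed-digit
tolerances rather than re-rounding, to avoid float-representation
artefacts at exact .5 boundaries.

## Limitations

* The plasma free fraction is not modelled anywhere (it was not
  measured in the emulated study); BP_ND is k3/k4 only.
* The Logan estimator is known-biased for this tracer (above).
* The Hill parameterisation and dispersion τ live upstream of the data
  this package sees; both are configurable declared defaults.
* Reference-tissue models, voxelwise fitting and image-space processing
  are out of scope.
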