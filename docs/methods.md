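# Methods

## Model family

The package models nuclear creep — strain per unit step stress,
J(t), in kPa⁻¹ — with linear viscoelastic networks. The primary model
is the four-element Burgers material,

J(t) = 1/k_M + (1/k_KV)(1 − e^(−t/τ)) + t/μ_M, τ = μ_KV/k_KV,

which combines an instantaneous elastic jump (Maxwell spring k_M), a
delayed elastic transition over the response time τ (Kelvin–Voigt arm
k_KV ∥ μ_KV), and unbounded steady-state flow (Maxwell dashpot μ_M).
Derived parameters follow exact identities: steady-state stiffness
k_ST = k_M·k_KV/(k_M + k_KV), compliance slope α = 1/μ_M, J_0 = 1/k_M,
J_∞ = 1/k_ST. The short-time approximation is the constant J_0; the
long-time approximation is J_∞ + αt, with residual (1/k_KV)e^(−t/τ).

Three-element alternatives are registered for comparison: Maxwell
fluid (1/k + t/μ), Kelvin–Voigt solid ((1/k)(1 − e^(−tk/μ))) and the
standard linear solid in both common parameterizations — the Kelvin
representation, a free spring k₀ in series with a Kelvin–Voigt arm
(k₁, μ₁), J = 1/k₀ + (1/k₁)(1 − e^(−t·k₁/μ₁)); and the Maxwell
representation, an equilibrium spring k_e in parallel with a Maxwell
arm (k₁, μ₁), J = (1/k_e)(1 − (k₁/(k_e+k₁))e^(−t/τ_ret)) with
τ_ret = μ₁(k_e+k₁)/(k_e·k₁). The two SLS forms describe the same
solid; the exact bijection (k₀ = k_e + k₁, k_v = k_e(k_e+k₁)/k₁,
μ_v = μ₁(k_e+k₁)²/k₁²) is implemented and tested. The Burgers model
nests the Kelvin-form SLS (μ_M → ∞) and the Maxwell fluid (k_KV → ∞).

Assumptions: linearity (compliance independent of stress amplitude),
incompressibility at the measurement timescale, and time-invariance of
the material over the ~12 s test. Nonlinear strain stiffening,
poroelastic transients and active fluctuations are out of scope.

## Trace conversion

**Micropipette aspiration.** A step suction ΔP through a pipette of
inner radius R_p aspirates the nucleus by L_p(t); the half-space punch
solution gives J(t) = 2πφ·L_p(t)/(3·R_p·ΔP) with geometrical wall
factor φ (default 2). The placement of φ differs between renderings of
this relation in the literature; the default puts it in the numerator
and a `phi_convention` switch selects the denominator form. Simulation
and conversion share the active convention, so round trips and
parameter-recovery results are convention-invariant; only absolute
moduli change (by φ²) between conventions. The pressure step is
treated as instantaneous at t = 0 and the first fitted sample is the
first post-step frame; J(0) is extrapolated by the model, not imposed.

**Nanoindentation.** A constant force f held through a spherical probe
of radius R on a sample of thickness h produces depth δ(t). The Hertz
half-space compliance 16√R·δ^{3/2}/(9f) (Poisson ratio fixed at 0.5)
is multiplied by the finite-thickness correction
1 + 1.133χ + 1.283χ² + 0.769χ³ + 0.0975χ⁴ in χ = √(Rδ)/h. The
correction is a series expansion in χ with no published validity bound
for this use; the package warns for χ > 1 and hard-flags (excludes
from fitting by default) χ > 3. With the default geometry (R = 41 µm,
h = 3 µm) nuclear-scale deformations reach χ > 3, so indentation
curves are primarily a cross-validation of the MPA-derived parameters
rather than an independent fitting route. Samples during the force
ramp (default 1 s) are discarded and time is re-zeroed at ramp end.

**Averaging.** Replicate curves are linearly interpolated onto a
common grid (no extrapolation; a grid outside any replicate's support
is an error naming the replicate) and summarized by per-point mean and
standard error.

## Fitting

`CreepModel.fit()` minimizes the unweighted sum of squared compliance
residuals (per-point weights optional) with `scipy.optimize.least_squares`
(trust-region reflective), each parameter bounded to [10⁻⁴, 10⁴] in
natural units — three orders of magnitude around the physiological
range, preventing runaway dashpots. Tolerances are xtol = ftol =
gtol = 10⁻¹², max 2000 evaluations; the fit is deterministic given
(curve, init, bounds) and never raises on non-convergence (the result
carries `converged=False` with the best parameters found).

Starting values: k_M from the first compliance sample; terminal slope
and intercept of the last 30% of points give μ_M and J_∞ (hence k_ST
and k_KV); τ from the 63% rise time toward J_∞. Flat or inverted
curves fall back to unit-magnitude defaults with a logged warning.

Goodness of fit is R² = 1 − SS_res/SS_tot about the mean of the
observed compliance. Confidence bounds are linearized: covariance
s²(JᵀJ)⁻¹ at the optimum with t-based 95% intervals on n − p degrees
of freedom; a singular Jacobian yields unbounded intervals with a
warning. Model selection ranks candidates by R², quantized at 10⁻⁶ so
that nested models fitting equally well tie and the tie resolves to
fewer parameters; AIC on the Gaussian residual likelihood is reported
alongside. Batch fitting tabulates per-nucleus fits, per-condition
means, and the cross-condition coefficient of variation (sample sd,
n − 1, over mean) of each parameter.

## Association analyses

Profiles are features × conditions matrices with class tags (rna,
protein, mechanics, chromatin). z-scores standardize each feature
across conditions with sample sd (n − 1); zero-variance features are
dropped with a warning. Pearson correlations are computed pairwise
between two profiles sharing condition order and are descriptive — no
p-values or multiple-testing correction, since with ~5 conditions they
are exploratory summaries. PCA runs on the standardized matrix
(conditions as observations) and reports two components; feature
co-clustering is read from proximity (or sign pattern) in the loading
plane. Fold changes are log2(numerator/denominator) per feature;
nonpositive inputs are skipped with a warning. Chromatin condensation
scores (per nucleus, per compartment, per evaluator) are averaged over
evaluators first, then nuclei. Protein levels measured by several
methods (IF, WB, MS) are each normalized to the method's own WT value
and then averaged unweighted across methods; the normalize-then-
average order was an open choice and is fixed as: combine methods,
then z-score.

## Synthetic data

The generator emulates the study conditions end to end: aspiration
creep of a Burgers material over 12 s at a 1 kPa step through a
3 µm-radius pipette (φ = 2), sampled at 10 Hz, 15 replicates per
condition (within the 10–20 per-condition range of the emulated
experiments), and indentation creep at 1 µN through a 41 µm bead on a
3 µm-thick sample with a 1 s force ramp and 10 s hold. Indentation
depths are obtained by bracketed root-finding on the monotone
thin-sample-corrected compliance (tolerance ~10⁻¹²).

Condition presets: **WT** k_M = 0.5 kPa, k_KV = 0.5 kPa,
μ_M = 9.5 kPa·s, μ_KV = 0.9 kPa·s (equivalently k_ST = 0.25 kPa,
τ = 1.8 s); **TKO** k_M = 0.27 kPa, k_ST = 0.15 kPa (hence
k_KV = 0.3375 kPa), μ_M = 2.3 kPa·s, with τ fixed at 1.5 s — the
midpoint of the 1–2.5 s range observed across conditions, since no
exact TKO value is tabulated — giving μ_KV = 0.50625 kPa·s.

Measurement noise is multiplicative Gaussian on the measured length
(L_p or δ), default CV 5%: multiplicative noise preserves positivity
and scales with deformation as image-tracking errors do. Identical
seeds give bit-identical output. The generator deliberately omits
per-nucleus biological parameter variability (a log-normal spread
exists as an option, off by default), drift, pipette-wall friction and
nonlinear stiffening — so passing recovery tests demonstrate correct
inference under the stated noise model, not robustness to every
artifact of real recordings.

Expression–mechanics profiles place latent lamin-A and lamin-B1 levels
per condition (WT 1, knockouts 0, rescues at ~50% for lamin-A, 100%
for lamin-B1), couple lamin-A linearly to (k_M, μ_M) and lamin-B1 to
(k_KV, μ_KV) with the preset element values as anchors, and add
independent Gaussian measurement noise of sd = 20% of each feature's
dynamic range. Under these defaults the lamin-A/Maxwell correlations
come out around 0.85 and the sign is recovered in ≥95% of seeded sets.

## Problem sizes and numerical choices

Default runs fit 120-point curves (10 Hz × 12 s); recovery suites use
15-replicate averages and summarize over 20–50 seeds, which keeps the
whole test suite and the acceptance script in the seconds-to-a-minute
range. The exponential argument is clamped at −700 to avoid overflow
during optimizer exploration of degenerate τ. Grids must be strictly
increasing; averaging never extrapolates; file readers convert
declared units (Pa/kPa, m/µm/nm, N/µN) into the internal convention on
ingestion.

## Known limitations

Per-nucleus confidence bounds assume independent homoscedastic
residuals, which averaged curves violate mildly (variance grows with
J under multiplicative noise); weighted fitting is available where
that matters. WT μ_M is the least-determined element (shallow terminal
slope relative to noise): its single-run recovery error is several
times that of k_M or k_ST, which is why selection and recovery claims
about viscosity are strongest for low-viscosity (TKO-like)
conditions. The indentation route with the default nuclear geometry
operates beyond the thin-film expansion's comfortable range (χ > 3)
and is flagged accordingly.
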