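# Methods

## The concentration model

The package models micellization as a smooth transition in the partitioning
of surfactant between monomers ([S₁]) and micellized molecules
([S_m] = [S]₀ − [S₁]). Its defining assumption is that the second
derivative of [S₁] with respect to the total concentration [S]₀ is a
negative Gaussian centred at the cmc with standard deviation σ. This
follows the probabilistic picture of micellization in which the degree of
micellization approaches a normal distribution in the transition region;
the cmc is the point of maximum change in gradient of the monomer
concentration (the Phillips condition applied to the concentration itself,
not to a measured property). Double integration gives [S₁] in closed form
in terms of erf/erfc; the amplitude

A(r) = 2 / (1 + √(2/π)·r·e^(−1/(2r²)) + erf(1/(√2·r)))

is not a free parameter: it is exactly the normalization constant enforcing
[S₁](0) = 0, and is always computed from r (`concentration.amplitude`).
For r < 0.4, A ≈ 1. The model assumes a constant mean aggregation number n,
so [M] = [S_m]/n; concentration-dependent aggregation numbers and
mass-action/thermodynamic micellization models are out of scope.

Key closed-form anchors used throughout the tests: the fractional degree of
micellization at the critical point is α_m(cmc) = (A/2)√(2/π)·r ≈ 0.4·r
(4% of the surfactant is micellized at the cmc for a typical r = 0.1), the
first derivative at the cmc is A/2, and the curvature peak is
−A/(√(2π)σ). The second derivative is returned with its negative sign; the
magnitude is used wherever a "maximum change in gradient" is sought.

Units are caller-consistent and never converted: the model is scale
invariant in (cmc, σ), and the literature mixes mM, mol·kg⁻¹ and nM.
For r < 10⁻⁶ an explicit analytic branch returns the piecewise-linear limit
[S₁] = min([S]₀, cmc), avoiding 0·∞; exponential underflow at small r is
treated as an exact zero (it is the correct limit), and erf/erfc come from
scipy.special. The far-above-cmc branch uses erfc rather than 1 − erf for
accuracy.

## Property models

Linear properties are weighted sums of species concentrations:
conductivity κ = a[S₁] + b[S_m] + κ_s (slopes a, b of the limiting straight
lines, residual solvent conductivity κ_s), molar conductivity
Λ_m = (κ − κ_s)/[S]₀, NMR shift δ_obs = (δ₁ − δ_m)[S₁]/[S]₀ + δ_m,
absorbance A = ([S₁]ε₁ + [S_m]ε_m)·ℓ and the two-wavelength absorbance
ratio. Partition-type properties follow the dye–micelle equilibrium
D_f + M ⇌ D_b with constant K: molar fractions X_f = 1/(1 + K[M]),
X_b = 1 − X_f weight the limiting intensities (fluorescence), spectral
ratios (pyrene I_I/I_III, valid for r < 0.4) or diffusion coefficients
(FCS). Surface tension uses the Szyszkowski equation
γ = γ₀ − (RT/ω)·ln(1 + K_ad[S₁]) on the monomer concentration only, since
micelles are not surface active. The aggregated fraction of a
non-surfactant species is γ_agg = 1 − [S₁]/[S]₀ with cmc := cac.

Three unrelated quantities called "γ" in the surfactant literature (surface
tension, differential degree of micellization, aggregated fraction) are
kept apart by distinct identifiers.

**Identifiability.** Because [M] = [S_m]/n, the pair (K, n) enters
partition-type models only through K[M]; K and n are jointly unidentifiable
from a single curve. The fitted parameter is therefore the composite
per-micellized-surfactant constant K/n (`k_per_s`); the per-micelle K is
available when n is supplied. Similarly, the pyrene-ratio constant `c` is
fitted as a single composite parameter; its decomposition into the binding
constant, the quenching constant and the brightness ratio is deliberately
not exposed, because the printed definition in the source literature is
typographically corrupted and committing to one expression would be a
guess.

**The integrated-Boltzmann (Carpena) model** for conductivity,
κ = κ_s + a[S]₀ + Δ(b − a)·ln[(1 + e^(([S]₀−cmc)/Δ))/(1 + e^(−cmc/Δ))], is
implemented as a comparison model (`kind="carpena"`), evaluated with
log-sum-exp so the exponential never overflows for sharp transitions. Its
width Δ[S]₀ is not the Gaussian σ: equating the curvatures of the two
sigmoids at the cmc gives σ/Δ = 4/√(2π) = 1.60, while least-squares fitting
the Boltzmann expression to a full noiseless concentration-model curve
gives σ/Δ ≈ 1.73–1.76 because the two sigmoids differ in shape, not only in
slope. `best_fit_width_ratio` implements the integrated-curve
interpretation of "best fit" (fitting the conductivity curves themselves);
fitting the derivative sigmoids instead would be the alternative reading,
and is not what the routine computes.

## Fitting

All fits are damped least squares (`scipy.optimize.least_squares`,
Levenberg–Marquardt for unbounded problems, trust-region-reflective when
bounds are supplied) with tight tolerances (relative SSR and step 10⁻¹²,
gradient 10⁻¹⁰). Positivity-constrained parameters — cmc/cac, r, binding
constants, the adsorption constant, sigmoid widths, the absorbance ratio
q_a — are fitted as their logarithm, which rules out negative-width
pathologies on sparse data; their standard errors are mapped back by the
delta method. Slopes, plateaus and offsets are fitted on the natural scale.
Weights are 1/y_err² when per-point uncertainties are present, unit
otherwise.

**Error convention.** Unweighted fits scale the covariance by the reduced
χ² (the convention behind the ± values of common commercial fitting
software); weighted fits report the unscaled inverse normal matrix. This
convention is a documented choice, not a claim of equivalence with any
particular publication. Non-convergence is always reported through the
`converged` flag and message, never silently; a singular normal matrix
yields NaN standard errors with a diagnostic.

**Initial guesses** are data driven: the cmc starts at the extremum of the
magnitude of the local-quadratic smoothed second derivative (window 20% of
the points, at least 5), clipped into the interior 10–90% of the
concentration range so that even featureless curves get a usable interior
start; r starts at 0.1; straight-line slopes come from least-squares lines
on the lowest/highest quarter of the data and sigmoid plateaus from the
first/last three points. With these starts, noiseless curves of every
property kind are recovered to better than six significant digits.

**Global fits** concatenate the weighted residual blocks of several curves;
a parameter carrying a share-group identifier occupies a single free slot
across all member curves, and the reduced χ² is computed over all points
and all free parameters. Sharing r across a temperature series (r is
empirically temperature independent while cmc, a, b drift) pools the
information of the whole series: the shared-parameter standard error is
never larger than the best individual-fit error.

**Sparse data.** When few points sample the transition, r is poorly
determined but the cmc is not: `sparse_fit_protocol` fits a k-point
subsample with r fixed (0.1 or 0.001). Fixing r at a small value
effectively places the cmc at the intersection of the two limiting straight
lines; the fixed values 0.1 and 0.001 give cmc estimates that agree within
error.

**Classical estimators** (two-line intersection, smoothed-derivative
extremum with quadratic refinement and first-occurrence tie-breaking,
Boltzmann sigmoid midpoint) are included purely for comparison. On
properties nonlinear in the species concentrations their estimates shift
with nuisance parameters such as the binding constant — the package's tests
demonstrate a > 10% drift of the two-line estimate across three orders of
magnitude in K while model fits stay on the true cmc. Concentration-range
masks (needed e.g. for surface-tension curves showing both a cac and a cmc)
are explicit user inputs, never auto-detected.

## Synthetic data

The generator evaluates a forward model on a linear or logarithmic grid and
adds independent Gaussian noise, absolute or relative; with relative noise,
points of vanishing signal keep a vanishing but nonzero uncertainty
(10⁻⁹ of the curve maximum) so that inverse-variance weights stay finite.
`y_err` is set to the nominal per-point sd, so weighted fits use the true
noise level and reduced χ² is calibrated (its 95% empirical band over 100
seeded 30-point conductivity replicates lies within [0.5, 1.6], and ±2 SE
intervals for the cmc cover the truth ≥ 90% of the time). Temperature
series use a second-order polynomial cmc(T), linear slopes a(T), b(T) and a
constant r, emulating conductivity studies of weakly surface-active drugs
(19 concentrations × 31 temperatures in the reference scenario shape).
Typical fluorescence grids are logarithmic and conductivity grids linear in
the examples and tests.

What the generator does **not** emulate: correlated or non-Gaussian
instrument noise, concentration errors on the x axis, impurity artefacts
near the cmc, drifting baselines, or aggregation-number changes across the
titration. Passing tests therefore demonstrate correctness of the
estimators under the model's own statistical assumptions, not robustness to
every failure mode of real titrations.

Problem sizes in the test suite (30–332 points per curve, ≤ 100 replicate
seeds, 5–31 curves per series) were chosen to match the reference scenarios
while keeping each statistical check comfortably sized.

## Known limitations

- Ion-selective-electrode counterion data, ITC, mixture-composition rules
  for r, nonparametric derivative methods and micelle–water partition
  workflows are out of scope.
- The aggregation-number n is never fitted; only composite binding
  constants are identifiable from single curves.
- Standard errors are asymptotic (inverse normal matrix); no bootstrap or
  Bayesian intervals.
- Model selection between the concentration model and the Boltzmann model
  is descriptive (side-by-side reduced χ²), mirroring practice; no formal
  test is performed.
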