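# cmcfit

Determination of the critical micelle concentration (cmc) and the width of
the micellization transition from titration curves, by nonlinear fitting of
a closed-form surfactant concentration model.

## The problem

Any solution property that changes on micelle formation — electrical
conductivity, surface tension, NMR chemical shift, the fluorescence of a
probe dye, the pyrene I_I/I_III band ratio, UV absorbance, or the mean
diffusion coefficient measured by FCS — can be titrated against total
surfactant concentration to locate the cmc. The classical recipes
(intersecting straight lines, derivative extrema, sigmoid midpoints) define
the cmc on the *property*, so the answer depends on the property, the plot
and the analyst. For properties that are nonlinear in the species
concentrations (dye fluorescence, band ratios, diffusion) these recipes are
systematically biased: the break they find moves with the dye–micelle
binding constant even though the surfactant itself has not changed.

`cmcfit` instead defines the cmc on the surfactant concentration itself.
The curvature of the monomer concentration [S₁] with respect to the total
concentration [S]₀ is modelled as a negative Gaussian centred at the cmc
with width σ = r·cmc:

    d²[S₁]/d[S]₀² = −(A/√(2π)σ) · exp(−([S]₀ − cmc)²/(2σ²))

Double integration with the normalization [S₁](0) = 0 gives the closed form

    [S₁] = cmc − (A/2) [ √(2/π)·σ·e^(−u²) − ([S]₀ − cmc)·erfc(u) ],
    u = ([S]₀ − cmc)/(√2 σ),
    A(r) = 2 / (1 + √(2/π)·r·e^(−1/2r²) + erf(1/√2 r)),

with [S_m] = [S]₀ − [S₁] and [M] = [S_m]/n for aggregation number n. The
model has two parameters: the **cmc** and the dimensionless **relative
transition width r = σ/cmc**. Each measurable property is then a known
function of [S₁], [S_m] or [M] (e.g. κ = a[S₁] + b[S_m] + κ_s for
conductivity, the Szyszkowski equation for surface tension, a partition
equilibrium for dye signals), and the cmc and r are obtained by weighted
least squares — per curve, or globally over a series of curves with shared
parameters. The same machinery fits the critical *aggregation*
concentration (cac) of non-surfactant self-assembling species such as
amyloid peptides.

## Worked example

```python
import numpy as np
from cmcfit import CmcCurveFit
from cmcfit.synthetic import GridSpec, NoiseSpec, simulate_curve

c = simulate_curve("conductivity",
                   {"cmc": 8.099, "r": 0.112, "a": 66.74, "b": 26.43, "kappa_s": 0.0},
                   GridSpec(0.05, 16.2, 100),
                   NoiseSpec(sd=0.005, mode="relative", seed=42))
est = CmcCurveFit(kind="conductivity").fit(c.x, c.y, c.y_err)
print(f"cmc = {est.cmc_:.3f} +/- {est.std_errors_['cmc']:.3f} mM")
print(f"r   = {est.r_:.3f} +/- {est.std_errors_['r']:.3f}")
print(f"sigma = {est.r_ * est.cmc_:.3f} mM, reduced chi^2 = {est.red_chi2_:.2f}")
```

prints

```
cmc = 8.105 +/- 0.032 mM
r   = 0.112 +/- 0.008
sigma = 0.906 mM, reduced chi^2 = 0.60
```

An SDS-like conductivity titration (100 points, 0.5% relative noise) is
generated and refitted: the estimated cmc (8.105 mM) and width (r = 0.112)
recover the generating values within one standard error, and the reduced χ²
near 1 confirms the weights match the noise. Estimators follow the
scikit-learn fit/predict convention; `GlobalCmcFit` fits curve series with
shared parameters (e.g. one temperature-independent r across a temperature
series), and `TwoLineIntersection`, `DerivativeEstimator` and
`BoltzmannSigmoid` provide the classical estimators for comparison.

The same analysis from the shell:

```sh
cmcfit simulate --property conductivity --param cmc=8.099 --param r=0.112 \
    --param a=66.74 --param b=26.43 --param kappa_s=0 \
    --grid linear:0.05:16.2:100 --noise relative:0.005 --seed 42 --out sds.csv
cmcfit fit sds.csv
#  cmc = 8.10478 +/- 0.0315   red_chi2 = 0.5999
cmcfit compare sds.csv
#  cmc (concentration model) = 8.10478   red_chi2 = 0.5999
#  cmc (Boltzmann/Carpena)   = 8.10699   red_chi2 = 0.6011
#  sigma/Delta[S]0 = 1.76
```

`cmcfit compare` fits the same data with the integrated-Boltzmann
(Carpena) conductivity model: the two cmc values agree to well under 0.1%
and the ratio of the two width parameters falls in the characteristic
1.5–1.8 band. Curve files are plain CSV
(`concentration,value[,error]` plus `# key: value` header comments).

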