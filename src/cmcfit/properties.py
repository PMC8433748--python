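"""Forward models: measurable properties as functions of total concentration.

Each property is a known concentration relationship with the monomer /
micelle concentrations supplied by the concentration model.  Linear
properties (conductivity, NMR shift, absorbance) are weighted sums of
species concentrations and show a slope break at the cmc; partition-type
properties (dye fluorescence, pyrene band ratio, mean diffusion) are
sigmoids in the micelle concentration governed by a binding equilibrium.

Three distinct quantities named "gamma" in the surfactant literature are
kept apart here: the surface tension (``surface_tension``), the differential
degree of micellization (``degree_of_micellization`` in
:mod:`cmcfit.concentration`) and the aggregated fraction
(``aggregated_fraction``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concentration import (
    MicellizationParams,
    amplitude,
    monomer_concentration,
)

__all__ = [
    "ConductivityParams",
    "CarpenaParams",
    "SurfaceTensionParams",
    "NmrParams",
    "DyeBindingParams",
    "PyreneRatioParams",
    "AbsorbanceParams",
    "DiffusionParams",
    "AggregationParams",
    "conductivity",
    "molar_conductivity",
    "carpena_conductivity",
    "equal_slope_width_ratio",
    "surface_tension",
    "nmr_shift",
    "dye_fractions",
    "fluorescence_intensity",
    "pyrene_spectral_ratio",
    "absorbance",
    "absorbance_ratio",
    "mean_diffusion",
    "aggregated_fraction",
]


@dataclass(frozen=True)
class ConductivityParams:
    """kappa = a*[S1] + b*[Sm] + kappa_s.

    ``a`` and ``b`` are the molar-conductivity slopes of the limiting
    straight lines below and above the cmc (e.g. uS/cm per mM); ``kappa_s``
    is the residual solvent conductivity.
    """

    a: float
    b: float
    kappa_s: float
    mic: MicellizationParams

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("slope a must be positive")


@dataclass(frozen=True)
class CarpenaParams:
    """Boltzmann-sigmoid differential-conductivity model (integrated form)."""

    a: float
    b: float
    kappa_s: float
    cmc: float
    delta: float  # transition width Delta[S]0, same unit as cmc

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("Carpena width delta must be positive")
        if not self.cmc > 0:
            raise ValueError("cmc must be positive")


@dataclass(frozen=True)
class SurfaceTensionParams:
    """Szyszkowski equation on the monomer concentration.

    gamma = gamma0 - st_coeff * ln(1 + K_ad * [S1]), with st_coeff = R*T/omega
    (omega: molar surface area).  Micelles are not surface active, so only
    [S1] enters.
    """

    gamma0: float
    st_coeff: float
    k_ad: float
    mic: MicellizationParams

    def __post_init__(self) -> None:
        if not self.gamma0 > 0:
            raise ValueError("solvent surface tension gamma0 must be positive")
        if self.k_ad < 0:
            raise ValueError("adsorption constant k_ad must be nonnegative")


@dataclass(frozen=True)
class NmrParams:
    """Observed shift as the population-weighted mean of monomer and micelle shifts."""

    delta_free: float
    delta_mic: float
    mic: MicellizationParams


@dataclass(frozen=True)
class DyeBindingParams:
    """Dye-micelle partition equilibrium D_f + M <-> D_b with constant K.

    Either ``k_bind`` (per micelle concentration; requires the aggregation
    number n on ``mic``) or the composite ``k_bind_per_surfactant`` = K/n
    (per micellized-surfactant concentration) must be given, not both: K and
    n are jointly unidentifiable from a single curve.
    """

    f_free: float
    f_bound: float
    mic: MicellizationParams
    k_bind: float | None = None
    k_bind_per_surfactant: float | None = None

    def __post_init__(self) -> None:
        if (self.k_bind is None) == (self.k_bind_per_surfactant is None):
            raise ValueError(
                "exactly one of k_bind and k_bind_per_surfactant must be given"
            )
        if self.f_free < 0 or self.f_bound < 0:
            raise ValueError("limiting intensities must be nonnegative")
        k = self.k_bind if self.k_bind is not None else self.k_bind_per_surfactant
        if k < 0:
            raise ValueError("binding constant must be nonnegative")


@dataclass(frozen=True)
class PyreneRatioParams:
    """Pyrene I_I/I_III spectral ratio, valid for r < 0.4.

    ``c`` is a single composite constant multiplying the micelle
    concentration; its decomposition into the binding constant, the
    quenching constant and the brightness ratio is not exposed (the printed
    definition in the source literature is corrupted).
    """

    sr_free: float
    sr_bound: float
    c: float
    mic: MicellizationParams

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("composite constant c must be nonnegative")


@dataclass(frozen=True)
class AbsorbanceParams:
    """Beer-Lambert absorbance of monomeric + micellized surfactant.

    ``eps_free`` / ``eps_mic`` are per-wavelength molar absorption
    coefficients (arrays or scalars); ``q1``, ``qm``, ``qa`` are the
    two-wavelength absorbance ratios used by :func:`absorbance_ratio`.
    """

    mic: MicellizationParams
    eps_free: np.ndarray | float = 1.0
    eps_mic: np.ndarray | float = 1.0
    path: float = 1.0
    q1: float | None = None
    qm: float | None = None
    qa: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.eps_free) < 0) or np.any(np.asarray(self.eps_mic) < 0):
            raise ValueError("absorption coefficients must be nonnegative")
        if not self.path > 0:
            raise ValueError("optical path must be positive")


@dataclass(frozen=True)
class DiffusionParams:
    """Mean translational diffusion of a dye exchanging between water and micelles."""

    d_free: float
    d_bound: float
    mic: MicellizationParams
    k_bind: float | None = None
    k_bind_per_surfactant: float | None = None

    def __post_init__(self) -> None:
        if not (self.d_free > self.d_bound > 0):
            raise ValueError("require d_free > d_bound > 0")
        if (self.k_bind is None) == (self.k_bind_per_surfactant is None):
            raise ValueError(
                "exactly one of k_bind and k_bind_per_surfactant must be given"
            )


@dataclass(frozen=True)
class AggregationParams:
    """Aggregated fraction of a non-surfactant self-assembling species.

    Reuses the concentration model with cmc := cac (critical aggregation
    concentration, e.g. ~90 nM for the amyloid-beta(1-42) peptide).
    """

    cac: float
    r: float

    @property
    def mic(self) -> MicellizationParams:
        return MicellizationParams(cmc=self.cac, r=self.r)


# ---------------------------------------------------------------------------
# forward models


def conductivity(s0, p: ConductivityParams):
    """Specific conductance kappa = a*[S1] + b*([S]0 - [S1]) + kappa_s."""
    s0 = np.asarray(s0, dtype=float)
    s1 = monomer_concentration(s0, p.mic)
    out = p.a * s1 + p.b * (s0 - s1) + p.kappa_s
    return float(out) if out.ndim == 0 else out


def molar_conductivity(s0, p: ConductivityParams):
    """Molar conductivity Lambda_m = (kappa - kappa_s)/[S]0; undefined at 0."""
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("molar conductivity requires s0 > 0")
    s1 = np.asarray(monomer_concentration(s0, p.mic))
    out = p.a * s1 / s0 + p.b * (s0 - s1) / s0
    return float(out) if out.ndim == 0 else out


def carpena_conductivity(s0, p: CarpenaParams):
    """Integrated Boltzmann-sigmoid conductivity model.

    kappa = kappa_s + a*[S]0 + Delta*(b - a) *
            ln[(1 + exp(([S]0 - cmc)/Delta)) / (1 + exp(-cmc/Delta))]

    evaluated with log-sum-exp so the exponential never overflows for sharp
    transitions or concentrations far above the cmc.
    """
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("total concentration must be nonnegative")
    # ln(1 + e^x) = logaddexp(0, x), stable for |x| large
    term = np.logaddexp(0.0, (s0 - p.cmc) / p.delta) - np.logaddexp(0.0, -p.cmc / p.delta)
    out = p.kappa_s + p.a * s0 + p.delta * (p.b - p.a) * term
    return float(out) if out.ndim == 0 else out


def equal_slope_width_ratio() -> float:
    """sigma/Delta[S]0 that equates the two conductivity models' curvature at the cmc.

    The Boltzmann model's second derivative at the cmc is (b-a)/(4 Delta);
    the concentration model's is ~(b-a)/(sqrt(2 pi) sigma) for r < 0.4.
    Equating them gives sigma/Delta = 4/sqrt(2 pi) = 1.60.
    """
    return 4.0 / np.sqrt(2.0 * np.pi)


def surface_tension(s0, p: SurfaceTensionParams):
    """Szyszkowski surface tension gamma = gamma0 - st_coeff*ln(1 + K_ad*[S1])."""
    s1 = monomer_concentration(s0, p.mic)
    out = p.gamma0 - p.st_coeff * np.log1p(p.k_ad * np.asarray(s1))
    return float(out) if np.ndim(out) == 0 else out


def nmr_shift(s0, p: NmrParams):
    """Observed chemical shift: (delta_1 - delta_m)*[S1]/[S]0 + delta_m."""
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("NMR shift requires s0 > 0")
    s1 = np.asarray(monomer_concentration(s0, p.mic))
    out = (p.delta_free - p.delta_mic) * s1 / s0 + p.delta_mic
    return float(out) if out.ndim == 0 else out


def dye_fractions(m, k_bind):
    """Molar fractions (X_f, X_b) of free and micelle-bound dye.

    X_f = 1/(1 + K[M]), X_b = K[M]/(1 + K[M]); the two sum to one exactly.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or k_bind < 0:
        raise ValueError("micelle concentration and binding constant must be >= 0")
    km = k_bind * m
    x_f = 1.0 / (1.0 + km)
    x_b = km / (1.0 + km)
    if x_f.ndim == 0:
        return float(x_f), float(x_b)
    return x_f, x_b


def _binding_km(s0, mic: MicellizationParams, k_bind, k_per_s):
    """K*[M] computed either per micelle (needs n) or per micellized surfactant."""
    s0 = np.asarray(s0, dtype=float)
    sm = s0 - np.asarray(monomer_concentration(s0, mic))
    if k_bind is not None:
        if mic.n is None:
            raise ValueError("per-micelle binding constant requires aggregation number n")
        return k_bind * sm / mic.n
    return k_per_s * sm


def fluorescence_intensity(s0, p: DyeBindingParams):
    """Dye emission F = F_f*X_f + F_b*X_b under the partition equilibrium."""
    km = _binding_km(s0, p.mic, p.k_bind, p.k_bind_per_surfactant)
    out = (p.f_free + p.f_bound * km) / (1.0 + km)
    return float(out) if np.ndim(out) == 0 else out


def pyrene_spectral_ratio(s0, p: PyreneRatioParams):
    """Pyrene band ratio SR = (SR_f + SR_b*c*[M]) / (1 + c*[M])."""
    if p.mic.n is None:
        cm = p.c * (np.asarray(s0, dtype=float) - np.asarray(monomer_concentration(s0, p.mic)))
    else:
        cm = _binding_km(s0, p.mic, p.c, None)
    out = (p.sr_free + p.sr_bound * cm) / (1.0 + cm)
    return float(out) if np.ndim(out) == 0 else out


def absorbance(s0, p: AbsorbanceParams, wavelength: int | None = None):
    """A = [S1]*eps_1*l + [Sm]*eps_m*l at one wavelength (index into eps arrays)."""
    s0 = np.asarray(s0, dtype=float)
    eps1 = np.atleast_1d(np.asarray(p.eps_free, dtype=float))
    epsm = np.atleast_1d(np.asarray(p.eps_mic, dtype=float))
    if wavelength is None:
        if eps1.size != 1 or epsm.size != 1:
            raise ValueError("wavelength index required for multi-wavelength coefficients")
        wavelength = 0
    if not (0 <= wavelength < eps1.size and wavelength < epsm.size):
        raise IndexError(f"unknown wavelength index {wavelength}")
    s1 = np.asarray(monomer_concentration(s0, p.mic))
    out = (s1 * eps1[wavelength] + (s0 - s1) * epsm[wavelength]) * p.path
    return float(out) if s0.ndim == 0 else out


def absorbance_ratio(s0, p: AbsorbanceParams):
    """Two-wavelength absorbance ratio q_A = ([S1]q1 + [Sm]qm*qa)/([S1] + [Sm]qa)."""
    if p.q1 is None or p.qm is None or p.qa is None:
        raise ValueError("absorbance_ratio requires q1, qm and qa")
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("absorbance ratio requires s0 > 0")
    s1 = np.asarray(monomer_concentration(s0, p.mic))
    sm = s0 - s1
    denom = s1 + sm * p.qa
    if np.any(denom == 0):
        raise FloatingPointError("zero denominator absorbance")
    out = (s1 * p.q1 + sm * p.qm * p.qa) / denom
    return float(out) if out.ndim == 0 else out


def mean_diffusion(s0, p: DiffusionParams):
    """Mean diffusion coefficient D = D_f*X_f + D_b*X_b of the exchanging dye."""
    km = _binding_km(s0, p.mic, p.k_bind, p.k_bind_per_surfactant)
    out = (p.d_free + p.d_bound * km) / (1.0 + km)
    return float(out) if np.ndim(out) == 0 else out


def aggregated_fraction(a_total, p: AggregationParams):
    """Fraction of aggregated species gamma = 1 - [S1]/[S]0 with cmc := cac.

    At the critical point this equals (A/2) sqrt(2/pi) r, e.g. ~0.14 for
    r = 0.36 (amyloid-beta at its cac).
    """
    a_total = np.asarray(a_total, dtype=float)
    if np.any(a_total <= 0):
        raise ValueError("total concentration must be positive")
    s1 = np.asarray(monomer_concentration(a_total, p.mic))
    out = 1.0 - s1 / a_total
    return float(out) if out.ndim == 0 else out


def critical_point_fraction(r: float) -> float:
    """Closed-form fractional degree of micellization at [S]0 = cmc: (A/2) sqrt(2/pi) r."""
    return 0.5 * float(amplitude(r)) * np.sqrt(2.0 / np.pi) * r
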