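"""Closed-form surfactant concentration model.

The model describes micellization as a smooth transition: the second
derivative of the monomer concentration [S1] with respect to the total
surfactant concentration [S]0 is a negative Gaussian centred at the cmc with
standard deviation sigma.  Double integration of that Gaussian, with the
normalization [S1](0) = 0 and the plateau [S1] -> cmc, gives [S1] in closed
form in terms of the error function.  Two parameters control the model: the
critical micelle concentration ``cmc`` and the relative transition width
``r = sigma / cmc``.  A constant mean aggregation number ``n`` converts the
micellized surfactant concentration [Sm] = [S]0 - [S1] into the micelle
concentration [M] = [Sm] / n.

Units are caller-consistent (mM, mol/kg, nM, ...): every quantity scales
with the unit chosen for ``cmc`` and the grid, and nothing is converted
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "MicellizationParams",
    "SpeciesProfile",
    "DerivativeProfile",
    "amplitude",
    "monomer_concentration",
    "species_profile",
    "first_derivative",
    "second_derivative",
    "degree_of_micellization",
    "sigma_from_relative_width",
]

# Below this relative width the smooth model is numerically indistinguishable
# from (and replaced by) the piecewise-linear limit [S1] = min(s0, cmc).
_R_LINEAR_LIMIT = 1e-6

_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class MicellizationParams:
    """Parameters of the concentration model.

    Parameters
    ----------
    cmc : float
        Critical micelle concentration, in any consistent concentration unit.
    r : float
        Relative transition width, ``sigma / cmc`` (dimensionless).
    n : float, optional
        Mean aggregation number; required only to form the micelle
        concentration [M] = [Sm] / n.
    """

    cmc: float
    r: float
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.cmc > 0:
            raise ValueError(f"cmc must be positive, got {self.cmc}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.n is not None and not self.n >= 1:
            raise ValueError(f"aggregation number n must be >= 1, got {self.n}")

    @property
    def sigma(self) -> float:
        """Absolute transition width sigma = r * cmc."""
        return self.r * self.cmc


@dataclass(frozen=True)
class SpeciesProfile:
    """Species concentrations along a total-concentration grid."""

    s0: np.ndarray
    s1: np.ndarray
    sm: np.ndarray
    m: np.ndarray | None
    amplitude: float


@dataclass(frozen=True)
class DerivativeProfile:
    """Derivatives of the monomer concentration along a grid.

    ``first`` is d[S1]/d[S]0 (dimensionless), ``second`` is d2[S1]/d[S]0^2
    (inverse concentration) and ``gamma`` is the differential degree of
    micellization d[Sm]/d[S]0 = 1 - first.
    """

    s0: np.ndarray
    first: np.ndarray
    second: np.ndarray
    gamma: np.ndarray


def amplitude(r: float | np.ndarray) -> float | np.ndarray:
    """Normalization amplitude A of the Gaussian transition.

    A(r) = 2 / (1 + sqrt(2/pi) * r * exp(-1/(2 r^2)) + erf(1/(sqrt(2) r)))

    is exactly the constant that makes the doubly-integrated Gaussian model
    satisfy [S1](0) = 0.  For r < 0.4 the amplitude is ~1; it decreases for
    wider transitions.  The exponential underflows to an exact zero for small
    r, which is the correct limit.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("relative transition width r must be positive")
    with np.errstate(under="ignore"):
        denom = 1.0 + _SQRT_2_OVER_PI * r * np.exp(-1.0 / (2.0 * r**2)) + special.erf(
            1.0 / (np.sqrt(2.0) * r)
        )
    out = 2.0 / denom
    return float(out) if out.ndim == 0 else out


def _validate_s0(s0: np.ndarray) -> np.ndarray:
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("total concentration s0 must be nonnegative")
    return s0


def monomer_concentration(
    s0: float | np.ndarray, params: MicellizationParams
) -> float | np.ndarray:
    """Monomer concentration [S1] as a function of total concentration.

    [S1] = cmc - (A/2) * ( sqrt(2/pi) sigma exp(-u^2) - ([S]0 - cmc) erfc(u) )

    with u = ([S]0 - cmc) / (sqrt(2) sigma).  Vectorized over grids.  For
    r below 1e-6 the piecewise-linear limit min(s0, cmc) is returned, which
    the smooth model approaches pointwise as r -> 0.
    """
    s0 = _validate_s0(s0)
    cmc, r = params.cmc, params.r
    if r < _R_LINEAR_LIMIT:
        out = np.minimum(s0, cmc)
        return float(out) if out.ndim == 0 else out
    sigma = r * cmc
    a = amplitude(r)
    u = (s0 - cmc) / (np.sqrt(2.0) * sigma)
    with np.errstate(under="ignore"):
        s1 = cmc - 0.5 * a * (
            _SQRT_2_OVER_PI * sigma * np.exp(-(u**2)) - (s0 - cmc) * special.erfc(u)
        )
    return float(s1) if s1.ndim == 0 else s1


def species_profile(s0_grid: np.ndarray, params: MicellizationParams) -> SpeciesProfile:
    """Evaluate [S1], [Sm] (and [M] when n is known) on an ascending grid."""
    s0 = _validate_s0(s0_grid)
    if s0.ndim != 1:
        raise ValueError("s0 grid must be one-dimensional")
    if np.any(np.diff(s0) < 0):
        raise ValueError("s0 grid must be ascending")
    s1 = np.asarray(monomer_concentration(s0, params))
    sm = s0 - s1
    m = sm / params.n if params.n is not None else None
    return SpeciesProfile(s0=s0, s1=s1, sm=sm, m=m, amplitude=float(amplitude(params.r)))


def first_derivative(
    s0: float | np.ndarray, params: MicellizationParams
) -> float | np.ndarray:
    """d[S1]/d[S]0 = (A/2) * erfc(([S]0 - cmc) / (sqrt(2) sigma)).

    A strictly positive sigmoid falling from ~A below the cmc to 0 above it.
    """
    s0 = _validate_s0(s0)
    if params.r < _R_LINEAR_LIMIT:
        out = np.where(s0 < params.cmc, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out
    u = (s0 - params.cmc) / (np.sqrt(2.0) * params.sigma)
    with np.errstate(under="ignore"):
        out = 0.5 * amplitude(params.r) * special.erfc(u)
    return float(out) if np.ndim(out) == 0 else out


def second_derivative(
    s0: float | np.ndarray, params: MicellizationParams
) -> float | np.ndarray:
    """d2[S1]/d[S]0^2: the negative Gaussian centred at the cmc.

    Returns -(A / (sqrt(2 pi) sigma)) * exp(-([S]0 - cmc)^2 / (2 sigma^2));
    the sign is negative everywhere (curvature of [S1]).  Where the "maximum
    change in gradient" is sought, use the magnitude.
    """
    s0 = _validate_s0(s0)
    sigma = params.sigma
    u = (s0 - params.cmc) / (np.sqrt(2.0) * sigma)
    with np.errstate(under="ignore"):
        out = -(amplitude(params.r) / (np.sqrt(2.0 * np.pi) * sigma)) * np.exp(-(u**2))
    return float(out) if np.ndim(out) == 0 else out


def derivative_profile(s0_grid: np.ndarray, params: MicellizationParams) -> DerivativeProfile:
    """First and second derivatives plus the differential degree of micellization."""
    s0 = _validate_s0(s0_grid)
    first = np.asarray(first_derivative(s0, params))
    second = np.asarray(second_derivative(s0, params))
    return DerivativeProfile(s0=s0, first=first, second=second, gamma=1.0 - first)


def degree_of_micellization(
    s0: float | np.ndarray, params: MicellizationParams, mode: str = "fractional"
) -> float | np.ndarray:
    """Degree of micellization.

    mode="differential": gamma = d[Sm]/d[S]0 = 1 - d[S1]/d[S]0.
    mode="fractional":   alpha_m = [Sm]/[S]0 (requires s0 > 0).

    At [S]0 = cmc the fractional degree reduces to (A/2) sqrt(2/pi) r, about
    0.4 r: for a typical r = 0.1 only ~4% of the surfactant is micellized at
    the cmc.
    """
    if mode == "differential":
        return 1.0 - first_derivative(s0, params)
    if mode == "fractional":
        s0 = _validate_s0(s0)
        if np.any(s0 == 0):
            raise ValueError("fractional degree of micellization undefined at s0 = 0")
        s1 = monomer_concentration(s0, params)
        out = 1.0 - s1 / s0
        return float(out) if np.ndim(out) == 0 else out
    raise ValueError(f"unknown mode {mode!r}; expected 'differential' or 'fractional'")


def sigma_from_relative_width(cmc_or_cac: float, r: float) -> float:
    """Absolute transition width sigma = r * cmc (or r * cac)."""
    if cmc_or_cac <= 0:
        raise ValueError("cmc/cac must be positive")
    if r < 0:
        raise ValueError("r must be nonnegative")
    return r * cmc_or_cac
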