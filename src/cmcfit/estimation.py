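"""Functional estimation layer: thin wrappers over the estimator classes.

Also hosts the model-comparison utilities: the concentration model versus
the integrated-Boltzmann (Carpena) conductivity model, and the sparse-data
fitting protocol with a fixed relative transition width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import FitResult, GlobalFitResult, ParameterSpec, TitrationCurve
from .estimators import (
    BoltzmannSigmoid,
    CmcCurveFit,
    DerivativeEstimator,
    GlobalCmcFit,
    TwoLineIntersection,
)
from .fitting import fit_curve as _fit_specs
from .fitting import global_fit as _global_specs
from .models import initial_guess
from .properties import equal_slope_width_ratio
from .synthetic import GridSpec, simulate_curve, subsample

__all__ = [
    "initial_guess",
    "fit_curve",
    "global_fit",
    "two_line_intersection_cmc",
    "derivative_cmc",
    "boltzmann_sigmoid_fit",
    "compare_carpena",
    "best_fit_width_ratio",
    "sparse_fit_protocol",
    "CarpenaComparison",
]


def fit_curve(curve: TitrationCurve, specs: list[ParameterSpec] | None = None) -> FitResult:
    """Nonlinear least-squares fit of one curve (see :func:`cmcfit.fitting.fit_curve`)."""
    return _fit_specs(curve, specs)


def global_fit(curves, spec_lists) -> GlobalFitResult:
    """Joint fit with shared parameters (see :func:`cmcfit.fitting.global_fit`)."""
    return _global_specs(curves, spec_lists)


def two_line_intersection_cmc(
    curve: TitrationCurve, low_frac: float = 0.25, high_frac: float = 0.25
) -> float:
    """Graphical estimate: intersection of lines fitted to the two branches."""
    est = TwoLineIntersection(low_frac=low_frac, high_frac=high_frac).fit(curve.x, curve.y)
    return est.cmc_


def derivative_cmc(curve: TitrationCurve, order: int = 2, window_frac: float = 0.2) -> float:
    """Extremum location of the smoothed numerical derivative of the data."""
    est = DerivativeEstimator(order=order, window_frac=window_frac).fit(curve.x, curve.y)
    return est.cmc_


def boltzmann_sigmoid_fit(curve: TitrationCurve) -> FitResult:
    """Empirical Boltzmann sigmoid fit (comparison estimator only)."""
    return BoltzmannSigmoid().fit(curve.x, curve.y).result_


@dataclass(frozen=True)
class CarpenaComparison:
    """Side-by-side fit of the two conductivity models to the same data."""

    model_fit: FitResult
    carpena_fit: FitResult
    cmc_model: float
    cmc_carpena: float
    red_chi2_model: float
    red_chi2_carpena: float
    sigma_delta_ratio: float  # (r*cmc) / Delta[S]0


def compare_carpena(curve: TitrationCurve) -> CarpenaComparison:
    """Fit the concentration model and the integrated-Boltzmann model.

    Both models describe conductivity data equally well in practice: the two
    cmc values essentially coincide and the width ratio sigma/Delta[S]0
    falls between ~1.5 and ~1.8.
    """
    if curve.kind != "conductivity":
        raise ValueError("compare_carpena requires a conductivity curve")
    m = CmcCurveFit(kind="conductivity").fit(curve.x, curve.y, curve.y_err)
    carpena_curve = TitrationCurve(
        kind="carpena", x=curve.x, y=curve.y, y_err=curve.y_err, meta=dict(curve.meta)
    )
    c = CmcCurveFit(kind="carpena").fit(carpena_curve.x, carpena_curve.y, carpena_curve.y_err)
    sigma = m.params_["r"] * m.params_["cmc"]
    return CarpenaComparison(
        model_fit=m.result_,
        carpena_fit=c.result_,
        cmc_model=m.cmc_,
        cmc_carpena=c.cmc_,
        red_chi2_model=m.red_chi2_,
        red_chi2_carpena=c.red_chi2_,
        sigma_delta_ratio=sigma / c.params_["delta"],
    )


def best_fit_width_ratio(
    cmc: float,
    r: float,
    grid: np.ndarray,
    a: float = 66.74,
    b: float = 26.43,
    kappa_s: float = 0.0,
) -> float:
    """Width ratio sigma/Delta[S]0 from fitting the Boltzmann model to the
    concentration model.

    A noiseless conductivity curve is generated from the concentration model
    and the integrated-Boltzmann expression is least-squares fitted to it
    (cmc, Delta, a, b and kappa_s all free); the returned ratio is the input
    sigma = r*cmc over the fitted Delta.  The slope defaults are SDS-like.
    The curvature-matching value is 4/sqrt(2*pi) = 1.60; the best-fit value
    over a full curve is ~1.75 because the two sigmoids differ in shape, not
    only in slope.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() > 0.0 or grid.max() < 2.0 * cmc:
        raise ValueError("grid must span at least [0, 2*cmc]")
    from .models import forward

    y = forward("conductivity", grid, {"cmc": cmc, "r": r, "a": a, "b": b, "kappa_s": kappa_s})
    fit = CmcCurveFit(
        kind="carpena",
        init={"cmc": cmc, "delta": r * cmc / equal_slope_width_ratio(), "a": a, "b": b, "kappa_s": kappa_s},
    ).fit(grid, y)
    return (r * cmc) / fit.params_["delta"]


def sparse_fit_protocol(
    curve: TitrationCurve,
    k: int,
    r_fixed: float | None = None,
    strategy: str = "endpoints_spread",
    seed: int = 0,
) -> FitResult:
    """Fit a k-point subsample, optionally with the relative width fixed.

    Fixing r to a small value (0.1 or 0.001) effectively determines the cmc
    at the intersection of the two limiting straight lines, which is robust
    when no points sample the transition region.  The chosen subsample
    indices are carried on the result.
    """
    if k < 6 and curve.kind in ("conductivity", "molar_conductivity", "carpena"):
        raise ValueError("conductivity-type sparse fits need at least 6 points")
    sub = subsample(curve, k, strategy=strategy, seed=seed) if k < len(curve) else curve
    fixed = {"r": r_fixed} if r_fixed is not None else None
    est = CmcCurveFit(kind=curve.kind, fixed=fixed).fit(sub.x, sub.y, sub.y_err)
    result = est.result_
    result.subsample_indices = np.asarray(sub.meta.get("subsample_indices", np.arange(len(sub))))
    return result
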