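"""Scikit-learn style estimators for cmc determination.

``CmcCurveFit`` fits a property forward model (concentration model plugged
into the property equation) to one titration curve; ``GlobalCmcFit`` fits
several curves jointly with shared parameters.  ``TwoLineIntersection``,
``DerivativeEstimator`` and ``BoltzmannSigmoid`` are the classical empirical
estimators kept for comparison: on properties that are nonlinear in the
species concentrations their break/extremum locations are systematically
offset from the cmc, which is the central argument for model-based fitting.

All estimators follow the sklearn contract: parameters in ``__init__``,
``fit(X, y)`` computing trailing-underscore attributes, ``predict`` where a
forward model exists, composability via ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .curves import FitResult, ParameterSpec, TitrationCurve
from .fitting import FitError, fit_curve, global_fit
from .models import MODELS, forward, initial_guess
from .smoothing import local_quadratic_derivatives, quadratic_refine, window_size

__all__ = [
    "CmcCurveFit",
    "GlobalCmcFit",
    "TwoLineIntersection",
    "DerivativeEstimator",
    "BoltzmannSigmoid",
    "EstimatorError",
]


class EstimatorError(RuntimeError):
    """An empirical estimator could not produce a value (e.g. flat derivative)."""


def _as_xy(X, y):
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise ValueError("X must be 1-d or a single-column 2-d array")
        x = x[:, 0]
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("X and y must have the same length")
    return x, y


def _sorted_curve(kind, x, y, y_err):
    order = np.argsort(x, kind="stable")
    return TitrationCurve(
        kind=kind,
        x=x[order],
        y=y[order],
        y_err=None if y_err is None else np.asarray(y_err, dtype=float)[order],
    )


class CmcCurveFit(RegressorMixin, BaseEstimator):
    """Fit the concentration model through a property equation to one curve.

    Parameters
    ----------
    kind : str
        Property kind (``conductivity``, ``surface_tension``, ``nmr``,
        ``fluorescence``, ``pyrene_ratio``, ``absorbance``,
        ``absorbance_ratio``, ``fcs_diffusion``, ``aggregation``,
        ``molar_conductivity`` or the comparison model ``carpena``).
    init : dict, optional
        Overrides for the data-driven initial guesses, name -> value.
    fixed : dict, optional
        Parameters held fixed at the given values (e.g. ``{"r": 0.1}`` for
        sparse data).
    x_mask : tuple, optional
        ``(lo, hi)`` concentration range restriction applied before fitting.

    Attributes
    ----------
    cmc_ : float
        Estimated critical concentration (the cac for ``aggregation``).
    params_, std_errors_, covariance_, red_chi2_, residuals_, converged_ :
        Fit outcome; see :class:`cmcfit.curves.FitResult` (kept in ``result_``).
    """

    def __init__(self, kind="conductivity", init=None, fixed=None, x_mask=None):
        self.kind = kind
        self.init = init
        self.fixed = fixed
        self.x_mask = x_mask

    def _specs(self, curve: TitrationCurve) -> list[ParameterSpec]:
        specs = initial_guess(curve)
        init = self.init or {}
        fixed = self.fixed or {}
        unknown = (set(init) | set(fixed)) - {s.name for s in specs}
        if unknown:
            raise FitError(f"unknown parameter(s) for kind {self.kind!r}: {sorted(unknown)}")
        out = []
        for s in specs:
            if s.name in fixed:
                out.append(
                    ParameterSpec(name=s.name, init=float(fixed[s.name]), fixed=True, scale=s.scale)
                )
            elif s.name in init:
                out.append(ParameterSpec(name=s.name, init=float(init[s.name]), scale=s.scale))
            else:
                out.append(s)
        return out

    def fit(self, X, y, y_err=None):
        x, y = _as_xy(X, y)
        curve = _sorted_curve(self.kind, x, y, y_err)
        if self.x_mask is not None:
            curve = curve.masked(*self.x_mask)
        result = fit_curve(curve, self._specs(curve))
        self.result_ = result
        self.params_ = dict(result.estimates)
        self.std_errors_ = dict(result.std_errors)
        self.covariance_ = result.covariance
        self.red_chi2_ = result.red_chi2
        self.residuals_ = result.residuals
        self.converged_ = result.converged
        self.message_ = result.message
        self.cmc_ = float(result.estimates[MODELS[self.kind].cmc_name])
        if "r" in result.estimates:
            self.r_ = float(result.estimates["r"])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return forward(self.kind, x, self.params_)


class GlobalCmcFit(BaseEstimator):
    """Joint fit of several curves of one kind with shared parameters.

    ``share`` names parameters (typically ``("r",)``) that take a single
    value across all curves; sharing pools the information of the whole
    series, e.g. a temperature series where the relative transition width
    is temperature independent while cmc, a and b vary.

    ``fit`` accepts a list of :class:`~cmcfit.curves.TitrationCurve` or of
    ``(x, y)`` / ``(x, y, y_err)`` tuples.
    """

    def __init__(self, kind="conductivity", share=("r",), init=None, fixed=None):
        self.kind = kind
        self.share = share
        self.init = init
        self.fixed = fixed

    def _coerce(self, curves) -> list[TitrationCurve]:
        out = []
        for c in curves:
            if isinstance(c, TitrationCurve):
                out.append(c)
            else:
                x, y, *rest = c
                out.append(_sorted_curve(self.kind, np.asarray(x, float), np.asarray(y, float), rest[0] if rest else None))
        return out

    def fit(self, curves, y=None):
        curves = self._coerce(curves)
        share = set(self.share or ())
        spec_lists = []
        for ci, curve in enumerate(curves):
            single = CmcCurveFit(kind=curve.kind, init=self._per(self.init, ci), fixed=self._per(self.fixed, ci))
            specs = single._specs(curve)
            specs = [
                ParameterSpec(
                    name=s.name,
                    init=s.init,
                    bounds=s.bounds,
                    fixed=s.fixed,
                    share_group=(s.name if (s.name in share and not s.fixed) else None),
                    scale=s.scale,
                )
                for s in specs
            ]
            spec_lists.append(specs)
        result = global_fit(curves, spec_lists)
        self.result_ = result
        self.shared_ = dict(result.shared)
        self.results_ = list(result.per_curve)
        self.red_chi2_ = result.red_chi2
        self.converged_ = result.converged
        self.cmcs_ = np.array(
            [r.estimates[MODELS[r.kind].cmc_name] for r in result.per_curve]
        )
        return self

    @staticmethod
    def _per(d, ci):
        if d is None:
            return None
        if isinstance(d, (list, tuple)):
            return d[ci]
        return d


class TwoLineIntersection(BaseEstimator):
    """Classical graphical estimator: intersection of two fitted straight lines.

    Least-squares lines are fitted to the lowest ``low_frac`` and highest
    ``high_frac`` of the concentration range; ``cmc_`` is the abscissa of
    their intersection.  Exact for genuinely piecewise-linear data, biased
    for any property that is nonlinear in the species concentrations.
    """

    def __init__(self, low_frac=0.25, high_frac=0.25):
        self.low_frac = low_frac
        self.high_frac = high_frac

    def fit(self, X, y):
        x, y = _as_xy(X, y)
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        n = len(x)
        k_lo = max(3, int(round(self.low_frac * n)))
        k_hi = max(3, int(round(self.high_frac * n)))
        if k_lo + k_hi > n:
            raise EstimatorError("low and high segments overlap; reduce the fractions")
        m1, c1 = np.polyfit(x[:k_lo], y[:k_lo], 1)
        m2, c2 = np.polyfit(x[-k_hi:], y[-k_hi:], 1)
        if abs(m1 - m2) <= 1e-14 * max(abs(m1), abs(m2), 1.0):
            raise EstimatorError("branch lines are parallel; no intersection")
        self.slopes_ = (float(m1), float(m2))
        self.intercepts_ = (float(c1), float(c2))
        self.cmc_ = float((c2 - c1) / (m1 - m2))
        return self


class DerivativeEstimator(BaseEstimator):
    """Classical derivative estimator: extremum of a smoothed derivative.

    ``order=1`` locates the interior extremum of the first derivative (for
    sigmoid-shaped properties); ``order=2`` the extremum of the magnitude of
    the second derivative (for slope-break properties such as conductivity).
    Smoothing is local-quadratic with a window of ``window_frac`` of the
    points (at least 5); the discrete extremum is refined by quadratic
    interpolation through the three neighbouring grid points, and exact ties
    resolve to the smallest concentration.
    """

    def __init__(self, order=2, window_frac=0.2):
        self.order = order
        self.window_frac = window_frac

    def fit(self, X, y):
        x, y = _as_xy(X, y)
        order_idx = np.argsort(x, kind="stable")
        x, y = x[order_idx], y[order_idx]
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        _, d1, d2 = local_quadratic_derivatives(x, y, frac=self.window_frac)
        half = window_size(len(x), self.window_frac) // 2
        interior = slice(half, len(x) - half if half else None)
        if self.order == 2:
            v = np.abs(d2)
        else:
            # deviation of the first derivative from its edge trend exposes
            # an interior peak or trough
            base = 0.5 * (d1[0] + d1[-1])
            v = np.abs(d1 - base)
        vi = v[interior]
        if len(vi) == 0 or np.ptp(vi) <= 1e-12 * max(np.max(np.abs(vi)), 1.0):
            raise EstimatorError("derivative is flat: no usable extremum")
        i = int(np.argmax(vi)) + (interior.start or 0)
        if i == 0 or i == len(x) - 1:
            raise EstimatorError("derivative extremum at the range boundary")
        self.grid_index_ = i
        self.cmc_ = quadratic_refine(x, v, i)
        return self


class BoltzmannSigmoid(BaseEstimator):
    """Empirical Boltzmann sigmoid y = A2 + (A1 - A2)/(1 + exp((x - x0)/dx)).

    A comparison estimator only: ``x0_`` is the sigmoid midpoint, which for
    nonlinear properties does not coincide with the cmc.  ``dx`` is kept
    positive by fitting its logarithm.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        x, y = _as_xy(X, y)
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        a1 = float(np.mean(y[:3]))
        a2 = float(np.mean(y[-3:]))
        mid = 0.5 * (a1 + a2)
        sign = 1.0 if a2 >= a1 else -1.0
        above = sign * (y - mid) > 0
        x0 = float(x[int(np.argmax(above))]) if above.any() and not above.all() else float(np.median(x))
        dx0 = max(0.05 * (x[-1] - x[0]), 1e-9)

        def model(t):
            x0_, ldx, a1_, a2_ = t
            return a2_ + (a1_ - a2_) / (1.0 + np.exp(np.clip((x - x0_) / np.exp(ldx), -700, 700)))

        res = least_squares(
            lambda t: model(t) - y,
            x0=np.array([x0, np.log(dx0), a1, a2]),
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=10000,
        )
        x0_, ldx, a1_, a2_ = res.x
        self.x0_ = float(x0_)
        self.dx_ = float(np.exp(ldx))
        self.plateaus_ = (float(a1_), float(a2_))
        self.converged_ = bool(res.success)
        dof = max(len(x) - 4, 1)
        red_chi2 = float(2 * res.cost / dof)
        jtj = res.jac.T @ res.jac
        try:
            cov_t = np.linalg.inv(jtj) * red_chi2
            scale = np.array([1.0, self.dx_, 1.0, 1.0])
            cov = cov_t * np.outer(scale, scale)
            std = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov, std = None, [float("nan")] * 4
        self.result_ = FitResult(
            kind="boltzmann",
            estimates={"x0": self.x0_, "dx": self.dx_, "a1": float(a1_), "a2": float(a2_)},
            std_errors={"x0": float(std[0]), "dx": float(std[1]), "a1": float(std[2]), "a2": float(std[3])},
            covariance=cov,
            free_names=["x0", "dx", "a1", "a2"],
            red_chi2=red_chi2,
            residuals=res.fun,
            n_points=len(x),
            n_free=4,
            converged=bool(res.success),
            message=res.message,
        )
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        a1, a2 = self.plateaus_
        return a2 + (a1 - a2) / (1.0 + np.exp((x - self.x0_) / self.dx_))
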