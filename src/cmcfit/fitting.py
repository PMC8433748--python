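"""Damped least-squares engine with log-scale transforms and parameter sharing.

Positivity-constrained parameters (cmc, r, binding constants, widths) are
fitted as their logarithm, which keeps the optimizer unconstrained and rules
out negative-width pathologies on sparse data; standard errors are mapped
back by the delta method.  A global fit concatenates the weighted residual
blocks of several curves and lets share-grouped parameters occupy a single
free slot.

Error convention: unweighted fits scale the covariance by the reduced
chi-squared (the convention behind typical commercial-software +/- values);
fits weighted by known per-point uncertainties do not.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .curves import FitResult, GlobalFitResult, ParameterSpec, TitrationCurve
from .models import MODELS, forward, initial_guess

__all__ = ["fit_curve", "global_fit", "FitError"]

_MAX_NFEV = 500 * 20  # generous; curves are small and well-conditioned


class FitError(RuntimeError):
    """Raised when a fitting problem is ill-posed (not for non-convergence)."""


def _to_internal(value: float, scale: str) -> float:
    return np.log(value) if scale == "log" else value


def _from_internal(t: float, scale: str) -> float:
    return float(np.exp(t)) if scale == "log" else float(t)


class _Layout:
    """Maps (curve index, parameter name) to slots of the free vector."""

    def __init__(self, spec_lists: list[list[ParameterSpec]]):
        self.spec_lists = spec_lists
        self.slot_of: list[dict] = [dict() for _ in spec_lists]
        self.fixed_of: list[dict] = [dict() for _ in spec_lists]
        self.free_specs: list[ParameterSpec] = []
        self.free_labels: list[str] = []
        group_slot: dict[str, int] = {}
        group_name: dict[str, str] = {}
        for ci, specs in enumerate(spec_lists):
            for spec in specs:
                if spec.fixed:
                    self.fixed_of[ci][spec.name] = spec.init
                    continue
                if spec.share_group is not None:
                    g = spec.share_group
                    if g in group_slot:
                        if group_name[g] != spec.name:
                            raise FitError(
                                f"share group {g!r} ties different parameters "
                                f"({group_name[g]!r} vs {spec.name!r})"
                            )
                        self.slot_of[ci][spec.name] = group_slot[g]
                        continue
                    group_slot[g] = len(self.free_specs)
                    group_name[g] = spec.name
                slot = len(self.free_specs)
                self.slot_of[ci][spec.name] = slot
                self.free_specs.append(spec)
                label = spec.name if len(spec_lists) == 1 or spec.share_group else (
                    f"{spec.name}[{ci}]"
                )
                self.free_labels.append(label)

    @property
    def n_free(self) -> int:
        return len(self.free_specs)

    def t0(self) -> np.ndarray:
        return np.array(
            [_to_internal(s.init, s.scale) for s in self.free_specs], dtype=float
        )

    def t_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(self.n_free, -np.inf)
        hi = np.full(self.n_free, np.inf)
        for j, s in enumerate(self.free_specs):
            blo, bhi = s.bounds
            if blo is not None:
                lo[j] = _to_internal(blo, s.scale) if not (s.scale == "log" and blo <= 0) else -np.inf
            if bhi is not None:
                hi[j] = _to_internal(bhi, s.scale)
        return lo, hi

    def params_for(self, ci: int, t: np.ndarray) -> dict:
        d = dict(self.fixed_of[ci])
        for name, slot in self.slot_of[ci].items():
            d[name] = _from_internal(t[slot], self.free_specs[slot].scale)
        return d


def _residual_builder(curves: list[TitrationCurve], layout: _Layout):
    weights = [
        np.ones(len(c)) if c.y_err is None else 1.0 / c.y_err for c in curves
    ]

    def residuals(t: np.ndarray) -> np.ndarray:
        blocks = []
        for ci, c in enumerate(curves):
            params = layout.params_for(ci, t)
            try:
                model = forward(c.kind, c.x, params)
            except (ValueError, FloatingPointError):
                # pathological parameter set during line search: large residual
                model = np.full(len(c), np.nan)
            blocks.append((model - c.y) * weights[ci])
        res = np.concatenate(blocks)
        return np.where(np.isfinite(res), res, 1e8)

    return residuals


def _covariance(res, layout: _Layout, n_points: int, weighted: bool):
    """Back-transformed covariance over free parameters; None when singular."""
    n_free = layout.n_free
    dof = max(n_points - n_free, 1)
    red_chi2 = float(2.0 * res.cost / dof)
    jac = res.jac
    jtj = jac.T @ jac
    try:
        cov_t = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return red_chi2, None
    if not weighted:
        cov_t = cov_t * red_chi2
    # delta method: d(exp t)/dt = value for log-scale slots
    scale_jac = np.array(
        [
            _from_internal(res.x[j], s.scale) if s.scale == "log" else 1.0
            for j, s in enumerate(layout.free_specs)
        ]
    )
    cov = cov_t * np.outer(scale_jac, scale_jac)
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(cov)):
        return red_chi2, None
    return red_chi2, cov


def _solve(curves: list[TitrationCurve], layout: _Layout):
    if layout.n_free == 0:
        raise FitError("no free parameters to fit")
    n_points = sum(len(c) for c in curves)
    if n_points < layout.n_free:
        raise FitError(
            f"{n_points} points cannot constrain {layout.n_free} free parameters"
        )
    fun = _residual_builder(curves, layout)
    lo, hi = layout.t_bounds()
    bounded = np.any(np.isfinite(lo)) or np.any(np.isfinite(hi))
    kwargs = dict(xtol=1e-12, ftol=1e-12, gtol=1e-10, max_nfev=_MAX_NFEV)
    if bounded:
        res = least_squares(fun, layout.t0(), bounds=(lo, hi), method="trf", **kwargs)
    else:
        res = least_squares(fun, layout.t0(), method="lm", **kwargs)
    return res, n_points


def _result_for_curve(ci, curves, layout, res, red_chi2, cov, weighted, message, converged):
    params = layout.params_for(ci, res.x)
    std = {}
    for name, slot in layout.slot_of[ci].items():
        std[name] = float(np.sqrt(cov[slot, slot])) if cov is not None else float("nan")
    # residuals of this curve's block
    offsets = np.cumsum([0] + [len(c) for c in curves])
    block = res.fun[offsets[ci] : offsets[ci + 1]]
    w = np.ones(len(curves[ci])) if curves[ci].y_err is None else 1.0 / curves[ci].y_err
    slots = sorted(set(layout.slot_of[ci].values()))
    sub_cov = cov[np.ix_(slots, slots)] if cov is not None else None
    inv_slot = {s: i for i, s in enumerate(slots)}
    free_names = [None] * len(slots)
    for name, slot in layout.slot_of[ci].items():
        free_names[inv_slot[slot]] = name
    return FitResult(
        kind=curves[ci].kind,
        estimates=params,
        std_errors=std,
        covariance=sub_cov,
        free_names=free_names,
        red_chi2=red_chi2,
        residuals=block / w,  # back to data units
        n_points=len(curves[ci]),
        n_free=len(slots),
        converged=converged,
        message=message,
        weighted=curves[ci].y_err is not None,
    )


def fit_curve(
    curve: TitrationCurve, specs: list[ParameterSpec] | None = None
) -> FitResult:
    """Weighted nonlinear least-squares fit of a curve with its property model.

    Weights are 1/y_err^2 when per-point uncertainties are present, unit
    otherwise.  Non-convergence is reported through ``converged``/``message``,
    never silently.
    """
    if specs is None:
        specs = initial_guess(curve)
    names = {s.name for s in specs}
    expected = set(MODELS[curve.kind].names)
    if names != expected:
        raise FitError(
            f"specs for kind {curve.kind!r} must cover {sorted(expected)}, got {sorted(names)}"
        )
    layout = _Layout([specs])
    res, n_points = _solve([curve], layout)
    weighted = curve.y_err is not None
    red_chi2, cov = _covariance(res, layout, n_points, weighted)
    message = res.message if res.success else f"did not converge: {res.message}"
    if cov is None:
        message += " [singular normal matrix: standard errors unavailable]"
    out = _result_for_curve(0, [curve], layout, res, red_chi2, cov, weighted, message, bool(res.success))
    return out


def global_fit(
    curves: list[TitrationCurve], spec_lists: list[list[ParameterSpec]]
) -> GlobalFitResult:
    """Joint least-squares fit over several curves with shared parameters.

    Parameters carrying the same ``share_group`` identifier occupy a single
    free slot; the residual blocks of all curves are concatenated and the
    reduced chi-squared is computed over all points and all free parameters.
    """
    if len(curves) != len(spec_lists):
        raise FitError("one spec list per curve required")
    for c, specs in zip(curves, spec_lists):
        names = {s.name for s in specs}
        if names != set(MODELS[c.kind].names):
            raise FitError(f"spec names do not match model for kind {c.kind!r}")
    layout = _Layout(spec_lists)
    res, n_points = _solve(curves, layout)
    weighted = all(c.y_err is not None for c in curves)
    red_chi2, cov = _covariance(res, layout, n_points, weighted)
    message = res.message if res.success else f"did not converge: {res.message}"
    per_curve = [
        _result_for_curve(ci, curves, layout, res, red_chi2, cov, weighted, message, bool(res.success))
        for ci in range(len(curves))
    ]
    shared = {}
    seen = set()
    for ci, specs in enumerate(spec_lists):
        for s in specs:
            if s.share_group is not None and s.share_group not in seen:
                seen.add(s.share_group)
                slot = layout.slot_of[ci][s.name]
                val = _from_internal(res.x[slot], layout.free_specs[slot].scale)
                se = float(np.sqrt(cov[slot, slot])) if cov is not None else float("nan")
                shared[s.name] = (val, se)
    return GlobalFitResult(
        shared=shared,
        per_curve=per_curve,
        red_chi2=red_chi2,
        converged=bool(res.success),
        message=message,
    )
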