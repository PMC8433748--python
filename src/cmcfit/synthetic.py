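"""Seeded generators of synthetic titration curves.

The generators emulate the statistical structure the estimation layer
assumes: a forward property model evaluated on a linear or logarithmic
concentration grid with independent Gaussian measurement noise (absolute or
relative), sparse subsets of a dense titration, and temperature series with
a polynomial cmc(T), linear slopes a(T)/b(T) and a temperature-independent
relative transition width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import TitrationCurve
from .models import forward

__all__ = [
    "NoiseSpec",
    "GridSpec",
    "ScenarioSeries",
    "simulate_curve",
    "subsample",
    "simulate_temperature_series",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Independent Gaussian noise: absolute sd, or relative to the model value."""

    sd: float
    mode: str = "relative"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("noise sd must be positive")
        if self.mode not in ("absolute", "relative"):
            raise ValueError("noise mode must be 'absolute' or 'relative'")


@dataclass(frozen=True)
class GridSpec:
    """Concentration grid: ``kind`` 'linear' or 'log', n points on [lo, hi]."""

    lo: float
    hi: float
    n: int
    kind: str = "linear"

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("grid needs at least 4 points")
        if not self.hi > self.lo:
            raise ValueError("grid needs hi > lo")
        if self.kind not in ("linear", "log"):
            raise ValueError("grid kind must be 'linear' or 'log'")
        if self.kind == "log" and self.lo <= 0:
            raise ValueError("logarithmic grid needs lo > 0")
        if self.lo < 0:
            raise ValueError("concentrations cannot be negative")

    def points(self) -> np.ndarray:
        if self.kind == "linear":
            return np.linspace(self.lo, self.hi, self.n)
        return np.geomspace(self.lo, self.hi, self.n)


@dataclass(frozen=True)
class ScenarioSeries:
    """Condition series for conductivity titrations, e.g. over temperature.

    cmc(T) follows the second-order polynomial ``cmc_poly`` (c0 + c1*T +
    c2*T^2), the slopes a(T) and b(T) are linear and the relative width r
    is constant across the series.
    """

    temperatures: tuple
    cmc_poly: tuple  # (c0, c1, c2)
    r: float
    a_poly: tuple  # (a0, a1): a(T) = a0 + a1*T
    b_poly: tuple
    kappa_s: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("condition values must be strictly increasing")

    def params_at(self, t: float) -> dict:
        c0, c1, c2 = self.cmc_poly
        a0, a1 = self.a_poly
        b0, b1 = self.b_poly
        return {
            "cmc": c0 + c1 * t + c2 * t * t,
            "r": self.r,
            "a": a0 + a1 * t,
            "b": b0 + b1 * t,
            "kappa_s": self.kappa_s,
        }


def simulate_curve(
    kind: str,
    params: dict,
    grid: GridSpec,
    noise: NoiseSpec | None = None,
    meta: dict | None = None,
) -> TitrationCurve:
    """Forward model on a grid, plus optional seeded Gaussian noise.

    With noise present, ``y_err`` is set to the nominal per-point sd, so a
    weighted fit of the curve uses the true noise level.  Identical seeds
    produce bitwise-identical curves.
    """
    x = grid.points()
    # kinds undefined at zero concentration need a strictly positive grid
    if kind in ("molar_conductivity", "nmr", "absorbance_ratio", "aggregation") and x[0] <= 0:
        raise ValueError(f"kind {kind!r} requires a strictly positive grid")
    y = forward(kind, x, params)
    y_err = None
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.mode == "relative":
            # points with vanishing signal keep a vanishing but nonzero
            # uncertainty so that weights 1/sd^2 remain finite
            sd = noise.sd * np.maximum(np.abs(y), 1e-9 * np.max(np.abs(y)))
        else:
            sd = np.full_like(y, noise.sd)
        y = y + rng.normal(0.0, 1.0, size=len(y)) * sd
        y_err = sd
    return TitrationCurve(kind=kind, x=x, y=y, y_err=y_err, meta=dict(meta or {}))


def subsample(
    curve: TitrationCurve, k: int, strategy: str = "endpoints_spread", seed: int = 0
) -> TitrationCurve:
    """Keep k of the curve's points.

    ``endpoints_spread`` always retains the first and last point and spreads
    the rest approximately evenly in concentration; ``random`` draws k
    points (always including the endpoints is not guaranteed) using the
    seed.  The selected indices are stored in ``meta['subsample_indices']``.
    """
    n = len(curve)
    if k > n:
        raise ValueError(f"cannot subsample {k} from {n} points")
    if k < 4:
        raise ValueError("subsample needs at least 4 points")
    if strategy == "endpoints_spread":
        targets = np.linspace(curve.x[0], curve.x[-1], k)
        idx: list[int] = []
        for t in targets:
            j = int(np.argmin(np.abs(curve.x - t)))
            while j in idx and j < n - 1:
                j += 1
            idx.append(j)
        idx = sorted(set(idx))
        # fill up if collisions removed points
        pool = [j for j in range(n) if j not in idx]
        while len(idx) < k and pool:
            idx.append(pool.pop(len(pool) // 2))
            idx = sorted(idx)
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(n, size=k, replace=False).tolist())
    else:
        raise ValueError("strategy must be 'endpoints_spread' or 'random'")
    idx = np.asarray(idx, dtype=int)
    meta = dict(curve.meta)
    meta["subsample_indices"] = idx.tolist()
    return TitrationCurve(
        kind=curve.kind,
        x=curve.x[idx],
        y=curve.y[idx],
        y_err=None if curve.y_err is None else curve.y_err[idx],
        meta=meta,
    )


def simulate_temperature_series(
    series: ScenarioSeries, grid: GridSpec, noise: NoiseSpec | None = None
) -> list[TitrationCurve]:
    """One conductivity curve per condition; per-curve seeds derive from the base seed."""
    curves = []
    for i, t in enumerate(series.temperatures):
        nz = None
        if noise is not None:
            nz = NoiseSpec(sd=noise.sd, mode=noise.mode, seed=noise.seed + i)
        curves.append(
            simulate_curve(
                "conductivity",
                series.params_at(float(t)),
                grid,
                noise=nz,
                meta={"temperature": float(t)},
            )
        )
    return curves
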