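"""Data carriers: titration curves, parameter specifications, fit results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TitrationCurve", "ParameterSpec", "FitResult", "GlobalFitResult"]

KINDS = (
    "conductivity",
    "molar_conductivity",
    "carpena",
    "surface_tension",
    "nmr",
    "fluorescence",
    "pyrene_ratio",
    "absorbance",
    "absorbance_ratio",
    "fcs_diffusion",
    "aggregation",
)


@dataclass
class TitrationCurve:
    """A (concentration, property) series of one property kind.

    ``x`` is the ascending total-concentration grid, ``y`` the measured
    property, ``y_err`` optional positive per-point uncertainties used as
    weights 1/y_err^2 in fits.  ``meta`` carries free-text labels (units,
    temperature, sample name).
    """

    kind: str
    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown property kind {self.kind!r}; expected one of {KINDS}")
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be one-dimensional and of equal length")
        if len(self.x) < 4:
            raise ValueError(f"curve needs at least 4 points, got {len(self.x)}")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("concentration grid must be ascending")
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
            if self.y_err.shape != self.y.shape:
                raise ValueError("y_err must match y in length")
            if np.any(self.y_err <= 0):
                raise ValueError("y_err must be strictly positive")

    def __len__(self) -> int:
        return len(self.x)

    def masked(self, lo: float | None = None, hi: float | None = None) -> "TitrationCurve":
        """Restrict to the concentration range [lo, hi] (inclusive)."""
        keep = np.ones(len(self.x), dtype=bool)
        if lo is not None:
            keep &= self.x >= lo
        if hi is not None:
            keep &= self.x <= hi
        return TitrationCurve(
            kind=self.kind,
            x=self.x[keep],
            y=self.y[keep],
            y_err=None if self.y_err is None else self.y_err[keep],
            meta=dict(self.meta),
        )


@dataclass
class ParameterSpec:
    """One fit parameter: initial value, bounds, fixed flag, sharing, scale.

    ``scale`` is "log" for positivity-constrained parameters (cmc, r,
    binding constants, widths), fitted internally as log(value), or
    "linear".  ``share_group`` ties the parameter across curves in a global
    fit (one free slot per group).
    """

    name: str
    init: float
    bounds: tuple[float | None, float | None] = (None, None)
    fixed: bool = False
    share_group: str | None = None
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if self.scale == "log" and self.init <= 0:
            raise ValueError(f"log-scale parameter {self.name!r} needs a positive init")
        lo, hi = self.bounds
        if lo is not None and self.init < lo or hi is not None and self.init > hi:
            raise ValueError(f"init of {self.name!r} outside bounds {self.bounds}")
        if self.fixed and self.share_group is not None:
            raise ValueError(f"fixed parameter {self.name!r} cannot join a share group")


@dataclass
class FitResult:
    """Outcome of a single-curve least-squares fit."""

    kind: str
    estimates: dict
    std_errors: dict
    covariance: np.ndarray | None
    free_names: list
    red_chi2: float
    residuals: np.ndarray
    n_points: int
    n_free: int
    converged: bool
    message: str = ""
    weighted: bool = False
    subsample_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.red_chi2 < 0:
            raise ValueError("reduced chi^2 cannot be negative")
        if len(self.residuals) != self.n_points:
            raise ValueError("residual count must equal n_points")


@dataclass
class GlobalFitResult:
    """Outcome of a joint fit over several curves with shared parameters."""

    shared: dict  # name -> (value, std_error)
    per_curve: list  # FitResult views, one per member curve
    red_chi2: float
    converged: bool
    message: str = ""
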