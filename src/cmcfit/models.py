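"""Registry of fittable property models.

Each property kind maps to an ordered parameter list, per-parameter scales
(log for positivity-constrained quantities), a vectorized forward function
``f(x, params_dict) -> y`` and a data-driven initial-guess routine.  The
estimation layer is generic over this registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import properties as props
from .concentration import MicellizationParams, monomer_concentration
from .curves import ParameterSpec, TitrationCurve
from .smoothing import local_quadratic_derivatives

__all__ = ["MODELS", "forward", "initial_guess", "default_specs"]


@dataclass(frozen=True)
class ModelDef:
    names: tuple
    scales: dict
    fn: Callable
    guess: Callable
    cmc_name: str = "cmc"


def _mic(d):
    return MicellizationParams(cmc=d["cmc"], r=d["r"])


def _f_conductivity(x, d):
    return props.conductivity(
        x, props.ConductivityParams(a=d["a"], b=d["b"], kappa_s=d["kappa_s"], mic=_mic(d))
    )


def _f_molar_conductivity(x, d):
    return props.molar_conductivity(
        x, props.ConductivityParams(a=d["a"], b=d["b"], kappa_s=0.0, mic=_mic(d))
    )


def _f_carpena(x, d):
    return props.carpena_conductivity(
        x,
        props.CarpenaParams(
            a=d["a"], b=d["b"], kappa_s=d["kappa_s"], cmc=d["cmc"], delta=d["delta"]
        ),
    )


def _f_surface_tension(x, d):
    return props.surface_tension(
        x,
        props.SurfaceTensionParams(
            gamma0=d["gamma0"], st_coeff=d["st_coeff"], k_ad=d["k_ad"], mic=_mic(d)
        ),
    )


def _f_nmr(x, d):
    return props.nmr_shift(
        x, props.NmrParams(delta_free=d["delta_free"], delta_mic=d["delta_mic"], mic=_mic(d))
    )


def _f_fluorescence(x, d):
    return props.fluorescence_intensity(
        x,
        props.DyeBindingParams(
            f_free=d["f_free"],
            f_bound=d["f_bound"],
            k_bind_per_surfactant=d["k_per_s"],
            mic=_mic(d),
        ),
    )


def _f_pyrene(x, d):
    return props.pyrene_spectral_ratio(
        x,
        props.PyreneRatioParams(
            sr_free=d["sr_free"], sr_bound=d["sr_bound"], c=d["c"], mic=_mic(d)
        ),
    )


def _f_absorbance(x, d):
    # molar absorption coefficients with the optical path folded in
    return props.absorbance(
        x, props.AbsorbanceParams(mic=_mic(d), eps_free=d["eps1"], eps_mic=d["epsm"], path=1.0)
    )


def _f_absorbance_ratio(x, d):
    return props.absorbance_ratio(
        x,
        props.AbsorbanceParams(
            mic=_mic(d), q1=d["q1"], qm=d["qm"], qa=d["qa"], eps_free=1.0, eps_mic=1.0
        ),
    )


def _f_diffusion(x, d):
    return props.mean_diffusion(
        x,
        props.DiffusionParams(
            d_free=d["d_free"],
            d_bound=d["d_bound"],
            k_bind_per_surfactant=d["k_per_s"],
            mic=_mic(d),
        ),
    )


def _f_aggregation(x, d):
    return props.aggregated_fraction(x, props.AggregationParams(cac=d["cac"], r=d["r"]))


# ---------------------------------------------------------------------------
# initial guesses


def _guess_cmc(x, y, frac=0.2):
    """Location of the extremum of the smoothed |second derivative|, clipped
    to the interior 10-90% of the concentration range."""
    try:
        _, _, d2 = local_quadratic_derivatives(x, y, frac=frac)
        i = int(np.argmax(np.abs(d2)))
        cmc0 = float(x[i])
    except Exception:
        cmc0 = float(np.median(x))
    lo = x[0] + 0.1 * (x[-1] - x[0])
    hi = x[0] + 0.9 * (x[-1] - x[0])
    cmc0 = float(np.clip(cmc0, lo, hi))
    return max(cmc0, 1e-12)


def _edge_means(y, k=3):
    return float(np.mean(y[:k])), float(np.mean(y[-k:]))


def _edge_slopes(x, y, frac=0.25):
    """Least-squares line slopes/intercepts on the lowest and highest frac of x."""
    n = len(x)
    k = max(3, int(round(frac * n)))
    mlo, clo = np.polyfit(x[:k], y[:k], 1)
    mhi, chi = np.polyfit(x[-k:], y[-k:], 1)
    return (float(mlo), float(clo)), (float(mhi), float(chi))


def _transition_scale(x, y, cmc0):
    """Rough concentration scale over which a sigmoid crosses its midpoint."""
    y0, y1 = _edge_means(y)
    mid = 0.5 * (y0 + y1)
    sign = 1.0 if y1 >= y0 else -1.0
    above = sign * (y - mid) > 0
    if above.any() and not above.all():
        xc = float(x[int(np.argmax(above))])
    else:
        xc = cmc0
    return max(abs(xc - cmc0), 0.05 * cmc0)


def _g_conductivity(x, y):
    cmc0 = _guess_cmc(x, y)
    (a0, c_lo), (b0, _) = _edge_slopes(x, y)
    return {"cmc": cmc0, "r": 0.1, "a": max(a0, 1e-12), "b": b0, "kappa_s": c_lo}


def _g_molar_conductivity(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    return {"cmc": cmc0, "r": 0.1, "a": max(y0, 1e-12), "b": y1}


def _g_carpena(x, y):
    g = _g_conductivity(x, y)
    return {
        "cmc": g["cmc"],
        "delta": 0.1 * g["cmc"] / 1.6,
        "a": g["a"],
        "b": g["b"],
        "kappa_s": g["kappa_s"],
    }


def _g_surface_tension(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    k0 = 10.0 / cmc0
    drop = max(y0 - y1, 1e-6 * max(abs(y0), 1.0))
    return {
        "cmc": cmc0,
        "r": 0.1,
        "gamma0": max(y0, 1e-12),
        "st_coeff": drop / np.log1p(k0 * cmc0),
        "k_ad": k0,
    }


def _g_nmr(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    return {"cmc": cmc0, "r": 0.1, "delta_free": y0, "delta_mic": y1}


def _g_binding(x, y, cmc0):
    """Composite per-surfactant binding constant from the half-rise point."""
    sm_half = _transition_scale(x, y, cmc0)
    return 1.0 / sm_half


def _g_fluorescence(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    return {
        "cmc": cmc0,
        "r": 0.1,
        "k_per_s": _g_binding(x, y, cmc0),
        "f_free": y0,
        "f_bound": y1,
    }


def _g_pyrene(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    return {
        "cmc": cmc0,
        "r": 0.1,
        "c": _g_binding(x, y, cmc0),
        "sr_free": y0,
        "sr_bound": y1,
    }


def _g_absorbance(x, y):
    cmc0 = _guess_cmc(x, y)
    (e10, _), (em0, _) = _edge_slopes(x, y)
    return {"cmc": cmc0, "r": 0.1, "eps1": max(e10, 1e-12), "epsm": max(em0, 1e-12)}


def _g_absorbance_ratio(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    return {"cmc": cmc0, "r": 0.1, "q1": y0, "qm": y1, "qa": 1.0}


def _g_diffusion(x, y):
    cmc0 = _guess_cmc(x, y)
    y0, y1 = _edge_means(y)
    d_f = max(y0, 1e-9)
    d_b = min(max(y1, 1e-12), 0.9 * d_f)
    return {
        "cmc": cmc0,
        "r": 0.1,
        "k_per_s": _g_binding(x, y, cmc0),
        "d_free": d_f,
        "d_bound": d_b,
    }


def _g_aggregation(x, y):
    # the aggregated fraction crosses ~0.2 r near the cac; use the half-rise
    cmc0 = _guess_cmc(x, y)
    return {"cac": cmc0, "r": 0.3}


_LOG = "log"
_LIN = "linear"

MODELS: dict[str, ModelDef] = {
    "conductivity": ModelDef(
        names=("cmc", "r", "a", "b", "kappa_s"),
        scales={"cmc": _LOG, "r": _LOG, "a": _LIN, "b": _LIN, "kappa_s": _LIN},
        fn=_f_conductivity,
        guess=_g_conductivity,
    ),
    "molar_conductivity": ModelDef(
        names=("cmc", "r", "a", "b"),
        scales={"cmc": _LOG, "r": _LOG, "a": _LIN, "b": _LIN},
        fn=_f_molar_conductivity,
        guess=_g_molar_conductivity,
    ),
    "carpena": ModelDef(
        names=("cmc", "delta", "a", "b", "kappa_s"),
        scales={"cmc": _LOG, "delta": _LOG, "a": _LIN, "b": _LIN, "kappa_s": _LIN},
        fn=_f_carpena,
        guess=_g_carpena,
    ),
    "surface_tension": ModelDef(
        names=("cmc", "r", "gamma0", "st_coeff", "k_ad"),
        scales={"cmc": _LOG, "r": _LOG, "gamma0": _LIN, "st_coeff": _LIN, "k_ad": _LOG},
        fn=_f_surface_tension,
        guess=_g_surface_tension,
    ),
    "nmr": ModelDef(
        names=("cmc", "r", "delta_free", "delta_mic"),
        scales={"cmc": _LOG, "r": _LOG, "delta_free": _LIN, "delta_mic": _LIN},
        fn=_f_nmr,
        guess=_g_nmr,
    ),
    "fluorescence": ModelDef(
        names=("cmc", "r", "k_per_s", "f_free", "f_bound"),
        scales={"cmc": _LOG, "r": _LOG, "k_per_s": _LOG, "f_free": _LIN, "f_bound": _LIN},
        fn=_f_fluorescence,
        guess=_g_fluorescence,
    ),
    "pyrene_ratio": ModelDef(
        names=("cmc", "r", "c", "sr_free", "sr_bound"),
        scales={"cmc": _LOG, "r": _LOG, "c": _LOG, "sr_free": _LIN, "sr_bound": _LIN},
        fn=_f_pyrene,
        guess=_g_pyrene,
    ),
    "absorbance": ModelDef(
        names=("cmc", "r", "eps1", "epsm"),
        scales={"cmc": _LOG, "r": _LOG, "eps1": _LIN, "epsm": _LIN},
        fn=_f_absorbance,
        guess=_g_absorbance,
    ),
    "absorbance_ratio": ModelDef(
        names=("cmc", "r", "q1", "qm", "qa"),
        scales={"cmc": _LOG, "r": _LOG, "q1": _LIN, "qm": _LIN, "qa": _LOG},
        fn=_f_absorbance_ratio,
        guess=_g_absorbance_ratio,
    ),
    "fcs_diffusion": ModelDef(
        names=("cmc", "r", "k_per_s", "d_free", "d_bound"),
        scales={"cmc": _LOG, "r": _LOG, "k_per_s": _LOG, "d_free": _LOG, "d_bound": _LOG},
        fn=_f_diffusion,
        guess=_g_diffusion,
    ),
    "aggregation": ModelDef(
        names=("cac", "r"),
        scales={"cac": _LOG, "r": _LOG},
        fn=_f_aggregation,
        guess=_g_aggregation,
        cmc_name="cac",
    ),
}


def forward(kind: str, x: np.ndarray, params: dict) -> np.ndarray:
    """Evaluate the forward model of a property kind at concentrations x."""
    if kind not in MODELS:
        raise ValueError(f"unknown property kind {kind!r}")
    return np.asarray(MODELS[kind].fn(np.asarray(x, dtype=float), params))


def initial_guess(curve: TitrationCurve) -> list[ParameterSpec]:
    """Data-driven starting values for fitting ``curve`` with its own kind.

    The critical concentration starts at the extremum of the smoothed
    numerical second derivative (clipped into the interior of the x range),
    the relative width at 0.1, straight-line slopes from the lowest/highest
    quarter of the data and sigmoid plateaus from the first/last 3 points.
    """
    kind = "carpena" if curve.kind == "carpena" else curve.kind
    model = MODELS[kind]
    g = model.guess(curve.x, curve.y)
    specs = []
    for name in model.names:
        init = g[name]
        scale = model.scales[name]
        if scale == _LOG and init <= 0:
            init = 1e-12
        specs.append(ParameterSpec(name=name, init=init, scale=scale))
    return specs


def default_specs(kind: str, params: dict) -> list[ParameterSpec]:
    """Specs initialized at supplied values (e.g. true generating parameters)."""
    model = MODELS[kind]
    return [
        ParameterSpec(name=n, init=float(params[n]), scale=model.scales[n])
        for n in model.names
    ]
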