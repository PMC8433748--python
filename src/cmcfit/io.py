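"""CSV curve files, fit configuration and machine-readable fit reports.

Curve files are plain CSV with a header row ``concentration,value[,error]``,
'.' decimals and ',' delimiter; metadata travels in leading comment lines of
the form ``# key: value`` (kind, units, temperature, label).  Reports are
JSON with full-precision numbers; configurations are YAML.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import FitResult, GlobalFitResult, TitrationCurve

__all__ = ["read_curve", "write_curve", "write_report", "read_report", "read_config"]

logger = logging.getLogger("cmcfit")


def _pkg_version() -> str:
    try:
        return version("cmcfit")
    except PackageNotFoundError:
        return "unknown"


class CurveParseError(ValueError):
    """A curve file could not be parsed; the message names the offending cell."""


def write_curve(curve: TitrationCurve, path) -> None:
    path = Path(path)
    lines = [f"# kind: {curve.kind}"]
    for key, val in curve.meta.items():
        lines.append(f"# {key}: {val}")
    cols = "concentration,value" + (",error" if curve.y_err is not None else "")
    lines.append(cols)
    for i in range(len(curve)):
        row = f"{float(curve.x[i])!r},{float(curve.y[i])!r}"
        if curve.y_err is not None:
            row += f",{float(curve.y_err[i])!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_curve(path, kind: str | None = None) -> TitrationCurve:
    """Load and validate a titration-curve CSV.

    Unsorted rows are sorted by concentration with a logged warning;
    malformed numeric cells raise :class:`CurveParseError` naming the line.
    """
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with path.open() as fh:
        raw = fh.readlines()
    for line in raw:
        if not line.startswith("#"):
            break
        header_lines += 1
        body = line.lstrip("#").strip()
        if ":" in body:
            key, val = body.split(":", 1)
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    required = {"concentration", "value"}
    if not required.issubset(df.columns):
        raise CurveParseError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    if len(df) < 4:
        raise CurveParseError(f"{path}: need at least 4 data rows, found {len(df)}")
    numeric = {}
    cols = ["concentration", "value"] + (["error"] if "error" in df.columns else [])
    for col in cols:
        vals = np.empty(len(df))
        for row, cell in enumerate(df[col]):
            try:
                # python strtod is exactly repr-roundtrip safe
                vals[row] = float(cell)
            except (TypeError, ValueError):
                raise CurveParseError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, "
                    f"data row {row + 1}"
                ) from None
        numeric[col] = vals
    x = numeric["concentration"]
    warnings_list = list(meta.pop("warnings", "").split(";")) if "warnings" in meta else []
    warnings_list = [w for w in warnings_list if w]
    if np.any(np.diff(x) < 0):
        msg = f"{path}: concentrations not ascending; rows sorted on load"
        logger.warning(msg)
        warnings_list.append(msg)
        order = np.argsort(x, kind="stable")
        for col in numeric:
            numeric[col] = numeric[col][order]
        x = numeric["concentration"]
    curve_kind = kind or meta.pop("kind", None)
    if curve_kind is None:
        raise CurveParseError(f"{path}: property kind missing (no '# kind:' header)")
    if warnings_list:
        meta["warnings"] = warnings_list
    return TitrationCurve(
        kind=curve_kind,
        x=x,
        y=numeric["value"],
        y_err=numeric.get("error"),
        meta=meta,
    )


def _result_payload(result: FitResult) -> dict:
    return {
        "kind": result.kind,
        "estimates": {k: float(v) for k, v in result.estimates.items()},
        "std_errors": {k: float(v) for k, v in result.std_errors.items()},
        "free_names": list(result.free_names),
        "covariance": None
        if result.covariance is None
        else np.asarray(result.covariance).tolist(),
        "red_chi2": float(result.red_chi2),
        "residuals": np.asarray(result.residuals).tolist(),
        "n_points": int(result.n_points),
        "n_free": int(result.n_free),
        "converged": bool(result.converged),
        "message": result.message,
        "weighted": bool(result.weighted),
        "subsample_indices": None
        if result.subsample_indices is None
        else np.asarray(result.subsample_indices).tolist(),
    }


def write_report(
    result: FitResult | GlobalFitResult,
    path,
    settings: dict | None = None,
    seed: int | None = None,
    warnings: list | None = None,
) -> None:
    """Serialize a fit outcome to JSON (full precision) with a text summary alongside."""
    path = Path(path)
    doc: dict = {
        "cmcfit_version": _pkg_version(),
        "settings": settings or {},
        "seed": seed,
        "warnings": warnings or [],
    }
    if isinstance(result, GlobalFitResult):
        doc["type"] = "global_fit"
        doc["shared"] = {
            k: {"value": float(v), "std_error": float(se)} for k, (v, se) in result.shared.items()
        }
        doc["red_chi2"] = float(result.red_chi2)
        doc["converged"] = bool(result.converged)
        doc["message"] = result.message
        doc["per_curve"] = [_result_payload(r) for r in result.per_curve]
    else:
        doc["type"] = "fit"
        doc.update(_result_payload(result))
    path.write_text(json.dumps(doc, indent=1) + "\n")
    summary = path.with_suffix(path.suffix + ".txt")
    summary.write_text(_summarize(doc))


def _summarize(doc: dict) -> str:
    lines = [f"cmcfit {doc['cmcfit_version']} report ({doc['type']})"]
    if doc["type"] == "global_fit":
        lines.append(f"converged: {doc['converged']}   reduced chi^2: {doc['red_chi2']:.6g}")
        if not doc["converged"]:
            lines.append(f"message: {doc['message']}")
        for name, sv in doc["shared"].items():
            lines.append(f"shared {name} = {sv['value']:.6g} +/- {sv['std_error']:.2g}")
        for i, r in enumerate(doc["per_curve"]):
            est = ", ".join(f"{k}={v:.6g}" for k, v in r["estimates"].items())
            lines.append(f"curve {i}: {est}")
    else:
        lines.append(f"converged: {doc['converged']}   reduced chi^2: {doc['red_chi2']:.6g}")
        if not doc["converged"]:
            lines.append(f"message: {doc['message']}")
        for k, v in doc["estimates"].items():
            se = doc["std_errors"].get(k)
            tail = f" +/- {se:.2g}" if se is not None and np.isfinite(se) else " (fixed)"
            lines.append(f"{k} = {v:.10g}{tail}")
    for w in doc.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path) -> dict:
    """Load a YAML fit configuration (property kind, parameter blocks, datasets)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
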