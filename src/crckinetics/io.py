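"""On-disk formats: curve tables (CSV, optional XLSX import) and model specs (JSON).

Curve tables are UTF-8 CSV with a commented metadata header::

    # format: crckinetics-curve v1
    # protein: XRCC1
    # treatment: none
    # n_cells: 12
    time_s,intensity_mean,intensity_sd
    0,0,0
    ...

Model specs are JSON documents with explicit ``components[]`` (role,
rates_per_s, tau_s, amplitude, has_removal), optional ``bleach``, ``baseline``
and a ``format_version`` field.  Readers reject invariant violations (naming
the offending row or field) rather than silently repairing them; both formats
round-trip at full precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import BleachComponent, CompositeModel, CRCParameters
from .curve import KineticCurve, MetadataBlock
from .exceptions import InputError, SchemaError

__all__ = [
    "read_curve_table",
    "write_curve_table",
    "read_model_spec",
    "write_model_spec",
    "model_to_dict",
    "model_from_dict",
    "CURVE_FORMAT_TAG",
    "MODEL_FORMAT_VERSION",
]

CURVE_FORMAT_TAG = "crckinetics-curve v1"
MODEL_FORMAT_VERSION = 1

_META_KEYS = {
    "protein": str,
    "treatment": str,
    "laser_power_fraction": float,
    "sampling_interval_s": float,
    "bac_id": str,
    "reporter": str,
    "notes": str,
}


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# Curve tables
# ---------------------------------------------------------------------------


def write_curve_table(curve: KineticCurve, path: Union[str, Path]) -> None:
    """Write a curve as CSV with a ``# key: value`` metadata header (full precision)."""
    path = Path(path)
    md = curve.metadata
    lines = [f"# format: {CURVE_FORMAT_TAG}"]
    for key in _META_KEYS:
        val = getattr(md, key)
        if val is None or val == "":
            continue
        lines.append(f"# {key}: {val}")
    lines.append(f"# n_cells: {curve.n_cells}")
    lines.append("time_s,intensity_mean,intensity_sd")
    for t, y, sd in zip(curve.timepoints, curve.intensity_mean, curve.intensity_sd):
        lines.append(f"{_fmt(t)},{_fmt(y)},{_fmt(sd)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_header(path: Path) -> dict:
    meta = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def _curve_from_frame(df: pd.DataFrame, meta: dict, source: str) -> KineticCurve:
    required = ["time_s", "intensity_mean", "intensity_sd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}; found {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    y = df["intensity_mean"].to_numpy(dtype=float)
    sd = df["intensity_sd"].to_numpy(dtype=float)
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError(f"{source}: time not strictly increasing at data row {bad[0] + 2} "
                          f"(t={t[bad[0] + 1]:g} after t={t[bad[0]]:g})")
    neg = np.where(sd < 0)[0]
    if neg.size:
        raise SchemaError(f"{source}: negative SD at data row {neg[0] + 1}")
    md_kwargs = {}
    for key, cast in _META_KEYS.items():
        if key in meta and meta[key] != "":
            try:
                md_kwargs[key] = cast(meta[key])
            except ValueError as exc:
                raise SchemaError(f"{source}: metadata field {key!r}: {exc}") from exc
    try:
        metadata = MetadataBlock(**md_kwargs)
        n_cells = int(meta.get("n_cells", 1))
        return KineticCurve(timepoints=t, intensity_mean=y, intensity_sd=sd,
                            n_cells=n_cells, metadata=metadata)
    except InputError as exc:
        raise SchemaError(f"{source}: {exc}") from exc


#: Permissive column-name mapping for spreadsheet imports.
_XLSX_ALIASES = {
    "time_s": ("time_s", "time", "time (s)", "t", "t_s", "seconds"),
    "intensity_mean": ("intensity_mean", "intensity", "mean", "mean intensity",
                       "raw intensity", "signal"),
    "intensity_sd": ("intensity_sd", "sd", "stdev", "std", "standard deviation", "sigma"),
}


def read_curve_table(path: Union[str, Path], dialect: str = "csv") -> KineticCurve:
    """Read a curve table; ``dialect`` is "csv" (canonical) or "xlsx" (permissive import)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if dialect == "csv":
        meta = _parse_header(path)
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        return _curve_from_frame(df, meta, source=str(path))
    if dialect == "xlsx":
        df = pd.read_excel(path)
        rename = {}
        lowered = {str(c).strip().lower(): c for c in df.columns}
        for canon, aliases in _XLSX_ALIASES.items():
            for alias in aliases:
                if alias in lowered:
                    rename[lowered[alias]] = canon
                    break
        df = df.rename(columns=rename)
        if "intensity_sd" not in df.columns:
            df["intensity_sd"] = 0.0
        return _curve_from_frame(df, {}, source=str(path))
    raise InputError(f"unknown dialect {dialect!r} (use 'csv' or 'xlsx')")


# ---------------------------------------------------------------------------
# Model specs
# ---------------------------------------------------------------------------


def model_to_dict(model: CompositeModel) -> dict:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "baseline": model.baseline,
        "components": [
            {
                "role": role,
                "rates_per_s": list(p.rates),
                "tau_s": p.detachment_delay,
                "amplitude": p.amplitude,
                "has_removal": p.has_removal,
            }
            for p, role in model.components
        ],
        "bleach": None,
    }
    if model.bleach is not None:
        doc["bleach"] = {"depth": model.bleach.depth,
                         "recovery_rate_per_s": model.bleach.recovery_rate}
    return doc


def model_from_dict(doc: dict, source: str = "<dict>") -> CompositeModel:
    if not isinstance(doc, dict) or "components" not in doc:
        raise SchemaError(f"{source}: not a model spec (missing 'components')")
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise SchemaError(f"{source}: format_version: expected {MODEL_FORMAT_VERSION}, got {version!r}")
    comps = []
    for i, c in enumerate(doc["components"]):
        where = f"{source}: components[{i}]"
        for fld in ("role", "rates_per_s", "amplitude", "has_removal"):
            if fld not in c:
                raise SchemaError(f"{where}.{fld}: missing")
        rates = c["rates_per_s"]
        for j, k in enumerate(rates):
            if not (isinstance(k, (int, float)) and math.isfinite(k) and k > 0):
                raise SchemaError(f"{where}.rates_per_s[{j}]: must be finite and > 0, got {k!r}")
        try:
            comps.append((
                CRCParameters(rates=tuple(rates),
                              detachment_delay=float(c.get("tau_s", 0.0)),
                              amplitude=float(c["amplitude"]),
                              has_removal=bool(c["has_removal"])),
                c["role"],
            ))
        except InputError as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    bleach = None
    if doc.get("bleach") is not None:
        b = doc["bleach"]
        try:
            bleach = BleachComponent(depth=float(b["depth"]),
                                     recovery_rate=float(b["recovery_rate_per_s"]))
        except (KeyError, InputError) as exc:
            raise SchemaError(f"{source}: bleach: {exc}") from exc
    try:
        return CompositeModel(components=tuple(comps), bleach=bleach,
                              baseline=float(doc.get("baseline", 0.0)))
    except InputError as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def write_model_spec(model: CompositeModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n", encoding="utf-8")


def read_model_spec(path: Union[str, Path]) -> CompositeModel:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    return model_from_dict(doc, source=str(path))
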