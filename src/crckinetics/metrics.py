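"""Interpretable scalars derived from fitted CRC models.

Halftime conventions (computed numerically on the model curve so they remain
correct for arbitrary composites):

* recruitment halftime — earliest time at which the curve reaches half of its
  maximum on the rising phase;
* removal halftime — earliest time past the peak at which the curve has
  decayed halfway from the peak toward its asymptote (the asymptote is the
  baseline plus the amplitudes of the non-removable components).

The evaluation horizon defaults to 10x the slowest model timescale
(1/min-rate plus the largest detachment delay); the decay search extends it
geometrically when the midpoint has not yet been crossed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import BleachComponent, CompositeModel, CRCParameters, evaluate_model
from .exceptions import HorizonError, InputError

__all__ = [
    "KineticsSummary",
    "ConditionComparison",
    "ParameterPath",
    "recruitment_halftime",
    "removal_halftime",
    "peak_of",
    "summarize",
    "rank_by_recruitment",
    "compare_conditions",
    "ordering_shift",
    "parameter_path",
]

_GRID = 4096  # dense-scan resolution for bracketing curve features


@dataclass(frozen=True)
class KineticsSummary:
    """Derived descriptors of one protein's kinetics under one condition."""

    recruitment_halftime: float
    removal_halftime: Optional[float]
    peak_time: Optional[float]
    plateau_fraction: float
    protein: str = ""
    condition: str = ""


@dataclass(frozen=True)
class ConditionComparison:
    """Treated-vs-untreated comparison of two structure-matched fits.

    ``rate_ratios`` maps parameter names to treated/untreated ratios;
    ``structure_mismatch`` describes why ratios could not be formed (all other
    fields are then None).  ``ordering_shift`` involves a second protein and is
    filled in by :func:`ordering_shift`, not here.
    """

    rate_ratios: Optional[Dict[str, float]]
    delta_recruitment_halftime: Optional[float]
    delta_removal_halftime: Optional[float]
    ordering_shift: Optional[float] = None
    structure_mismatch: Optional[str] = None


@dataclass(frozen=True)
class ParameterPath:
    """Interpolated parameter sets between two fitted models.

    ``mode="parallel"``: every parameter moves at every step (rates
    geometrically, amplitudes/delays/baseline linearly), path length =
    ``steps``.  ``mode="sequential"``: one parameter moves per segment, each
    over ``steps`` points, path length = p*(steps-1)+1.
    """

    models: Tuple[CompositeModel, ...]
    mode: str
    steps: int


# ---------------------------------------------------------------------------
# Curve-feature extraction
# ---------------------------------------------------------------------------


def _model_of(obj) -> CompositeModel:
    if isinstance(obj, CompositeModel):
        return obj
    model = getattr(obj, "model", None)
    if isinstance(model, CompositeModel):
        return model
    raise InputError(f"expected a CompositeModel or a fit result, got {type(obj).__name__}")


def default_horizon(model: CompositeModel) -> float:
    """10x the slowest timescale: max over components of (1/min rate + tau)."""
    slowest = 0.0
    for p, _ in model.components:
        slowest = max(slowest, 1.0 / min(p.rates) + p.detachment_delay)
    if model.bleach is not None:
        slowest = max(slowest, 1.0 / model.bleach.recovery_rate)
    return 10.0 * slowest


def peak_of(model_or_fit, horizon: Optional[float] = None) -> Tuple[Optional[float], float]:
    """(peak_time, peak_value) of the model curve.

    ``peak_time`` is None for curves without an interior maximum (no component
    detaches: the curve rises monotonically to its asymptote, whose value is
    returned as the peak).
    """
    model = _model_of(model_or_fit)
    if not model.has_removal:
        return None, model.asymptote()
    h = horizon if horizon is not None else default_horizon(model)
    t = np.linspace(0.0, h, _GRID)
    y = evaluate_model(model, t)
    i = int(np.argmax(y))
    lo = t[max(i - 1, 0)]
    hi = t[min(i + 1, t.size - 1)]
    if hi > lo:
        sol = minimize_scalar(lambda x: -_value(model, x), bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-9 * max(h, 1.0)})
        if sol.success and -sol.fun >= y[i]:
            return float(sol.x), float(-sol.fun)
    return float(t[i]), float(y[i])


def _value(model: CompositeModel, t: float) -> float:
    return float(evaluate_model(model, np.array([t]))[0])


def recruitment_halftime(model_or_fit, horizon: Optional[float] = None) -> float:
    """Earliest t with I(t) = I_max/2 on the rising phase of the model curve."""
    model = _model_of(model_or_fit)
    h = horizon if horizon is not None else default_horizon(model)
    t_peak, peak = peak_of(model, horizon=h)
    if peak <= 0:
        raise HorizonError("model curve has no positive maximum; no recruitment halftime")
    target = peak / 2.0
    t_hi = t_peak if t_peak is not None else h
    t = np.linspace(0.0, t_hi, _GRID)
    y = evaluate_model(model, t)
    above = np.where(y >= target)[0]
    if above.size == 0:
        raise HorizonError(
            f"curve does not reach half its maximum within the horizon ({t_hi:g} s)"
        )
    i = above[0]
    if i == 0:
        return float(t[0]) if y[0] >= target else 0.0
    return float(brentq(lambda x: _value(model, x) - target, t[i - 1], t[i], xtol=1e-12, rtol=1e-14))


def removal_halftime(model_or_fit, horizon: Optional[float] = None) -> Optional[float]:
    """Earliest t past the peak with I(t) = (I_peak + I_inf)/2; None without removal."""
    model = _model_of(model_or_fit)
    if not model.has_removal:
        return None
    h = horizon if horizon is not None else default_horizon(model)
    t_peak, peak = peak_of(model, horizon=h)
    asym = model.asymptote()
    target = 0.5 * (peak + asym)
    lo = t_peak
    hi = h
    for _attempt in range(8):
        t = np.linspace(lo, hi, _GRID)
        y = evaluate_model(model, t)
        below = np.where(y <= target)[0]
        if below.size:
            i = below[0]
            if i == 0:
                return float(t[0])
            return float(brentq(lambda x: _value(model, x) - target, t[i - 1], t[i],
                                xtol=1e-12, rtol=1e-14))
        lo, hi = hi, hi * 4.0
    raise HorizonError("decay midpoint not reached within the extended horizon")


def summarize(model_or_fit, protein: str = "", condition: str = "",
              horizon: Optional[float] = None) -> KineticsSummary:
    """Bundle halftimes, peak time and plateau fraction into one record."""
    model = _model_of(model_or_fit)
    t_peak, peak = peak_of(model, horizon=horizon)
    rec = recruitment_halftime(model, horizon=horizon)
    rem = removal_halftime(model, horizon=horizon)
    asym = model.asymptote()
    plateau = 1.0 if peak == 0 else min(max(asym / peak, 0.0), 1.0)
    return KineticsSummary(
        recruitment_halftime=rec,
        removal_halftime=rem,
        peak_time=t_peak,
        plateau_fraction=plateau,
        protein=protein,
        condition=condition,
    )


def rank_by_recruitment(summaries: Sequence[KineticsSummary]) -> List[KineticsSummary]:
    """Temporal map: sort by recruitment halftime, ties broken by protein label."""
    if not summaries:
        raise InputError("need at least one summary to rank")
    conditions = {s.condition for s in summaries}
    if len(conditions) > 1:
        raise InputError(f"cannot rank across mixed conditions: {sorted(conditions)}")
    return sorted(summaries, key=lambda s: (s.recruitment_halftime, s.protein))


# ---------------------------------------------------------------------------
# Condition comparison and parameter paths
# ---------------------------------------------------------------------------


def _structures_match(a: CompositeModel, b: CompositeModel) -> Optional[str]:
    if len(a.components) != len(b.components):
        return f"component counts differ ({len(a.components)} vs {len(b.components)})"
    for i, ((pa, ra), (pb, rb)) in enumerate(zip(a.components, b.components)):
        if ra != rb:
            return f"component {i}: roles differ ({ra} vs {rb})"
        if pa.n != pb.n or pa.has_removal != pb.has_removal:
            return f"component {i}: chain structures differ (n={pa.n}/{pb.n}, removal={pa.has_removal}/{pb.has_removal})"
    if (a.bleach is None) != (b.bleach is None):
        return "bleach component present in only one model"
    return None


def _named_params(model: CompositeModel) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for i, (p, _role) in enumerate(model.components):
        for j, k in enumerate(p.rates, start=1):
            out[f"c{i}.k{j}"] = k
        if p.has_removal:
            out[f"c{i}.tau"] = p.detachment_delay
        out[f"c{i}.A"] = p.amplitude
    if model.bleach is not None:
        out["bleach.depth"] = model.bleach.depth
        out["bleach.rate"] = model.bleach.recovery_rate
    out["baseline"] = model.baseline
    return out


def compare_conditions(fit_untreated, fit_treated) -> ConditionComparison:
    """Per-parameter treated/untreated ratios and halftime deltas.

    If the two fits do not share the same structure a mismatch report is
    returned instead of ratios.
    """
    mu = _model_of(fit_untreated)
    mt = _model_of(fit_treated)
    mismatch = _structures_match(mu, mt)
    if mismatch is not None:
        return ConditionComparison(
            rate_ratios=None, delta_recruitment_halftime=None,
            delta_removal_halftime=None, structure_mismatch=mismatch,
        )
    pu = _named_params(mu)
    pt = _named_params(mt)
    ratios = {}
    for name, vu in pu.items():
        vt = pt[name]
        ratios[name] = vt / vu if vu != 0 else (math.inf if vt > 0 else 1.0)
    d_rec = recruitment_halftime(mt) - recruitment_halftime(mu)
    ru, rt = removal_halftime(mu), removal_halftime(mt)
    d_rem = (rt - ru) if (ru is not None and rt is not None) else None
    return ConditionComparison(
        rate_ratios=ratios,
        delta_recruitment_halftime=d_rec,
        delta_removal_halftime=d_rem,
    )


def ordering_shift(protein_a_untreated, protein_a_treated,
                   protein_b_untreated, protein_b_treated) -> float:
    """Signed change, across conditions, of the recruitment lag between two proteins.

    lag = t1/2(B) - t1/2(A); returns lag_treated - lag_untreated.  A negative
    value means the treatment erodes A's head start over B.
    """
    lag_u = (recruitment_halftime(_model_of(protein_b_untreated))
             - recruitment_halftime(_model_of(protein_a_untreated)))
    lag_t = (recruitment_halftime(_model_of(protein_b_treated))
             - recruitment_halftime(_model_of(protein_a_treated)))
    return lag_t - lag_u


def _interp(name: str, a: float, b: float, frac: float) -> float:
    # rates are scale parameters -> geometric; amplitudes, delays, baseline -> linear
    geometric = (".k" in name and not name.endswith(".A")) or name == "bleach.rate"
    if geometric and a > 0 and b > 0:
        return a * (b / a) ** frac
    return a + (b - a) * frac


def _model_from_named(template: CompositeModel, values: Dict[str, float]) -> CompositeModel:
    comps = []
    for i, (p, role) in enumerate(template.components):
        rates = tuple(values[f"c{i}.k{j}"] for j in range(1, p.n + 1))
        tau = values.get(f"c{i}.tau", 0.0) if p.has_removal else 0.0
        comps.append((CRCParameters(rates=rates, detachment_delay=tau,
                                    amplitude=values[f"c{i}.A"],
                                    has_removal=p.has_removal), role))
    bleach = None
    if template.bleach is not None:
        bleach = BleachComponent(depth=values["bleach.depth"],
                                 recovery_rate=values["bleach.rate"])
    return CompositeModel(components=tuple(comps), bleach=bleach,
                          baseline=values["baseline"])


def parameter_path(fit_a, fit_b, steps: int = 10, mode: str = "parallel") -> ParameterPath:
    """Interpolate between two structure-matched fits ("Animation"/"P animation").

    ``parallel`` moves every kinetic constant simultaneously in ``steps``
    frames; ``sequential`` animates one parameter at a time (``steps`` frames
    per parameter), showing each constant's individual contribution.
    """
    if steps < 2:
        raise InputError("steps must be >= 2")
    if mode not in ("parallel", "sequential"):
        raise InputError("mode must be 'parallel' or 'sequential'")
    ma = _model_of(fit_a)
    mb = _model_of(fit_b)
    mismatch = _structures_match(ma, mb)
    if mismatch is not None:
        raise InputError(f"structure mismatch: {mismatch}")
    pa = _named_params(ma)
    pb = _named_params(mb)
    names = list(pa)
    models: List[CompositeModel] = []
    if mode == "parallel":
        for s in range(steps):
            frac = s / (steps - 1)
            vals = {nm: _interp(nm, pa[nm], pb[nm], frac) for nm in names}
            models.append(_model_from_named(ma, vals))
    else:
        current = dict(pa)
        models.append(_model_from_named(ma, current))
        for nm in names:
            for s in range(1, steps):
                frac = s / (steps - 1)
                vals = dict(current)
                vals[nm] = _interp(nm, pa[nm], pb[nm], frac)
                models.append(_model_from_named(ma, vals))
            current[nm] = pb[nm]
    return ParameterPath(models=tuple(models), mode=mode, steps=steps)
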