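"""Weighted nonlinear least-squares fitting of CRC models to kinetic curves.

Organized in the statsmodels idiom: build a :class:`CRCModel` from a
:class:`~crckinetics.curve.KineticCurve` (plus a structure template), call
``fit()`` / ``fit_select()`` and work with the returned :class:`CRCResults`
(estimates, standard errors, selection trace, ``summary()``, ``predict()``,
``bootstrap()``).  Thin module-level functions (:func:`fit_fixed_structure`,
:func:`select_chain_length`, :func:`fit_composite`,
:func:`bootstrap_uncertainty`, :func:`remove_bleach`) expose the same
operations functionally.

Positivity of rates and amplitudes is enforced by optimizing log-transformed
parameters; the detachment delay uses a softplus transform (tau >= 0).  Each
fit runs a seeded multistart: the template's own values first, then random
starts with log-uniform rates spanning 1e-4..10 1/s (recruitment halftimes in
this kind of data span seconds to tens of minutes), tau uniform over
[0, t_max/2] and the amplitude taken from the curve maximum.

Chain length is selected by fitting n = 1, 2, ... and stopping at the first n
whose successor no longer improves the fit: by default an AICc drop of more
than 2.0 is required to accept the larger model (a relative-SSE floor is the
alternative criterion), which quantifies the "fit quality unchanged" stopping
rule with a standard parsimony threshold.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import (
    BleachComponent,
    CompositeModel,
    CRCParameters,
    evaluate_model,
)
from .curve import KineticCurve
from .exceptions import InputError, NonConvergenceError, NumericalError

__all__ = [
    "FitOptions",
    "CRCModel",
    "CRCResults",
    "FitResult",
    "fit_fixed_structure",
    "select_chain_length",
    "fit_composite",
    "bootstrap_uncertainty",
    "remove_bleach",
    "initial_template",
]

_LOG_RATE_LO, _LOG_RATE_HI = math.log(1e-4), math.log(10.0)


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the fitting and model-selection machinery.

    selection_criterion: "aicc" (default) accepts a longer chain only if AICc
    improves by more than ``aicc_threshold``; "sse" accepts it only if the
    weighted SSE improves by more than ``sse_rel_threshold`` relative.
    weighting: "none" (default; the per-timepoint SD measures cell-to-cell
    biological spread, not uncertainty of the mean) or "inverse-variance".
    """

    n_max: int = 8
    selection_criterion: str = "aicc"
    aicc_threshold: float = 2.0
    sse_rel_threshold: float = 0.01
    weighting: str = "none"
    n_starts: int = 10
    seed: int = 0
    max_iterations: int = 400

    def __post_init__(self):
        if self.n_max < 1:
            raise InputError("n_max must be >= 1")
        if self.selection_criterion not in ("aicc", "sse"):
            raise InputError("selection_criterion must be 'aicc' or 'sse'")
        if self.aicc_threshold <= 0 or self.sse_rel_threshold <= 0:
            raise InputError("selection thresholds must be > 0")
        if self.weighting not in ("none", "inverse-variance"):
            raise InputError("weighting must be 'none' or 'inverse-variance'")
        if self.n_starts < 1:
            raise InputError("n_starts must be >= 1")


# ---------------------------------------------------------------------------
# Parameter codec: CompositeModel <-> transformed free vector
# ---------------------------------------------------------------------------

def _softplus(x: float) -> float:
    return math.log1p(math.exp(-abs(x))) + max(x, 0.0)


def _softplus_inv(y: float) -> float:
    y = max(y, 1e-12)
    # inverse of log(1 + e^x); stable for large y
    return y + math.log(-math.expm1(-y)) if y > 30 else math.log(math.expm1(y))


_TRANSFORMS = {
    "log": (math.log, math.exp, lambda x: x),            # d value / d theta = value
    "softplus": (_softplus_inv, _softplus, None),
    "id": (lambda v: v, lambda v: v, lambda x: 1.0),
}


class _ParamCodec:
    """Maps a CompositeModel's parameters onto an unconstrained vector.

    Parameter names: ``c{i}.k{j}`` (rates, log), ``c{i}.tau`` (softplus),
    ``c{i}.A`` (log), ``bleach.depth`` / ``bleach.rate`` (log), ``baseline``
    (identity).  Names in ``fixed`` keep their template value.
    """

    def __init__(self, template: CompositeModel, fixed: Optional[Sequence[str]] = None):
        self.template = template
        fixed = set(fixed) if fixed is not None else set()
        # baseline is fixed by default (curves are baseline-subtracted);
        # "~baseline" opts it back into the fit
        if "~baseline" in fixed:
            fixed.discard("~baseline")
        else:
            fixed.add("baseline")
        self.fixed = frozenset(fixed)
        self.names: List[str] = []
        self.transforms: List[str] = []
        values: List[float] = []
        for i, (p, _role) in enumerate(template.components):
            for j, k in enumerate(p.rates, start=1):
                self.names.append(f"c{i}.k{j}")
                self.transforms.append("log")
                values.append(k)
            if p.has_removal:
                self.names.append(f"c{i}.tau")
                self.transforms.append("softplus")
                values.append(p.detachment_delay)
            self.names.append(f"c{i}.A")
            self.transforms.append("log")
            values.append(p.amplitude)
        if template.bleach is not None:
            self.names += ["bleach.depth", "bleach.rate"]
            self.transforms += ["log", "log"]
            values += [template.bleach.depth, template.bleach.recovery_rate]
        self.names.append("baseline")
        self.transforms.append("id")
        values.append(template.baseline)
        unknown = fixed - set(self.names)
        if unknown:
            raise InputError(f"fixed parameter names not in model: {sorted(unknown)}")
        self.values = np.array(values, dtype=float)
        self.free_mask = np.array([nm not in fixed for nm in self.names])
        self.free_names = [nm for nm, f in zip(self.names, self.free_mask) if f]

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    def theta_of(self, values: np.ndarray) -> np.ndarray:
        out = np.empty(self.n_free)
        j = 0
        for v, tr, f in zip(values, self.transforms, self.free_mask):
            if f:
                out[j] = _TRANSFORMS[tr][0](v)
                j += 1
        return out

    def values_of(self, theta: np.ndarray) -> np.ndarray:
        vals = self.values.copy()
        j = 0
        for i, (tr, f) in enumerate(zip(self.transforms, self.free_mask)):
            if f:
                vals[i] = _TRANSFORMS[tr][1](theta[j])
                j += 1
        return vals

    def jacobian_scale(self, values: np.ndarray) -> np.ndarray:
        """|d value / d theta| at the solution, for delta-method SEs (free only)."""
        out = []
        for v, tr, f in zip(values, self.transforms, self.free_mask):
            if not f:
                continue
            if tr == "log":
                out.append(v)
            elif tr == "softplus":
                out.append(1.0 - math.exp(-max(v, 1e-12)))  # sigmoid(theta)
            else:
                out.append(1.0)
        return np.array(out)

    def build(self, values: np.ndarray) -> CompositeModel:
        comps = []
        idx = 0
        for p, role in self.template.components:
            nk = len(p.rates)
            rates = tuple(values[idx : idx + nk])
            idx += nk
            tau = 0.0
            if p.has_removal:
                tau = float(values[idx])
                idx += 1
            amp = float(values[idx])
            idx += 1
            comps.append((CRCParameters(rates=rates, detachment_delay=tau,
                                        amplitude=amp, has_removal=p.has_removal), role))
        bleach = None
        if self.template.bleach is not None:
            bleach = BleachComponent(depth=float(values[idx]), recovery_rate=float(values[idx + 1]))
            idx += 2
        baseline = float(values[idx])
        return CompositeModel(components=tuple(comps), bleach=bleach, baseline=baseline)

    def theta_bounds(self, t_max: float, y_scale: float) -> Tuple[np.ndarray, np.ndarray]:
        """Wide safety rails on the transformed parameters (keep exp() sane)."""
        lo, hi = [], []
        for nm, tr, f in zip(self.names, self.transforms, self.free_mask):
            if not f:
                continue
            if tr == "log":
                if nm.endswith(".A") or nm.endswith(".depth"):
                    lo.append(math.log(max(y_scale, 1e-300) * 1e-8))
                    hi.append(math.log(max(y_scale, 1e-300) * 1e4))
                else:
                    lo.append(math.log(1e-8))
                    hi.append(math.log(1e4))
            elif tr == "softplus":
                lo.append(-50.0)
                hi.append(_softplus_inv(max(2.0 * t_max, 1.0)))
            else:
                lo.append(-np.inf)
                hi.append(np.inf)
        return np.array(lo), np.array(hi)


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------


@dataclass
class CRCResults:
    """Fitted composite model with residual statistics and uncertainties.

    ``selection_trace`` lists ``(n, criterion_value, sse)`` rows for every
    chain length tried (a single row for fixed-structure fits).
    """

    model: CompositeModel
    sse: float
    reduced_chi_square: float
    n_selected: Optional[int]
    selection_trace: List[Tuple[int, float, float]]
    parameter_standard_errors: Dict[str, float]
    converged: bool
    seed: int
    n_obs: int
    n_free: int
    curve: KineticCurve = field(repr=False)
    options: FitOptions = field(repr=False)
    fixed: Tuple[str, ...] = ()
    no_plateau: bool = False
    component_collapse: bool = False
    message: str = ""

    # -- statsmodels-style surface -------------------------------------------------
    @property
    def params(self) -> Dict[str, float]:
        codec = _ParamCodec(self.model, fixed=self.fixed)
        return dict(zip(codec.names, codec.values))

    @property
    def bse(self) -> Dict[str, float]:
        return dict(self.parameter_standard_errors)

    def predict(self, times=None) -> np.ndarray:
        t = self.curve.timepoints if times is None else times
        return evaluate_model(self.model, t)

    def resid(self) -> np.ndarray:
        return self.curve.intensity_mean - self.predict()

    def recompute_sse(self) -> float:
        """Weighted SSE re-evaluated from scratch (self-consistency check)."""
        w = _weights(self.curve, self.options)
        r = (self.predict() - self.curve.intensity_mean) * w
        return float(r @ r)

    def bootstrap(self, n_boot: int = 200, seed: int = 0) -> Dict[str, Tuple[float, float]]:
        return bootstrap_uncertainty(self.curve, self, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        buf = io.StringIO()
        md = self.curve.metadata
        w = buf.write
        w("CRC model fit\n")
        w("=" * 64 + "\n")
        w(f"protein: {md.protein}    treatment: {md.treatment}\n")
        w(f"observations: {self.n_obs}    free parameters: {self.n_free}\n")
        w(f"weighted SSE: {self.sse:.6g}    reduced chi^2: {self.reduced_chi_square:.6g}\n")
        w(f"converged: {self.converged}    seed: {self.seed}\n")
        if self.n_selected is not None:
            w(f"selected chain length n = {self.n_selected}"
              + ("  [no criterion plateau reached]" if self.no_plateau else "") + "\n")
        if self.component_collapse:
            w("warning: two components converged to near-identical parameters\n")
        w("-" * 64 + "\n")
        w(f"{'parameter':<16}{'estimate':>16}{'std err':>16}\n")
        for name, val in self.params.items():
            if name in self.parameter_standard_errors:
                se = f"{self.parameter_standard_errors[name]:>16.4g}"
                w(f"{name:<16}{val:>16.6g}{se}\n")
            else:
                w(f"{name:<16}{val:>16.6g}{'(fixed)':>16}\n")
        if self.selection_trace and len(self.selection_trace) > 1:
            w("-" * 64 + "\n")
            w(f"{'n':<6}{'criterion':>16}{'sse':>16}\n")
            for n, crit, sse in self.selection_trace:
                w(f"{n:<6}{crit:>16.6g}{sse:>16.6g}\n")
        return buf.getvalue()

    def plot(self, ax=None):
        """Data (mean +/- SD) with the fitted curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        t = self.curve.timepoints
        ax.errorbar(t, self.curve.intensity_mean, yerr=self.curve.intensity_sd,
                    fmt=".", ms=3, alpha=0.5, label="data (mean ± SD)")
        tt = np.linspace(t[0], t[-1], 400)
        ax.plot(tt, self.predict(tt), "-", lw=1.5, label="CRC fit")
        ax.set_xlabel("time after micro-irradiation (s)")
        ax.set_ylabel("damage-site intensity")
        ax.legend()
        return ax


#: Back-compatible alias: the results object doubles as the fit-result record.
FitResult = CRCResults


# ---------------------------------------------------------------------------
# Fitting internals
# ---------------------------------------------------------------------------


def _weights(curve: KineticCurve, options: FitOptions) -> np.ndarray:
    if options.weighting == "inverse-variance":
        sd = curve.intensity_sd
        if np.any(sd <= 0):
            raise InputError("inverse-variance weighting requires strictly positive SD everywhere")
        return 1.0 / sd
    return np.ones(len(curve))


def _sse_floor(curve: KineticCurve) -> float:
    scale = max(float(np.max(np.abs(curve.intensity_mean))), 1e-30)
    return len(curve) * (1e-12 * scale) ** 2


def _aicc(sse: float, n_obs: int, n_par: int, floor: float) -> float:
    k = n_par + 1  # + residual variance
    sse = max(sse, floor)
    aic = n_obs * math.log(sse / n_obs) + 2 * k
    denom = n_obs - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / denom


def _random_start(codec: _ParamCodec, rng: np.random.Generator,
                  t_max: float, y_max: float) -> np.ndarray:
    vals = codec.values.copy()
    for i, (nm, tr) in enumerate(zip(codec.names, codec.transforms)):
        if not codec.free_mask[i]:
            continue
        if tr == "log" and (nm.endswith(".A") or nm.endswith(".depth")):
            vals[i] = max(y_max, 1e-6)
        elif tr == "log":
            vals[i] = math.exp(rng.uniform(_LOG_RATE_LO, _LOG_RATE_HI))
        elif tr == "softplus":
            vals[i] = rng.uniform(0.0, t_max / 2.0)
    return codec.theta_of(vals)


def _fit_multistart(curve: KineticCurve, template: CompositeModel,
                    options: FitOptions, fixed: Sequence[str],
                    extra_starts: Sequence[np.ndarray] = ()) -> CRCResults:
    t = curve.timepoints
    y = curve.intensity_mean
    w = _weights(curve, options)
    codec = _ParamCodec(template, fixed=fixed)
    n_free = codec.n_free
    if len(curve) < 2 * n_free:
        raise InputError(
            f"curve has {len(curve)} timepoints but the structure has {n_free} free "
            "parameters; need at least 2x as many points as free parameters"
        )
    y_max = max(float(np.max(y)), 1e-12)
    lo, hi = codec.theta_bounds(float(t[-1]), y_max)

    def residuals(theta):
        try:
            model = codec.build(codec.values_of(theta))
            pred = evaluate_model(model, t)
        except (NumericalError, InputError, OverflowError, FloatingPointError):
            return np.full(t.size, 1e150)
        r = (pred - y) * w
        return np.where(np.isfinite(r), r, 1e150)

    rng = np.random.default_rng(options.seed)
    starts: List[np.ndarray] = []
    try:
        starts.append(np.clip(codec.theta_of(codec.values), lo, hi))
    except (ValueError, OverflowError):
        pass
    starts.extend(np.clip(s, lo, hi) for s in extra_starts)
    while len(starts) < max(options.n_starts, 1) + len(extra_starts):
        starts.append(np.clip(_random_start(codec, rng, float(t[-1]), y_max), lo, hi))

    best = None
    any_success = False
    for theta0 in starts:
        try:
            sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf",
                                x_scale="jac", max_nfev=options.max_iterations * max(n_free, 1))
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        if not math.isfinite(sse) or sse >= 1e200:
            continue
        any_success = any_success or bool(sol.success)
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise NonConvergenceError("no optimizer start produced a finite fit")

    sse, sol = best
    values = codec.values_of(sol.x)
    model = codec.build(values)
    dof = max(len(curve) - n_free, 1)
    red_chi2 = sse / dof

    # delta-method standard errors from the TRF Jacobian (w.r.t. theta)
    ses = {}
    try:
        J = sol.jac
        JTJ = J.T @ J
        cov_theta = np.linalg.pinv(JTJ) * red_chi2
        se_theta = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
        scale = codec.jacobian_scale(values)
        for name, s_th, sc in zip(codec.free_names, se_theta, scale):
            ses[name] = float(s_th * sc)
    except Exception:
        ses = {name: float("nan") for name in codec.free_names}

    result = CRCResults(
        model=model,
        sse=sse,
        reduced_chi_square=red_chi2,
        n_selected=None,
        selection_trace=[],
        parameter_standard_errors=ses,
        converged=any_success,
        seed=options.seed,
        n_obs=len(curve),
        n_free=n_free,
        curve=curve,
        options=options,
        fixed=tuple(sorted(codec.fixed)) if "baseline" in codec.fixed
        else tuple(sorted(codec.fixed | {"~baseline"})),
        message=getattr(sol, "message", ""),
    )
    if not any_success:
        result.message = "no start reported formal convergence; best local minimum returned"
    return result


def initial_template(curve: KineticCurve, n: int, removal: bool) -> CompositeModel:
    """Data-driven initial single-chain structure for chain length ``n``.

    Rates are seeded from the observed half-rise time, the removal rate from
    the tail decay, and the delay from the peak position; used as the first
    multistart point when no user template exists.
    """
    t = curve.timepoints
    y = curve.intensity_mean
    y_max = max(float(np.max(y)), 1e-12)
    i_peak = int(np.argmax(y))
    above = np.where(y >= 0.5 * y_max)[0]
    t_half = float(t[above[0]]) if above.size else float(t[-1]) / 2.0
    t_half = max(t_half, float(t[1]) / 2.0, 1e-3)
    m = n - 1 if removal else n
    base = m * math.log(2.0) / t_half
    spread = np.geomspace(0.6, 1.8, m) if m > 1 else np.array([1.0])
    rec = tuple(base * spread)
    if removal:
        t_peak = max(float(t[i_peak]), t_half)
        tail = y[i_peak:]
        k_rem = 0.01
        if tail.size > 3 and tail[-1] < 0.9 * y_max and tail[-1] > 0:
            dt = float(t[-1] - t[i_peak])
            if dt > 0:
                k_rem = min(max(math.log(y_max / max(tail[-1], 1e-3 * y_max)) / dt, 1e-5), 5.0)
        rates = rec + (k_rem,)
        # nudge degenerate guesses apart
        rates = tuple(k * (1 + 1e-3 * i) for i, k in enumerate(rates))
        params = CRCParameters(rates=rates, detachment_delay=max(t_peak - t_half, 1e-3),
                               amplitude=y_max, has_removal=True)
    else:
        rec = tuple(k * (1 + 1e-3 * i) for i, k in enumerate(rec))
        params = CRCParameters(rates=rec, amplitude=y_max, has_removal=False)
    return CompositeModel.single(params)


# ---------------------------------------------------------------------------
# Model class (statsmodels idiom)
# ---------------------------------------------------------------------------


class CRCModel:
    """CRC kinetics estimator for one observed curve.

    Parameters
    ----------
    curve : KineticCurve
        Observed aggregate kinetics (baseline-subtracted, t=0 at
        micro-irradiation).
    template : CompositeModel, optional
        Structure to fit (chain lengths, roles, bleach, baseline) whose
        current values seed the first optimizer start.  Omit it to use
        ``fit_select`` (automatic chain-length selection).
    fixed : sequence of str, optional
        Parameter names (``c0.k1``, ``c0.tau``, ``c0.A``, ``bleach.depth``,
        ``bleach.rate``, ``baseline``) held at their template values.  The
        baseline is fixed by default (curves are baseline-subtracted); free it
        by passing ``fixed=("~baseline",)``.
    options : FitOptions, optional
    """

    def __init__(self, curve: KineticCurve, template: Optional[CompositeModel] = None,
                 fixed: Optional[Sequence[str]] = None, options: Optional[FitOptions] = None):
        self.curve = curve
        self.template = template
        self.fixed = tuple(fixed) if fixed is not None else ()
        self.options = options or FitOptions()

    @classmethod
    def from_dataframe(cls, df, template=None, n_cells: int = 1, metadata=None, **kw) -> "CRCModel":
        """Build from a DataFrame with time_s / intensity_mean / intensity_sd columns."""
        from .curve import MetadataBlock

        curve = KineticCurve(
            timepoints=df["time_s"].to_numpy(float),
            intensity_mean=df["intensity_mean"].to_numpy(float),
            intensity_sd=df["intensity_sd"].to_numpy(float) if "intensity_sd" in df
            else np.zeros(len(df)),
            n_cells=n_cells,
            metadata=metadata or MetadataBlock(),
        )
        return cls(curve, template=template, **kw)

    def fit(self) -> CRCResults:
        """Fit the given template structure (all roles/chain lengths fixed)."""
        if self.template is None:
            raise InputError("fit() needs a structure template; use fit_select() otherwise")
        res = _fit_multistart(self.curve, self.template, self.options, self.fixed)
        res = _sort_components(res, self.curve, self.options)
        floor = _sse_floor(self.curve)
        crit = _aicc(res.sse, res.n_obs, res.n_free, floor) \
            if self.options.selection_criterion == "aicc" else res.sse
        res.selection_trace = [(_total_n(res.model), crit, res.sse)]
        return res

    def fit_select(self, removal: bool = False) -> CRCResults:
        """Fit single chains of increasing length; keep the minimal adequate n.

        ``removal``: whether the protein is expected to detach (adds the
        dissociation reaction and the detachment delay to every candidate).
        """
        opt = self.options
        floor = _sse_floor(self.curve)
        n_min = 2 if removal else 1
        prev: Optional[Tuple[int, float, CRCResults]] = None
        trace: List[Tuple[int, float, float]] = []
        no_plateau = False
        n = n_min
        while n <= max(opt.n_max, n_min):
            template = initial_template(self.curve, n, removal)
            try:
                res = _fit_multistart(self.curve, template, opt, self.fixed)
            except InputError:
                break  # not enough data for this many parameters
            crit = _aicc(res.sse, res.n_obs, res.n_free, floor) \
                if opt.selection_criterion == "aicc" else res.sse
            trace.append((n, crit, res.sse))
            if prev is not None:
                if opt.selection_criterion == "aicc":
                    improved = prev[1] - crit > opt.aicc_threshold
                else:
                    improved = (prev[2].sse - res.sse) > opt.sse_rel_threshold * prev[2].sse
                if not improved:
                    break
            prev = (n, crit, res)
            if n == max(opt.n_max, n_min):
                no_plateau = len(trace) >= 2  # still improving at the cap
            n += 1
        if prev is None:
            raise NonConvergenceError("chain-length selection produced no usable fit")
        n_sel, _crit, best = prev
        best.n_selected = n_sel
        best.selection_trace = trace
        best.no_plateau = no_plateau
        return best


def _total_n(model: CompositeModel) -> int:
    return sum(p.n for p, _ in model.components)


def _sort_components(res: CRCResults, curve: KineticCurve, options: FitOptions) -> CRCResults:
    """Order fitted components by ascending recruitment halftime (label-switching rule)."""
    if len(res.model.components) < 2:
        return res
    from .metrics import recruitment_halftime

    keyed = []
    for idx, (p, role) in enumerate(res.model.components):
        try:
            ht = recruitment_halftime(CompositeModel.single(p))
        except Exception:
            ht = math.inf
        keyed.append((ht, idx, p, role))
    keyed.sort(key=lambda x: (x[0], x[1]))
    # collapse warning: two components converged to near-identical parameters
    collapse = False
    for (_, _, p1, _), (_, _, p2, _) in zip(keyed, keyed[1:]):
        if p1.n == p2.n and p1.has_removal == p2.has_removal:
            v1 = np.array(p1.rates + (p1.detachment_delay,))
            v2 = np.array(p2.rates + (p2.detachment_delay,))
            if np.allclose(v1, v2, rtol=1e-3, atol=1e-9):
                collapse = True
    res.model = CompositeModel(
        components=tuple((p, role) for _, _, p, role in keyed),
        bleach=res.model.bleach, baseline=res.model.baseline,
    )
    # re-key per-component standard errors to the new component order
    perm = {old_idx: new_idx for new_idx, (_, old_idx, _, _) in enumerate(keyed)}
    remapped: Dict[str, float] = {}
    for name, se in res.parameter_standard_errors.items():
        if name.startswith("c") and "." in name:
            head, tail = name.split(".", 1)
            remapped[f"c{perm[int(head[1:])]}.{tail}"] = se
        else:
            remapped[name] = se
    res.parameter_standard_errors = remapped
    res.component_collapse = collapse
    return res


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def fit_fixed_structure(curve: KineticCurve, structure: CompositeModel,
                        options: Optional[FitOptions] = None,
                        fixed: Optional[Sequence[str]] = None) -> CRCResults:
    """Fit a fixed composite structure to a curve (multistart weighted NLLS)."""
    return CRCModel(curve, template=structure, fixed=fixed, options=options).fit()


def select_chain_length(curve: KineticCurve, removal: bool = False,
                        options: Optional[FitOptions] = None) -> CRCResults:
    """Select the minimal chain length n whose successor no longer improves the fit."""
    return CRCModel(curve, options=options).fit_select(removal=removal)


def fit_composite(curve: KineticCurve, template: CompositeModel,
                  options: Optional[FitOptions] = None,
                  fixed: Optional[Sequence[str]] = None) -> CRCResults:
    """Fit a multi-component template; components returned sorted by recruitment halftime."""
    n_free = _ParamCodec(template, fixed=fixed).n_free
    if n_free >= len(curve) / 2:
        raise InputError(
            f"identifiability guard: {n_free} free parameters for {len(curve)} timepoints"
        )
    return CRCModel(curve, template=template, fixed=fixed, options=options).fit()


def bootstrap_uncertainty(curve: KineticCurve, fit: CRCResults, n_boot: int = 200,
                          seed: int = 0, level: float = 0.95) -> Dict[str, Tuple[float, float]]:
    """Residual-resampling bootstrap confidence intervals for all free parameters.

    Residuals of the fit are resampled with replacement onto the fitted curve;
    each replicate is refit from the point estimate (single start).  Returns
    ``{name: (lo, hi)}`` percentile intervals, widened to contain the point
    estimate. Deterministic under a fixed seed.
    """
    if not fit.converged:
        raise InputError("bootstrap requires a converged fit")
    if n_boot < 2:
        raise InputError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    pred = fit.predict()
    res_vec = curve.intensity_mean - pred
    opt = replace(fit.options, n_starts=1, seed=seed)
    codec = _ParamCodec(fit.model, fixed=fit.fixed)
    samples = {name: [] for name in codec.free_names}
    for _b in range(n_boot):
        y_star = pred + rng.choice(res_vec, size=res_vec.size, replace=True)
        boot_curve = KineticCurve(
            timepoints=curve.timepoints, intensity_mean=y_star,
            intensity_sd=curve.intensity_sd, n_cells=curve.n_cells,
            metadata=curve.metadata,
        )
        try:
            r = _fit_multistart(boot_curve, fit.model, opt, fit.fixed)
        except (NonConvergenceError, InputError):
            continue
        bc = _ParamCodec(r.model, fixed=fit.fixed)
        for name, v, f in zip(bc.names, bc.values, bc.free_mask):
            if f:
                samples[name].append(v)
    alpha = (1.0 - level) / 2.0
    intervals: Dict[str, Tuple[float, float]] = {}
    point = dict(zip(codec.names, codec.values))
    for name, vals in samples.items():
        if not vals:
            intervals[name] = (float("nan"), float("nan"))
            continue
        lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
        lo = min(float(lo), point[name])
        hi = max(float(hi), point[name])
        intervals[name] = (lo, hi)
    return intervals


def remove_bleach(curve: KineticCurve, fit: CRCResults) -> KineticCurve:
    """Subtract the fitted bleach deficit from a curve (SD unchanged).

    The corrected curve's metadata records the removed component's depth and
    recovery rate.
    """
    bleach = fit.model.bleach
    if bleach is None:
        raise InputError("the fit has no bleach component to remove")
    corrected = curve.intensity_mean - bleach(curve.timepoints)
    note = (f"bleach component removed: depth={bleach.depth:g}, "
            f"recovery_rate={bleach.recovery_rate:g}/s")
    return curve.with_intensity(corrected, note=note)
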