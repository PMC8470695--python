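"""Consecutive-reactions-chain (CRC) kinetic model: parameterizations and curve evaluation.

The CRC model describes the accumulation of a DNA-repair protein at a laser
micro-irradiation site as an irreversible linear chain of first-order
reactions

    X_0 --k_1--> X_1 --k_2--> ... --k_{n-1}--> X_{n-1}

with ``X_0(0) = 1`` and all downstream species initially empty.  The observed
damage-site signal is the occupancy of the terminal species scaled by an
amplitude ``A`` (intensity units).  A protein that detaches again carries a
final dissociation reaction: after a detachment delay ``tau`` the terminal
species additionally decays at rate ``k_n`` (the rate is zero for ``t < tau``).

Measured curves are often a *sum* of such chains ("removable" plus
"non-removable" fractions, multiphase recruitment) plus an optional residual
photobleaching deficit; :class:`CompositeModel` represents that sum.

Two evaluation engines are provided and cross-checked against each other:

* an analytic sum-of-exponentials (Bateman-type) solution, valid whenever all
  rate constants are pairwise distinct — including ``tau > 0``, handled by
  propagating the species vector to ``tau`` and superposing sub-chain
  solutions afterwards;
* a stiff-capable ODE integrator (``scipy.integrate.solve_ivp``, LSODA,
  rtol 1e-9 / atol 1e-12) that splits the integration at ``t = tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DegenerateRatesError, InputError, NumericalError

__all__ = [
    "CRCParameters",
    "BleachComponent",
    "CompositeModel",
    "evaluate_component",
    "evaluate_model",
    "evaluate_closed_form",
    "species_trajectories",
    "RATE_DEGENERACY_RTOL",
]

#: Relative tolerance below which two rate constants are treated as equal
#: (the analytic solution then becomes numerically unusable).
RATE_DEGENERACY_RTOL = 1e-6

Role = Literal["phase", "removable", "non-removable"]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CRCParameters:
    """One consecutive-reactions chain.

    Parameters
    ----------
    rates : tuple of float
        Rate constants ``k_1 .. k_n`` in 1/s.  When ``has_removal`` is True the
        last entry is the dissociation constant ``k_n`` and the preceding ones
        are recruitment constants; otherwise every entry is a recruitment
        constant.  At least one recruitment constant is required.
    detachment_delay : float
        ``tau`` in seconds; the dissociation reaction is inactive for
        ``t < tau``.  Must be 0 when ``has_removal`` is False.
    amplitude : float
        ``A`` in intensity units; maps the dimensionless terminal-species
        occupancy to the measured bound signal.
    has_removal : bool
        Whether the chain ends in a dissociation reaction.
    """

    rates: Tuple[float, ...]
    detachment_delay: float = 0.0
    amplitude: float = 1.0
    has_removal: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rates", tuple(float(k) for k in self.rates))
        if len(self.recruitment_rates) < 1:
            raise InputError(
                "at least one recruitment rate is required "
                f"(got rates={self.rates!r}, has_removal={self.has_removal})"
            )
        if any(not (k > 0) or not math.isfinite(k) for k in self.rates):
            raise InputError(f"all rate constants must be finite and > 0, got {self.rates!r}")
        if not (self.amplitude > 0) or not math.isfinite(self.amplitude):
            raise InputError(f"amplitude must be finite and > 0, got {self.amplitude!r}")
        if self.has_removal:
            if not (self.detachment_delay >= 0) or not math.isfinite(self.detachment_delay):
                raise InputError(f"detachment delay must be finite and >= 0, got {self.detachment_delay!r}")
        elif self.detachment_delay != 0:
            raise InputError("detachment_delay must be 0 when has_removal is False")

    @property
    def n(self) -> int:
        """Total reaction count (recruitment reactions plus the removal one, if any)."""
        return len(self.rates)

    @property
    def recruitment_rates(self) -> Tuple[float, ...]:
        return self.rates[:-1] if self.has_removal else self.rates

    @property
    def removal_rate(self) -> Optional[float]:
        return self.rates[-1] if self.has_removal else None

    @property
    def n_species(self) -> int:
        """Number of bound-state species X_0 .. X_{m} (m = recruitment reactions)."""
        return len(self.recruitment_rates) + 1


@dataclass(frozen=True)
class BleachComponent:
    """Residual photobleaching deficit ``B(t) = -depth * exp(-recovery_rate * t)``.

    Models the signal lost to bleaching during micro-irradiation that upstream
    compensation did not fully restore: always <= 0, recovering monotonically
    toward 0, with ``B(0) = -depth``.
    """

    depth: float
    recovery_rate: float

    def __post_init__(self):
        if not (self.depth > 0) or not math.isfinite(self.depth):
            raise InputError(f"bleach depth must be finite and > 0, got {self.depth!r}")
        if not (self.recovery_rate > 0) or not math.isfinite(self.recovery_rate):
            raise InputError(f"bleach recovery rate must be finite and > 0, got {self.recovery_rate!r}")

    def __call__(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return -self.depth * np.exp(-self.recovery_rate * t)


@dataclass(frozen=True)
class CompositeModel:
    """Weighted sum of CRC chains plus optional bleach term and constant baseline.

    ``components`` is an ordered list of ``(CRCParameters, role)`` pairs with
    role in {"phase", "removable", "non-removable"}; a "non-removable"
    component must have ``has_removal=False``.  The model curve is

        baseline + sum(component curves) + bleach curve.
    """

    components: Tuple[Tuple[CRCParameters, Role], ...]
    bleach: Optional[BleachComponent] = None
    baseline: float = 0.0

    def __post_init__(self):
        comps = tuple((p, str(r)) for p, r in self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) < 1:
            raise InputError("a composite model needs at least one component")
        for i, (params, role) in enumerate(comps):
            if role not in ("phase", "removable", "non-removable"):
                raise InputError(f"component {i}: unknown role {role!r}")
            if not isinstance(params, CRCParameters):
                raise InputError(f"component {i}: expected CRCParameters, got {type(params).__name__}")
            if role == "non-removable" and params.has_removal:
                raise InputError(f"component {i}: a non-removable component cannot have a removal reaction")
        if not math.isfinite(self.baseline):
            raise InputError("baseline must be finite")

    @classmethod
    def single(cls, params: CRCParameters, role: Role = "phase", baseline: float = 0.0,
               bleach: Optional[BleachComponent] = None) -> "CompositeModel":
        return cls(components=((params, role),), bleach=bleach, baseline=baseline)

    @property
    def has_removal(self) -> bool:
        return any(p.has_removal for p, _ in self.components)

    @property
    def total_amplitude(self) -> float:
        return sum(p.amplitude for p, _ in self.components)

    def asymptote(self) -> float:
        """Model value as t -> infinity.

        Chains with removal drain completely; bleach recovers to 0; chains
        without removal saturate at their amplitude.
        """
        return self.baseline + sum(p.amplitude for p, _ in self.components if not p.has_removal)

    def __call__(self, times, method: str = "auto") -> np.ndarray:
        return evaluate_model(self, times, method=method)


# ---------------------------------------------------------------------------
# Analytic (Bateman-type) machinery
# ---------------------------------------------------------------------------


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise InputError("times must be a 1-D sequence")
    if t.size and t[0] < 0:
        raise InputError("times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise InputError("times must be sorted ascending")
    return t


def rates_degenerate(rates: Sequence[float], rtol: float = RATE_DEGENERACY_RTOL) -> bool:
    """True if any pair of rates is closer than ``rtol`` relative."""
    lam = np.sort(np.asarray(rates, dtype=float))
    if lam.size < 2:
        return False
    gaps = np.diff(lam) / lam[1:]
    return bool(np.any(gaps < rtol))


def _bateman_weights(lam: np.ndarray) -> np.ndarray:
    # w_i = 1 / prod_{j != i} (lam_j - lam_i)
    diff = lam[None, :] - lam[:, None]
    np.fill_diagonal(diff, 1.0)
    return 1.0 / diff.prod(axis=1)


def _batf(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """sum_i exp(-lam_i t) / prod_{j != i}(lam_j - lam_i), vectorized over t."""
    w = _bateman_weights(lam)
    return np.exp(-np.outer(t, lam)) @ w


def _terminal_no_removal(rec: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Terminal-species occupancy of a pure recruitment chain (distinct rates)."""
    lam = rec
    w = _bateman_weights(lam)
    # c_i = prod_{j != i} lam_j * w_i
    c = w * lam.prod() / lam
    out = 1.0 - np.exp(-np.outer(t, lam)) @ c
    out[t == 0.0] = 0.0  # exact boundary value (the sum cancels only to ~1e-15)
    return out


def _terminal_with_decay(rec: np.ndarray, decay: float, t: np.ndarray) -> np.ndarray:
    """Terminal occupancy when the terminal species decays at ``decay`` from t=0.

    Standard Bateman solution for the last member of a chain with rate vector
    (rec_1 .. rec_m, decay); for m = 0 this is a bare exponential.
    """
    if rec.size == 0:
        return np.exp(-decay * t)
    lam = np.concatenate([rec, [decay]])
    out = rec.prod() * _batf(lam, t)
    out[t == 0.0] = 0.0  # exact boundary value
    return out


def _species_no_removal(rec: np.ndarray, t: np.ndarray) -> np.ndarray:
    """All species occupancies X_0..X_m of a pure chain; shape (m+1, len(t))."""
    m = rec.size
    out = np.empty((m + 1, t.size))
    out[0] = np.exp(-rec[0] * t) if m else np.ones_like(t)
    for s in range(1, m):
        lam = rec[: s + 1]
        out[s] = rec[:s].prod() * _batf(lam, t)
    if m:
        out[m] = 1.0 - out[:m].sum(axis=0)
    return out


def _terminal_analytic(params: CRCParameters, t: np.ndarray) -> np.ndarray:
    """Analytic terminal occupancy for pairwise-distinct rates, any tau."""
    rec = np.asarray(params.recruitment_rates, dtype=float)
    if not params.has_removal:
        return _terminal_no_removal(rec, t)
    decay = params.removal_rate
    tau = params.detachment_delay
    if tau == 0.0:
        return _terminal_with_decay(rec, decay, t)
    out = np.empty_like(t)
    before = t <= tau
    out[before] = _terminal_no_removal(rec, t[before])
    after = ~before
    if np.any(after):
        # propagate the species vector to tau, then superpose sub-chains with
        # the dissociation reaction switched on
        y_tau = _species_no_removal(rec, np.array([tau]))[:, 0]
        u = t[after] - tau
        acc = np.zeros(u.size)
        m = rec.size
        for s in range(m + 1):
            if y_tau[s] == 0.0:
                continue
            acc += y_tau[s] * _terminal_with_decay(rec[s:], decay, u)
        out[after] = acc
    return out


# ---------------------------------------------------------------------------
# Numerical (ODE) engine
# ---------------------------------------------------------------------------

_ODE_RTOL = 1e-9
_ODE_ATOL = 1e-12


def _integrate_chain(params: CRCParameters, t: np.ndarray) -> np.ndarray:
    """Integrate the chain ODE; returns species matrix incl. dissociated pool.

    Shape ``(n_species + 1, len(t))``; last row is the dissociated pool (zero
    throughout if the chain has no removal reaction).
    """
    rec = np.asarray(params.recruitment_rates, dtype=float)
    m = rec.size
    dim = m + 2  # X_0..X_m + dissociated pool

    def rhs(t_, y, removal_active):
        dy = np.zeros(dim)
        flow = rec * y[:m]
        dy[:m] -= flow
        dy[1 : m + 1] += flow
        if removal_active and params.has_removal:
            out = params.removal_rate * y[m]
            dy[m] -= out
            dy[m + 1] += out
        return dy

    y0 = np.zeros(dim)
    y0[0] = 1.0
    tau = params.detachment_delay if params.has_removal else 0.0
    t, inverse = np.unique(t, return_inverse=True)
    t_end = t[-1] if t.size else 0.0

    result = np.empty((dim, t.size))

    def run_segment(t0, t1, y_start, t_eval, removal_active):
        if t_eval.size == 0 and t1 <= t0:
            return y_start
        # always integrate through t1 so the returned state is exactly y(t1)
        needs_endpoint = t_eval.size == 0 or t_eval[-1] < t1
        t_eval_full = np.concatenate([t_eval, [t1]]) if needs_endpoint else t_eval
        sol = solve_ivp(
            rhs, (t0, max(t1, t0 + 1e-30)), y_start, method="LSODA",
            t_eval=t_eval_full,
            rtol=_ODE_RTOL, atol=_ODE_ATOL, args=(removal_active,),
        )
        if not sol.success:
            raise NumericalError(f"chain integration failed: {sol.message}")
        if t_eval.size:
            result[:, np.searchsorted(t, t_eval)] = sol.y[:, : t_eval.size]
        return sol.y[:, -1]

    if params.has_removal and tau < t_end:
        pre = t[t <= tau]
        y_at_tau = run_segment(0.0, tau, y0, pre, removal_active=False)
        post = t[t > tau]
        run_segment(tau, t_end, y_at_tau, post, removal_active=True)
    else:
        run_segment(0.0, t_end, y0, t, removal_active=params.has_removal and tau <= 0.0)
    return result[:, inverse]


# ---------------------------------------------------------------------------
# Public evaluation operations
# ---------------------------------------------------------------------------


def evaluate_component(params: CRCParameters, times, method: str = "auto") -> np.ndarray:
    """Model curve ``A * X_{n-1}(t)`` of one chain on a sorted time grid.

    ``method``: "auto" uses the analytic solution when all rates are pairwise
    distinct and falls back to ODE integration otherwise; "analytic" and
    "ode" force the respective engine ("analytic" raises
    :class:`DegenerateRatesError` on near-equal rates).
    """
    t = _check_times(times)
    if t.size == 0:
        return np.zeros(0)
    degenerate = rates_degenerate(params.rates)
    if method == "analytic" and degenerate:
        raise DegenerateRatesError(
            f"rates {params.rates!r} are equal within rtol={RATE_DEGENERACY_RTOL:g}; "
            "use method='ode'"
        )
    if method == "ode" or (method == "auto" and degenerate):
        occ = _integrate_chain(params, t)[params.n_species - 1]
        occ = np.clip(occ, 0.0, None)  # integrator may undershoot 0 by ~atol
    elif method in ("auto", "analytic"):
        occ = np.clip(_terminal_analytic(params, t), 0.0, None)
    else:
        raise InputError(f"unknown method {method!r}")
    return params.amplitude * occ


def evaluate_closed_form(params: CRCParameters, times,
                         rate_rtol: float = RATE_DEGENERACY_RTOL) -> np.ndarray:
    """Analytic sum-of-exponentials solution (restricted validity).

    Valid when (a) the chain has no removal reaction, or (b) ``tau == 0`` with
    all rates pairwise distinct.  Raises :class:`DegenerateRatesError` for
    near-equal rates and :class:`InputError` outside the validity regime.
    """
    t = _check_times(times)
    if params.has_removal and params.detachment_delay != 0.0:
        raise InputError("closed form requires has_removal=False or tau=0; use evaluate_component")
    if rates_degenerate(params.rates, rate_rtol):
        raise DegenerateRatesError(
            f"rates {params.rates!r} degenerate within rtol={rate_rtol:g}; use the numerical engine"
        )
    rec = np.asarray(params.recruitment_rates, dtype=float)
    if params.has_removal:
        occ = _terminal_with_decay(rec, params.removal_rate, t)
    else:
        occ = _terminal_no_removal(rec, t)
    return params.amplitude * np.clip(occ, 0.0, None)


def species_trajectories(params: CRCParameters, times) -> np.ndarray:
    """Occupancies of X_0 .. X_{n-1} plus the dissociated pool (ODE engine).

    Returns an array of shape ``(n_species + 1, len(times))``; each column
    sums to 1 within integrator tolerance (mass conservation).
    """
    t = _check_times(times)
    if t.size == 0:
        return np.zeros((params.n_species + 1, 0))
    return _integrate_chain(params, t)


def evaluate_model(model: CompositeModel, times, method: str = "auto") -> np.ndarray:
    """Composite curve: baseline + sum of component curves + bleach term."""
    t = _check_times(times)
    out = np.full(t.size, float(model.baseline))
    for params, _role in model.components:
        out += evaluate_component(params, t, method=method)
    if model.bleach is not None:
        out += model.bleach(t)
    return out
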