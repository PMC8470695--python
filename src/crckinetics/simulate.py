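"""Synthetic kinetic curves emulating the live-cell acquisition design.

Generates per-cell damage-site intensity traces from a ground-truth
:class:`~crckinetics.core.CompositeModel` and aggregates them into the
mean +/- SD curve form in which such data is published: 8-21 cells per
protein, sampling intervals of 0.5-5 s, curves spanning recruitment halftimes
from seconds to beyond ten minutes.

Generative contract per cell ``c``::

    trace_c(t) = s_c * I_model(t) + eps_{c,t}

with ``log s_c ~ N(0, cell_scale_sd)`` (cell-to-cell amplitude variability:
expression level, damage dose) and ``eps ~ N(0, noise_sd_fraction * peak)``
(detector noise).  Acquisition photobleaching can be injected per frame and
compensated by dividing with a normalized reference decay, mirroring the
upstream correction applied to real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import BleachComponent, CompositeModel, CRCParameters, evaluate_model
from .curve import KineticCurve, MetadataBlock
from .exceptions import InputError

__all__ = [
    "SimulationDesign",
    "CellTrace",
    "BenchmarkFixture",
    "simulate_cell_traces",
    "aggregate_traces",
    "simulate_curve",
    "inject_acquisition_bleach",
    "compensate_bleaching",
    "make_benchmark_suite",
    "CELL_COUNT_RANGE",
    "STANDARD_INTERVALS",
]

#: Cells per protein in the acquisition design the generator emulates.
CELL_COUNT_RANGE = (8, 21)
#: Sampling intervals (s) used in the acquisition design.
STANDARD_INTERVALS = (0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class SimulationDesign:
    """Acquisition design of one simulated experiment.

    ``n_cells=None`` draws the cell count uniformly from 8-21 (seeded).
    ``sampling_interval`` outside 0.5-5 s is rejected unless
    ``enforce_interval_range`` is switched off.  ``noise_sd_fraction`` scales
    additive Gaussian noise as a fraction of the model peak;
    ``cell_scale_sd`` is the log-scale spread of per-cell amplitudes.
    """

    n_cells: Optional[int] = None
    sampling_interval: float = 2.0
    duration: float = 600.0
    noise_sd_fraction: float = 0.05
    cell_scale_sd: float = 0.2
    acquisition_bleach_rate: Optional[float] = None
    seed: int = 0
    enforce_interval_range: bool = True

    def __post_init__(self):
        if self.n_cells is not None and self.n_cells < 1:
            raise InputError("n_cells must be >= 1")
        if not (self.sampling_interval > 0):
            raise InputError("sampling_interval must be > 0")
        if self.enforce_interval_range and not (0.5 <= self.sampling_interval <= 5.0):
            raise InputError(
                f"sampling_interval {self.sampling_interval!r} outside the standard 0.5-5 s "
                "range; pass enforce_interval_range=False to override"
            )
        if not (self.duration > self.sampling_interval):
            raise InputError("duration must exceed the sampling interval")
        if self.noise_sd_fraction < 0 or self.cell_scale_sd < 0:
            raise InputError("noise parameters must be >= 0")
        if self.acquisition_bleach_rate is not None and self.acquisition_bleach_rate < 0:
            raise InputError("acquisition_bleach_rate must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n_frames = int(math.floor(self.duration / self.sampling_interval)) + 1
        return np.arange(n_frames) * self.sampling_interval


@dataclass(frozen=True)
class CellTrace:
    """One cell's intensity trace on the common acquisition grid."""

    timepoints: np.ndarray
    intensities: np.ndarray
    cell_id: int
    scale: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "intensities", y)
        if t.shape != y.shape:
            raise InputError("timepoints and intensities must have the same shape")
        if not np.all(np.isfinite(y)):
            raise InputError("intensities must be finite")


@dataclass(frozen=True)
class BenchmarkFixture:
    """A (curve, ground-truth model) pair from the benchmark suite."""

    name: str
    curve: KineticCurve
    truth: CompositeModel
    design: SimulationDesign
    expected_removal: bool


# ---------------------------------------------------------------------------
# Trace generation and aggregation
# ---------------------------------------------------------------------------


def simulate_cell_traces(model: CompositeModel, design: SimulationDesign) -> List[CellTrace]:
    """Per-cell traces; deterministic under the design's seed."""
    rng = np.random.default_rng(design.seed)
    n_cells = design.n_cells
    if n_cells is None:
        n_cells = int(rng.integers(CELL_COUNT_RANGE[0], CELL_COUNT_RANGE[1] + 1))
    t = design.grid
    base = evaluate_model(model, t)
    peak = float(np.max(np.abs(base)))
    noise_sd = design.noise_sd_fraction * peak
    traces = []
    for c in range(n_cells):
        scale = float(np.exp(rng.normal(0.0, design.cell_scale_sd))) if design.cell_scale_sd > 0 else 1.0
        eps = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else np.zeros(t.size)
        traces.append(CellTrace(timepoints=t, intensities=scale * base + eps,
                                cell_id=c, scale=scale))
    if design.acquisition_bleach_rate:
        traces = inject_acquisition_bleach(traces, design.acquisition_bleach_rate)
    return traces


def aggregate_traces(traces: Sequence[CellTrace],
                     metadata: Optional[MetadataBlock] = None) -> KineticCurve:
    """Mean and sample SD across cells at every timepoint."""
    if len(traces) < 2:
        raise InputError("need at least 2 traces to aggregate")
    t0 = traces[0].timepoints
    for tr in traces[1:]:
        if tr.timepoints.shape != t0.shape or not np.array_equal(tr.timepoints, t0):
            raise InputError("all traces must share the same time grid")
    stack = np.vstack([tr.intensities for tr in traces])
    sd = stack.std(axis=0, ddof=1)
    sd[np.ptp(stack, axis=0) == 0.0] = 0.0  # identical values have exactly zero spread
    return KineticCurve(
        timepoints=t0,
        intensity_mean=stack.mean(axis=0),
        intensity_sd=sd,
        n_cells=len(traces),
        metadata=metadata or MetadataBlock(protein="synthetic"),
    )


def simulate_curve(model: CompositeModel, design: SimulationDesign,
                   metadata: Optional[MetadataBlock] = None) -> KineticCurve:
    """Convenience: simulate traces and aggregate them in one call."""
    return aggregate_traces(simulate_cell_traces(model, design), metadata=metadata)


# ---------------------------------------------------------------------------
# Acquisition photobleaching
# ---------------------------------------------------------------------------


def inject_acquisition_bleach(traces: Sequence[CellTrace], rate: float) -> List[CellTrace]:
    """Multiply frame j of every trace by exp(-rate * j) (rate in 1/frame).

    Creates the *uncompensated* acquisition condition; ``rate=0`` is the
    identity.
    """
    if rate < 0:
        raise InputError("bleach rate must be >= 0")
    out = []
    for tr in traces:
        decay = np.exp(-rate * np.arange(tr.timepoints.size))
        out.append(replace(tr, intensities=tr.intensities * decay))
    return out


def compensate_bleaching(obj, reference: np.ndarray):
    """Divide each frame by a reference decay series normalized to 1 at frame 0.

    ``obj`` may be a :class:`KineticCurve` (mean and SD are both rescaled —
    the correction is a per-frame change of units) or a sequence of
    :class:`CellTrace`.  Exact inverse of multiplicative bleaching when the
    reference matches the true bleach process.
    """
    ref = np.asarray(reference, dtype=float)
    if np.any(ref <= 0):
        raise InputError("reference decay must be strictly positive")
    if abs(ref[0] - 1.0) > 1e-9:
        raise InputError("reference decay must be normalized to 1 at frame 0")
    if isinstance(obj, KineticCurve):
        if ref.size != len(obj):
            raise InputError(f"reference length {ref.size} != curve length {len(obj)}")
        return KineticCurve(
            timepoints=obj.timepoints,
            intensity_mean=obj.intensity_mean / ref,
            intensity_sd=obj.intensity_sd / ref,
            n_cells=obj.n_cells,
            metadata=obj.metadata,
        )
    traces = list(obj)
    if not traces:
        raise InputError("no traces to compensate")
    if ref.size != traces[0].timepoints.size:
        raise InputError(f"reference length {ref.size} != trace length {traces[0].timepoints.size}")
    return [replace(tr, intensities=tr.intensities / ref) for tr in traces]


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------


def _noise_free(seed: int, interval: float, duration: float) -> SimulationDesign:
    return SimulationDesign(n_cells=2, sampling_interval=interval, duration=duration,
                            noise_sd_fraction=0.0, cell_scale_sd=0.0, seed=seed,
                            enforce_interval_range=True)


def make_benchmark_suite(seed: int = 0) -> Dict[str, BenchmarkFixture]:
    """Deterministic noise-free fixtures spanning the regimes seen in real data.

    fast_plateau      one-step recruitment, halftime ~1.4 s (sub-2 s sensors)
    slow_riser        one-step recruitment, halftime ~693 s (>10 min factors)
    delayed_removal   two recruitment steps + delayed dissociation
    two_phase         sum of a fast and a slow recruitment phase
    non_removable     removable (70%) + non-removable (30%) fractions
    bleach_contaminated  recruitment plus an uncompensated bleach deficit

    Each fixture's curve is regenerable from its truth model with the stored
    design; all are noise-free so that re-fitting closes exactly.
    """
    suite: Dict[str, BenchmarkFixture] = {}

    def add(name, truth, design, expected_removal):
        md = MetadataBlock(protein=f"synthetic:{name}", treatment="none",
                           sampling_interval_s=design.sampling_interval,
                           notes=f"benchmark fixture (seed={seed})")
        curve = simulate_curve(truth, design, metadata=md)
        suite[name] = BenchmarkFixture(name=name, curve=curve, truth=truth,
                                       design=design, expected_removal=expected_removal)

    add("fast_plateau",
        CompositeModel.single(CRCParameters(rates=(0.5,), amplitude=1200.0)),
        _noise_free(seed, interval=0.5, duration=40.0), expected_removal=False)

    add("slow_riser",
        CompositeModel.single(CRCParameters(rates=(0.001,), amplitude=800.0)),
        _noise_free(seed, interval=5.0, duration=4000.0), expected_removal=False)

    add("delayed_removal",
        CompositeModel.single(CRCParameters(rates=(0.05, 0.02, 0.005), detachment_delay=100.0,
                                            amplitude=1000.0, has_removal=True)),
        _noise_free(seed, interval=2.0, duration=600.0), expected_removal=True)

    add("two_phase",
        CompositeModel(components=(
            (CRCParameters(rates=(math.log(2.0) / 5.0,), amplitude=400.0), "phase"),
            (CRCParameters(rates=(math.log(2.0) / 120.0,), amplitude=600.0), "phase"),
        )),
        _noise_free(seed, interval=1.0, duration=720.0), expected_removal=False)

    add("non_removable",
        CompositeModel(components=(
            (CRCParameters(rates=(0.1, 0.01), detachment_delay=20.0,
                           amplitude=700.0, has_removal=True), "removable"),
            (CRCParameters(rates=(0.08,), amplitude=300.0), "non-removable"),
        )),
        _noise_free(seed, interval=2.0, duration=600.0), expected_removal=True)

    add("bleach_contaminated",
        CompositeModel.single(
            CRCParameters(rates=(0.05,), amplitude=500.0),
            bleach=BleachComponent(depth=150.0, recovery_rate=0.15),
        ),
        _noise_free(seed, interval=1.0, duration=300.0), expected_removal=False)

    return suite
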