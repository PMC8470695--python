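"""Observed kinetic curves (mean damage-site intensity over time) and their metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["KineticCurve", "MetadataBlock", "TREATMENTS", "LASER_POWER_FRACTIONS"]

#: Controlled vocabulary for the treatment field; free text goes through "other:<text>".
TREATMENTS = ("none", "talazoparib_100nM")
#: Micro-irradiation laser attenuation levels used in the acquisition design.
LASER_POWER_FRACTIONS = (0.70, 0.80)


@dataclass(frozen=True)
class MetadataBlock:
    """Acquisition metadata attached to a curve.

    ``treatment`` must be one of :data:`TREATMENTS` or an ``"other:<text>"``
    tag; ``laser_power_fraction`` one of :data:`LASER_POWER_FRACTIONS` or any
    other positive fraction (recorded as-is, tagged non-standard).
    """

    protein: str = "unknown"
    treatment: str = "none"
    laser_power_fraction: Optional[float] = None
    sampling_interval_s: Optional[float] = None
    bac_id: str = ""
    reporter: str = ""
    notes: str = ""

    def __post_init__(self):
        if self.treatment not in TREATMENTS and not self.treatment.startswith("other:"):
            raise InputError(
                f"treatment {self.treatment!r} not in {TREATMENTS} and not tagged 'other:<text>'"
            )
        if self.laser_power_fraction is not None and not (0 < self.laser_power_fraction <= 1):
            raise InputError(f"laser_power_fraction must be in (0, 1], got {self.laser_power_fraction!r}")

    @property
    def standard_laser_power(self) -> bool:
        return self.laser_power_fraction in LASER_POWER_FRACTIONS


@dataclass(frozen=True)
class KineticCurve:
    """Aggregate time series: per-timepoint mean intensity and across-cell SD.

    Invariants (enforced at construction): equal lengths, strictly increasing
    non-negative timepoints, non-negative SD, and — when the grid starts at
    t = 0 — no *positive* initial signal beyond 3 SD (curves are
    baseline-subtracted relative to the pre-irradiation value, and recruitment
    cannot be instantaneous; a negative start is allowed because residual
    photobleaching produces a genuine initial deficit).
    """

    timepoints: np.ndarray
    intensity_mean: np.ndarray
    intensity_sd: np.ndarray
    n_cells: int = 1
    metadata: MetadataBlock = field(default_factory=MetadataBlock)

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.intensity_mean, dtype=float)
        sd = np.asarray(self.intensity_sd, dtype=float)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "intensity_mean", y)
        object.__setattr__(self, "intensity_sd", sd)
        if not (t.ndim == y.ndim == sd.ndim == 1) or not (t.size == y.size == sd.size):
            raise InputError("timepoints, intensity_mean, intensity_sd must be 1-D and equally long")
        if t.size < 2:
            raise InputError("a curve needs at least 2 timepoints")
        if t[0] < 0:
            raise InputError("timepoints must be >= 0")
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise InputError(f"timepoints must be strictly increasing (violated at row {bad[0] + 1})")
        if not np.all(np.isfinite(y)):
            raise InputError("intensity_mean contains non-finite values")
        neg = np.where(~(sd >= 0))[0]
        if neg.size:
            raise InputError(f"intensity_sd must be >= 0 (violated at row {neg[0]})")
        if self.n_cells < 1:
            raise InputError("n_cells must be >= 1")
        if t[0] == 0.0 and y[0] > 3.0 * sd[0] + 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            raise InputError(
                f"intensity at t=0 is {y[0]:g} > 3*SD ({3 * sd[0]:g}): curve does not look "
                "baseline-subtracted (no instantaneous recruitment is possible)"
            )

    def __len__(self) -> int:
        return self.timepoints.size

    @property
    def peak(self) -> float:
        return float(np.max(self.intensity_mean))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.timepoints,
                "intensity_mean": self.intensity_mean,
                "intensity_sd": self.intensity_sd,
            }
        )

    def with_intensity(self, new_mean: np.ndarray, note: str = "") -> "KineticCurve":
        """Copy with replaced mean series (SD and grid unchanged)."""
        md = self.metadata
        if note:
            joined = (md.notes + "; " if md.notes else "") + note
            md = replace(md, notes=joined)
        return KineticCurve(
            timepoints=self.timepoints.copy(),
            intensity_mean=np.asarray(new_mean, dtype=float),
            intensity_sd=self.intensity_sd.copy(),
            n_cells=self.n_cells,
            metadata=md,
        )
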