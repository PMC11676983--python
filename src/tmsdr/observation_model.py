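"""FRET reporter observation model and trace normalization.

Fluorescence readout of strand displacement: the gate carries a
fluorophore/quencher pair, so the signal grows affinely with the
concentration of the unquenched reporter species.  Measured traces are
converted to substitution-ratio time courses by normalizing between two
calibration levels recorded under identical instrument settings:

* baseline  -- the intact gate alone (fluorophore + quencher, no reaction,
  fully quenched);
* positive control -- the fluorophore-only species at the reference
  concentration, i.e. the signal a 100% substitution ratio would give.

Calibration traces are reduced to time-averaged scalar levels, which makes
the normalization robust to instrument jitter and invariant under any
affine rescaling of the detector.
"""

from __future__ import annotations

import enum
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigError, DataError
from .reaction_model import TMSDRSystem, Trajectory

__all__ = [
    "TraceRole",
    "FluorescenceTrace",
    "CalibrationSet",
    "SubstitutionCourse",
    "AggregatedCourse",
    "predict_fluorescence",
    "normalize_to_substitution",
    "aggregate_replicates",
]

TRACE_COLUMNS = ["time_s", "signal"]


class TraceRole(str, enum.Enum):
    REACTION = "reaction"
    BASELINE = "baseline"
    POSITIVE_CONTROL = "positive_control"


@dataclass(frozen=True)
class FluorescenceTrace:
    """A single fluorescence time series in arbitrary units."""

    times: np.ndarray
    intensity: np.ndarray
    label: TraceRole = TraceRole.REACTION
    replicate_id: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if times.ndim != 1 or intensity.shape != times.shape:
            raise ValueError("times and intensity must be 1-D and equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "label", TraceRole(self.label))

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensity))

    def to_csv(self, path: Union[str, Path, io.IOBase]) -> None:
        pd.DataFrame({"time_s": self.times, "signal": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path, io.IOBase],
        label: TraceRole = TraceRole.REACTION,
        replicate_id: int = 1,
    ) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"trace CSV {path} missing columns {missing}")
        return cls(
            df["time_s"].to_numpy(), df["signal"].to_numpy(), label, replicate_id
        )


@dataclass(frozen=True)
class CalibrationSet:
    """Baseline and positive-control traces bracketing the signal range.

    reference_concentration is the concentration (nM) of the fluorophore-only
    control species, i.e. the concentration a substitution ratio of 1 maps to.
    """

    baseline: Sequence[FluorescenceTrace]
    positive_control: Sequence[FluorescenceTrace]
    reference_concentration: float = 10.0

    def __post_init__(self) -> None:
        if not self.baseline or not self.positive_control:
            raise DataError("calibration requires >= 1 baseline and control trace")
        if self.reference_concentration <= 0:
            raise ValueError("reference_concentration must be positive")
        if self.f_positive <= self.f_baseline:
            raise CalibrationError(
                f"positive-control level {self.f_positive:.3g} must exceed "
                f"baseline level {self.f_baseline:.3g}"
            )

    @property
    def f_baseline(self) -> float:
        """Time-averaged baseline level, pooled over replicates."""
        return float(np.mean([t.mean_intensity for t in self.baseline]))

    @property
    def f_positive(self) -> float:
        """Time-averaged positive-control level, pooled over replicates."""
        return float(np.mean([t.mean_intensity for t in self.positive_control]))


@dataclass(frozen=True)
class SubstitutionCourse:
    """A normalized substitution-ratio time course (unitless, ~[0, 1]).

    Values are deliberately NOT clipped to [0, 1]: measurement noise puts
    points slightly outside, and clipping would bias downstream fitting.
    """

    times: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        if times.shape != ratio.shape or times.ndim != 1:
            raise ValueError("times and ratio must be 1-D and equal length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ratio", ratio)


@dataclass(frozen=True)
class AggregatedCourse:
    """Pointwise mean and sample SD over replicate substitution courses."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    single_replicate: bool = False


def predict_fluorescence(
    trajectory: Trajectory,
    system: TMSDRSystem,
    f0: float,
    f100: float,
) -> FluorescenceTrace:
    """Noise-free fluorescence predicted from a simulated trajectory.

    intensity(t) = f0 + (f100 - f0) * [reporter](t) / x1_0, the affine map
    taking reporter concentration 0 to the quenched baseline f0 and full
    conversion (reporter = x1_0) to the positive-control level f100.
    """
    if not f100 > f0:
        raise ValueError(f"f100={f100} must exceed f0={f0}")
    x1_0 = trajectory.x1[0]
    if x1_0 <= 0:
        raise ConfigError("trajectory must start with positive invader (x1) concentration")
    reporter = trajectory.species(system.reporter_species)
    intensity = f0 + (f100 - f0) * reporter / x1_0
    return FluorescenceTrace(trajectory.times, intensity, TraceRole.REACTION)


def normalize_to_substitution(
    reaction: FluorescenceTrace, calib: CalibrationSet
) -> SubstitutionCourse:
    """Convert a raw trace into a substitution-ratio time course.

    r(t) = (F(t) - F_baseline) / (F_positive - F_baseline), with the
    calibration levels taken as time-averaged scalars.  A trace identical to
    the baseline maps to ~0 everywhere, one identical to the positive
    control to ~1.
    """
    span = calib.f_positive - calib.f_baseline
    ratio = (reaction.intensity - calib.f_baseline) / span
    return SubstitutionCourse(reaction.times, ratio)


def aggregate_replicates(courses: Sequence[SubstitutionCourse]) -> AggregatedCourse:
    """Pointwise mean and sample standard deviation (n-1 denominator).

    All courses must share an identical time grid.  A single replicate
    yields SD 0 with ``single_replicate=True`` and a warning.
    """
    if not courses:
        raise DataError("need at least one course to aggregate")
    times = courses[0].times
    for c in courses[1:]:
        if c.times.shape != times.shape or not np.allclose(c.times, times):
            raise DataError("replicate time grids do not match")
    values = np.vstack([c.ratio for c in courses])
    mean = values.mean(axis=0)
    if len(courses) == 1:
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
        return AggregatedCourse(times, mean, np.zeros_like(mean), 1, True)
    sd = values.std(axis=0, ddof=1)
    return AggregatedCourse(times, mean, sd, len(courses), False)
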