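"""Velocity statistics, boxplot summaries and fluorescence motor counting.

Filament velocities come from three measurement modes: automated tracking
(per-frame positions), kymograph evaluation (a single slope per filament)
and manual endpoint marking.  Per-filament mean velocities are combined
into population summaries weighted by each filament's observation
duration, so long-observed filaments count proportionally more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "FilamentTrack",
    "VelocitySummary",
    "BoxplotStats",
    "IntensityCalibration",
    "MoleculeCount",
    "instantaneous_velocities",
    "per_filament_velocity",
    "time_weighted_population",
    "boxplot_stats",
    "count_molecules",
    "motor_number_from_surface",
]

_MODES = ("tracked", "kymograph", "manual_endpoint")


@dataclass
class FilamentTrack:
    """Per-frame positions of one transported filament.

    ``positions`` is the coordinate along the transport direction (leading
    or trailing end, centroid, or end-to-pivot distance for swiveling
    filaments marked by hand).  For kymograph mode the velocity is read as
    a slope from the kymograph and supplied via ``kymograph_velocity``;
    the positions are then the slope line evaluated at the frame times.
    """

    frame_times: np.ndarray
    positions: np.ndarray
    filament_length: float
    mode: str = "tracked"
    filament_id: str = ""
    kymograph_velocity: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frame_times.size < 2:
            raise ValueError("track needs at least 2 frames")
        if self.positions.size != self.frame_times.size:
            raise ValueError("positions must match frame_times length")
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not self.filament_length > 0:
            raise ValueError("filament_length must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    @property
    def duration(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])


@dataclass(frozen=True)
class VelocitySummary:
    """Population velocity statistics (time weighted and raw)."""

    population_mean: float
    population_sd: float
    population_median: float
    unweighted_mean: float
    unweighted_sd: float
    n_filaments: int
    total_duration: float

    def to_dict(self) -> dict:
        return {
            "population_mean_nm_s": self.population_mean,
            "population_sd_nm_s": self.population_sd,
            "population_median_nm_s": self.population_median,
            "unweighted_mean_nm_s": self.unweighted_mean,
            "unweighted_sd_nm_s": self.unweighted_sd,
            "n_filaments": self.n_filaments,
            "total_duration_s": self.total_duration,
        }


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
        }


@dataclass(frozen=True)
class IntensityCalibration:
    """Mean background-subtracted intensity of a single fluorophore."""

    single_fluor_intensity: float
    background: float = 0.0  # a.u. per unit area

    def __post_init__(self) -> None:
        if not self.single_fluor_intensity > 0:
            raise ValueError("single_fluor_intensity must be positive")


@dataclass(frozen=True)
class MoleculeCount:
    count: float
    linear_density_per_100nm: Optional[float] = None


def instantaneous_velocities(track: FilamentTrack) -> np.ndarray:
    """Frame-to-frame velocity: displacement divided by time difference."""
    dt = np.diff(track.frame_times)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in track")
    return np.diff(track.positions) / dt


def per_filament_velocity(track: FilamentTrack) -> tuple[float, float]:
    """Mean velocity of one filament and its observation duration.

    Tracked and manual-endpoint tracks: unweighted mean of the
    instantaneous velocities.  Kymograph tracks carry an inherently
    averaged slope which is passed through unchanged.
    """
    if track.mode == "kymograph" and track.kymograph_velocity is not None:
        return float(track.kymograph_velocity), track.duration
    v = instantaneous_velocities(track)
    return float(v.mean()), track.duration


def time_weighted_population(
    velocities: Sequence[float], durations: Sequence[float]
) -> VelocitySummary:
    """Population summary with per-filament means weighted by duration.

    The weighted mean is Σwᵢvᵢ/Σwᵢ.  The weighted SD uses frequency-weight
    normalization Σwᵢ(vᵢ−m)² / (W − W̄) with W the total and W̄ the mean
    weight, which reduces to the n−1 sample formula for equal weights.
    The weighted median is the smallest value at which the cumulative
    weight reaches half the total.
    """
    v = np.asarray(list(velocities), dtype=float)
    w = np.asarray(list(durations), dtype=float)
    if v.size == 0 or v.size != w.size:
        raise ValueError("need matching, non-empty velocity and duration lists")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("durations must be non-negative with positive total")
    total = w.sum()
    mean = float((w * v).sum() / total)
    if v.size == 1:
        sd = 0.0
    else:
        denom = total - total / v.size
        sd = float(np.sqrt((w * (v - mean) ** 2).sum() / denom)) if denom > 0 else 0.0

    order = np.argsort(v, kind="stable")
    vs, cum = v[order], np.cumsum(w[order])
    idx = int(np.searchsorted(cum, 0.5 * total))
    median = vs[min(idx, vs.size - 1)]

    return VelocitySummary(
        population_mean=mean,
        population_sd=sd,
        population_median=float(median),
        unweighted_mean=float(v.mean()),
        unweighted_sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        n_filaments=v.size,
        total_duration=float(total),
    )


def boxplot_stats(values: Iterable[float]) -> BoxplotStats:
    """Median, quartiles, whiskers and outliers with 1.5·IQR fences.

    Quartiles use linear interpolation between order statistics.  Outliers
    are points above q3 + 1.5(q3−q1) or below q1 − 1.5(q3−q1); whiskers
    extend to the most extreme non-outlier points.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    outliers = np.sort(x[(x < lo) | (x > hi)])
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(o) for o in outliers),
    )


def count_molecules(
    integrated_intensity: float,
    cal: IntensityCalibration,
    area: float = 0.0,
    length_nm: Optional[float] = None,
) -> MoleculeCount:
    """Molecule count: background-subtracted intensity over the
    single-fluorophore calibration intensity.

    A negative background-subtracted intensity clips to zero with a
    warning.  When ``length_nm`` is given, the linear density (molecules
    per 100 nm) is reported as well.
    """
    net = integrated_intensity - cal.background * area
    if net < 0:
        warnings.warn("background-subtracted intensity is negative; count set to 0")
        net = 0.0
    count = net / cal.single_fluor_intensity
    density = None
    if length_nm is not None:
        if not length_nm > 0:
            raise ValueError("length_nm must be positive")
        density = count / (length_nm / 100.0)
    return MoleculeCount(count=float(count), linear_density_per_100nm=density)


def motor_number_from_surface(
    mt_length: float, surface_density: float, reach: float = 50.0
) -> int:
    """Motors able to engage a surface-bound filament.

    ``mt_length`` (nm) times the reach-band width (nm; the lateral strip
    of surface from which a motor can contact the filament) times the
    surface density (motors/µm²), rounded to the nearest integer.
    """
    if mt_length < 0 or surface_density < 0 or reach <= 0:
        raise ValueError("inputs must be positive (length may be zero)")
    count = (mt_length / 1000.0) * (reach / 1000.0) * surface_density
    return int(round(count))
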