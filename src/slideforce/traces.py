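"""Force-trace analysis for optical-tweezers motility experiments.

A microsphere held in a harmonic optical trap is attached to a filament
transported by a team of motors.  The trap force recorded against time
shows three phases: a free-bead baseline (thermal fluctuations around a
constant detector offset), a rise after the bead binds to the moving
filament, and a plateau once the trap load has stalled transport.  The
stopping force is the vector magnitude of the plateau force after
subtracting the per-axis baseline offsets.

This module provides the trace container plus the estimators: baseline
offset, binding detection, automated plateau selection, and the
stopping-force computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .constants import DEFAULT_TEMPERATURE, KB

__all__ = [
    "ForceTrace",
    "TraceAnnotation",
    "StoppingForceResult",
    "estimate_offset",
    "detect_binding",
    "detect_binding_events",
    "detect_plateau",
    "stopping_force_from_plateau",
    "annotate_trace",
    "analyze_trace",
    "estimate_stiffness_equipartition",
]


@dataclass
class ForceTrace:
    """Synchronized x/y trap-force time series.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing, nominally uniform.
    force_x, force_y
        Trap force per axis in pN (signed, including any detector offset).
    trap_stiffness
        Trap spring constant in pN/nm (same for both axes).
    stage_x, stage_y
        Optional stage position channels in nm.
    metadata
        Free-form provenance (simulation config, ground truth, file origin).
    """

    time: np.ndarray
    force_x: np.ndarray
    force_y: np.ndarray
    trap_stiffness: float
    stage_x: Optional[np.ndarray] = None
    stage_y: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force_x = np.asarray(self.force_x, dtype=float)
        self.force_y = np.asarray(self.force_y, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.force_x.size != n or self.force_y.size != n:
            raise ValueError("force channels must match time length")
        for name in ("stage_x", "stage_y"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.size != n:
                    raise ValueError(f"{name} must match time length")
                setattr(self, name, ch)
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.isfinite(self.trap_stiffness) or self.trap_stiffness <= 0:
            raise ValueError("trap_stiffness must be positive and finite")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        """Median sample interval (s)."""
        return float(np.median(np.diff(self.time)))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def force_magnitude(self, offsets: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        """Absolute force |F - offset| in pN."""
        return np.hypot(self.force_x - offsets[0], self.force_y - offsets[1])

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        return (self.time >= t0) & (self.time <= t1)


@dataclass(frozen=True)
class TraceAnnotation:
    """Analysis windows for one trace.

    The baseline window must lie entirely before the binding time and the
    plateau window entirely after it.
    """

    baseline_window: tuple[float, float]
    binding_time: float
    plateau_window: tuple[float, float]

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        p0, p1 = self.plateau_window
        if not (b0 < b1 and p0 < p1):
            raise ValueError("windows must be non-empty")
        if b1 > self.binding_time:
            raise ValueError("baseline window must precede binding time")
        if p0 < self.binding_time:
            raise ValueError("plateau window must start after binding time")


@dataclass(frozen=True)
class StoppingForceResult:
    """Stopping force of one trace, with the per-axis ingredients."""

    offset_x: float
    offset_y: float
    plateau_mean_x: float
    plateau_mean_y: float
    stopping_force: float
    n_baseline: int
    n_plateau: int
    plateau_sd: float

    def to_dict(self) -> dict:
        return {
            "offset_x_pN": self.offset_x,
            "offset_y_pN": self.offset_y,
            "plateau_mean_x_pN": self.plateau_mean_x,
            "plateau_mean_y_pN": self.plateau_mean_y,
            "stopping_force_pN": self.stopping_force,
            "n_baseline": self.n_baseline,
            "n_plateau": self.n_plateau,
            "plateau_sd_pN": self.plateau_sd,
        }


def estimate_offset(
    trace: ForceTrace, baseline_window: tuple[float, float], min_samples: int = 10
) -> tuple[float, float]:
    """Per-axis force offset: arithmetic mean over a pre-attachment window."""
    t0, t1 = baseline_window
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError("baseline window outside trace time range")
    mask = trace.window_mask(baseline_window)
    if int(mask.sum()) < min_samples:
        raise ValueError(f"baseline window has fewer than {min_samples} samples")
    return float(trace.force_x[mask].mean()), float(trace.force_y[mask].mean())


def _smoothed_magnitude(
    trace: ForceTrace,
    offsets: Optional[tuple[float, float]],
    baseline_s: float,
    smooth_s: float,
) -> tuple[np.ndarray, tuple[float, float]]:
    if offsets is None:
        t_end = min(trace.time[0] + baseline_s, trace.time[-1])
        offsets = estimate_offset(trace, (trace.time[0], t_end))
    mag = trace.force_magnitude(offsets)
    size = max(1, int(round(smooth_s * trace.sample_rate)))
    return uniform_filter1d(mag, size=size, mode="nearest"), offsets


def detect_binding_events(
    trace: ForceTrace,
    rise_threshold: float = 2.0,
    confirm_force: float = 2.0,
    smooth_s: float = 0.1,
    baseline_s: float = 5.0,
    confirm_window_s: float = 1.0,
    release_fraction: float = 0.5,
    offsets: Optional[tuple[float, float]] = None,
) -> list[float]:
    """All bead-binding times in a trace.

    A binding event is a fast rise of the smoothed absolute force: the
    derivative of the moving-average force magnitude must exceed
    ``rise_threshold`` (pN/s) and the magnitude must subsequently exceed
    ``confirm_force`` (pN above baseline) within ``confirm_window_s``.
    After a confirmed event the search resumes once the magnitude drops
    back below ``release_fraction * confirm_force`` (detachment).
    """
    smooth, _ = _smoothed_magnitude(trace, offsets, baseline_s, smooth_s)
    dt = trace.dt
    n = smooth.size
    h = max(1, int(round(smooth_s * trace.sample_rate / 2)))
    deriv = np.zeros(n)
    deriv[h:-h] = (smooth[2 * h :] - smooth[: -2 * h]) / (2 * h * dt)

    above = deriv > rise_threshold
    edges = np.flatnonzero(above & ~np.roll(above, 1))
    edges = edges[edges > 0]
    confirm_n = max(1, int(round(confirm_window_s / dt)))

    events: list[float] = []
    i_min = 0
    for i in edges:
        if i < i_min:
            continue
        seg = smooth[i : i + confirm_n]
        if seg.size and seg.max() > confirm_force:
            events.append(float(trace.time[i]))
            # skip to detachment before searching for the next event
            after = smooth[i:]
            rel = np.flatnonzero(after < release_fraction * confirm_force)
            # ignore the samples before the force actually built up
            built = np.flatnonzero(after > confirm_force)
            if built.size:
                rel = rel[rel > built[0]]
            i_min = i + (int(rel[0]) if rel.size else n)
    return events


def detect_binding(trace: ForceTrace, **kwargs) -> Optional[float]:
    """Earliest binding time, or None if the trace shows no event."""
    events = detect_binding_events(trace, **kwargs)
    return events[0] if events else None


def detect_plateau(
    trace: ForceTrace,
    binding_time: float,
    slope_tol: float = 0.1,
    min_duration: float = 2.0,
    smooth_s: float = 0.1,
    baseline_s: float = 5.0,
    offsets: Optional[tuple[float, float]] = None,
    scan_step_s: float = 0.25,
) -> Optional[tuple[float, float]]:
    """Longest post-binding window whose force magnitude is flat.

    The window ends at the detachment point (smoothed magnitude falling
    below 20% of its running maximum after having exceeded 1 pN) or at the
    end of the trace.  Candidate starts are scanned forward from the
    binding time; the first start whose robust (Theil–Sen) slope of the
    smoothed force magnitude is within ``±slope_tol`` pN/s yields the
    longest admissible window.  Returns None when no window of at least
    ``min_duration`` seconds qualifies, e.g. when the attachment broke
    while the force was still ramping.
    """
    baseline_s = min(baseline_s, max(binding_time - trace.time[0] - trace.dt, trace.dt))
    smooth, _ = _smoothed_magnitude(trace, offsets, baseline_s, smooth_s)
    t = trace.time
    fs = trace.sample_rate
    i0 = int(np.searchsorted(t, binding_time))
    if i0 >= t.size - 2:
        raise ValueError("binding_time not within trace")

    seg = smooth[i0:]
    runmax = np.maximum.accumulate(seg)
    dropped = (seg < 0.2 * runmax) & (runmax > 1.0)
    i_end = i0 + int(np.argmax(dropped)) if dropped.any() else t.size

    if t[i_end - 1] - binding_time < min_duration:
        return None

    step = max(1, int(round(scan_step_s * fs)))
    min_n = max(2, int(round(min_duration * fs)))
    for s in range(i0, i_end - min_n + 1, step):
        # local flatness at the window start keeps the rising edge out of
        # the plateau; the global slope guards the window as a whole
        loc = np.linspace(s, s + min_n - 1, min(300, min_n)).astype(int)
        if abs(stats.theilslopes(smooth[loc], t[loc]).slope) > slope_tol:
            continue
        idx = np.linspace(s, i_end - 1, min(300, i_end - s)).astype(int)
        slope = stats.theilslopes(smooth[idx], t[idx]).slope
        if abs(slope) <= slope_tol:
            return float(t[s]), float(t[i_end - 1])
    return None


def stopping_force_from_plateau(
    trace: ForceTrace, annotation: TraceAnnotation, min_plateau_s: float = 0.5
) -> StoppingForceResult:
    """Stopping force from plateau averaging.

    Per-axis plateau means minus per-axis baseline offsets, combined by
    Pythagoras into an absolute force in arbitrary direction.  Averaging
    the signed per-axis values before taking the magnitude means thermal
    excursions do not rectify into a positive bias as long as the plateau
    force is well clear of zero.
    """
    p0, p1 = annotation.plateau_window
    if p1 - p0 < min_plateau_s:
        raise ValueError(f"plateau window shorter than {min_plateau_s} s")
    off_x, off_y = estimate_offset(trace, annotation.baseline_window)
    mask = trace.window_mask(annotation.plateau_window)
    n_plateau = int(mask.sum())
    if n_plateau < 2:
        raise ValueError("plateau window contains too few samples")
    mean_x = float(trace.force_x[mask].mean())
    mean_y = float(trace.force_y[mask].mean())
    stopping = float(np.hypot(mean_x - off_x, mean_y - off_y))
    sd = float(np.hypot(trace.force_x[mask] - off_x, trace.force_y[mask] - off_y).std())
    n_baseline = int(trace.window_mask(annotation.baseline_window).sum())
    return StoppingForceResult(
        offset_x=off_x,
        offset_y=off_y,
        plateau_mean_x=mean_x,
        plateau_mean_y=mean_y,
        stopping_force=stopping,
        n_baseline=n_baseline,
        n_plateau=n_plateau,
        plateau_sd=sd,
    )


def annotate_trace(
    trace: ForceTrace,
    baseline_s: float = 5.0,
    binding_kwargs: Optional[dict] = None,
    plateau_kwargs: Optional[dict] = None,
) -> TraceAnnotation:
    """Automatic annotation: baseline window, binding time, plateau window.

    Raises ValueError when no binding event or no plateau is found.
    """
    binding = detect_binding(trace, baseline_s=baseline_s, **(binding_kwargs or {}))
    if binding is None:
        raise ValueError("no binding event detected")
    b_end = min(trace.time[0] + baseline_s, binding - trace.dt)
    plateau = detect_plateau(trace, binding, baseline_s=baseline_s, **(plateau_kwargs or {}))
    if plateau is None:
        raise ValueError("no force plateau detected (attachment may have broken early)")
    return TraceAnnotation(
        baseline_window=(float(trace.time[0]), float(b_end)),
        binding_time=float(binding),
        plateau_window=plateau,
    )


def analyze_trace(trace: ForceTrace, **kwargs) -> StoppingForceResult:
    """End-to-end stopping-force pipeline for one trace."""
    annotation = annotate_trace(trace, **kwargs)
    return stopping_force_from_plateau(trace, annotation)


def estimate_stiffness_equipartition(
    trace: ForceTrace,
    baseline_window: tuple[float, float],
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Diagnostic trap-stiffness check from the equipartition theorem.

    For a free bead, var(F) = k·kB·T per axis, so k = var(F)/(kB·T).
    Uses the mean of the two axis variances over the baseline window.
    This is a consistency check on recorded traces, not a calibration.
    """
    mask = trace.window_mask(baseline_window)
    if int(mask.sum()) < 100:
        warnings.warn("equipartition estimate from <100 samples is unreliable")
    var = 0.5 * (trace.force_x[mask].var() + trace.force_y[mask].var())
    return float(var / (KB * temperature))
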