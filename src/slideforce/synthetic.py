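"""Synthetic optical-trap and motility assays with known ground truth.

Every downstream estimator in this package can be validated by parameter
recovery against the generators in this module:

* :func:`simulate_trap_trace` — a bead in a harmonic trap, free thermal
  motion (exact Ornstein–Uhlenbeck updates) followed by rigid coupling to
  a filament transported with a linear force–velocity relation
  v(F) = v0 − F/γ, so the trap force rises to the plateau γ·v0.
* :func:`simulate_fv_scan` — force-feedback scan segments with Gaussian
  velocity noise around the linear relation.
* :func:`simulate_track` — filament positions with localization noise.
* :func:`simulate_intensities` — integrated fluorescence of n fluorophores.
* :func:`simulate_overlap_series` — overlap shortening against the
  entropic force of confined crosslinkers, stalling at N·kB·T/F.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .constants import DEFAULT_TEMPERATURE, KB
from .friction import FVScan, FVSegment
from .motility import FilamentTrack
from .traces import ForceTrace

__all__ = [
    "SimConfig",
    "OverlapSeries",
    "GEOMETRY_PRESETS",
    "preset_config",
    "simulate_trap_trace",
    "simulate_fv_scan",
    "simulate_track",
    "simulate_intensities",
    "simulate_overlap_series",
]

_GEOMETRIES = ("gliding", "sliding", "non_aligned", "mt_anchored")

#: Unloaded velocity (nm/s) and team friction coefficient (pN·s/nm) for the
#: four anchorage geometries.  γ is chosen so that the plateau force γ·v0
#: matches the regime each geometry produces: tens of pN for statically
#: surface-anchored motors (gliding), sub-pN for diffusively anchored
#: motors between aligned microtubules (sliding), and several pN for the
#: two geometrically restricted cases.
GEOMETRY_PRESETS: dict[str, dict] = {
    "gliding": {"unloaded_velocity": 270.0, "team_friction": 10.0 / 270.0},
    "sliding": {"unloaded_velocity": 57.0, "team_friction": 0.7 / 57.0},
    "non_aligned": {"unloaded_velocity": 180.0, "team_friction": 5.9 / 180.0},
    "mt_anchored": {"unloaded_velocity": 205.0, "team_friction": 6.0 / 205.0},
}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic trap assay.

    Parameters
    ----------
    geometry
        Anchorage geometry label; purely descriptive metadata for the
        trace (the dynamics are set by the numeric parameters).
    trap_stiffness
        Trap spring constant per axis, pN/nm (typical 0.05–0.1).
    bead_drag
        Bead drag coefficient, pN·s/nm (Stokes drag of a 1 µm silica
        sphere in water is ~9.4e-6).
    temperature
        Bath temperature, K.
    sample_rate, duration
        Recording rate (Hz) and length (s).
    unloaded_velocity
        Filament transport speed at zero load, nm/s (v0).
    team_friction
        Magnitude γ of the linear force–velocity slope, pN·s/nm; the
        transmitted force at stall is γ·v0.
    binding_time
        Time at which the bead binds the filament (s); None for a trace
        that stays a free bead throughout.
    detachment_force
        Motor-load magnitude at which the bead–filament link breaks (pN),
        or None for an unbreakable link.
    rebind_delay
        If set together with detachment_force, the bead rebinds this many
        seconds after each detachment.
    offset_force
        Constant detector force offset per axis, pN.
    transport_angle
        Direction of filament transport in the x–y plane, radians.
    seed
        Mandatory RNG seed; identical configs give bit-identical traces.
    """

    seed: int
    geometry: str = "gliding"
    trap_stiffness: float = 0.05
    bead_drag: float = 9.4e-6
    temperature: float = DEFAULT_TEMPERATURE
    sample_rate: float = 1000.0
    duration: float = 60.0
    unloaded_velocity: float = 270.0
    team_friction: float = 10.0 / 270.0
    binding_time: Optional[float] = 10.0
    detachment_force: Optional[float] = None
    rebind_delay: Optional[float] = None
    offset_force: tuple[float, float] = (0.0, 0.0)
    transport_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        for name in ("trap_stiffness", "bead_drag", "sample_rate", "duration"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        if not (np.isfinite(self.temperature) and self.temperature >= 0):
            raise ValueError("temperature must be non-negative and finite")
        if self.team_friction < 0:
            raise ValueError("team_friction must be non-negative")
        if not np.isfinite(self.unloaded_velocity):
            raise ValueError("unloaded_velocity must be finite")
        if self.binding_time is not None and not (
            0 <= self.binding_time < self.duration
        ):
            raise ValueError("require duration > binding_time >= 0")
        if self.detachment_force is not None and self.detachment_force <= 0:
            raise ValueError("detachment_force must be positive when set")

    @property
    def plateau_force(self) -> float:
        """Asymptotic motor load γ·v0 (pN), excluding the detector offset."""
        return self.team_friction * self.unloaded_velocity

    def to_dict(self) -> dict:
        d = asdict(self)
        d["offset_force"] = list(self.offset_force)
        return d


@dataclass
class OverlapSeries:
    """Overlap length against time for one crosslinked microtubule pair."""

    times: np.ndarray
    overlap_lengths: np.ndarray
    n_crosslinkers: int
    temperature: float
    motor_force: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.overlap_lengths = np.asarray(self.overlap_lengths, dtype=float)
        if self.n_crosslinkers < 0:
            raise ValueError("n_crosslinkers must be non-negative")
        if np.any(self.overlap_lengths <= 0):
            raise ValueError("overlap lengths must stay positive")
        if np.any(np.diff(self.overlap_lengths) > 0):
            raise ValueError("overlap lengths must be non-increasing")


def preset_config(geometry: str, seed: int, **overrides) -> SimConfig:
    """SimConfig for one of the four anchorage-geometry presets."""
    if geometry not in GEOMETRY_PRESETS:
        raise ValueError(f"unknown geometry {geometry!r}")
    params: dict = {"geometry": geometry, "seed": seed, **GEOMETRY_PRESETS[geometry]}
    params.update(overrides)
    return SimConfig(**params)


def _ou_segment(
    rng: np.random.Generator,
    n: int,
    x0: float,
    mean: float,
    relax_rate: float,
    stationary_sd: float,
    dt: float,
) -> np.ndarray:
    """Exact discrete-time Ornstein–Uhlenbeck sample path of length n.

    x_{i+1} = mean + a (x_i - mean) + s √(1-a²) ξ with a = exp(-λ dt);
    exact for any dt, so equipartition holds at every sample rate.
    """
    if n <= 0:
        return np.empty(0)
    a = math.exp(-relax_rate * dt)
    w = stationary_sd * math.sqrt(1.0 - a * a) * rng.standard_normal(n)
    centered = lfilter([1.0], [1.0, -a], w, zi=np.array([a * (x0 - mean)]))[0]
    return mean + centered


def simulate_trap_trace(config: SimConfig) -> ForceTrace:
    """Simulate a bead-in-trap force trace with optional motor transport.

    Before ``binding_time`` the bead position is an exact OU process per
    axis (relaxation rate k/γ_bead, stationary positional variance
    kB·T/k).  At binding the bead couples rigidly to the filament, which
    advances along ``transport_angle`` at v(F) = v0 − F/γ where F is the
    trap force component along the transport axis; the bead displacement
    perpendicular to transport stays frozen at its binding value.  The
    force along the axis therefore relaxes exponentially (time constant
    γ/k) to the plateau γ·v0.  If ``detachment_force`` is set the link
    breaks when the motor load exceeds it and the free-bead process
    resumes from the current position (rebinding after ``rebind_delay``
    when configured).

    The recorded force is trap_stiffness × bead displacement plus the
    constant per-axis ``offset_force``.  Ground truth (binding times,
    plateau force) is stored in the trace metadata.
    """
    k = config.trap_stiffness
    dt = 1.0 / config.sample_rate
    n = int(round(config.duration * config.sample_rate))
    if n < 2:
        raise ValueError("duration × sample_rate must give at least 2 samples")
    rng = np.random.default_rng(config.seed)
    relax = k / config.bead_drag
    sd = math.sqrt(KB * config.temperature / k) if config.temperature > 0 else 0.0

    cos_a, sin_a = math.cos(config.transport_angle), math.sin(config.transport_angle)
    pos = np.empty((n, 2))  # bead displacement from trap center, nm

    # initial free-bead state drawn from the stationary distribution
    state = rng.standard_normal(2) * sd
    i = 0
    binding_times: list[float] = []
    next_bind = (
        int(round(config.binding_time * config.sample_rate))
        if config.binding_time is not None
        else n
    )
    gamma = config.team_friction
    v0 = config.unloaded_velocity

    while i < n:
        # ---- free phase up to the next binding index ----
        j = min(max(next_bind, i), n)
        if j > i:
            for ax in range(2):
                seg = _ou_segment(rng, j - i, state[ax], 0.0, relax, sd, dt)
                pos[i:j, ax] = seg
            if j > i:
                state = pos[j - 1].copy()
            i = j
        if i >= n:
            break

        # ---- bound phase: deterministic relaxation toward the plateau ----
        binding_times.append(i * dt)
        par0 = state[0] * cos_a + state[1] * sin_a
        perp0 = -state[0] * sin_a + state[1] * cos_a
        t_rel = (np.arange(n - i) + 1) * dt
        if gamma == 0:
            # frictionless link transmits no force: bead sits at trap center
            par = np.zeros(n - i)
        elif not np.isfinite(gamma):
            # unstoppable filament: bead dragged at v0, force ramps linearly
            par = par0 + v0 * t_rel
        else:
            tau = gamma / k
            x_inf = gamma * v0 / k
            par = x_inf + (par0 - x_inf) * np.exp(-t_rel / tau)

        load = k * np.hypot(par, perp0)
        if config.detachment_force is not None:
            brk = np.flatnonzero(load > config.detachment_force)
        else:
            brk = np.empty(0, dtype=int)
        j = i + (int(brk[0]) + 1 if brk.size else n - i)
        m = j - i
        pos[i:j, 0] = par[:m] * cos_a - perp0 * sin_a
        pos[i:j, 1] = par[:m] * sin_a + perp0 * cos_a
        state = pos[j - 1].copy()
        i = j
        if brk.size and config.rebind_delay is not None:
            next_bind = i + int(round(config.rebind_delay * config.sample_rate))
        else:
            next_bind = n  # stay free for the remainder

    time = np.arange(n) * dt
    force = k * pos + np.asarray(config.offset_force)
    return ForceTrace(
        time=time,
        force_x=force[:, 0],
        force_y=force[:, 1],
        trap_stiffness=k,
        metadata={
            "config": config.to_dict(),
            "true_binding_times": binding_times,
            "true_plateau_force": config.plateau_force,
            "geometry": config.geometry,
            "seed": config.seed,
        },
    )


def simulate_fv_scan(
    config: SimConfig,
    setpoints: Sequence[float],
    noise_sd: float,
    seed: Optional[int] = None,
    segment_duration: float = 10.0,
) -> FVScan:
    """Force-feedback scan of one pair: velocity response to set forces.

    Each segment's response velocity is v0 − F/γ plus Gaussian noise of
    standard deviation ``noise_sd`` (nm/s); quality weights are drawn
    uniformly from [0.5, 1].  Setpoints should include forward and
    backward (negative) forces, as in the instrument routine.
    """
    setpoints = np.asarray(list(setpoints), dtype=float)
    if setpoints.size == 0:
        raise ValueError("setpoint list must not be empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if config.team_friction <= 0:
        raise ValueError("force-feedback scan requires team_friction > 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    v0 = config.unloaded_velocity
    gamma = config.team_friction
    responses = v0 - setpoints / gamma + noise_sd * rng.standard_normal(setpoints.size)
    weights = rng.uniform(0.5, 1.0, size=setpoints.size)
    segments = [
        FVSegment(
            mode="constant_force",
            setpoint=float(f),
            response=float(v),
            quality_weight=float(w),
            duration=segment_duration,
        )
        for f, v, w in zip(setpoints, responses, weights)
    ]
    return FVScan(
        segments=segments,
        unloaded_velocity=v0,
        pair_id=f"sim-{config.seed if seed is None else seed}",
        metadata={
            "true_team_friction": gamma,
            "true_stopping_force": gamma * v0,
            "noise_sd": noise_sd,
        },
    )


def simulate_track(
    v_true: float,
    loc_noise_sd: float,
    frame_interval: float,
    n_frames: int,
    seed: int,
    filament_length: float = 5000.0,
    mode: str = "tracked",
) -> FilamentTrack:
    """Filament track: linear motion plus iid Gaussian localization noise."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if loc_noise_sd < 0:
        raise ValueError("localization noise sd must be non-negative")
    if frame_interval <= 0:
        raise ValueError("frame interval must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    pos = v_true * t + loc_noise_sd * rng.standard_normal(n_frames)
    return FilamentTrack(
        frame_times=t,
        positions=pos,
        filament_length=filament_length,
        mode=mode,
        filament_id=f"sim-{seed}",
        metadata={"v_true": v_true, "loc_noise_sd": loc_noise_sd},
    )


def simulate_intensities(
    n_molecules: int, single_mean: float, single_cv: float, seed: int
) -> np.ndarray:
    """Per-fluorophore intensities whose sum is an integrated measurement.

    Draws ``n_molecules`` positive values from a gamma distribution with
    the given mean and coefficient of variation (delta at the mean when
    cv = 0).  Sum the return value to get the integrated intensity.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    if single_cv < 0:
        raise ValueError("single_cv must be non-negative")
    if single_mean <= 0:
        raise ValueError("single_mean must be positive")
    if n_molecules == 0:
        return np.empty(0)
    if single_cv == 0:
        return np.full(n_molecules, float(single_mean))
    rng = np.random.default_rng(seed)
    shape = 1.0 / single_cv**2
    scale = single_mean * single_cv**2
    return rng.gamma(shape, scale, size=n_molecules)


def simulate_overlap_series(
    n_crosslinkers: int,
    motor_force: float,
    L_start: float,
    temperature: float = DEFAULT_TEMPERATURE,
    rate: float = 50.0,
    seed: int = 0,
    record_interval: float = 1.0,
    stall_fraction: float = 0.005,
    min_length: float = 1.0,
) -> OverlapSeries:
    """Overlap shortening under a constant motor force against the
    entropic force of N confined crosslinkers.

    The overlap shortens at velocity ``rate`` × (F_motor − N·kB·T/L),
    with ``rate`` the sliding mobility in nm/s per pN of net force, and
    asymptotes at the stall length L* = N·kB·T/F_motor.  Integration
    (explicit Euler with a step bounded well below the relaxation scale)
    continues until the length is within ``stall_fraction`` of L*, so the
    final recorded length is within 1% of the stall length.  For N = 0
    there is no opposing force and the overlap shortens linearly until
    ``min_length``.  The series is deterministic; ``seed`` is recorded in
    the metadata for provenance.
    """
    if motor_force <= 0:
        raise ValueError("motor_force must be positive")
    if L_start <= 0:
        raise ValueError("L_start must be positive")
    if n_crosslinkers < 0:
        raise ValueError("n_crosslinkers must be non-negative")
    l_stall = n_crosslinkers * KB * temperature / motor_force
    if n_crosslinkers > 0 and L_start <= l_stall:
        raise ValueError(
            f"L_start={L_start} nm already at or below stall length {l_stall:.3g} nm"
        )

    target = l_stall * (1.0 + stall_fraction) if n_crosslinkers > 0 else min_length
    # Euler step: keep each step below 1% of the instantaneous distance to
    # stall so the approach is monotone and accurate.
    dt = 0.01 * max(L_start - l_stall, min_length) / (rate * motor_force)
    times = [0.0]
    lengths = [L_start]
    t, L = 0.0, L_start
    next_record = record_interval
    max_steps = 10_000_000
    for _ in range(max_steps):
        if L <= target:
            break
        net = motor_force - (n_crosslinkers * KB * temperature / L)
        step_dt = min(dt, 0.05 * (L - l_stall) / (rate * max(net, 1e-12)))
        L_new = L - rate * net * step_dt
        L_new = max(L_new, target)
        t += step_dt
        L = L_new
        if t >= next_record or L <= target:
            times.append(t)
            lengths.append(L)
            next_record = t + record_interval
    else:
        raise RuntimeError("overlap integration did not converge")

    # at balance the overlap sits at the stalled length; record a settle
    # tail so downstream stall detection sees the flat asymptote
    n_settle = max(5, len(times) // 3)
    for _ in range(n_settle):
        t += record_interval
        times.append(t)
        lengths.append(L)

    return OverlapSeries(
        times=np.array(times),
        overlap_lengths=np.array(lengths),
        n_crosslinkers=n_crosslinkers,
        temperature=temperature,
        motor_force=motor_force,
        metadata={"seed": seed, "rate": rate, "L_stall": l_stall},
    )
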