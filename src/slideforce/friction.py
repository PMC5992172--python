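"""Weighted force–velocity fits and stopping-force extrapolation.

For aligned microtubule pairs slid by diffusively anchored motors the
stall force is below the thermal noise floor of the trap, so it cannot be
read off a force plateau.  Instead the trap applies set forces (or set
stage velocities) and records the response; the force–velocity relation
is linear, F = intercept + slope·v, and the stopping force is the force
difference between no-load velocity and stall:

    F_stop = |slope| · v_unloaded

The slope magnitude is the friction coefficient of the motor team.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FVSegment",
    "FVScan",
    "FrictionFitResult",
    "fit_force_velocity",
    "stopping_force_from_fit",
    "compare_pre_post_velocities",
]

_MODES = ("constant_force", "constant_velocity")


@dataclass(frozen=True)
class FVSegment:
    """One scan segment.

    In constant_force mode the setpoint is a force (pN) and the response a
    velocity (nm/s); in constant_velocity mode the roles are swapped.  The
    quality weight in (0, 1] rates how steady the sliding was and scales
    the segment's squared residual in the fit.
    """

    mode: str
    setpoint: float
    response: float
    quality_weight: float = 1.0
    duration: float = float("nan")

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not 0.0 < self.quality_weight <= 1.0:
            raise ValueError("quality_weight must lie in (0, 1]")

    @property
    def force(self) -> float:
        return self.setpoint if self.mode == "constant_force" else self.response

    @property
    def velocity(self) -> float:
        return self.response if self.mode == "constant_force" else self.setpoint


@dataclass
class FVScan:
    """All force–velocity segments recorded on one microtubule pair."""

    segments: list[FVSegment]
    unloaded_velocity: float
    pair_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unloaded_velocity == 0:
            raise ValueError("unloaded velocity must be nonzero to orient the axis")

    @property
    def forces(self) -> np.ndarray:
        return np.array([s.force for s in self.segments])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([s.velocity for s in self.segments])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.quality_weight for s in self.segments])


@dataclass(frozen=True)
class FrictionFitResult:
    slope: float  # pN·s/nm, signed (negative for a resisting team)
    intercept: float  # pN
    slope_se: float
    intercept_se: float
    stopping_force: float  # pN
    stopping_force_se: float
    r_squared: float
    n_segments: int

    def to_dict(self) -> dict:
        return {
            "slope_pN_s_per_nm": self.slope,
            "intercept_pN": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "stopping_force_pN": self.stopping_force,
            "stopping_force_se_pN": self.stopping_force_se,
            "r_squared": self.r_squared,
            "n_segments": self.n_segments,
        }


class StoppingForceEstimate(NamedTuple):
    value: float
    se: float


def fit_force_velocity(scan: FVScan) -> FrictionFitResult:
    """Weighted least-squares fit of force on velocity.

    Force is regressed on velocity regardless of scan mode (the target
    quantity is a force difference), with quality weights applied as
    multiplicative factors on the squared residuals.  Both scan modes are
    pooled.  The transport axis is oriented so the unloaded velocity is
    positive; backward (assisting) setpoints enter with negative sign.
    """
    if len(scan.segments) < 3:
        raise ValueError("need at least 3 segments for a weighted fit")
    v = scan.velocities
    f = scan.forces
    if np.ptp(v) == 0:
        raise ValueError("all velocities identical: rank-deficient design")
    sign = np.sign(scan.unloaded_velocity)
    v = v * sign
    f = f * sign
    v0 = abs(scan.unloaded_velocity)

    model = sm.WLS(f, sm.add_constant(v), weights=scan.weights)
    res = model.fit()
    intercept, slope = (float(p) for p in res.params)
    intercept_se, slope_se = (float(b) for b in res.bse)
    stopping = abs(slope) * v0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared)
    if not np.isfinite(r_squared):  # zero-variance response (flat line)
        r_squared = 1.0 if res.ssr < 1e-12 else 0.0
    return FrictionFitResult(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        stopping_force=stopping,
        stopping_force_se=slope_se * v0,
        r_squared=r_squared,
        n_segments=len(scan.segments),
    )


def stopping_force_from_fit(
    fit: FrictionFitResult,
    unloaded_velocity: float,
    unloaded_velocity_se: float = 0.0,
) -> StoppingForceEstimate:
    """Stopping force |slope|·v0 with first-order error propagation."""
    if unloaded_velocity < 0:
        raise ValueError("unloaded_velocity must be non-negative here (magnitude)")
    if not np.isfinite(fit.slope):
        raise ValueError("fit slope is not finite")
    value = abs(fit.slope) * unloaded_velocity
    se = float(
        np.hypot(fit.slope_se * unloaded_velocity, abs(fit.slope) * unloaded_velocity_se)
    )
    return StoppingForceEstimate(value=float(value), se=se)


class KSComparison(NamedTuple):
    statistic: float
    pvalue: float
    n_pre: int
    n_post: int


def compare_pre_post_velocities(
    pre: Iterable[float], post: Iterable[float]
) -> KSComparison:
    """Two-sample Kolmogorov–Smirnov comparison of velocity samples.

    Used to check that bead attachment and repeated force–velocity scans
    did not degrade transport.
    """
    pre = np.asarray(list(pre), dtype=float)
    post = np.asarray(list(post), dtype=float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("need at least 2 observations on each side")
    res = stats.ks_2samp(pre, post)
    return KSComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_pre=pre.size,
        n_post=post.size,
    )
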