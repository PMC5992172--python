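"""Passive-force calculators: entropic crosslinker force and filament buckling.

Two trap-free corroborations of motor-team stopping forces:

* A fixed number N of diffusible crosslinkers (e.g. Ase1) confined to a
  shortening microtubule overlap of length L behaves as a 1-D ideal gas
  and pushes the overlap apart with force F = N·kB·T/L.  Sliding motors
  compact the overlap until this entropic force balances their drive, so
  the stalled (N, L) pair reads out the motor team's stopping force.

* A filament segment of length L and flexural rigidity EI that buckles
  under compression reports the compressive force at the buckling
  threshold.  The force is computed as prefactor·EI/L² with the
  prefactor defaulting to 4π.  Note the classical Euler formula for a
  clamped–clamped beam uses 4π²; the default follows the convention of
  the assay literature this module mirrors and is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB

__all__ = [
    "OverlapMeasurement",
    "BucklingEvent",
    "entropic_force",
    "buckling_force",
    "stall_overlap_inversion",
    "EULER_CLAMPED_PREFACTOR",
]

#: Classical Euler clamped–clamped buckling prefactor (4π²); the default
#: prefactor used by :func:`buckling_force` is 4π, i.e. a factor π lower.
EULER_CLAMPED_PREFACTOR = 4.0 * math.pi**2


@dataclass(frozen=True)
class OverlapMeasurement:
    """Crosslinker count N, overlap length L (nm) and temperature (K)."""

    n_molecules: int
    overlap_length: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        if not self.overlap_length > 0:
            raise ValueError("overlap_length must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class BucklingEvent:
    """Buckled segment length (µm) and flexural rigidity (N·m²)."""

    segment_length: float
    flexural_rigidity: float = 6e-24
    pre_buckle_fluctuation_time: float = float("nan")  # descriptive only

    def __post_init__(self) -> None:
        if not self.segment_length > 0:
            raise ValueError("segment_length must be positive")
        if not self.flexural_rigidity > 0:
            raise ValueError("flexural_rigidity must be positive")


def entropic_force(m: OverlapMeasurement) -> float:
    """1-D ideal-gas expansion force N·kB·T/L in pN.

    Valid for a dilute confined gas of crosslinkers; linear in N and
    inversely proportional to L.
    """
    return m.n_molecules * KB * m.temperature / m.overlap_length


def buckling_force(e: BucklingEvent, prefactor: float = 4.0 * math.pi) -> float:
    """Buckling force prefactor·EI/L² in pN.

    ``segment_length`` is in µm and ``flexural_rigidity`` in N·m²; the
    result is converted to pN.  ``prefactor`` defaults to 4π (see module
    docstring); pass :data:`EULER_CLAMPED_PREFACTOR` for the classical
    clamped–clamped Euler value 4π².
    """
    if not prefactor > 0:
        raise ValueError("prefactor must be positive")
    length_m = e.segment_length * 1e-6
    force_n = prefactor * e.flexural_rigidity / length_m**2
    return force_n * 1e12  # N -> pN


def stall_overlap_inversion(series, slope_tol: float = 0.01) -> float:
    """Motor-team stopping force from a stalled overlap-shortening series.

    At stall, the motor drive balances the entropic crosslinker force, so
    evaluating N·kB·T/L at the final overlap length recovers the motor
    force.  Requires the series to actually have stalled: the relative
    shortening rate over the last recorded span must be below
    ``slope_tol`` (fraction of final length per second, scaled by the
    recording interval).
    """
    if series.n_crosslinkers == 0:
        raise ValueError("series has no crosslinkers: no force balance possible")
    lengths = np.asarray(series.overlap_lengths, dtype=float)
    times = np.asarray(series.times, dtype=float)
    if lengths.size < 2:
        raise ValueError("series too short")
    tail = max(2, lengths.size // 10)
    span = times[-1] - times[-tail]
    rate = abs(lengths[-1] - lengths[-tail]) / max(span, 1e-12)
    if rate > slope_tol * lengths[-1]:
        raise ValueError("series has not stalled (final slope above tolerance)")
    m = OverlapMeasurement(
        n_molecules=series.n_crosslinkers,
        overlap_length=float(lengths[-1]),
        temperature=series.temperature,
    )
    return entropic_force(m)
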