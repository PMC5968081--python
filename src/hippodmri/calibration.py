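"""Protocol-design math for ex vivo PGSE acquisitions.

For a pulsed-gradient spin-echo sequence with rectangular gradient pulses the
diffusion sensitization is ``b = (gamma G delta)^2 (Delta - delta/3)``.  Fixed
tissue has both a short T2 and strongly reduced diffusivities, so the usable
echo time and b value are bounded by requiring the combined signal decay
``exp(-TE/T2) * exp(-b D)`` to stay above a floor (default 0.05), split
equally between the two decays: each factor must stay above ``sqrt(floor)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import GAMMA_WATER_PROTON


@dataclass(frozen=True)
class PulseTiming:
    """Rectangular PGSE pulse pair: G (T/m), delta and Delta (s)."""

    G: float
    delta: float
    Delta: float
    gamma: float = GAMMA_WATER_PROTON

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("gradient magnitude must be >= 0")
        if not 0 < self.delta < self.Delta:
            raise ValueError("need 0 < delta < Delta")

    @property
    def q(self) -> float:
        """Wavevector magnitude q = gamma * delta * G (rad/m)."""
        return self.gamma * self.delta * self.G

    @property
    def tau(self) -> float:
        """Effective diffusion time tau = Delta - delta/3 (s)."""
        return self.Delta - self.delta / 3.0


@dataclass(frozen=True)
class SignalFloor:
    """Lowest acceptable value of exp(-TE/T2) * exp(-b D)."""

    total_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.total_floor < 1:
            raise ValueError("total_floor must lie in (0, 1)")

    @property
    def per_decay_floor(self) -> float:
        """Floor per decay when the budget is split equally: sqrt(total)."""
        return math.sqrt(self.total_floor)


def compute_b(timing: PulseTiming) -> float:
    """b value in s/mm^2 for a rectangular PGSE pulse pair.

    b = (gamma G delta)^2 (Delta - delta/3), computed in SI (s/m^2) and
    converted to the conventional s/mm^2 (factor 1e-6).
    """
    return timing.q ** 2 * timing.tau * 1e-6


def invert_b(b_target: float, delta: float, Delta: float,
             gamma: float = GAMMA_WATER_PROTON) -> float:
    """Gradient magnitude G (T/m) producing ``b_target`` (s/mm^2)."""
    if b_target < 0:
        raise ValueError("b must be >= 0")
    tau = Delta - delta / 3.0
    if tau <= 0:
        raise ValueError("need delta < Delta")
    q = math.sqrt(b_target * 1e6 / tau)
    return q / (gamma * delta)


def compute_te_max(t2: float, floor: SignalFloor = SignalFloor()) -> float:
    """Largest echo time (ms) keeping exp(-TE/T2) above the per-decay floor."""
    if t2 <= 0:
        raise ValueError("T2 must be > 0")
    return -t2 * math.log(floor.per_decay_floor)


def compute_b_max(d: float, floor: SignalFloor = SignalFloor()) -> float:
    """Largest b (s/mm^2) keeping exp(-b D) above the per-decay floor.

    ``d`` is the mean diffusivity in mm^2/s.
    """
    if d <= 0:
        raise ValueError("D must be > 0")
    return -math.log(floor.per_decay_floor) / d


def report_te_max(t2: float, floor: SignalFloor = SignalFloor()) -> int:
    """TE_max rounded to the nearest millisecond (protocol convention)."""
    return round(compute_te_max(t2, floor))


def report_b_max(d: float, floor: SignalFloor = SignalFloor()) -> int:
    """b_max floored to an integer number of s/mm^2 (protocol convention)."""
    return math.floor(compute_b_max(d, floor))
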