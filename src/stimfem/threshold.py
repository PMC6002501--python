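"""Activation-threshold search by bracketed bisection at 1 uA resolution.

The unit extracellular field corresponds to 1 mA delivered current, so the
search variable is the stimulus amplitude in uA scaling that field.  The
upper bracket doubles from an initial bound until suprathreshold, then
bisection narrows to the stated resolution; the reported threshold is the
smallest tested suprathreshold integer amplitude (ceiling convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .mrg import (FiberGeometry, MembraneParameters, StimulusWaveform,
                  simulate, resting_state)

__all__ = ["SearchSettings", "ThresholdResult", "find_threshold",
           "bisect_activation"]


@dataclass(frozen=True)
class SearchSettings:
    resolution_uA: float = 1.0
    initial_upper_uA: float = 1000.0       # 1 mA
    growth_factor: float = 2.0
    max_upper_uA: float = 1.0e6            # 1 A: beyond this, unexcitable
    duration_ms: float = 5.0
    dt_us: float = 2.0
    dt_after_us: float = 10.0

    def __post_init__(self):
        if self.resolution_uA <= 0:
            raise ValueError("resolution must be positive")
        if self.growth_factor <= 1:
            raise ValueError("bracket growth factor must exceed 1")


@dataclass
class ThresholdResult:
    threshold_uA: Optional[float]          # None if unexcitable
    n_simulations: int
    excitable: bool

    def __float__(self):
        if self.threshold_uA is None:
            raise ValueError("fiber was unexcitable at the maximum bound")
        return float(self.threshold_uA)


def bisect_activation(activates: Callable[[float], bool],
                      settings: SearchSettings = SearchSettings(),
                      bracket: Optional[tuple] = None) -> ThresholdResult:
    """Generic bracketed bisection on a monotone activation predicate.

    ``bracket`` optionally seeds (lo, hi); the bounds are verified and the
    search falls back to doubling if the seed does not bracket.
    """
    n = 0
    lo = 0.0
    hi = settings.initial_upper_uA
    if bracket is not None:
        b_lo, b_hi = bracket
        n += 2
        if activates(b_hi):
            if not activates(b_lo):
                lo, hi = b_lo, b_hi
            else:
                lo, hi = 0.0, b_lo
            return _bisect(activates, lo, hi, settings, n)
        lo, hi = b_hi, b_hi * settings.growth_factor
    while True:
        n += 1
        if activates(hi):
            break
        lo = hi
        hi *= settings.growth_factor
        if hi > settings.max_upper_uA:
            return ThresholdResult(None, n, excitable=False)
    return _bisect(activates, lo, hi, settings, n)


def _bisect(activates, lo, hi, settings, n) -> ThresholdResult:
    res = settings.resolution_uA
    while hi - lo > res:
        mid = math.ceil((lo + hi) / 2 / res) * res
        if mid >= hi:
            mid = hi - res
        n += 1
        if activates(mid):
            hi = mid
        else:
            lo = mid
    return ThresholdResult(hi, n, excitable=True)


def find_threshold(fiber: FiberGeometry, params: MembraneParameters,
                   extracellular_unit_V: np.ndarray,
                   waveform: StimulusWaveform = StimulusWaveform(),
                   settings: SearchSettings = SearchSettings(),
                   initial_state: Optional[dict] = None,
                   bracket: Optional[tuple] = None) -> ThresholdResult:
    """Threshold (uA) for a fiber in a unit (1 mA) extracellular field."""
    if initial_state is None:
        initial_state = resting_state(fiber, params)

    def activates(amp: float) -> bool:
        return simulate(fiber, params, extracellular_unit_V, waveform,
                        amp, duration_ms=settings.duration_ms,
                        dt_us=settings.dt_us,
                        dt_after_us=settings.dt_after_us,
                        initial_state=initial_state).activated

    return bisect_activation(activates, settings, bracket=bracket)
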