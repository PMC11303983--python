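"""Environmental driver gradients: counter-varying oxygen and sulfide diffusivities.

The environment is summarised by the pair (a_O, a_S) of first-order exchange
rates between the substrates and their background pools.  Along a gradient the
oxygen diffusivity spans 10^-2 to 10^0 h^-1 on a log10-equispaced grid while
the sulfide diffusivity traverses a mirrored range in the opposite sense.  An
*environmental asymmetry factor* f rescales the log-half-width of the sulfide
range about its fixed midpoint 10^-1: f = 1 reproduces the mirrored symmetric
range 10^-2..10^0, f = 0.8 narrows it to 10^-1.8..10^-0.2, f = 2 widens it to
10^-3..10^1, and f = 0 pins sulfide diffusivity at 10^-1 so that only oxygen
diffusivity changes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "EnvironmentalAsymmetry",
    "DriverSequence",
    "make_driver_sequence",
    "make_temporal_pattern",
    "LOG10_A_O_MIN",
    "LOG10_A_O_MAX",
    "LOG10_A_S_MIDPOINT",
]

# the oxygen-diffusivity range is fixed; only the sulfide range is rescaled
LOG10_A_O_MIN = -2.0
LOG10_A_O_MAX = 0.0
LOG10_A_S_MIDPOINT = -1.0


class Direction(enum.Enum):
    """Sense of environmental change along a gradient."""

    TOWARD_OXIC = "toward_oxic"      # a_O increasing, a_S decreasing
    TOWARD_ANOXIC = "toward_anoxic"  # a_O decreasing, a_S increasing

    def reversed(self) -> "Direction":
        return (
            Direction.TOWARD_ANOXIC
            if self is Direction.TOWARD_OXIC
            else Direction.TOWARD_OXIC
        )


@dataclass(frozen=True)
class EnvironmentalAsymmetry:
    """Scaling factor for the log10 half-width of the sulfide-diffusivity range.

    ``factor == 1`` is the environmentally symmetric reference; values below 1
    mean sulfide diffusivity changes less than oxygen diffusivity, values above
    1 mean it changes more.  ``factor == 0`` holds it constant at 10^-1 h^-1.
    """

    factor: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor < 0:
            raise ValueError(f"asymmetry factor must be >= 0, got {self.factor!r}")

    def log10_a_S_range(self) -> tuple[float, float]:
        """(low, high) endpoints of log10 a_S."""
        return (
            LOG10_A_S_MIDPOINT - self.factor,
            LOG10_A_S_MIDPOINT + self.factor,
        )


def _as_asymmetry(a: "EnvironmentalAsymmetry | float") -> EnvironmentalAsymmetry:
    return a if isinstance(a, EnvironmentalAsymmetry) else EnvironmentalAsymmetry(float(a))


@dataclass(frozen=True)
class DriverSequence:
    """Paired driver values along an environmental gradient.

    ``a_O`` and ``a_S`` are equal-length arrays of diffusivities (h^-1);
    ``time_h`` is present only for temporal schedules and stamps the biological
    time at which each (a_O, a_S) pair takes effect.
    """

    a_O: np.ndarray
    a_S: np.ndarray
    direction: Direction
    time_h: np.ndarray | None = None
    t_end: float | None = None  # end of the last segment (temporal mode)

    def __post_init__(self) -> None:
        a_O = np.asarray(self.a_O, dtype=float)
        a_S = np.asarray(self.a_S, dtype=float)
        object.__setattr__(self, "a_O", a_O)
        object.__setattr__(self, "a_S", a_S)
        if a_O.ndim != 1 or a_O.shape != a_S.shape:
            raise ValueError("a_O and a_S must be equal-length 1-d sequences")
        if np.any(a_O <= 0) or np.any(a_S <= 0):
            raise ValueError("all diffusivities must be > 0")
        if self.time_h is not None:
            t = np.asarray(self.time_h, dtype=float)
            object.__setattr__(self, "time_h", t)
            if t.shape != a_O.shape or np.any(np.diff(t) <= 0):
                raise ValueError("time_h must be strictly increasing and match length")
            if self.t_end is not None and self.t_end <= t[-1]:
                raise ValueError("t_end must exceed the last segment start")

    def __len__(self) -> int:
        return len(self.a_O)

    def reversed(self) -> "DriverSequence":
        """Elementwise reversal of both driver arrays (gradient mode only)."""
        if self.time_h is not None:
            raise ValueError("cannot reverse a time-indexed schedule")
        return DriverSequence(
            self.a_O[::-1].copy(), self.a_S[::-1].copy(), self.direction.reversed()
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"step_index": np.arange(len(self))}
        if self.time_h is not None:
            cols["time_h"] = self.time_h
        cols["a_O"] = self.a_O
        cols["a_S"] = self.a_S
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def make_driver_sequence(
    n_steps: int = 101,
    asymmetry: EnvironmentalAsymmetry | float = 1.0,
    direction: Direction = Direction.TOWARD_OXIC,
) -> DriverSequence:
    """Log10-equispaced counter-varying gradient of the two diffusivities.

    Oxygen diffusivity spans 10^-2..10^0 h^-1 in the requested direction;
    sulfide diffusivity spans the factor-scaled range about 10^-1 traversed in
    the opposite sense (constant at 10^-1 when the factor is 0).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    asym = _as_asymmetry(asymmetry)
    la_O = np.linspace(LOG10_A_O_MIN, LOG10_A_O_MAX, n_steps)
    lo, hi = asym.log10_a_S_range()
    la_S = np.linspace(hi, lo, n_steps)  # opposite sense to a_O
    a_O, a_S = 10.0 ** la_O, 10.0 ** la_S
    if direction is Direction.TOWARD_ANOXIC:
        # reverse after exponentiation so the two directions' sequences are
        # bitwise elementwise reverses of each other
        a_O, a_S = a_O[::-1].copy(), a_S[::-1].copy()
    return DriverSequence(a_O, a_S, direction)


def make_temporal_pattern(
    phase_durations: Sequence[float] = (5.0e5, 5.0e5, 5.0e5),
    n_steps_per_ramp: int = 50,
    asymmetry: EnvironmentalAsymmetry | float = 1.0,
) -> DriverSequence:
    """Three-phase time-indexed driver schedule for the temporal mode.

    Phase 1 holds the anoxic-favouring extreme (low a_O, high a_S); phase 2
    ramps stepwise to the oxic-favouring extreme; phase 3 ramps back.  Each
    ramp is log10-equispaced with ``n_steps_per_ramp`` segments of equal
    duration, so a full quasi-static traversal crosses each tipping point once
    (one upward and one downward regime shift per substrate).

    Returns a :class:`DriverSequence` whose ``time_h`` stamps the start of each
    piecewise-constant segment.
    """
    if len(phase_durations) != 3 or any(d <= 0 for d in phase_durations):
        raise ValueError("phase_durations must be three positive durations")
    if n_steps_per_ramp < 2:
        raise ValueError("n_steps_per_ramp must be >= 2")
    asym = _as_asymmetry(asymmetry)
    d1, d2, d3 = (float(d) for d in phase_durations)
    lo_S, hi_S = asym.log10_a_S_range()

    la_O_up = np.linspace(LOG10_A_O_MIN, LOG10_A_O_MAX, n_steps_per_ramp)
    la_S_dn = np.linspace(hi_S, lo_S, n_steps_per_ramp)

    times = [0.0]
    la_O = [LOG10_A_O_MIN]
    la_S = [hi_S]
    # phase 2: ramp toward oxic (skip index 0: it is the phase-1 hold value)
    for i in range(1, n_steps_per_ramp):
        times.append(d1 + (i - 1) * d2 / (n_steps_per_ramp - 1))
        la_O.append(la_O_up[i])
        la_S.append(la_S_dn[i])
    # phase 3: ramp back toward anoxic
    for i in range(1, n_steps_per_ramp):
        times.append(d1 + d2 + (i - 1) * d3 / (n_steps_per_ramp - 1))
        la_O.append(la_O_up[n_steps_per_ramp - 1 - i])
        la_S.append(la_S_dn[n_steps_per_ramp - 1 - i])
    return DriverSequence(
        10.0 ** np.array(la_O),
        10.0 ** np.array(la_S),
        Direction.TOWARD_OXIC,
        time_h=np.array(times),
        t_end=d1 + d2 + d3,
    )
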