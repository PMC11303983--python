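"""Tipping-point detection and response-symmetry quantification.

A tipping point along a gradient of stable states is located where the change
in system state between two consecutive gradient steps is largest.  The change
metric defaults to the absolute difference of log10 substrate concentration,
maximised over oxygen and sulfide: the substrates are the variables whose
shift magnitudes define response symmetry, and on a log scale an upward and a
downward regime shift of the same relative extent have equal magnitude, which
is what makes the symmetric configuration's shifts exactly comparable.

Response symmetry is assessed through *total shift magnitudes*: the sum of
the risen substrate's increase and the fallen substrate's decrease across one
tipping step, compared between the two directions of environmental change.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .environment import DriverSequence, EnvironmentalAsymmetry
from .model import ModelParameters, SystemState, symmetric_default_parameters
from .simulate import (
    DirectionRun,
    HysteresisResult,
    SimulationError,
    SimulationSettings,
    run_hysteresis,
)

__all__ = [
    "Transition",
    "TippingPoint",
    "SymmetryReport",
    "detect_tipping",
    "total_shift_magnitude",
    "post_shift_level",
    "analyze_hysteresis",
    "compare_to_symmetric",
    "scan_system_asymmetry",
    "scan_environmental_asymmetry",
]

# substrate concentrations below this are clipped before taking log10
_LOG_CLIP = 1e-12


class Transition(enum.Enum):
    ANOXIC_TO_OXIC = "anoxic_to_oxic"
    OXIC_TO_ANOXIC = "oxic_to_anoxic"


@dataclass(frozen=True)
class TippingPoint:
    """A detected regime shift between two consecutive gradient steps.

    ``index`` is the lower of the two bracketing step indices; the location is
    the log10 midpoint of the bracketing oxygen diffusivities (unbiased with
    respect to scan direction, resolved to one gradient step either way).
    Magnitudes are unsigned per-substrate changes across the tipping step, in
    log10 μM for the default metric or μM for the raw metric.
    """

    transition: Transition
    index: int
    location_log10_a_O: float
    magnitude_O: float
    magnitude_S: float
    tied: bool = False
    metric: str = "log10"

    @property
    def location_a_O(self) -> float:
        return 10.0 ** self.location_log10_a_O

    @property
    def total_magnitude(self) -> float:
        return self.magnitude_O + self.magnitude_S


@dataclass(frozen=True)
class SymmetryReport:
    """Paired tipping points of a hysteresis run and their comparison.

    ``magnitude_asymmetry`` is signed: total(oxic->anoxic) minus
    total(anoxic->oxic); zero means perfect response symmetry.  Location
    shifts (log10 a_O units) are relative to a symmetric reference run and are
    ``None`` until filled by :func:`compare_to_symmetric`.  A missing tipping
    point (monostable response) leaves the derived fields ``None``.
    """

    tp_anoxic_to_oxic: TippingPoint | None
    tp_oxic_to_anoxic: TippingPoint | None
    magnitude_asymmetry: float | None = None
    bistability_width: float | None = None
    location_shift_up: float | None = None
    location_shift_down: float | None = None

    def to_dict(self) -> dict:
        def tp_dict(tp: TippingPoint | None) -> dict | None:
            if tp is None:
                return None
            return {
                "transition": tp.transition.value,
                "index": tp.index,
                "location_log10_a_O": tp.location_log10_a_O,
                "location_a_O": tp.location_a_O,
                "magnitude_O": tp.magnitude_O,
                "magnitude_S": tp.magnitude_S,
                "total_magnitude": tp.total_magnitude,
                "tied": tp.tied,
                "metric": tp.metric,
            }

        return {
            "tp_anoxic_to_oxic": tp_dict(self.tp_anoxic_to_oxic),
            "tp_oxic_to_anoxic": tp_dict(self.tp_oxic_to_anoxic),
            "magnitude_asymmetry": self.magnitude_asymmetry,
            "bistability_width": self.bistability_width,
            "location_shift_up": self.location_shift_up,
            "location_shift_down": self.location_shift_down,
        }


def _substrate_series(states: Sequence[SystemState]) -> tuple[np.ndarray, np.ndarray]:
    O = np.array([s.O for s in states], dtype=float)
    S = np.array([s.S for s in states], dtype=float)
    return O, S


def _transform(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "log10":
        return np.log10(np.clip(x, _LOG_CLIP, None))
    if metric == "raw":
        return x
    raise ValueError(f"unknown metric {metric!r}; use 'log10' or 'raw'")


def detect_tipping(
    states: Sequence[SystemState],
    drivers: DriverSequence,
    metric: str = "log10",
    no_tipping_floor: float = 0.5,
) -> TippingPoint | None:
    """Locate the largest consecutive-step state change along a gradient.

    For every consecutive pair of stable states the per-substrate change is
    computed in the transformed scale and the larger of the oxygen and sulfide
    changes taken; the tipping step is the argmax.  If no pair exceeds
    ``no_tipping_floor`` the response is treated as monostable and ``None``
    is returned.  Exact ties in the argmax are broken toward the pair closest
    to the gradient midpoint (then the lower index) and flagged.
    """
    if len(states) != len(drivers):
        raise ValueError("states and drivers must have equal length")
    if len(states) < 2:
        raise ValueError("need at least two states to detect a tipping point")
    O, S = _substrate_series(states)
    dO = np.abs(np.diff(_transform(O, metric)))
    dS = np.abs(np.diff(_transform(S, metric)))
    change = np.maximum(dO, dS)
    cmax = change.max()
    if cmax < no_tipping_floor:
        return None
    is_max = np.isclose(change, cmax, rtol=1e-12, atol=0.0)
    candidates = np.flatnonzero(is_max)
    mid = (len(change) - 1) / 2.0
    i = int(min(candidates, key=lambda k: (abs(k - mid), k)))
    transition = (
        Transition.ANOXIC_TO_OXIC if O[i + 1] > O[i] else Transition.OXIC_TO_ANOXIC
    )
    loc = 0.5 * (np.log10(drivers.a_O[i]) + np.log10(drivers.a_O[i + 1]))
    return TippingPoint(
        transition=transition,
        index=i,
        location_log10_a_O=float(loc),
        magnitude_O=float(dO[i]),
        magnitude_S=float(dS[i]),
        tied=len(candidates) > 1,
        metric=metric,
    )


def total_shift_magnitude(tp: TippingPoint) -> float:
    """Sum of the two substrates' unsigned shift magnitudes across the tip."""
    return tp.total_magnitude


def post_shift_level(run: DirectionRun, tp: TippingPoint) -> float:
    """Concentration attained by the risen substrate after its upward shift.

    Reports the plateau of the post-shift branch: the maximum equilibrium
    concentration of the substrate that increased across the tipping step,
    over all gradient steps beyond it.  This is the level the substrate
    settles at once the new state is established, and is insensitive to how
    close to the tipping point the gradient happens to place its first
    post-shift step.
    """
    name = "O" if tp.transition is Transition.ANOXIC_TO_OXIC else "S"
    values = run.substrate(name)[tp.index + 1:]
    if len(values) == 0:
        raise ValueError("no gradient steps beyond the tipping point")
    return float(values.max())


def analyze_hysteresis(
    result: HysteresisResult,
    metric: str = "log10",
    no_tipping_floor: float = 0.5,
) -> SymmetryReport:
    """Detect both tipping points of a hysteresis run and compare magnitudes."""
    tp_up = detect_tipping(
        result.toward_oxic.states, result.toward_oxic.drivers, metric, no_tipping_floor
    )
    tp_down = detect_tipping(
        result.toward_anoxic.states, result.toward_anoxic.drivers, metric, no_tipping_floor
    )
    mag_asym = None
    width = None
    if tp_up is not None and tp_down is not None:
        mag_asym = tp_down.total_magnitude - tp_up.total_magnitude
        width = abs(tp_up.location_log10_a_O - tp_down.location_log10_a_O)
    return SymmetryReport(
        tp_anoxic_to_oxic=tp_up,
        tp_oxic_to_anoxic=tp_down,
        magnitude_asymmetry=mag_asym,
        bistability_width=width,
    )


def compare_to_symmetric(
    report: SymmetryReport, reference: SymmetryReport
) -> SymmetryReport:
    """Fill the location-shift fields of ``report`` relative to a reference run.

    Shifts are (report location - reference location) in log10 a_O units:
    positive means the tipping point moved to a higher oxygen diffusivity.
    Fields whose tipping point is missing in either run stay ``None``.
    """
    shift_up = shift_down = None
    if report.tp_anoxic_to_oxic is not None and reference.tp_anoxic_to_oxic is not None:
        shift_up = (
            report.tp_anoxic_to_oxic.location_log10_a_O
            - reference.tp_anoxic_to_oxic.location_log10_a_O
        )
    if report.tp_oxic_to_anoxic is not None and reference.tp_oxic_to_anoxic is not None:
        shift_down = (
            report.tp_oxic_to_anoxic.location_log10_a_O
            - reference.tp_oxic_to_anoxic.location_log10_a_O
        )
    return replace(report, location_shift_up=shift_up, location_shift_down=shift_down)


_SCAN_COLUMNS = [
    "loc_up_log10_a_O",
    "loc_down_log10_a_O",
    "magnitude_O_up",
    "magnitude_S_up",
    "magnitude_O_down",
    "magnitude_S_down",
    "total_up",
    "total_down",
    "magnitude_asymmetry",
    "location_shift_up",
    "location_shift_down",
    "bistability_width",
]


def _report_row(report: SymmetryReport) -> dict:
    row: dict = {c: np.nan for c in _SCAN_COLUMNS}
    flags = []
    tp_up, tp_down = report.tp_anoxic_to_oxic, report.tp_oxic_to_anoxic
    if tp_up is not None:
        row["loc_up_log10_a_O"] = tp_up.location_log10_a_O
        row["magnitude_O_up"] = tp_up.magnitude_O
        row["magnitude_S_up"] = tp_up.magnitude_S
        row["total_up"] = tp_up.total_magnitude
        if tp_up.tied:
            flags.append("tie_up")
    else:
        flags.append("no_tipping_up")
    if tp_down is not None:
        row["loc_down_log10_a_O"] = tp_down.location_log10_a_O
        row["magnitude_O_down"] = tp_down.magnitude_O
        row["magnitude_S_down"] = tp_down.magnitude_S
        row["total_down"] = tp_down.total_magnitude
        if tp_down.tied:
            flags.append("tie_down")
    else:
        flags.append("no_tipping_down")
    for name in ("magnitude_asymmetry", "bistability_width",
                 "location_shift_up", "location_shift_down"):
        v = getattr(report, name)
        if v is not None:
            row[name] = v
    row["flags"] = ";".join(flags)
    return row


def _run_scan(
    param_name: str,
    values: Sequence[float],
    configure: Callable[[float], tuple[ModelParameters, "EnvironmentalAsymmetry | float"]],
    reference_value: float,
    settings: SimulationSettings | None,
    n_steps: int,
    metric: str,
    no_tipping_floor: float,
) -> pd.DataFrame:
    settings = settings or SimulationSettings()

    def analyze_one(v: float) -> SymmetryReport:
        params, asym = configure(v)
        result = run_hysteresis(params, asym, settings, n_steps)
        return analyze_hysteresis(result, metric, no_tipping_floor)

    reference = analyze_one(reference_value)
    rows = []
    for v in values:
        try:
            if v == reference_value:
                report = reference
            else:
                report = analyze_one(float(v))
            report = compare_to_symmetric(report, reference)
            row = _report_row(report)
        except SimulationError as err:
            row = {c: np.nan for c in _SCAN_COLUMNS}
            row["flags"] = f"failed:{err}"
        row[param_name] = v
        rows.append(row)
    return pd.DataFrame(rows)[[param_name, *_SCAN_COLUMNS, "flags"]]


def scan_system_asymmetry(
    H_O_values: Sequence[float],
    settings: SimulationSettings | None = None,
    n_steps: int = 101,
    params: ModelParameters | None = None,
    metric: str = "log10",
    no_tipping_floor: float = 0.5,
) -> pd.DataFrame:
    """Sweep the oxygen half-inhibition constant of the sulfur bacteria.

    The cyanobacterial sulfide half-inhibition constant stays at its symmetric
    value throughout; the environment is symmetric (factor 1).  Location
    shifts in each row are relative to the symmetric reference (H_O equal to
    the cyanobacterial constant), which is run once regardless of whether it
    appears in ``H_O_values``.
    """
    base = params or symmetric_default_parameters()
    if any(v <= 0 for v in H_O_values):
        raise ValueError("H_O values must be positive")
    return _run_scan(
        "H_O",
        H_O_values,
        lambda v: (base.with_overrides(H_O=v), 1.0),
        reference_value=base.H_S,
        settings=settings,
        n_steps=n_steps,
        metric=metric,
        no_tipping_floor=no_tipping_floor,
    )


def scan_environmental_asymmetry(
    factors: Sequence[float],
    settings: SimulationSettings | None = None,
    n_steps: int = 101,
    params: ModelParameters | None = None,
    metric: str = "log10",
    no_tipping_floor: float = 0.5,
) -> pd.DataFrame:
    """Sweep the environmental asymmetry factor with symmetric parameters.

    Factor 1 is the symmetric reference; factor 0 pins sulfide diffusivity at
    its midpoint so only oxygen diffusivity varies.
    """
    base = params or symmetric_default_parameters()
    if any(v < 0 for v in factors):
        raise ValueError("asymmetry factors must be >= 0")
    return _run_scan(
        "factor",
        factors,
        lambda v: (base, EnvironmentalAsymmetry(float(v))),
        reference_value=1.0,
        settings=settings,
        n_steps=n_steps,
        metric=metric,
        no_tipping_floor=no_tipping_floor,
    )
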