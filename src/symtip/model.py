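"""Core model: two antagonistic microbial functional groups coupled by mutual inhibition.

The system has five state variables: the densities of cyanobacteria (``N_CB``)
and sulfur-reducing bacteria (``N_SB``), the concentrations of the two
inhibitory substrates oxygen (``O``) and sulfide (``S``), and the shared
nutrient phosphorus (``P``).  Each group grows on phosphorus following Monod
kinetics and is inhibited by the substrate the *other* group produces, which
closes a mutual-inhibition feedback loop and makes oxic and anoxic states
alternative attractors.  Substrates relax toward fixed background
concentrations at first-order exchange rates (the "diffusivities" ``a_O`` and
``a_S``), and oxygen and sulfide annihilate each other through an abiotic
oxidation term ``c*O*S``.

All rates are per hour, all concentrations in micromolar, densities in
cells per litre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "SystemState",
    "monod_growth",
    "haldane_inhibition",
    "derivatives",
    "symmetric_default_parameters",
    "mirror_state",
]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and background concentrations of the five-variable system.

    Immutable: asymmetric configurations are produced with :meth:`with_overrides`
    (copy-with-override), never by mutation, so parameter scans cannot leak state.

    Attributes
    ----------
    g_max : float
        Maximum specific growth rate shared by both groups, h^-1.
    k_P : float
        Half-saturation constant on phosphorus, μM (shared).
    H_S : float
        Half-inhibition constant of sulfide acting on cyanobacteria, μM.
    H_O : float
        Half-inhibition constant of oxygen acting on sulfur-reducing bacteria, μM.
    y_P : float
        Growth yield on phosphorus, cells μM^-1 (shared).
    p_O : float
        Oxygen produced per cyanobacterial cell grown, μM cell^-1.
    p_S : float
        Sulfide produced per sulfur-bacterium cell grown, μM cell^-1.
    m : float
        Mortality rate, h^-1 (shared).
    alpha_P : float
        Phosphorus exchange rate with the background pool, h^-1.
    O_b, S_b, P_b : float
        Background concentrations of oxygen, sulfide and phosphorus, μM.
    c : float
        Abiotic oxidation coefficient of the O·S reaction, μM^-1 h^-1.
    """

    g_max: float = 0.1
    k_P: float = 0.5
    H_S: float = 100.0
    H_O: float = 100.0
    y_P: float = 1.67e8
    p_O: float = 3.00e-8
    p_S: float = 3.00e-8
    m: float = 0.04
    alpha_P: float = 0.1
    O_b: float = 100.0
    S_b: float = 100.0
    P_b: float = 10.0
    c: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be nonnegative, got {v!r}")
        for name in ("g_max", "m", "y_P", "k_P", "H_S", "H_O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")

    @property
    def is_system_symmetric(self) -> bool:
        """True when the two groups are parameterically interchangeable."""
        return self.H_S == self.H_O and self.p_O == self.p_S

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class SystemState:
    """One point of the five-dimensional state space.

    ``N_CB``/``N_SB`` in cells L^-1, ``O``/``S``/``P`` in μM.
    """

    N_CB: float
    N_SB: float
    O: float
    S: float
    P: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"state component {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"state component {f.name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.N_CB, self.N_SB, self.O, self.S, self.P], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(v) for v in y))

    def mirror(self) -> "SystemState":
        """Swap the roles of the two groups and their substrates."""
        return SystemState(self.N_SB, self.N_CB, self.S, self.O, self.P)

    def __iter__(self) -> Iterator[float]:
        yield from (self.N_CB, self.N_SB, self.O, self.S, self.P)


def mirror_state(state: SystemState) -> SystemState:
    """Functional alias of :meth:`SystemState.mirror`."""
    return state.mirror()


def monod_growth(g_max: float, k_P: float, P: float) -> float:
    """Saturating growth rate ``g_max * P / (k_P + P)`` in h^-1.

    Monotone nondecreasing in ``P``, bounded by ``g_max``; equals ``g_max/2``
    at ``P == k_P``.
    """
    if g_max < 0 or P < 0:
        raise ValueError("monod_growth requires g_max >= 0 and P >= 0")
    if k_P <= 0:
        raise ValueError("monod_growth requires k_P > 0")
    return g_max * P / (k_P + P)


def haldane_inhibition(H: float, X: float) -> float:
    """Growth-reduction factor ``1 / (1 + X/H)`` of an inhibitor at concentration X.

    Dimensionless, in (0, 1]; equals exactly 0.5 when the inhibitor sits at its
    half-inhibition constant ``H``.
    """
    if H <= 0:
        raise ValueError("haldane_inhibition requires H > 0")
    if X < 0:
        raise ValueError("haldane_inhibition requires X >= 0")
    return 1.0 / (1.0 + X / H)


def _rhs(y: np.ndarray, p: ModelParameters, a_O: float, a_S: float) -> np.ndarray:
    """Raw right-hand side on a plain array [N_CB, N_SB, O, S, P].

    Hot path for the integrator: no validation, no dataclass construction.
    """
    N_CB, N_SB, O, S, P = y
    g = p.g_max * P / (p.k_P + P)
    h_S = 1.0 / (1.0 + S / p.H_S)
    h_O = 1.0 / (1.0 + O / p.H_O)
    growth_CB = g * h_S * N_CB
    growth_SB = g * h_O * N_SB
    oxid = p.c * (O * S)
    return np.array(
        [
            growth_CB - p.m * N_CB,
            growth_SB - p.m * N_SB,
            p.p_O * growth_CB - oxid + a_O * (p.O_b - O),
            p.p_S * growth_SB - oxid + a_S * (p.S_b - S),
            -(growth_CB + growth_SB) / p.y_P + p.alpha_P * (p.P_b - P),
        ]
    )


def derivatives(
    state: SystemState, params: ModelParameters, a_O: float, a_S: float
) -> SystemState:
    """Time-derivatives of the five state variables.

    Growth of each group is Monod in phosphorus multiplied by the inhibition
    factor of the opposing substrate; substrate production is proportional to
    realized growth; both substrates are destroyed by the abiotic oxidation
    term and exchanged with their backgrounds at rates ``a_O``/``a_S``.

    Returns the derivative vector packaged as a :class:`SystemState`-shaped
    record (components may be negative; they are rates, not a state).
    """
    if a_O < 0 or a_S < 0:
        raise ValueError("diffusivities must be >= 0")
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state component")
    d = _rhs(y, params, a_O, a_S)
    # bypass SystemState's nonnegativity check: derivatives are signed
    out = object.__new__(SystemState)
    for name, v in zip(("N_CB", "N_SB", "O", "S", "P"), d):
        object.__setattr__(out, name, float(v))
    return out


def symmetric_default_parameters() -> ModelParameters:
    """The symmetric reference configuration.

    Both groups share every biotic rate, the two half-inhibition constants are
    equal (100 μM) and the two production constants are equal (3e-8 μM/cell),
    so the model is invariant under the group/substrate swap.
    """
    p = ModelParameters()
    assert p.is_system_symmetric
    return p
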