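"""Modified Lotka-Volterra predator-prey model with microplastic toxicant burden.

The state is the 4-vector ``(x1, x2, C1, C2)``: prey density, predator density,
and the mean internal microplastic concentration of prey and predator. The
populations follow classical Lotka-Volterra kinetics with three feeding-decline
corrections (``d1`` on prey growth, ``d2`` on predator gain, ``d3`` on predation
loss) and a linear toxicological mortality term per unit internal burden
(``r11*C1`` for prey, ``r21*C2`` for predator):

    dx1/dt = x1 * [(r10 - d1) - r11*C1 - (a1 - d3)*x2]
    dx2/dt = x2 * [-r20 - r21*C2 + (a2 - d2)*x1]
    dC1/dt = S1*CE - g1
    dC2/dt = S2*CE + k*C1 - g2

subject to x1, x2, C1, C2 >= 0. Uptake is proportional to the (constant)
environmental concentration ``CE``; egestion (``g1``, ``g2``) is a constant
removal rate independent of the internal burden, and ``k*C1`` is the trophic
transfer (bioaccumulation) of prey burden into the predator. Because the toxin
subsystem is decoupled from the densities, it admits a closed-form solution
that serves as an exact oracle for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "State",
    "ValidationError",
    "validate_params",
    "derivatives",
    "rhs",
    "equilibrium_toxfree",
    "lv_invariant",
    "toxin_closed_form",
]


class ValidationError(ValueError):
    """Raised when model parameters violate the model's sign structure."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the model plus the environmental concentration.

    Rates are per month; densities in No./m^3; internal concentrations in the
    same abstract concentration units as ``CE`` (particles/m^3).
    """

    r10: float = 4.1     # intrinsic prey growth rate without toxicity
    r20: float = 4.0     # natural predator mortality rate
    r11: float = 0.0     # toxicological response intensity of prey
    r21: float = 0.0     # toxicological response intensity of predator
    a1: float = 0.052    # predation loss coefficient on prey
    a2: float = 0.052    # predator gain coefficient from feeding
    d1: float = 0.1      # decline in prey feeding ability (reduces r10)
    d2: float = 0.002    # decline in predatory performance (reduces a2)
    d3: float = 0.002    # decline in predation pressure on prey (reduces a1)
    S1: float = 0.042    # particle-selection/uptake coefficient of prey
    S2: float = 0.039    # particle-selection/uptake coefficient of predator
    g1: float = 1.2      # microplastic egestion rate of prey
    g2: float = 1.3      # microplastic egestion rate of predator
    k: float = 2.0       # bioaccumulation transfer coefficient prey -> predator
    CE: float = 30.0     # environmental microplastic concentration, constant

    # effective rates after the feeding-decline corrections
    @property
    def prey_growth_eff(self) -> float:
        return self.r10 - self.d1

    @property
    def predation_eff(self) -> float:
        return self.a1 - self.d3

    @property
    def conversion_eff(self) -> float:
        return self.a2 - self.d2

    def violations(self) -> list[str]:
        return validate_params(self)

    def validate(self) -> "ModelParameters":
        """Return self if valid, else raise naming the violated constraint."""
        v = validate_params(self)
        if v:
            raise ValidationError("; ".join(v))
        return self

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class State:
    """System state at one time: densities and internal burdens, all >= 0."""

    t: float
    x1: float
    x2: float
    C1: float
    C2: float

    def __post_init__(self) -> None:
        if min(self.x1, self.x2, self.C1, self.C2) < 0:
            raise ValueError("state components x1, x2, C1, C2 must be nonnegative")

    @property
    def y(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.C1, self.C2], dtype=float)


def validate_params(params: ModelParameters) -> list[str]:
    """Check the model's sign structure; return one message per violation.

    Empty list means the parameter set is valid.
    """
    out: list[str] = []
    for name in ("r10", "r20", "a1", "a2"):
        if getattr(params, name) <= 0:
            out.append(f"{name} must be positive")
    for name in ("r11", "r21", "d1", "d2", "d3", "S1", "S2", "g1", "g2", "k", "CE"):
        if getattr(params, name) < 0:
            out.append(f"{name} must be nonnegative")
    # effective rates must preserve the predator-prey sign structure
    if params.r10 - params.d1 <= 0:
        out.append("r10 - d1 must be positive")
    if params.a1 - params.d3 <= 0:
        out.append("a1 - d3 must be positive")
    if params.a2 - params.d2 <= 0:
        out.append("a2 - d2 must be positive")
    return out


def rhs(t: float, y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Raw vector field (no nonnegativity projection) at state ``y``.

    ``y`` is ``(x1, x2, C1, C2)``. Vectorised over trailing axes of ``y``.
    """
    x1, x2, C1, C2 = y
    p = params
    dx1 = x1 * ((p.r10 - p.d1) - p.r11 * C1 - (p.a1 - p.d3) * x2)
    dx2 = x2 * (-p.r20 - p.r21 * C2 + (p.a2 - p.d2) * x1)
    dC1 = p.S1 * p.CE - p.g1
    dC2 = p.S2 * p.CE + p.k * C1 - p.g2
    return np.array([dx1, dx2, np.broadcast_to(dC1, np.shape(dx1)), dC2], dtype=float)


def derivatives(state: State, params: ModelParameters) -> np.ndarray:
    """Raw rates (dx1/dt, dx2/dt, dC1/dt, dC2/dt) at a validated state.

    This is the field before any nonnegativity projection; the projection is
    applied by the integrator.
    """
    params.validate()
    return rhs(state.t, state.y, params)


def equilibrium_toxfree(params: ModelParameters) -> tuple[float, float]:
    """Nontrivial fixed point of the toxin-free populations.

    With C1 = C2 = 0 (or r11 = r21 = 0) the population equations reduce to the
    classical Lotka-Volterra pair with effective rates; its interior fixed
    point is x1* = r20/(a2-d2), x2* = (r10-d1)/(a1-d3).
    """
    params.validate()
    return params.r20 / params.conversion_eff, params.prey_growth_eff / params.predation_eff


def lv_invariant(x1: float, x2: float, params: ModelParameters) -> float:
    """First integral H of the toxin-free system, used as an accuracy oracle.

    H = (a2-d2)*x1 - r20*ln(x1) + (a1-d3)*x2 - (r10-d1)*ln(x2) is constant
    along exact toxin-free orbits and attains its global minimum at the
    interior fixed point.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("lv_invariant requires strictly positive densities")
    p = params
    H = (p.conversion_eff * x1 - p.r20 * np.log(x1)
         + p.predation_eff * x2 - p.prey_growth_eff * np.log(x2))
    return float(H) if H.ndim == 0 else H


def toxin_closed_form(
    t: float | np.ndarray, params: ModelParameters, clamped: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic solution of the toxin subsystem from C1(0) = C2(0) = 0.

    The burden equations do not depend on the densities, so they integrate in
    closed form: C1 is linear in t and C2 quadratic. With ``clamped`` (the
    default, matching the integrator's projection) a component is held at zero
    while its raw rate is negative and follows the unclamped branch afterwards.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("toxin_closed_form requires t >= 0")
    p = params
    alpha = p.S1 * p.CE - p.g1          # raw C1 rate (constant)
    beta = p.S2 * p.CE - p.g2           # raw C2 rate at C1 = 0

    if not clamped:
        C1 = alpha * t
        C2 = beta * t + 0.5 * p.k * alpha * t**2
        return C1, C2

    a = max(alpha, 0.0)                 # clamped C1 slope
    C1 = a * t
    if beta >= 0:
        C2 = beta * t + 0.5 * p.k * a * t**2
    elif p.k * a > 0:
        # raw C2 rate beta + k*a*t turns positive at t*; clamped at 0 before
        t_star = -beta / (p.k * a)
        tau = np.maximum(t - t_star, 0.0)
        C2 = beta * tau + 0.5 * p.k * a * (np.maximum(t, t_star) ** 2 - t_star**2)
    else:
        C2 = np.zeros_like(t)
    return C1, C2
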