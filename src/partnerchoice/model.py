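"""Analytic model of iterated partner choice in an iterated Stag hunt.

A focal individual repeatedly chooses partners from a population of
unconditional cooperators and defectors, each carrying one of two
perceptible colors (purple or teal).  The focal is boundedly rational,
described by three probabilities:

``omega`` (awareness)
    probability of identifying and picking a cooperator when forced to
    choose a new partner;
``s`` (stickiness)
    probability of re-pairing with the previous partner after that
    partner cooperated;
``b`` (color bias)
    probability of picking a purple partner when neither stickiness nor
    awareness resolves the choice.

The population is summarised by the cooperator proportions ``rho``
(among purple agents) and ``tau`` (among teal agents).

The state of the process is the association distribution ``P(i)`` over
the four partner types, kept in the fixed canonical order

    ((purple, coop), (purple, defect), (teal, coop), (teal, defect)).

``P(i)`` evolves by an affine first-order recursion: with probability
``s * gamma(i)`` the focal keeps a cooperating partner (whose color
distribution is the cooperator-conditional ``g(i)``), otherwise it draws
a fresh partner from ``nu = omega * C + (1 - omega) * P(0)``.  The
cooperator mass ``gamma(i) = P_pc(i) + P_tc(i)`` obeys an autonomous
affine recursion with geometric closed form

    gamma(i) = e * (1 - f**i) / (1 - f) + f**i * gamma0,

with ``e = 1 - (1 - omega) * (1 - gamma0)`` and
``f = s * (1 - omega) * (1 - gamma0)``, converging geometrically to
``e / (1 - f)``.  Both routes are implemented so that each can check the
other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PC",
    "PD",
    "TC",
    "TD",
    "TYPE_LABELS",
    "DegeneratePopulationError",
    "FocalParams",
    "PopulationParams",
    "GammaParams",
    "as_distribution",
    "swap_colors",
    "initial_distribution",
    "cooperator_color_distribution",
    "new_partner_distribution",
    "cooperator_conditional",
    "step",
    "trajectory",
    "gamma_closed_form",
    "gamma_limit",
]

# Canonical partner-type indices: (color, strategy) with purple before teal
# and cooperator before defector.  Even index <=> cooperator.
PC, PD, TC, TD = 0, 1, 2, 3
TYPE_LABELS = ("purple_coop", "purple_defect", "teal_coop", "teal_defect")

#: Tolerance separating float round-off from genuine probability-mass bugs.
SUM_TOL = 1e-12

#: Below this distance from 1, the geometric-sum denominator (1 - f) is
#: treated as zero and the limit form of the closed form is used.
_F_ONE_TOL = 1e-14


class DegeneratePopulationError(ValueError):
    """Raised when an operation needs cooperators but none have mass."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class FocalParams:
    """Awareness, stickiness and purple-bias of the focal individual."""

    omega: float
    s: float
    b: float

    def __post_init__(self) -> None:
        _check_prob("omega", self.omega)
        _check_prob("s", self.s)
        _check_prob("b", self.b)


@dataclass(frozen=True)
class PopulationParams:
    """Cooperator proportions by color: ``rho`` purple, ``tau`` teal."""

    rho: float
    tau: float

    def __post_init__(self) -> None:
        _check_prob("rho", self.rho)
        _check_prob("tau", self.tau)


@dataclass(frozen=True)
class GammaParams:
    """Coefficients of the affine recursion for the cooperator mass.

    ``gamma(i+1) = e + f * gamma(i) - e * f / s`` reduces, after
    substituting the generating parameters, to the intercept/rate pair

        e = 1 - (1 - omega) * (1 - gamma0)
        f = s * (1 - omega) * (1 - gamma0)

    with ``0 <= f <= 1``.
    """

    gamma0: float
    e: float
    f: float

    def __post_init__(self) -> None:
        _check_prob("gamma0", self.gamma0)
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f!r}")

    @classmethod
    def from_focal(cls, focal: FocalParams, gamma0: float) -> "GammaParams":
        _check_prob("gamma0", gamma0)
        defect0 = (1.0 - focal.omega) * (1.0 - gamma0)
        return cls(gamma0=gamma0, e=1.0 - defect0, f=focal.s * defect0)


def as_distribution(vec, tol: float = SUM_TOL) -> np.ndarray:
    """Validate and return ``vec`` as a length-4 probability vector.

    Entries within ``tol`` of the bounds of [0, 1] are clipped; anything
    further out, or a total mass differing from 1 by more than ``tol``,
    raises ``ValueError`` — round-off is absorbed, logic errors are not.
    """
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected a length-4 vector, got shape {arr.shape}")
    if np.any(arr < -tol) or np.any(arr > 1.0 + tol):
        raise ValueError(f"entries outside [0, 1] beyond tolerance: {arr!r}")
    total = float(arr.sum())
    if abs(total - 1.0) > tol:
        raise ValueError(f"probabilities sum to {total!r}, not 1")
    return np.clip(arr, 0.0, 1.0)


def swap_colors(dist: np.ndarray) -> np.ndarray:
    """Exchange purple and teal entries of a partner-type vector."""
    return np.asarray(dist)[[TC, TD, PC, PD]]


def initial_distribution(focal: FocalParams, pop: PopulationParams) -> np.ndarray:
    """First-iteration choice P(0): color by bias ``b``, strategy by prevalence.

    Returns ``(b*rho, b*(1-rho), (1-b)*tau, (1-b)*(1-tau))``.
    """
    b, rho, tau = focal.b, pop.rho, pop.tau
    return as_distribution(
        [b * rho, b * (1.0 - rho), (1.0 - b) * tau, (1.0 - b) * (1.0 - tau)]
    )


def cooperator_color_distribution(pop: PopulationParams) -> np.ndarray:
    """Color distribution C of a partner chosen among cooperators.

    Mass sits only on the cooperator slots, split by how prevalent
    cooperation is in each color: ``(rho/(rho+tau), 0, tau/(rho+tau), 0)``.
    """
    total = pop.rho + pop.tau
    if total <= 0.0:
        raise DegeneratePopulationError(
            "no cooperators in the population (rho + tau = 0)"
        )
    return as_distribution([pop.rho / total, 0.0, pop.tau / total, 0.0])


def new_partner_distribution(focal: FocalParams, pop: PopulationParams) -> np.ndarray:
    """Fresh-partner distribution ``nu = omega * C + (1 - omega) * P(0)``.

    When ``omega == 0`` the cooperator component never fires, so a
    population without cooperators is then acceptable.
    """
    p0 = initial_distribution(focal, pop)
    if focal.omega == 0.0:
        return p0
    c = cooperator_color_distribution(pop)
    return as_distribution(focal.omega * c + (1.0 - focal.omega) * p0)


def cooperator_conditional(P: np.ndarray) -> np.ndarray:
    """Color distribution g of the partner given that it cooperates.

    Normalises the cooperator entries of ``P`` by the cooperator mass
    ``gamma = P_pc + P_tc``; undefined (raises) when ``gamma == 0``.
    """
    P = as_distribution(P)
    gamma = P[PC] + P[TC]
    if gamma <= 0.0:
        raise DegeneratePopulationError(
            "cooperator mass is zero; the conditional is undefined"
        )
    return as_distribution([P[PC] / gamma, 0.0, P[TC] / gamma, 0.0])


def step(P_i: np.ndarray, focal: FocalParams, pop: PopulationParams) -> np.ndarray:
    """One iteration of the partner-choice recursion.

    ``P(i+1) = (1 - s*gamma(i)) * nu + s*gamma(i) * g(i)`` where
    ``gamma(i)`` is the cooperator mass of ``P_i``.  When the sticky
    term has zero coefficient, ``g`` need not (and cannot always) be
    evaluated; the step then returns ``nu``.
    """
    P_i = as_distribution(P_i)
    gamma = P_i[PC] + P_i[TC]
    nu = new_partner_distribution(focal, pop)
    keep = focal.s * gamma
    if keep == 0.0:
        return nu
    g = cooperator_conditional(P_i)
    return as_distribution((1.0 - keep) * nu + keep * g)


def trajectory(
    focal: FocalParams, pop: PopulationParams, n_iters: int
) -> list[np.ndarray]:
    """Iterate the recursion, returning ``[P(0), P(1), ..., P(n_iters)]``."""
    if n_iters < 0:
        raise ValueError("n_iters must be nonnegative")
    out = [initial_distribution(focal, pop)]
    for _ in range(n_iters):
        out.append(step(out[-1], focal, pop))
    return out


def gamma_closed_form(focal: FocalParams, gamma0: float, i: int) -> float:
    """Closed-form cooperator-pairing probability at iteration ``i``.

    ``gamma(i) = e * (1 - f**i) / (1 - f) + f**i * gamma0``.  The
    degenerate case ``f == 1`` (only reachable at s=1, omega=0,
    gamma0=0, where e=0) uses the continuity limit ``e*i + gamma0``.
    """
    if i < 0:
        raise ValueError("iteration index must be nonnegative")
    gp = GammaParams.from_focal(focal, gamma0)
    if abs(1.0 - gp.f) < _F_ONE_TOL:
        value = gp.e * i + gp.gamma0
    else:
        fi = gp.f**i
        value = gp.e * (1.0 - fi) / (1.0 - gp.f) + fi * gp.gamma0
    if not -SUM_TOL <= value <= 1.0 + SUM_TOL:
        raise AssertionError(f"gamma({i}) = {value!r} escaped [0, 1]")
    return float(min(max(value, 0.0), 1.0))


def gamma_limit(focal: FocalParams, gamma0: float) -> float:
    """Geometric limit ``e / (1 - f)`` of the cooperator mass."""
    gp = GammaParams.from_focal(focal, gamma0)
    if abs(1.0 - gp.f) < _F_ONE_TOL:
        raise DegeneratePopulationError("f = 1: the recursion has no fixed point")
    return gp.e / (1.0 - gp.f)
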