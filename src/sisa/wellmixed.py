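"""Well-mixed (mean-field) SISa dynamics.

For a population in which every individual effectively contacts ``k``
others, the infected fraction ``i`` obeys

    di/dt = a (1 - i) + beta k i (1 - i) - g i

whose unique equilibrium in [0, 1] is the admissible root of the quadratic
``a (1 - i) + beta k i (1 - i) = g i``.  With ``a > 0`` the equilibrium is
strictly positive for every ``beta`` and ``g``: spontaneous infection
removes the classic epidemic threshold.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .params import DerivedQuantities, SISaParams

__all__ = [
    "wellmixed_rhs",
    "steady_state_wellmixed",
    "integrate_wellmixed",
    "basic_reproductive_ratio",
    "derived_quantities",
]

_BOUNDARY_TOL = 1e-12


def wellmixed_rhs(i: float, params: SISaParams, k: float) -> float:
    """Time derivative of the infected fraction at prevalence ``i``.

    ``k`` is the mean number of contacts per individual; the transmission
    pressure on a susceptible is ``beta * k * i``.
    """
    if not (0.0 <= i <= 1.0):
        raise ValueError(f"infected fraction must lie in [0, 1], got {i}")
    if k < 0:
        raise ValueError(f"mean contacts k must be non-negative, got {k}")
    s = 1.0 - i
    return params.a * s + params.beta * k * i * s - params.g * i


def steady_state_wellmixed(params: SISaParams, k: float) -> float:
    """Equilibrium infected fraction of the well-mixed SISa model.

    Solves ``a(1-i) + beta*k*i*(1-i) - g*i = 0`` for the root in [0, 1].
    Strictly positive whenever ``a > 0``; equals ``a/(a+g)`` when
    ``beta*k = 0``.
    """
    if k < 0:
        raise ValueError(f"mean contacts k must be non-negative, got {k}")
    if params.is_null:
        raise ValueError("all-zero parameter set has no defined steady state")
    a, g, bk = params.a, params.g, params.beta * k
    if bk == 0.0:
        if a + g == 0.0:
            raise ValueError("a = g = 0 with no transmission: steady state undefined")
        return a / (a + g)
    # bk * i^2 + (a + g - bk) * i - a = 0; the "+" root is the admissible one.
    b = a + g - bk
    disc = b * b + 4.0 * bk * a
    if b > 0:
        # stable form: avoids cancellation when bk << a + g
        root = 2.0 * a / (b + math.sqrt(disc))
    else:
        root = (-b + math.sqrt(disc)) / (2.0 * bk)
    if not (-_BOUNDARY_TOL <= root <= 1.0 + _BOUNDARY_TOL):
        raise RuntimeError(f"no steady-state root in [0, 1]: got {root}")
    return min(max(root, 0.0), 1.0)


class Trajectory(NamedTuple):
    """Time grid and infected fraction of an integrated epidemic."""

    t: np.ndarray
    i: np.ndarray


def integrate_wellmixed(
    params: SISaParams,
    k: float,
    i0: float,
    t_end: float,
    n_points: int = 500,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the well-mixed SISa ODE from prevalence ``i0`` to ``t_end`` years."""
    if not (math.isfinite(i0) and math.isfinite(t_end)):
        raise ValueError("i0 and t_end must be finite")
    if not (0.0 <= i0 <= 1.0):
        raise ValueError(f"initial infected fraction must lie in [0, 1], got {i0}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda _t, y: [wellmixed_rhs(min(max(y[0], 0.0), 1.0), params, k)],
        (0.0, t_end),
        [i0],
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"integration failed: {sol.message}")
    i = np.clip(sol.y[0], 0.0, 1.0)
    return Trajectory(t=sol.t, i=i)


def basic_reproductive_ratio(params: SISaParams, k: float) -> float:
    """Basic reproductive ratio ``R0 = beta * k / g``.

    Expected secondary infections caused by one infected individual with
    ``k`` susceptible contacts before recovery.  Independent of ``a``.
    """
    if params.g <= 0:
        raise ValueError("basic reproductive ratio undefined for g = 0")
    if k < 0:
        raise ValueError(f"mean contacts k must be non-negative, got {k}")
    return params.beta * k / params.g


def derived_quantities(
    params: SISaParams, k: float, influence_convention: str = "competing"
) -> DerivedQuantities:
    """Lifetime, cycle length, influence and R0 for a parameter set.

    ``influence_convention`` selects how the per-edge transmission
    probability is computed:

    - ``"competing"`` (default): ``beta / (beta + g)``, the exact
      probability that an exponential transmission clock fires before the
      exponential recovery clock.
    - ``"ratio"``: ``beta / g``, the expected number of transmissions per
      edge over the infected lifetime (an upper bound on the probability,
      adequate when ``beta << g``).
    """
    lifetime = 1.0 / params.g if params.g > 0 else math.inf
    cycle = 1.0 / params.a if params.a > 0 else math.inf
    if influence_convention == "competing":
        denom = params.beta + params.g
        influence = params.beta / denom if denom > 0 else 0.0
    elif influence_convention == "ratio":
        influence = params.beta / params.g if params.g > 0 else math.inf
    else:
        raise ValueError(f"unknown influence convention {influence_convention!r}")
    r0 = basic_reproductive_ratio(params, k) if params.g > 0 else math.inf
    return DerivedQuantities(r0=r0, lifetime=lifetime, cycle=cycle, influence=influence)
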