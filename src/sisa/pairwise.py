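"""Pair-approximation (moment-closure) SISa dynamics on a network.

Beyond the counts of susceptible and infected individuals, the pairwise
description tracks the number of adjacent node-state pairs.  Counts use the
*ordered* convention: each undirected edge contributes two ordered pairs,
so ``[SS] + 2[SI] + [II] = 2E`` where ``[SI]`` is the ordered (S, I) count
and equals the number of unordered S-I edges.

Triples ``[XYZ]`` (X adjacent to Y adjacent to Z, X != Z allowed to be any
node other than the centre's partner) are never stored; they are eliminated
with the transitivity-corrected moment closure

    [XYZ] ~= ((k-1)/k) * ([XY][YZ]/[Y]) * ((1-phi) + phi*N*[XZ]/(k*[X][Z]))

where ``k`` is the (common) number of contacts per node and ``phi`` the
network transitivity.  The reduced system evolves ``(I, [SI], [II])``;
``S = N - I`` and ``[SS] = 2E - 2[SI] - [II]`` follow from conservation.

Internally the module works with *unordered* edge-class counts
``P_ss = [SS]/2``, ``P_si = [SI]``, ``P_ii = [II]/2`` which sum to ``E``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import SISaParams
from .wellmixed import steady_state_wellmixed

__all__ = [
    "PairwiseState",
    "NetworkSummary",
    "CorrelationSet",
    "random_mixing_pairs",
    "closure_triples",
    "pairwise_rhs",
    "integrate_pairwise",
    "steady_state_pairwise",
    "closed_form_steady_state",
    "correlations_from_pairs",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Summary statistics entering the pairwise equations.

    ``k`` is the contacts per node (mean out-degree for directed
    nomination networks), ``phi`` the transitivity (triangles / triples).
    """

    N: float
    k: float
    phi: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"population size must be positive, got {self.N}")
        if self.k < 0:
            raise ValueError(f"mean degree must be non-negative, got {self.k}")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"transitivity must lie in [0, 1], got {self.phi}")

    @property
    def E(self) -> float:
        """Undirected edge count implied by ``k = 2E/N``."""
        return self.k * self.N / 2.0


@dataclass(frozen=True)
class PairwiseState:
    """Node and ordered-pair counts ``(S, I, SS, SI, II)``.

    ``SS`` and ``II`` are full ordered counts (twice the unordered edge
    count); ``SI`` counts ordered (S, I) pairs and therefore equals the
    unordered S-I edge count.
    """

    S: float
    I: float
    SS: float
    SI: float
    II: float

    def __post_init__(self) -> None:
        for name in ("S", "I", "SS", "SI", "II"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"pair count {name!r} must be non-negative")

    @property
    def N(self) -> float:
        return self.S + self.I

    @property
    def two_E(self) -> float:
        return self.SS + 2.0 * self.SI + self.II


class CorrelationSet(NamedTuple):
    """Spatial correlations ``C_SS, C_SI, C_II``; 1 means random placement."""

    c_ss: float
    c_si: float
    c_ii: float


def random_mixing_pairs(i: float, net: NetworkSummary) -> PairwiseState:
    """Pair counts for states assigned independently at prevalence ``i``.

    All spatial correlations equal 1 for this state, which is the natural
    initial condition for an epidemic started from an unclustered seed.
    """
    if not (0.0 <= i <= 1.0):
        raise ValueError(f"prevalence must lie in [0, 1], got {i}")
    N, two_e = net.N, 2.0 * net.E
    s = 1.0 - i
    return PairwiseState(
        S=s * N,
        I=i * N,
        SS=two_e * s * s,
        SI=two_e * s * i,
        II=two_e * i * i,
    )


def closure_triples(
    pairs: PairwiseState, net: NetworkSummary, x: str, y: str, z: str
) -> float:
    """Moment-closure estimate of the ordered triple count ``[XYZ]``.

    States are given as ``"S"`` or ``"I"``.  Returns 0 when the centre
    class ``[Y]`` is empty (no triples can pass through an empty class).
    """
    counts = {"S": pairs.S, "I": pairs.I}
    ordered = {
        ("S", "S"): pairs.SS,
        ("I", "I"): pairs.II,
        ("S", "I"): pairs.SI,
        ("I", "S"): pairs.SI,
    }
    for state in (x, y, z):
        if state not in counts:
            raise ValueError(f"unknown state {state!r}")
    k, phi, N = net.k, net.phi, net.N
    if k <= 0:
        raise ValueError("closure requires k > 0")
    Y = counts[y]
    if Y <= 0:
        return 0.0
    xy, yz = ordered[(x, y)], ordered[(y, z)]
    if xy <= 0.0 or yz <= 0.0:
        return 0.0
    base = (k - 1.0) / k * xy * yz / Y
    if phi == 0.0:
        return base
    X, Z = counts[x], counts[z]
    if X <= 0 or Z <= 0:
        return 0.0
    xz = ordered[(x, z)]
    return base * ((1.0 - phi) + phi * N * xz / (k * X * Z))


def _rhs_reduced(y: np.ndarray, params: SISaParams, net: NetworkSummary) -> np.ndarray:
    """Derivatives of ``(I, P_si, P_ii)`` (unordered edge-class counts)."""
    N, E = net.N, net.E
    I, p_si, p_ii = y
    I = min(max(I, 0.0), N)
    S = N - I
    p_si = max(p_si, 0.0)
    p_ii = max(p_ii, 0.0)
    p_ss = max(E - p_si - p_ii, 0.0)
    a, g, beta = params.a, params.g, params.beta

    state = PairwiseState(S=S, I=I, SS=2.0 * p_ss, SI=p_si, II=2.0 * p_ii)
    t_isi = closure_triples(state, net, "I", "S", "I")
    t_iss = closure_triples(state, net, "I", "S", "S")

    dI = a * S + beta * p_si - g * I
    dp_si = (
        a * (2.0 * p_ss - p_si)
        + g * (2.0 * p_ii - p_si)
        + beta * (t_iss - t_isi - p_si)
    )
    dp_ii = a * p_si - 2.0 * g * p_ii + beta * (p_si + t_isi)
    return np.array([dI, dp_si, dp_ii])


def pairwise_rhs(
    state: PairwiseState, params: SISaParams, net: NetworkSummary
) -> dict[str, float]:
    """Time derivatives of all five pairwise variables.

    The ``SS`` derivative is implied by edge conservation
    ``d[SS]/dt + 2 d[SI]/dt + d[II]/dt = 0`` and node conservation
    ``dS/dt = -dI/dt``.
    """
    if abs(state.N - net.N) > 1e-6 * max(net.N, 1.0):
        raise ValueError(
            f"state population {state.N} inconsistent with network N={net.N}"
        )
    if abs(state.two_E - 2.0 * net.E) > 1e-6 * max(2.0 * net.E, 1.0):
        raise ValueError(
            f"pair counts sum to {state.two_E}, expected 2E = {2.0 * net.E}"
        )
    y = np.array([state.I, state.SI, state.II / 2.0])
    dI, dp_si, dp_ii = _rhs_reduced(y, params, net)
    d_si = dp_si
    d_ii = 2.0 * dp_ii
    d_ss = -2.0 * d_si - d_ii
    return {"S": -dI, "I": dI, "SS": d_ss, "SI": d_si, "II": d_ii}


class PairwiseTrajectory(NamedTuple):
    t: np.ndarray
    i: np.ndarray
    correlations: list["CorrelationSet"]
    states: list[PairwiseState]


def _state_from_reduced(y: np.ndarray, net: NetworkSummary) -> PairwiseState:
    I, p_si, p_ii = y
    I = min(max(float(I), 0.0), net.N)
    p_si = max(float(p_si), 0.0)
    p_ii = max(float(p_ii), 0.0)
    p_ss = max(net.E - p_si - p_ii, 0.0)
    return PairwiseState(S=net.N - I, I=I, SS=2.0 * p_ss, SI=p_si, II=2.0 * p_ii)


def integrate_pairwise(
    params: SISaParams,
    net: NetworkSummary,
    i0: float,
    t_end: float,
    n_points: int = 500,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> PairwiseTrajectory:
    """Integrate the reduced pairwise system from random-mixing pairs at ``i0``."""
    if not (0.0 <= i0 <= 1.0):
        raise ValueError(f"initial prevalence must lie in [0, 1], got {i0}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    init = random_mixing_pairs(i0, net)
    y0 = np.array([init.I, init.SI, init.II / 2.0])
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda _t, y: _rhs_reduced(y, params, net),
        (0.0, t_end),
        y0,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"pairwise integration failed: {sol.message}")
    states = [_state_from_reduced(sol.y[:, j], net) for j in range(sol.y.shape[1])]
    corrs = [correlations_from_pairs(s, net) for s in states]
    i = np.array([s.I / net.N for s in states])
    return PairwiseTrajectory(t=sol.t, i=i, correlations=corrs, states=states)


def steady_state_pairwise(
    params: SISaParams,
    net: NetworkSummary,
    tol: float = 1e-10,
) -> tuple[float, CorrelationSet]:
    """Equilibrium infected fraction and correlations of the pairwise system.

    Found by damped root-finding on the reduced three-variable system,
    initialised at random-mixing pairs consistent with the well-mixed
    equilibrium; falls back to long-time integration if the root-finder
    stalls or leaves the physical region.
    """
    if params.is_null:
        raise ValueError("all-zero parameter set has no defined steady state")
    if net.k == 0 or params.beta == 0:
        # no transmission pressure: unstructured equilibrium, correlations 1
        i_star = steady_state_wellmixed(params, 0.0)
        return i_star, CorrelationSet(1.0, 1.0, 1.0)
    i_guess = steady_state_wellmixed(params, net.k)
    init = random_mixing_pairs(i_guess, net)
    y0 = np.array([init.I, init.SI, init.II / 2.0])
    scale = max(net.N, net.E, 1.0)
    sol = root(
        lambda y: _rhs_reduced(y, params, net) / scale,
        y0,
        method="hybr",
        tol=tol,
    )
    y = sol.x
    ok = (
        sol.success
        and np.all(np.isfinite(y))
        and -1e-9 * net.N <= y[0] <= net.N * (1 + 1e-9)
        and y[1] >= -1e-9 * net.E
        and y[2] >= -1e-9 * net.E
        and y[1] + y[2] <= net.E * (1 + 1e-9)
    )
    if not ok:
        # fall back to relaxation: integrate until derivatives are negligible
        rate = max(params.a + params.g, params.g, params.beta, 1e-6)
        traj = integrate_pairwise(params, net, i_guess, t_end=200.0 / rate, n_points=50)
        last = traj.states[-1]
        y = np.array([last.I, last.SI, last.II / 2.0])
        resid = np.linalg.norm(_rhs_reduced(y, params, net) / scale)
        if resid > 1e-6:
            raise RuntimeError(
                f"pairwise steady state did not converge (residual {resid:.3e})"
            )
    state = _state_from_reduced(y, net)
    corrs = correlations_from_pairs(state, net)
    return state.I / net.N, corrs


def closed_form_steady_state(params: SISaParams, net: NetworkSummary) -> tuple[float, float]:
    """Closed-form pairwise equilibrium ``(i*, C_SI*)`` for ``a = 0``, ``phi = 0``.

    Derived by solving the stationary pairwise system analytically:
    with ``kappa = (k-1)/k`` and ``R = beta*k/g``,

        i* = (R - 1/kappa) / (1 + R - 1/kappa)

    when ``beta*(k-1) > g`` and 0 otherwise (pair approximation restores a
    threshold at ``beta (k-1) = g`` once spontaneous infection is absent).
    """
    if params.a != 0:
        raise ValueError("closed form requires a = 0")
    if net.phi != 0:
        raise ValueError("closed form requires phi = 0")
    if net.k <= 1 or params.g <= 0:
        raise ValueError("closed form requires k > 1 and g > 0")
    kappa = (net.k - 1.0) / net.k
    R = params.beta * net.k / params.g
    excess = R - 1.0 / kappa
    if excess <= 0:
        return 0.0, float("nan")
    i_star = excess / (1.0 + excess)
    # ordered [SI] = S * (k - g / (beta * kappa)); C_SI = N*[SI] / (k*S*I)
    si_per_s = net.k - params.g / (params.beta * kappa)
    c_si = si_per_s / (net.k * i_star)
    return i_star, c_si


def correlations_from_pairs(pairs: PairwiseState, net: NetworkSummary) -> CorrelationSet:
    """Spatial correlations ``C_XY = N^2 [XY] / (2E [X][Y])``.

    Equals 1 in expectation when states are placed uniformly at random.
    Correlations involving an empty class are undefined and reported as NaN.
    """
    N, two_e = net.N, 2.0 * net.E
    if two_e <= 0:
        return CorrelationSet(math.nan, math.nan, math.nan)
    S, I = pairs.S, pairs.I
    c_ss = N * N * pairs.SS / (two_e * S * S) if S > 0 else math.nan
    c_ii = N * N * pairs.II / (two_e * I * I) if I > 0 else math.nan
    c_si = N * N * pairs.SI / (two_e * S * I) if (S > 0 and I > 0) else math.nan
    return CorrelationSet(c_ss=c_ss, c_si=c_si, c_ii=c_ii)
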