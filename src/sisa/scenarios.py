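"""Forecasting and intervention analysis.

Builds on the pairwise equations (deterministic, fast) to answer the
applied questions: what prevalence do the current rates imply at
equilibrium, how long until we get there, how uncertain is the prediction,
and which rate is the most effective intervention target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .params import SISaParams
from .pairwise import (
    NetworkSummary,
    PairwiseTrajectory,
    integrate_pairwise,
    random_mixing_pairs,
    steady_state_pairwise,
    _rhs_reduced,
    _state_from_reduced,
    correlations_from_pairs,
)
from scipy.integrate import solve_ivp

__all__ = [
    "ParameterSchedule",
    "forecast",
    "time_to_equilibrium",
    "uncertainty_band",
    "sensitivity",
    "SensitivityResult",
]


@dataclass(frozen=True)
class ScheduleSegment:
    t_start: float
    t_end: float
    params: SISaParams
    net: NetworkSummary


class ParameterSchedule:
    """Piecewise-constant (rates, network) assignments over a time horizon.

    Segments must be contiguous, non-overlapping and cover the horizon;
    times are decimal years (absolute or relative, the forecast only uses
    differences and breakpoints).
    """

    def __init__(self, segments: Sequence[tuple[float, float, SISaParams, NetworkSummary]]):
        segs = [ScheduleSegment(*s) for s in segments]
        segs.sort(key=lambda s: s.t_start)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        for s in segs:
            if s.t_end <= s.t_start:
                raise ValueError(f"empty segment [{s.t_start}, {s.t_end}]")
        for s1, s2 in zip(segs, segs[1:]):
            if abs(s1.t_end - s2.t_start) > 1e-9:
                raise ValueError(
                    f"schedule gap or overlap between t={s1.t_end} and t={s2.t_start}"
                )
        self.segments = segs

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end


def forecast(
    schedule: ParameterSchedule,
    i0: float,
    t_end: float | None = None,
    points_per_year: float = 10.0,
) -> PairwiseTrajectory:
    """Integrate the pairwise equations through a parameter schedule.

    The state (prevalence and pair correlations) carries across
    breakpoints; when the mean degree changes between segments, pair counts
    are rescaled to the new edge total preserving the spatial correlations.
    A single-segment schedule reproduces :func:`integrate_pairwise` on the
    same grid.
    """
    if t_end is None:
        t_end = schedule.t_end
    if t_end > schedule.t_end + 1e-9:
        raise ValueError(f"t_end {t_end} beyond schedule horizon {schedule.t_end}")
    seg0 = schedule.segments[0]
    times: list[np.ndarray] = []
    prev: list[np.ndarray] = []
    corrs = []
    states = []
    carry = random_mixing_pairs(i0, seg0.net)
    t_cursor = schedule.t_start
    for seg in schedule.segments:
        if t_cursor >= t_end:
            break
        seg_end = min(seg.t_end, t_end)
        duration = seg_end - t_cursor
        n_pts = max(int(round(duration * points_per_year)) + 1, 2)
        net = seg.net
        # re-express carried state on this segment's network, preserving correlations
        if abs(net.E - carry.SS / 2 - carry.SI - carry.II / 2) > 1e-9 * max(net.E, 1):
            c = correlations_from_pairs(carry, NetworkSummary(N=net.N, k=(carry.two_E) / net.N, phi=net.phi))
            i = carry.I / carry.N
            base = random_mixing_pairs(i, net)
            carry = type(carry)(
                S=base.S,
                I=base.I,
                SS=base.SS * (c.c_ss if np.isfinite(c.c_ss) else 1.0),
                SI=base.SI * (c.c_si if np.isfinite(c.c_si) else 1.0),
                II=base.II * (c.c_ii if np.isfinite(c.c_ii) else 1.0),
            )
            # restore edge conservation exactly (correlation scaling can drift)
            tot = carry.SS / 2 + carry.SI + carry.II / 2
            f = net.E / tot
            carry = type(carry)(S=carry.S, I=carry.I, SS=carry.SS * f, SI=carry.SI * f, II=carry.II * f)
        y0 = np.array([carry.I, carry.SI, carry.II / 2.0])
        t_eval = np.linspace(0.0, duration, n_pts)
        sol = solve_ivp(
            lambda _t, y: _rhs_reduced(y, seg.params, net),
            (0.0, duration),
            y0,
            t_eval=t_eval,
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"forecast integration failed in segment at {t_cursor}")
        seg_states = [_state_from_reduced(sol.y[:, j], net) for j in range(sol.y.shape[1])]
        times.append(sol.t + t_cursor)
        prev.append(np.array([s.I / net.N for s in seg_states]))
        corrs.extend(correlations_from_pairs(s, net) for s in seg_states)
        states.extend(seg_states)
        carry = seg_states[-1]
        t_cursor = seg_end
    return PairwiseTrajectory(
        t=np.concatenate(times), i=np.concatenate(prev), correlations=corrs, states=states
    )


def time_to_equilibrium(
    params: SISaParams,
    net: NetworkSummary,
    i0: float,
    tolerance: float = 0.01,
    t_max: float = 2000.0,
) -> float:
    """First time at which prevalence is within ``tolerance`` of equilibrium.

    Integrates the pairwise equations from random-mixing pairs at ``i0``;
    returns 0 if already within tolerance.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    i_star, _ = steady_state_pairwise(params, net)
    if abs(i0 - i_star) < tolerance:
        return 0.0
    traj = integrate_pairwise(params, net, i0, t_end=t_max, n_points=8001)
    inside = np.abs(traj.i - i_star) < tolerance
    if not inside.any():
        raise RuntimeError(f"equilibrium not approached within {t_max} years")
    j = int(np.argmax(inside))
    # refine the crossing linearly between grid points
    if j == 0:
        return float(traj.t[0])
    t0, t1 = traj.t[j - 1], traj.t[j]
    d0 = abs(traj.i[j - 1] - i_star) - tolerance
    d1 = abs(traj.i[j] - i_star) - tolerance
    frac = d0 / (d0 - d1) if d0 != d1 else 0.0
    return float(t0 + frac * (t1 - t0))


def uncertainty_band(
    lo: SISaParams, hi: SISaParams, net: NetworkSummary
) -> tuple[float, float]:
    """Steady-state prevalences at the minimising and maximising parameter sets."""
    i_lo, _ = steady_state_pairwise(lo, net)
    i_hi, _ = steady_state_pairwise(hi, net)
    return (min(i_lo, i_hi), max(i_lo, i_hi))


class SensitivityResult(NamedTuple):
    """Derivatives of equilibrium prevalence with respect to each rate.

    ``per_001`` entries are the absolute change in the *percent* infected
    for a 0.01/yr change in the rate (the conventional intervention axis);
    ``best_intervention`` is the rate with the largest |derivative|.
    """

    dI_da: float
    dI_dbeta: float
    dI_dg: float
    per_001: dict[str, float]
    best_intervention: str


def sensitivity(
    params: SISaParams, net: NetworkSummary, step: float = 1e-4
) -> SensitivityResult:
    """Finite-difference sensitivities of the pairwise equilibrium.

    Central differences; one-sided when the step would push a rate
    negative.  Signs satisfy dI*/da >= 0, dI*/dbeta >= 0, dI*/dg <= 0.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")

    def at(**kw) -> float:
        p = SISaParams(
            a=kw.get("a", params.a), g=kw.get("g", params.g), beta=kw.get("beta", params.beta)
        )
        return steady_state_pairwise(p, net)[0]

    derivs = {}
    for name in ("a", "beta", "g"):
        x = getattr(params, name)
        if x - step < 0:
            derivs[name] = (at(**{name: x + step}) - at(**{name: x})) / step
        else:
            derivs[name] = (at(**{name: x + step}) - at(**{name: x - step})) / (2 * step)
    per_001 = {name: 100.0 * d * 0.01 for name, d in derivs.items()}
    best = max(derivs, key=lambda nm: abs(derivs[nm]))
    return SensitivityResult(
        dI_da=derivs["a"],
        dI_dbeta=derivs["beta"],
        dI_dg=derivs["g"],
        per_001=per_001,
        best_intervention=best,
    )
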