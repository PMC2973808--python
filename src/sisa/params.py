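"""Core parameter and state containers for the SISa contagion model.

The SISa model extends the classic susceptible-infected-susceptible (SIS)
process with an "automatic" (spontaneous) infection channel: a susceptible
individual becomes infected at a constant rate ``a`` regardless of contacts,
at rate ``beta`` per infected contact, and an infected individual recovers
at rate ``g`` independent of contacts.  All rates are per year by package
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SISaParams",
    "PopulationState",
    "DerivedQuantities",
]


@dataclass(frozen=True)
class SISaParams:
    """Rate triple driving SISa dynamics (all per year).

    Parameters
    ----------
    a
        Spontaneous ("automatic") infection rate acting on each susceptible.
    g
        Recovery rate, contact-independent.
    beta
        Transmission rate per infected contact.
    """

    a: float
    g: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("a", "g", "beta"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"rate {name!r} must be finite, got {value}")
            if value < 0:
                raise ValueError(f"rate {name!r} must be non-negative, got {value}")

    @property
    def is_null(self) -> bool:
        """True when all three rates vanish (frozen, degenerate dynamics)."""
        return self.a == 0.0 and self.g == 0.0 and self.beta == 0.0


@dataclass(frozen=True)
class PopulationState:
    """Counts of susceptible and infected individuals in a closed population.

    Birth and death are neglected, so ``S + I = N`` is conserved.
    """

    S: float
    I: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.I < 0:
            raise ValueError(f"state counts must be non-negative: S={self.S}, I={self.I}")

    @property
    def N(self) -> float:
        return self.S + self.I

    @property
    def infected_fraction(self) -> float:
        if self.N == 0:
            raise ValueError("empty population has no infected fraction")
        return self.I / self.N


@dataclass(frozen=True)
class DerivedQuantities:
    """Scalar summaries of a SISa parameter set.

    Attributes
    ----------
    r0
        Basic reproductive ratio ``beta * k / g``.
    lifetime
        Mean time spent infected before recovery, ``1/g`` years
        (``inf`` when ``g = 0``).
    cycle
        Mean time between spontaneous infections, ``1/a`` years
        (``inf`` when ``a = 0``).
    influence
        Probability that an infected individual transmits along a given
        edge before recovering.
    """

    r0: float
    lifetime: float
    cycle: float
    influence: float
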