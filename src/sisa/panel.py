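"""Longitudinal panel data: per-subject binary states at scheduled waves.

A panel couples a subjects x waves state table (``"S"``/``"I"``, NaN for
missing observations) with wave timestamps and a wave-resolved contact
network.  This is the estimator's input: the calibration procedure
regresses wave-to-wave transitions on contact counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import INFECTED, SUSCEPTIBLE, ContactNetwork

__all__ = ["PanelDataset", "read_panel_csv", "write_panel_csv", "bmi_to_state"]


def bmi_to_state(bmi: float) -> str:
    """Binary obesity state from body-mass index: infected iff BMI >= 30 kg/m^2.

    All lower weights (underweight, normal, overweight) are susceptible.
    """
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    return INFECTED if bmi >= 30.0 else SUSCEPTIBLE


@dataclass
class PanelDataset:
    """Subjects x waves state table with wave times and networks.

    ``states``: DataFrame indexed by subject, one column per wave, values
    ``"S"``, ``"I"`` or NaN (missing).  ``networks``: one
    :class:`ContactNetwork` per wave (entries may repeat the same network).
    """

    states: pd.DataFrame
    wave_times: np.ndarray
    networks: list[ContactNetwork | None]

    def __post_init__(self) -> None:
        self.wave_times = np.asarray(self.wave_times, dtype=float)
        if len(self.wave_times) != self.states.shape[1]:
            raise ValueError("one timestamp required per wave")
        if np.any(np.diff(self.wave_times) <= 0):
            raise ValueError("wave times must be strictly increasing")
        if len(self.networks) != len(self.wave_times):
            raise ValueError("one network entry required per wave")
        valid = self.states.stack().dropna().unique()
        bad = set(valid) - {SUSCEPTIBLE, INFECTED}
        if bad:
            raise ValueError(f"states must be binary S/I, found {bad}")

    @property
    def n_waves(self) -> int:
        return self.states.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.states.shape[0]

    def dt(self, wave: int) -> float:
        """Interval in years between ``wave`` and ``wave + 1``."""
        if not (0 <= wave < self.n_waves - 1):
            raise ValueError(f"no interval starting at wave {wave}")
        return float(self.wave_times[wave + 1] - self.wave_times[wave])

    @property
    def mean_dt(self) -> float:
        return float(np.mean(np.diff(self.wave_times)))

    def network_at(self, wave: int) -> ContactNetwork:
        net = self.networks[wave]
        if net is None:
            raise ValueError(f"no network attached for wave {wave}")
        return net


def write_panel_csv(panel: PanelDataset, path) -> None:
    """Write a panel as long-format CSV: subject_id, wave, time, state."""
    rows = []
    for subject, row in panel.states.iterrows():
        for w in range(panel.n_waves):
            state = row.iloc[w]
            rows.append(
                {
                    "subject_id": subject,
                    "wave": w,
                    "time": panel.wave_times[w],
                    "state": "" if pd.isna(state) else state,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panel_csv(
    path,
    networks: Sequence[ContactNetwork] | ContactNetwork | None = None,
) -> PanelDataset:
    """Read a long-format panel CSV (subject_id, wave, time, bmi and/or state).

    When a ``state`` column is absent or empty, states are derived from the
    ``bmi`` column via :func:`bmi_to_state`.  ``networks`` may be a single
    network (reused for every wave) or one per wave.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "wave", "time"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel CSV must have columns {sorted(required)}")
    if "state" in df.columns:
        state = df["state"].where(df["state"].isin([SUSCEPTIBLE, INFECTED]))
    else:
        state = pd.Series(pd.NA, index=df.index, dtype=object)
    if "bmi" in df.columns:
        derived = df["bmi"].map(lambda b: bmi_to_state(b) if pd.notna(b) else pd.NA)
        state = state.fillna(derived)
    df = df.assign(state=state)
    states = df.pivot_table(
        index="subject_id", columns="wave", values="state", aggfunc="first"
    ).sort_index(axis=1)
    times = df.groupby("wave")["time"].mean().sort_index().to_numpy()
    n_waves = states.shape[1]
    if networks is None:
        nets: list[ContactNetwork | None] = [None] * n_waves
    elif isinstance(networks, ContactNetwork):
        nets = [networks] * n_waves
    else:
        nets = list(networks)
    return PanelDataset(states=states, wave_times=times, networks=nets)
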