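"""Synthetic benchmark panels with known ground truth.

Generates a cohort-style contact network, runs the stochastic SISa process
from a stated initial prevalence, snapshots it at exam waves, and packages
the ground-truth rates — so the estimation pipeline can be validated
end-to-end without any external data.  Defaults mirror the obesity
case-study magnitudes: N = 3500 subjects, 7 waves at 4-year spacing,
mean degree 2.8, transitivity 0.64, truth (a, g, beta) =
(0.02, 0.04, 0.005) per year from 14% initial prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .network import ContactNetwork, generate_fhs_like, write_edge_list
from .panel import PanelDataset, write_panel_csv
from .params import SISaParams
from .simulate import sample_panel, simulate_sisa

__all__ = ["BenchmarkPanel", "make_benchmark_panel"]

DEFAULT_TRUTH = SISaParams(a=0.02, g=0.04, beta=0.005)


@dataclass
class BenchmarkPanel:
    """A synthetic panel plus the ground truth that generated it."""

    panel: PanelDataset
    truth: SISaParams
    network: ContactNetwork = field(repr=False)
    i0: float
    seed: int | None

    def truth_record(self) -> dict:
        return {
            "a": self.truth.a,
            "g": self.truth.g,
            "beta": self.truth.beta,
            "i0": self.i0,
            "seed": self.seed,
            "n_subjects": self.panel.n_subjects,
            "waves": self.panel.n_waves,
            "wave_times": list(map(float, self.panel.wave_times)),
        }

    def write(self, panel_path, edges_path, truth_path) -> None:
        """Write panel CSV, edge-list CSV and the truth JSON sidecar."""
        write_panel_csv(self.panel, panel_path)
        write_edge_list(self.network, edges_path)
        with open(truth_path, "w") as fh:
            json.dump(self.truth_record(), fh, indent=2)


def make_benchmark_panel(
    n: int = 3500,
    waves: int = 7,
    wave_spacing: float = 4.0,
    truth: SISaParams = DEFAULT_TRUTH,
    mean_k: float = 2.8,
    phi: float = 0.64,
    p_isolated: float = 0.05,
    i0: float = 0.14,
    dropout: float = 0.0,
    seed: int | None = None,
) -> BenchmarkPanel:
    """Generate a reproducible synthetic panel from known rates.

    ``dropout`` is the per-wave probability that a subject permanently
    leaves the study after their first missed exam (cohort attrition);
    dropped subjects have missing states from that wave on but remain in
    the contact network.
    """
    if waves < 2:
        raise ValueError("a panel needs at least two waves")
    if not (0.0 <= dropout < 1.0):
        raise ValueError(f"dropout must lie in [0, 1), got {dropout}")
    import numpy as np

    rng = np.random.default_rng(seed)
    net_seed, sim_seed, drop_seed = rng.integers(0, 2**31 - 1, size=3)
    net = generate_fhs_like(
        n, mean_k=mean_k, phi_target=phi, p_isolated=p_isolated, seed=int(net_seed)
    )
    t_end = wave_spacing * (waves - 1)
    sim = simulate_sisa(
        net,
        truth,
        initial=i0,
        t_end=t_end + 1e-9,
        seed=int(sim_seed),
        record_dt=max(t_end / 200.0, 0.25),
        record_correlations=False,
    )
    wave_times = [w * wave_spacing for w in range(waves)]
    panel = sample_panel(sim, wave_times)
    if dropout > 0:
        drop_rng = np.random.default_rng(int(drop_seed))
        states = panel.states.copy()
        for idx in range(panel.n_subjects):
            for w in range(1, waves):
                if drop_rng.random() < dropout:
                    states.iloc[idx, w:] = np.nan
                    break
        panel = PanelDataset(
            states=states, wave_times=panel.wave_times, networks=panel.networks
        )
    return BenchmarkPanel(panel=panel, truth=truth, network=net, i0=i0, seed=seed)
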