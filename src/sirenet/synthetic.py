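"""Fixtures and synthetic data: the core network, random PKNs, and expression
matrices simulated from a ground-truth weighted logic network.

The simulator emulates the shape of a two-condition, multi-cell-type
single-nucleus experiment at the point in the pipeline where the models
consume it: node activities on the [0, 1] scale (post-normalization), one
steady state per condition of a known weighted network, plus truncated
Gaussian cell-level noise and identically distributed off-network filler
genes.  It is deliberately not a faithful count-level snRNA-seq simulator (no
dropout, no batch structure); its purpose is ground-truth recovery testing of
differential expression, ILP inference and weight fitting.

All randomness flows from a single master seed through spawned child
sequences, so any component can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from anndata import AnnData

from .network_model import Edge, SignedNetwork, parse_sif
from .procomren import SteadyStateResult, WeightedNetwork, steady_state

__all__ = [
    "SimulationConfig",
    "core_network_fixture",
    "core_channel_scores",
    "generate_random_pkn",
    "simulate_expression",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for :func:`simulate_expression`.

    ``clamps`` maps each condition label to the clamped input-node values
    defining that condition's steady state.
    """

    n_genes: int = 100
    n_cells: int = 100
    cell_types: tuple[str, ...] = ("L23",)
    noise_sd: float = 0.05
    clamps: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"CTL": {}, "CASE": {}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.cell_types:
            raise ValueError("at least one cell type required")


def core_network_fixture() -> SignedNetwork:
    """The six-node translation-control core network (seven signed edges)."""
    with resources.files("sirenet.data").joinpath("core_network.sif").open() as fh:
        return parse_sif(fh)


def core_channel_scores() -> pd.DataFrame:
    """Packaged per-channel protein-interaction evidence for the core genes."""
    with resources.files("sirenet.data").joinpath("string_scores.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def generate_random_pkn(
    n_nodes: int, n_edges: int, inhibitory_fraction: float, seed: int
) -> SignedNetwork:
    """Random signed directed network without self-loops, reproducible by seed.

    Exactly ``round(inhibitory_fraction * n_edges)`` edges are inhibitory.
    """
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise ValueError("inhibitory_fraction must be in [0, 1]")
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes (max {max_edges})")
    rng = np.random.default_rng(seed)
    names = [f"G{i}" for i in range(n_nodes)]
    pairs = [(a, b) for a in names for b in names if a != b]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    n_inhib = round(inhibitory_fraction * n_edges)
    signs = np.array([-1] * n_inhib + [1] * (n_edges - n_inhib))
    rng.shuffle(signs)
    edges: list[Edge] = [
        (*pairs[i], int(s)) for i, s in zip(chosen, signs)
    ]
    return SignedNetwork(nodes=frozenset(names), edges=tuple(edges))


def simulate_expression(
    truth: WeightedNetwork, config: SimulationConfig
) -> tuple[AnnData, dict]:
    """Two-condition expression from steady states of a known weighted network.

    Per condition and cell type, network-gene means are the condition's
    quasi-steady state; each cell's value is mean + N(0, noise_sd) truncated
    at 0.  Filler genes (up to ``n_genes`` total) are drawn identically in
    both conditions.  Returns the AnnData (cells x genes, ``obs`` columns
    ``condition`` and ``cell_type``) and a ground-truth record holding the
    generating weights and per-condition steady states.
    """
    net_genes = sorted(truth.base.nodes)
    for cond, clamps in config.clamps.items():
        unknown = set(clamps) - truth.base.nodes
        if unknown:
            raise KeyError(f"clamp nodes for {cond!r} not in network: {sorted(unknown)}")
    n_filler = max(0, config.n_genes - len(net_genes))
    genes = net_genes + [f"FILLER{i}" for i in range(n_filler)]

    master = np.random.SeedSequence(config.seed)
    ss_filler, ss_noise = master.spawn(2)
    filler_means = np.random.default_rng(ss_filler).uniform(0.1, 0.9, size=n_filler)

    steady: dict[str, SteadyStateResult] = {}
    for cond, clamps in config.clamps.items():
        res = steady_state(truth, clamps, init=0.5)
        if not res.converged:
            raise RuntimeError(
                f"steady state for condition {cond!r} did not converge "
                f"(cyclic network oscillation?)"
            )
        steady[cond] = res

    rng = np.random.default_rng(ss_noise)
    blocks, obs_rows = [], []
    for cell_type in config.cell_types:
        for cond in config.clamps:
            means = np.array(
                [steady[cond].values[g] for g in net_genes] + list(filler_means)
            )
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_cells, len(genes)))
            blocks.append(np.maximum(means + noise, 0.0))
            obs_rows += [
                {"condition": cond, "cell_type": cell_type}
                for _ in range(config.n_cells)
            ]
    x = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows, index=[f"cell{i}" for i in range(x.shape[0])])
    adata = AnnData(X=x, obs=obs, var=pd.DataFrame(index=genes))
    truth_record = {
        "weights": dict(truth.weights),
        "steady_states": {cond: dict(r.values) for cond, r in steady.items()},
        "clamps": {cond: dict(c) for cond, c in config.clamps.items()},
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return adata, truth_record
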