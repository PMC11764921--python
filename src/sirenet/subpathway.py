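"""Core-network extraction, sub-pathway scoring (SSP/AISP), pattern calls.

The core module is the EIF4EBP1–EIF4E translation-control pair; the core
network is its first neighborhood (adding MAPK1, MKNK1, RPS6KA5 and MTOR).
Four canonical sub-pathway routes lead from the kinases to EIF4E:

    I   MAPK1 -> MKNK1 -> EIF4E
    II  MAPK1 -> RPS6KA5 -| EIF4EBP1 -| EIF4E
    III MAPK1 -| EIF4EBP1 -| EIF4E
    IV  MTOR  -| EIF4EBP1 -| EIF4E

Strength of the Sub-Pathway (SSP) is the product over post-input path nodes
of the on-path incoming edge weight, expressed as a percent:

    SSP = 100 * prod_i k(i)

The Abnormality Index (AISP) additionally scales each factor by the upstream
node's log2 fold change (absolute value by default):

    AISP = 100 * prod_i k(i) * |log2FC(upstream of i)|

Pattern calling uses the edge-weight rule: a route is active when every edge
on it has fitted weight strictly above the threshold (default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .network_model import SignedNetwork
from .procomren import WeightedNetwork

__all__ = [
    "SubPathway",
    "PathScore",
    "CORE_MODULE",
    "CORE_PATTERNS",
    "extract_core_network",
    "path_from_nodes",
    "compute_ssp",
    "compute_aisp",
    "classify_activation_patterns",
]

#: the translation-control regulation pair at the heart of the core network
CORE_MODULE = frozenset({"EIF4EBP1", "EIF4E"})

#: canonical routes through the core network (ordered input ... endpoint)
CORE_PATTERNS: dict[str, tuple[str, ...]] = {
    "I": ("MAPK1", "MKNK1", "EIF4E"),
    "II": ("MAPK1", "RPS6KA5", "EIF4EBP1", "EIF4E"),
    "III": ("MAPK1", "EIF4EBP1", "EIF4E"),
    "IV": ("MTOR", "EIF4EBP1", "EIF4E"),
}


@dataclass(frozen=True)
class SubPathway:
    """An ordered walk input -> ... -> endpoint through a host network."""

    nodes: tuple[str, ...]
    pattern_id: str = "custom"

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a sub-pathway needs at least two nodes")

    @property
    def steps(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes[:-1], self.nodes[1:]))


@dataclass(frozen=True)
class PathScore:
    ssp: float
    aisp: float
    factors: tuple[float, ...]


def path_from_nodes(
    net: SignedNetwork, nodes: tuple[str, ...] | list[str], pattern_id: str = "custom"
) -> SubPathway:
    """Build a SubPathway, checking each consecutive pair is a host edge."""
    path = SubPathway(nodes=tuple(nodes), pattern_id=pattern_id)
    for src, tgt in path.steps:
        if not any(e[0] == src and e[1] == tgt for e in net.edges):
            raise KeyError(f"no edge {src} -> {tgt} in the host network")
    return path


def extract_core_network(
    net: SignedNetwork, module_nodes: set[str] | frozenset[str] = CORE_MODULE
) -> SignedNetwork:
    """Induced subgraph on the module nodes plus their 1-hop in/out neighbors."""
    missing = frozenset(module_nodes) - net.nodes
    if missing:
        raise KeyError(f"module nodes not in network: {sorted(missing)}")
    keep = set(module_nodes)
    for src, tgt, _sign in net.edges:
        if src in module_nodes:
            keep.add(tgt)
        if tgt in module_nodes:
            keep.add(src)
    return net.subnetwork(keep)


def _on_path_weight(weights: WeightedNetwork, src: str, tgt: str) -> tuple[float, int]:
    for edge in sorted(weights.base.edges):
        if edge[0] == src and edge[1] == tgt:
            return weights.weights[edge], edge[2]
    raise KeyError(f"no weighted edge {src} -> {tgt}")


def compute_ssp(
    path: SubPathway, weights: WeightedNetwork, full_fan_in: bool = False
) -> float:
    """Strength of the sub-pathway, percent.

    Each post-input node contributes its on-path incoming edge weight; with
    ``full_fan_in=True`` it instead contributes the sum of all its incoming
    weights of the same sign as the on-path edge (the full total-probability
    mass feeding it).
    """
    ssp = 100.0
    for src, tgt in path.steps:
        k, sign = _on_path_weight(weights, src, tgt)
        if full_fan_in:
            k = sum(
                weights.weights[e]
                for e in weights.base.predecessors(tgt)
                if e[2] == sign
            )
        ssp *= k
    return ssp


def compute_aisp(
    path: SubPathway,
    weights: WeightedNetwork,
    log2fc: dict[str, float],
    absolute: bool = True,
) -> float:
    """Abnormality index: SSP-style product with per-step fold-change scaling.

    Each step's weight is multiplied by the upstream (source) node's log2 fold
    change — absolute value by default so that the index measures magnitude of
    dysregulation; ``absolute=False`` propagates signs instead.  A missing
    fold change counts as 0 (no evidence of dysregulation kills the route).
    """
    aisp = 100.0
    for src, tgt in path.steps:
        k, _sign = _on_path_weight(weights, src, tgt)
        fc = log2fc.get(src, 0.0)
        aisp *= k * (abs(fc) if absolute else fc)
    return aisp


def score_path(
    path: SubPathway,
    weights: WeightedNetwork,
    log2fc: dict[str, float],
    absolute: bool = True,
) -> PathScore:
    """SSP and AISP together with the per-step weight factors."""
    factors = tuple(_on_path_weight(weights, s, t)[0] for s, t in path.steps)
    return PathScore(
        ssp=compute_ssp(path, weights),
        aisp=compute_aisp(path, weights, log2fc, absolute=absolute),
        factors=factors,
    )


def classify_activation_patterns(
    core_weights: WeightedNetwork,
    threshold: float = 0.2,
    patterns: dict[str, tuple[str, ...]] = CORE_PATTERNS,
) -> set[str]:
    """Active patterns: every on-route edge weight strictly above threshold."""
    active = set()
    for pid, route in patterns.items():
        try:
            ks = [
                _on_path_weight(core_weights, s, t)[0]
                for s, t in zip(route[:-1], route[1:])
            ]
        except KeyError:
            continue
        if all(k > threshold for k in ks):
            active.add(pid)
    return active
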