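"""Cell-specific causal subnetwork inference by integer linear programming.

Given a signed, directed prior-knowledge network (PKN), a set of perturbed
input nodes with known direction, and ternary measurements c_j in {-1, 0, +1}
(binarized differential expression for one cell type), the ILP selects node
states x_j in {-1, 0, +1} minimizing

    sum_j alpha * |x_j - c_j|  +  sum_j beta * (x_j+ + x_j-)

i.e. a mismatch penalty on measured nodes plus a node penalty that favors the
smallest activated subnetwork.  Each state is decomposed as
x_j = x_j+ - x_j- with binary x_j+, x_j-, and every active non-input node must
have a cause: a sign-consistent incoming edge from an active node.  The
constraint set follows the Melas/CARNIVAL causal-reasoning family:

(i)   x_j+ + x_j- <= 1                      (exclusive decomposition)
(ii)  x_j+ <= sum of incoming e_u+,         (a state needs a cause;
      x_j- <= sum of incoming e_u-           not imposed on inputs)
(iii) for edge u = (s -> t, sign):          (sign-consistent propagation)
      e_u+ <= x_s+ if activating else x_s-
      e_u- <= x_s- if activating else x_s+
(iv)  an input with direction v may take state 0 or v (it is an available
      cause, not a forced one): the opposite-sign variable is fixed to 0.

Cycles are permitted; no acyclicity constraints are added (two nodes in a
positive loop can sustain each other, exactly as in the combinatorial
enumeration of :func:`brute_force_oracle`, which serves as the independent
correctness check on small instances).

The ILP is solved with HiGHS through :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp
from sklearn.base import BaseEstimator

from .network_model import Edge, SignedNetwork

__all__ = [
    "ILPConfig",
    "ILPModel",
    "ActivatedSubnetwork",
    "SharedSubnetwork",
    "CausalSubnetworkILP",
    "build_ilp",
    "solve_network_inference",
    "brute_force_oracle",
    "shared_subnetwork",
]


@dataclass(frozen=True)
class ILPConfig:
    """Penalties and solver settings.

    ``alpha`` — mismatch penalty (> 0); ``beta`` — node penalty (>= 0).  A
    beta/alpha ratio outside the recommended [0.03, 0.5] band triggers a
    warning but is allowed.
    """

    alpha: float = 1.0
    beta: float = 0.1
    time_limit: float | None = None
    mip_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        ratio = self.beta / self.alpha
        if not 0.03 <= ratio <= 0.5:
            warnings.warn(
                f"beta/alpha ratio {ratio:.3g} outside the recommended [0.03, 0.5] band"
            )


@dataclass
class ILPModel:
    """Assembled MILP: objective vector, constant offset, and constraints."""

    pkn: SignedNetwork
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    inputs: dict[str, int]
    measurement: dict[str, int]
    config: ILPConfig
    c: np.ndarray = field(repr=False)
    constant: float = 0.0
    A: sparse.csr_matrix = field(repr=False, default=None)
    b: np.ndarray = field(repr=False, default=None)
    upper: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ActivatedSubnetwork:
    """Optimal node states and the sign-consistent edges among active nodes."""

    cell_type: str | None
    node_states: dict[str, int]
    used_edges: tuple[Edge, ...]
    objective: float
    gap: float = 0.0
    status: str = "optimal"


@dataclass(frozen=True)
class SharedSubnetwork:
    """Intersection of several activated subnetworks (shared module)."""

    network: SignedNetwork
    node_states: dict[str, int]


def _validate_ternary(mapping: dict[str, int], allowed: tuple[int, ...], what: str) -> None:
    for node, value in mapping.items():
        if value not in allowed:
            raise ValueError(f"{what} value for {node!r} must be in {allowed}, got {value!r}")


def build_ilp(
    pkn: SignedNetwork,
    inputs: dict[str, int],
    measurement: dict[str, int],
    config: ILPConfig = ILPConfig(),
) -> ILPModel:
    """Assemble the MILP for one cell type.

    ``inputs`` maps perturbed nodes to their direction (+1/-1); ``measurement``
    maps measured nodes to c_j in {-1, 0, +1}.  Both must reference network
    nodes only.
    """
    _validate_ternary(inputs, (1, -1), "input")
    _validate_ternary(measurement, (1, 0, -1), "measurement")
    missing = (set(inputs) | set(measurement)) - pkn.nodes
    if missing:
        raise KeyError(f"nodes absent from the network: {sorted(missing)}")

    nodes = tuple(sorted(pkn.nodes))
    edges = tuple(sorted(pkn.edges))
    n, m = len(nodes), len(edges)
    nidx = {node: i for i, node in enumerate(nodes)}
    xp = lambda j: 2 * j  # noqa: E731
    xm = lambda j: 2 * j + 1  # noqa: E731
    ep = lambda u: 2 * n + 2 * u  # noqa: E731
    em = lambda u: 2 * n + 2 * u + 1  # noqa: E731
    nvar = 2 * n + 2 * m

    c = np.zeros(nvar)
    constant = 0.0
    for j in range(n):
        c[xp(j)] += config.beta
        c[xm(j)] += config.beta
    for node, cj in measurement.items():
        j = nidx[node]
        if cj == 1:
            constant += config.alpha
            c[xp(j)] -= config.alpha
            c[xm(j)] += config.alpha
        elif cj == -1:
            constant += config.alpha
            c[xp(j)] += config.alpha
            c[xm(j)] -= config.alpha
        else:
            c[xp(j)] += config.alpha
            c[xm(j)] += config.alpha

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b: list[float] = []

    def add_row(entries: list[tuple[int, float]], ub: float) -> None:
        r = len(b)
        for col, val in entries:
            rows.append(r)
            cols.append(col)
            vals.append(val)
        b.append(ub)

    incoming_p: dict[int, list[int]] = {j: [] for j in range(n)}
    incoming_m: dict[int, list[int]] = {j: [] for j in range(n)}
    for u, (src, tgt, sign) in enumerate(edges):
        incoming_p[nidx[tgt]].append(ep(u))
        incoming_m[nidx[tgt]].append(em(u))
        s = nidx[src]
        src_p, src_m = (xp(s), xm(s)) if sign == 1 else (xm(s), xp(s))
        add_row([(ep(u), 1.0), (src_p, -1.0)], 0.0)  # (iii)
        add_row([(em(u), 1.0), (src_m, -1.0)], 0.0)

    for j, node in enumerate(nodes):
        add_row([(xp(j), 1.0), (xm(j), 1.0)], 1.0)  # (i)
        if node not in inputs:  # (ii)
            add_row([(xp(j), 1.0)] + [(col, -1.0) for col in incoming_p[j]], 0.0)
            add_row([(xm(j), 1.0)] + [(col, -1.0) for col in incoming_m[j]], 0.0)

    upper = np.ones(nvar)
    for node, v in inputs.items():  # (iv): forbid the opposite sign only
        j = nidx[node]
        upper[xm(j) if v == 1 else xp(j)] = 0.0

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(b), nvar) if b else (0, nvar)
    )
    return ILPModel(
        pkn=pkn,
        nodes=nodes,
        edges=edges,
        inputs=dict(inputs),
        measurement=dict(measurement),
        config=config,
        c=c,
        constant=constant,
        A=A,
        b=np.asarray(b),
        upper=upper,
    )


def _consistent_edges(edges: tuple[Edge, ...], states: dict[str, int]) -> tuple[Edge, ...]:
    """Edges joining two active nodes whose states respect the edge sign."""
    return tuple(
        (s, t, sign)
        for s, t, sign in edges
        if states.get(t, 0) != 0 and states.get(s, 0) != 0 and states[t] == sign * states[s]
    )


def solve_network_inference(
    model: ILPModel, cell_type: str | None = None
) -> ActivatedSubnetwork:
    """Solve the assembled MILP and extract the activated subnetwork.

    The reported used-edge set is recomputed from the optimal states (every
    sign-consistent edge between two active nodes), which is deterministic and
    independent of which of several equivalent edge-variable assignments the
    solver returns.
    """
    n = len(model.nodes)
    if model.c.size == 0:
        return ActivatedSubnetwork(cell_type, {}, (), model.constant)

    options: dict[str, float] = {}
    if model.config.time_limit is not None:
        options["time_limit"] = model.config.time_limit
    if model.config.mip_gap:
        options["mip_rel_gap"] = model.config.mip_gap
    res = milp(
        c=model.c,
        constraints=LinearConstraint(model.A, -np.inf, model.b),
        integrality=np.ones_like(model.c),
        bounds=Bounds(np.zeros_like(model.c), model.upper),
        options=options or None,
    )
    if res.x is None:
        raise RuntimeError(f"MILP failed with status {res.status}: {res.message}")
    x = np.rint(res.x).astype(int)
    states = {
        node: int(x[2 * j] - x[2 * j + 1]) for j, node in enumerate(model.nodes)
    }
    status = "optimal" if res.status == 0 else "incumbent"
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    return ActivatedSubnetwork(
        cell_type=cell_type,
        node_states=states,
        used_edges=_consistent_edges(model.edges, states),
        objective=float(res.fun) + model.constant,
        gap=gap,
        status=status,
    )


def brute_force_oracle(
    pkn: SignedNetwork,
    inputs: dict[str, int],
    measurement: dict[str, int],
    config: ILPConfig = ILPConfig(),
    max_free_nodes: int = 12,
) -> tuple[float, list[dict[str, int]]]:
    """Exhaustive enumeration of sign-consistent assignments (exact optimum).

    Independent of the ILP path: feasibility is checked combinatorially —
    every active non-input node needs an incoming edge (s, j, sign) with
    active s and state_j == sign * state_s; an input with direction v ranges
    over {0, v}.  Returns the optimal objective and *all* optimal assignments.
    Refuses networks with more than ``max_free_nodes`` non-input nodes.
    """
    _validate_ternary(inputs, (1, -1), "input")
    _validate_ternary(measurement, (1, 0, -1), "measurement")
    nodes = sorted(pkn.nodes)
    free = [nd for nd in nodes if nd not in inputs]
    if len(free) > max_free_nodes:
        raise ValueError(
            f"{len(free)} non-input nodes exceeds the enumeration bound {max_free_nodes}"
        )
    choices = [
        ((0, inputs[nd]) if nd in inputs else (-1, 0, 1)) for nd in nodes
    ]
    incoming = {nd: pkn.predecessors(nd) for nd in nodes}

    best = np.inf
    optima: list[dict[str, int]] = []
    for combo in itertools.product(*choices):
        states = dict(zip(nodes, combo))
        feasible = all(
            state == 0
            or nd in inputs
            or any(
                states[s] != 0 and state == sign * states[s]
                for s, _t, sign in incoming[nd]
            )
            for nd, state in states.items()
        )
        if not feasible:
            continue
        obj = sum(config.beta * abs(v) for v in states.values()) + sum(
            config.alpha * abs(states[nd] - cj) for nd, cj in measurement.items()
        )
        if obj < best - 1e-12:
            best = obj
            optima = [states]
        elif abs(obj - best) <= 1e-12:
            optima.append(states)
    return float(best), optima


def shared_subnetwork(results: list[ActivatedSubnetwork]) -> SharedSubnetwork:
    """Intersect activated subnetworks across cell types.

    A node is kept when it carries the same nonzero state in every result; an
    edge is kept when it is used in every result and both endpoints survive.
    """
    if not results:
        raise ValueError("at least one result required")
    kept_states: dict[str, int] = {}
    for node, state in results[0].node_states.items():
        if state != 0 and all(r.node_states.get(node) == state for r in results[1:]):
            kept_states[node] = state
    shared_edges = set(results[0].used_edges)
    for r in results[1:]:
        shared_edges &= set(r.used_edges)
    edges = tuple(
        sorted(e for e in shared_edges if e[0] in kept_states and e[1] in kept_states)
    )
    net = SignedNetwork(nodes=frozenset(kept_states), edges=edges)
    return SharedSubnetwork(network=net, node_states=kept_states)


class CausalSubnetworkILP(BaseEstimator):
    """Estimator wrapper around the causal-reasoning ILP.

    Parameters mirror :class:`ILPConfig`.  ``fit`` takes the PKN plus the
    per-cell-type measurement and input dictionaries and exposes the solution
    through fitted attributes.

    Attributes
    ----------
    result_ : ActivatedSubnetwork
    node_states_ : dict mapping node -> {-1, 0, +1}
    used_edges_ : tuple of (source, target, sign)
    objective_ : float
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta: float = 0.1,
        time_limit: float | None = None,
        mip_gap: float = 0.0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.time_limit = time_limit
        self.mip_gap = mip_gap

    def fit(
        self,
        pkn: SignedNetwork,
        measurement: dict[str, int],
        inputs: dict[str, int] | None = None,
        cell_type: str | None = None,
    ) -> "CausalSubnetworkILP":
        config = ILPConfig(
            alpha=self.alpha,
            beta=self.beta,
            time_limit=self.time_limit,
            mip_gap=self.mip_gap,
        )
        model = build_ilp(pkn, inputs or {}, measurement, config)
        self.result_ = solve_network_inference(model, cell_type=cell_type)
        self.node_states_ = self.result_.node_states
        self.used_edges_ = self.result_.used_edges
        self.objective_ = self.result_.objective
        return self
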