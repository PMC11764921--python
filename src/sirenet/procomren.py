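"""Probabilistic logic contextualization of a signed network.

Each node i carries a semi-quantitative activity X(i) in [0, 1] (the
probability that a randomly chosen molecule of species i is in its active
form).  Every edge carries a weight k_j(i) in [0, 1] expressing the relative
influence of parent j on target i.  Weights obey the law of total
probability: per target, activating weights sum to exactly 1 (when the node
has any activator) and inhibiting weights sum to at most 1.  Activities
evolve by the synchronous mean-field update

    X_t(i) = ( sum_j+ k_j+(i) * X_{t-1}(j+) ) * ( 1 - sum_j- k_j-(i) * X_{t-1}(j-) )

a dynamic-Bayesian-network expectation propagated without sampling.  A node
with inhibitors but no activators uses basal activation 1 in the first factor
(pure inhibition acts on full activity); a node with no parents keeps its
value.  Quasi-steady states are fixed points of this map with the designated
input nodes clamped.

Contextualization fits one weight set to two experimental conditions (control
and case), each a clamped steady-state problem, by minimizing the mean squared
error between predicted and measured node activities.  The weight constraints
hold by construction: per-target activating weights are a softmax over free
logits, and inhibiting weights a softmax over (l + 1) logits whose slack entry
absorbs 1 - sum k_j-.  Optimization is multi-start quasi-Newton (L-BFGS-B,
finite-difference gradients) with reproducible per-restart seeds; node values
are initialized from N(0.5, 0.1) truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .network_model import Edge, SignedNetwork

__all__ = [
    "WeightedNetwork",
    "ConditionObservation",
    "FitResult",
    "SteadyStateResult",
    "ProbabilisticLogicModel",
    "normalize_to_unit_interval",
    "condition_means",
    "dbn_update",
    "steady_state",
    "fit_weights",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class WeightedNetwork:
    """A signed network with per-edge weights obeying total probability.

    ``weights`` maps each ``(source, target, sign)`` edge to k in [0, 1];
    for every node with at least one activator the activating weights sum to
    1 (within 1e-9), and inhibiting weights sum to at most 1.
    """

    base: SignedNetwork
    weights: dict[Edge, float]

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.base.edges):
            raise ValueError("weights must cover exactly the network's edges")
        for edge, k in self.weights.items():
            if not -_WEIGHT_TOL <= k <= 1 + _WEIGHT_TOL:
                raise ValueError(f"weight {k} of edge {edge} outside [0, 1]")
        for node in self.base.nodes:
            incoming = self.base.predecessors(node)
            act = sum(self.weights[e] for e in incoming if e[2] == 1)
            inh = sum(self.weights[e] for e in incoming if e[2] == -1)
            if any(e[2] == 1 for e in incoming) and abs(act - 1.0) > 1e-6:
                raise ValueError(
                    f"activating weights into {node!r} sum to {act}, expected 1"
                )
            if inh > 1 + 1e-6:
                raise ValueError(f"inhibiting weights into {node!r} sum to {inh} > 1")

    def activators(self, node: str) -> list[Edge]:
        return [e for e in self.base.predecessors(node) if e[2] == 1]

    def inhibitors(self, node: str) -> list[Edge]:
        return [e for e in self.base.predecessors(node) if e[2] == -1]


@dataclass(frozen=True)
class ConditionObservation:
    """Targets and clamps for one experimental condition.

    ``targets`` — measured node activities in [0, 1] the model should
    reproduce at steady state; ``clamps`` — input nodes held fixed.
    """

    label: str
    targets: dict[str, float]
    clamps: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for what, mapping in (("target", self.targets), ("clamp", self.clamps)):
            for node, v in mapping.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{what} value for {node!r} must be in [0, 1]")


@dataclass(frozen=True)
class SteadyStateResult:
    values: dict[str, float]
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class FitResult:
    network: WeightedNetwork
    mse: float
    n_restarts: int
    best_restart_seed: int
    converged: bool
    iterations: int


def normalize_to_unit_interval(
    adata: AnnData,
    cell_type: str,
    genes: list[str] | None = None,
    condition_key: str = "condition",
    ctl_label: str = "CTL",
    case_label: str = "CASE",
    cell_type_key: str = "cell_type",
) -> dict[str, dict[str, float]]:
    """Per-gene condition means min–max scaled to [0, 1] across the two conditions.

    The condition with the lower mean maps to 0 and the higher to 1; equal
    means both map to 0.5.  Returns ``{condition label: {gene: value}}``.
    Genes absent from the matrix are omitted.
    """
    sub = adata[adata.obs[cell_type_key] == cell_type]
    wanted = list(adata.var_names) if genes is None else genes
    out: dict[str, dict[str, float]] = {ctl_label: {}, case_label: {}}
    for gene in wanted:
        if gene not in sub.var_names:
            continue
        col = sub[:, gene]
        means = {}
        for label in (ctl_label, case_label):
            x = col[col.obs[condition_key] == label].X
            if hasattr(x, "toarray"):
                x = x.toarray()
            means[label] = float(np.asarray(x).mean())
        lo, hi = min(means.values()), max(means.values())
        for label in (ctl_label, case_label):
            out[label][gene] = 0.5 if hi == lo else (means[label] - lo) / (hi - lo)
    return out


def condition_means(
    adata: AnnData,
    cell_type: str,
    genes: list[str] | None = None,
    condition_key: str = "condition",
    cell_type_key: str = "cell_type",
    clip: bool = True,
) -> dict[str, dict[str, float]]:
    """Raw per-condition mean expression per gene (optionally clipped to [0, 1]).

    Suitable as fitting targets when the measurements already live on the
    activity scale, e.g. output of the synthetic simulator.
    """
    sub = adata[adata.obs[cell_type_key] == cell_type]
    wanted = list(sub.var_names) if genes is None else [g for g in genes if g in sub.var_names]
    out: dict[str, dict[str, float]] = {}
    for label in sub.obs[condition_key].unique():
        block = sub[sub.obs[condition_key] == label][:, wanted]
        x = block.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        means = np.asarray(x).mean(axis=0)
        if clip:
            means = np.clip(means, 0.0, 1.0)
        out[str(label)] = dict(zip(wanted, means.astype(float)))
    return out


def dbn_update(values: dict[str, float], node: str, net: WeightedNetwork) -> float:
    """One mean-field update of *node* given parent values."""
    act_edges = net.activators(node)
    inh_edges = net.inhibitors(node)
    if not act_edges and not inh_edges:
        return values[node]
    activation = (
        sum(net.weights[e] * values[e[0]] for e in act_edges) if act_edges else 1.0
    )
    inhibition = sum(net.weights[e] * values[e[0]] for e in inh_edges)
    return activation * (1.0 - inhibition)


def steady_state(
    net: WeightedNetwork,
    clamps: dict[str, float],
    init: dict[str, float] | float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SteadyStateResult:
    """Synchronous iteration to a quasi-steady state with clamped inputs.

    On acyclic networks this converges exactly within longest-path-length
    iterations; cyclic networks may oscillate, in which case the last state is
    returned with ``converged=False``.
    """
    unknown = set(clamps) - net.base.nodes
    if unknown:
        raise KeyError(f"clamped nodes not in network: {sorted(unknown)}")
    nodes = sorted(net.base.nodes)
    if isinstance(init, dict):
        values = {nd: float(init.get(nd, 0.5)) for nd in nodes}
    else:
        values = {nd: float(init) for nd in nodes}
    values.update(clamps)
    free = [nd for nd in nodes if nd not in clamps]
    for it in range(1, max_iter + 1):
        new = dict(values)
        for nd in free:
            new[nd] = dbn_update(values, nd, net)
        delta = max((abs(new[nd] - values[nd]) for nd in free), default=0.0)
        values = new
        if delta < tol:
            return SteadyStateResult(values=values, n_iter=it, converged=True)
    return SteadyStateResult(values=values, n_iter=max_iter, converged=False)


# ---------------------------------------------------------------------------
# constrained parameterization: logits -> valid weights


def _parameter_layout(net: SignedNetwork) -> list[tuple[str, int, list[Edge], list[Edge]]]:
    """Free-parameter blocks per node: (node, n_params, act_edges, inh_edges).

    A single activator is forced to weight 1 (no parameter); m >= 2 activators
    get m logits (softmax); l >= 1 inhibitors get l + 1 logits (softmax with a
    slack entry absorbing the unassigned inhibition mass).
    """
    layout = []
    for node in sorted(net.nodes):
        incoming = net.predecessors(node)
        act = sorted(e for e in incoming if e[2] == 1)
        inh = sorted(e for e in incoming if e[2] == -1)
        n_params = (len(act) if len(act) >= 2 else 0) + (len(inh) + 1 if inh else 0)
        layout.append((node, n_params, act, inh))
    return layout


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _theta_to_weights(theta: np.ndarray, layout) -> dict[Edge, float]:
    weights: dict[Edge, float] = {}
    pos = 0
    for _node, n_params, act, inh in layout:
        block = theta[pos : pos + n_params]
        pos += n_params
        off = 0
        if len(act) == 1:
            weights[act[0]] = 1.0
        elif len(act) >= 2:
            w = _softmax(block[: len(act)])
            off = len(act)
            weights.update(zip(act, w))
        if inh:
            w = _softmax(block[off : off + len(inh) + 1])
            weights.update(zip(inh, w[:-1]))  # last entry is slack
    return weights


def fit_weights(
    net: SignedNetwork,
    observations: list[ConditionObservation],
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    steady_tol: float = 1e-6,
    steady_max_iter: int = 1000,
    transition_mode: str = "steady_state",
) -> FitResult:
    """Fit edge weights by constrained MSE minimization across conditions.

    Each observation is predicted at quasi-steady state under its clamps
    (``transition_mode="one_step"`` instead predicts every observation after
    the first as a single synchronous update from the previous condition's
    state).  The constrained weights are optimized through the softmax
    parameterization, multi-start L-BFGS-B with per-restart seeds spawned from
    ``seed``; the best restart is returned.
    """
    if not observations:
        raise ValueError("at least one observation required")
    measured = {nd for obs in observations for nd in obs.targets}
    missing = measured - net.nodes
    if missing:
        raise KeyError(f"measured nodes not in network: {sorted(missing)}")
    if not measured:
        raise ValueError("no measured nodes")

    layout = _parameter_layout(net)
    n_params = sum(blk[1] for blk in layout)
    pairs = [(obs, nd) for obs in observations for nd in sorted(obs.targets)]

    def predict(weights: dict[Edge, float], init: dict[str, float]) -> dict[str, dict[str, float]]:
        wnet = WeightedNetwork(base=net, weights=weights)
        preds: dict[str, dict[str, float]] = {}
        prev: dict[str, float] | None = None
        for k, obs in enumerate(observations):
            if transition_mode == "one_step" and k > 0 and prev is not None:
                values = dict(prev)
                values.update(obs.clamps)
                free = [nd for nd in sorted(net.nodes) if nd not in obs.clamps]
                new = dict(values)
                for nd in free:
                    new[nd] = dbn_update(values, nd, wnet)
                preds[obs.label] = new
                prev = new
            else:
                res = steady_state(
                    wnet, obs.clamps, init=init, tol=steady_tol, max_iter=steady_max_iter
                )
                preds[obs.label] = res.values
                prev = res.values
        return preds

    def objective(theta: np.ndarray, init: dict[str, float]) -> float:
        preds = predict(_theta_to_weights(theta, layout), init)
        err = [preds[obs.label][nd] - obs.targets[nd] for obs, nd in pairs]
        return float(np.mean(np.square(err)))

    child_seeds = np.random.SeedSequence(seed).spawn(max(n_restarts, 1))
    best: tuple[float, np.ndarray, int, bool, int] | None = None
    for r, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        init = {
            nd: float(np.clip(rng.normal(0.5, 0.1), 0.0, 1.0))
            for nd in sorted(net.nodes)
        }
        theta0 = rng.normal(0.0, 1.0, size=n_params)
        if n_params:
            res = minimize(
                objective,
                theta0,
                args=(init,),
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": tol},
            )
            cand = (float(res.fun), res.x, r, bool(res.success), int(res.nit))
        else:
            cand = (objective(theta0, init), theta0, r, True, 0)
        if best is None or cand[0] < best[0]:
            best = cand
    mse, theta, r_best, converged, iters = best
    network = WeightedNetwork(base=net, weights=_theta_to_weights(theta, layout))
    return FitResult(
        network=network,
        mse=mse,
        n_restarts=n_restarts,
        best_restart_seed=r_best,
        converged=converged,
        iterations=iters,
    )


class ProbabilisticLogicModel(BaseEstimator):
    """Estimator wrapper around the DBN weight fit.

    Attributes (after ``fit``)
    --------------------------
    network_ : WeightedNetwork        fitted weighted network
    weights_ : dict edge -> float     fitted weights
    mse_ : float                      best-restart mean squared error
    result_ : FitResult
    """

    def __init__(
        self,
        n_restarts: int = 20,
        seed: int = 0,
        tol: float = 1e-8,
        max_iter: int = 2000,
        steady_tol: float = 1e-6,
        steady_max_iter: int = 1000,
        transition_mode: str = "steady_state",
    ):
        self.n_restarts = n_restarts
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.steady_tol = steady_tol
        self.steady_max_iter = steady_max_iter
        self.transition_mode = transition_mode

    def fit(
        self, net: SignedNetwork, observations: list[ConditionObservation]
    ) -> "ProbabilisticLogicModel":
        self.result_ = fit_weights(
            net,
            observations,
            n_restarts=self.n_restarts,
            seed=self.seed,
            tol=self.tol,
            max_iter=self.max_iter,
            steady_tol=self.steady_tol,
            steady_max_iter=self.steady_max_iter,
            transition_mode=self.transition_mode,
        )
        self.network_ = self.result_.network
        self.weights_ = dict(self.result_.network.weights)
        self.mse_ = self.result_.mse
        return self

    def predict(self, clamps: dict[str, float], init: float = 0.5) -> dict[str, float]:
        """Steady-state node activities under the given clamps."""
        if not hasattr(self, "network_"):
            raise RuntimeError("model is not fitted")
        return steady_state(self.network_, clamps, init=init).values


def weighted_network_to_frame(net: WeightedNetwork) -> pd.DataFrame:
    """Tabular (source, target, sign, weight) view, sorted, for serialization."""
    rows = [
        {"source": s, "target": t, "sign": sign, "weight": net.weights[(s, t, sign)]}
        for s, t, sign in sorted(net.base.edges)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "sign", "weight"])
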