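"""Synthetic inputs: truth networks, Boolean trajectories, panels, priors.

Everything the inference pipeline consumes can be generated here without
external downloads: ground-truth fuzzy logic networks with feedback loops
and AND gates, synchronous Boolean trajectories subsampled to sparse
"experimental" time series, steady-state perturbation panels, and prior
networks mixing a chosen fraction of true edges with noise edges, all with
Uniform(0, 1) confidence scores.  All generators are pure functions of
their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .logic import HillParams, LogicModel, SimulationConfig, simulate_steady_state, simulate_timeseries
from .objective import Condition, PerturbationDataset
from .prior import Edge, PriorNetwork

__all__ = [
    "TruthNetworkSpec",
    "toy9",
    "make_truth_network",
    "boolean_trajectories",
    "subsample_timepoints",
    "timeseries_dataset_from_trajectories",
    "make_steady_state_panel",
    "perturb_prior",
]

# 'i' is skipped in node names so it is never confused with an index symbol.
_NAMES = "abcdefghjklmnopqrstuvwxyz"


@dataclass(frozen=True)
class TruthNetworkSpec:
    """Shape constraints for a randomly generated ground-truth network."""

    n_nodes: int = 9
    n_edges: int = 10
    n_feedback_loops: int = 1
    n_and_gates: int = 1
    inhibition_fraction: float = 0.15
    n_stimulated: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges < 1:
            raise ValueError("a connected network needs at least one edge")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("n_edges must be >= n_nodes - 1 for connectivity")
        if not 1 <= self.n_stimulated < self.n_nodes:
            raise ValueError("need at least one stimulated and one downstream node")
        if self.n_feedback_loops < 0 or self.n_and_gates < 0:
            raise ValueError("loop and gate counts must be non-negative")
        base = self.n_nodes - self.n_stimulated
        if self.n_edges < base + self.n_feedback_loops:
            raise ValueError("not enough edges for the requested feedback loops")


def _node_names(n: int) -> list[str]:
    if n <= len(_NAMES):
        return list(_NAMES[:n])
    return [f"n{k}" for k in range(n)]


def toy9() -> LogicModel:
    """The bundled 9-node, 10-edge benchmark network.

    Contains one negative feedback loop (c -> h -> j -| c) and one AND gate
    ((c AND d) -> f); nodes a and b are the stimulated receptors and all
    other nodes are measured.  The full wiring beyond those structural facts
    is this package's own choice, documented here as the reference fixture
    for the structure-recovery experiments.
    """
    edges = [
        ("a", "c", 1, 1), ("j", "c", -1, 1),   # c = f(a) AND (1 - f(j))
        ("b", "d", 1, 1),
        ("c", "f", 1, 1), ("d", "f", 1, 1),    # the AND gate into f
        ("d", "e", 1, 1),
        ("c", "h", 1, 1),
        ("h", "j", 1, 1),
        ("f", "g", 1, 1), ("e", "g", 1, 2),    # g = f OR e
    ]
    roles = {n: "measured" for n in "cdefghj"}
    roles.update({"a": "stimulated", "b": "stimulated"})
    return LogicModel.from_edges(list("abcdefghj"), edges, HillParams(), roles)


def make_truth_network(spec: TruthNetworkSpec) -> LogicModel:
    """Random connected signed network matching a :class:`TruthNetworkSpec`.

    Construction: stimulated nodes first; every downstream node receives one
    incoming edge from an earlier node (the first downstream nodes attach to
    the stimulated ones so every stimulus has an outgoing edge); feedback
    loops are added as negative back-edges closing an ancestor chain; the
    remaining edge budget is spent on random extra edges.  AND gates merge
    all regulators of randomly chosen indegree>=2 nodes into one clause.
    """
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec.n_nodes)
    n_stim = spec.n_stimulated
    parent_of: dict[int, int] = {}
    edges: set[tuple[int, int]] = set()
    for pos in range(n_stim, spec.n_nodes):
        if pos - n_stim < n_stim:
            par = pos - n_stim  # attach the first downstream nodes to stimuli
        else:
            par = int(rng.integers(0, pos))
        parent_of[pos] = par
        edges.add((par, pos))

    if spec.n_feedback_loops:
        # Guarantee at least one downstream-to-downstream path so a back-edge
        # can close a cycle: rewire the last node onto a downstream parent.
        if spec.n_nodes - n_stim < 2:
            raise ValueError("feedback loops need at least two downstream nodes")
        last = spec.n_nodes - 1
        if not any(i >= n_stim for (i, j) in edges):
            edges.discard((parent_of[last], last))
            parent_of[last] = int(rng.integers(n_stim, last))
            edges.add((parent_of[last], last))

    # Random extra edges first (they enrich the cycle candidates), leaving
    # one edge of budget per requested feedback loop.
    pool = [
        (i, j)
        for i in range(spec.n_nodes)
        for j in range(n_stim, spec.n_nodes)
        if i != j and (i, j) not in edges
    ]
    n_extra = spec.n_edges - len(edges) - spec.n_feedback_loops
    if n_extra > len(pool):
        raise ValueError("n_edges exceeds the number of admissible pairs")
    if n_extra > 0:
        for k in rng.choice(len(pool), size=n_extra, replace=False):
            edges.add(pool[int(k)])

    signs: dict[tuple[int, int], int] = {}
    for _ in range(spec.n_feedback_loops):
        graph = nx.DiGraph(sorted(edges))
        candidates = []
        for v in range(n_stim, spec.n_nodes):
            reach = nx.descendants(graph, v) if v in graph else set()
            candidates.extend(
                (u, v) for u in sorted(reach)
                if u >= n_stim and u != v and (u, v) not in edges
            )
        if not candidates:
            raise ValueError("could not place the requested feedback loops")
        u, v = candidates[int(rng.integers(0, len(candidates)))]
        edges.add((u, v))
        signs[(u, v)] = -1  # back-edge closing a negative feedback loop

    for e in sorted(edges):
        if e not in signs:
            signs[e] = -1 if rng.random() < spec.inhibition_fraction else 1

    indeg: dict[int, int] = {}
    for (_, j) in edges:
        indeg[j] = indeg.get(j, 0) + 1
    and_candidates = sorted(j for j, d in indeg.items() if d >= 2)
    if len(and_candidates) < spec.n_and_gates:
        raise ValueError("not enough indegree>=2 nodes for the requested AND gates")
    and_nodes = set(
        int(and_candidates[k])
        for k in rng.choice(len(and_candidates), size=spec.n_and_gates, replace=False)
    ) if spec.n_and_gates else set()

    records = []
    clause_counter: dict[int, int] = {}
    for (i, j) in sorted(edges):
        if j in and_nodes:
            label = 1
        else:
            clause_counter[j] = clause_counter.get(j, 0) + 1
            label = clause_counter[j]
        records.append((names[i], names[j], signs[(i, j)], label))
    roles = {names[k]: ("stimulated" if k < n_stim else "measured")
             for k in range(spec.n_nodes)}
    return LogicModel.from_edges(names, records, HillParams(), roles)


def boolean_trajectories(
    model: LogicModel, n_series: int = 5, length: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Synchronous Boolean trajectories from uniformly random initial states.

    Each trajectory is a ``(length, m)`` 0/1 array whose first row is the
    random initial state; parentless nodes (including stimuli) hold their
    initial value.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(mode="boolean")
    out = []
    for _ in range(n_series):
        init = rng.integers(0, 2, model.m).astype(float)
        out.append(simulate_timeseries(model, init, None, length, cfg))
    return out


def subsample_timepoints(series, k: int, keep_first: bool = True, seed: int = 0):
    """Randomly keep ``k`` time points of a trajectory, preserving order.

    Returns ``(indices, sub_series)``; index 0 is always retained when
    ``keep_first`` (the initial state is part of the experimental record).
    """
    series = np.asarray(series)
    n = series.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}")
    rng = np.random.default_rng(seed)
    if keep_first:
        rest = rng.choice(np.arange(1, n), size=k - 1, replace=False) if k > 1 else []
        idx = np.sort(np.concatenate([[0], np.asarray(rest, dtype=int)])).astype(int)
    else:
        idx = np.sort(rng.choice(n, size=k, replace=False)).astype(int)
    return idx, series[idx]


def timeseries_dataset_from_trajectories(
    model: LogicModel,
    trajectories,
    n_keep=(6, 7),
    seed: int = 0,
) -> PerturbationDataset:
    """Subsample trajectories into a sparse time-series dataset.

    Per trajectory, ``k`` is drawn from ``n_keep`` and ``k`` time points
    (always including the initial state) are retained.  Measured nodes are
    the model's non-stimulated nodes; each trajectory's condition clamps the
    stimulated nodes to their initial values.
    """
    rng = np.random.default_rng(seed)
    stim = model.stimulated
    measured = [n for n in model.nodes if n not in stim]
    meas_idx = [model.index(n) for n in measured]
    conditions, series, times = [], [], []
    for traj in trajectories:
        traj = np.asarray(traj, dtype=float)
        k = int(rng.choice(np.asarray(n_keep)))
        idx, sub = subsample_timepoints(traj, k, keep_first=True,
                                        seed=int(rng.integers(0, 2**31 - 1)))
        conditions.append(Condition.make(
            {n: float(traj[0, model.index(n)]) for n in stim}
        ))
        series.append(sub[:, meas_idx])
        times.append(idx.astype(float))
    return PerturbationDataset.time_series(measured, conditions, series, times)


def make_steady_state_panel(
    model: LogicModel,
    conditions,
    noise_sd: float = 0.0,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
):
    """Simulate a steady-state perturbation panel from a known model.

    ``conditions`` is a list of clamp maps (or :class:`Condition`); each
    must clamp every stimulated node.  Gaussian noise of sd ``noise_sd`` is
    added to the measured values and truncated to [0, 1].  Returns
    ``(dataset, converged_flags)``; non-convergent conditions are flagged
    and their last state used.
    """
    cfg = sim_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    conds = [c if isinstance(c, Condition) else Condition.make(c) for c in conditions]
    stim = set(model.stimulated)
    measured = model.measured or [n for n in model.nodes if n not in stim]
    rows, flags = [], []
    for cond in conds:
        clamp = cond.clamp_map()
        if not stim <= set(clamp):
            raise ValueError("every stimulated node must be clamped in each condition")
        state, conv, _ = simulate_steady_state(model, clamp, cfg)
        rows.append([state[model.index(n)] for n in measured])
        flags.append(conv)
    values = np.asarray(rows)
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape), 0.0, 1.0)
    dataset = PerturbationDataset.steady_state(measured, conds, values)
    return dataset, flags


def perturb_prior(
    truth: LogicModel,
    prior_ratio: float,
    noise_ratio: float = 0.0,
    seed: int = 0,
    d_max_default: int | None = 2,
) -> PriorNetwork:
    """Prior network of partially-known, partially-noisy edges.

    ``round(prior_ratio * n_truth)`` true edges are drawn uniformly without
    replacement and ``round(noise_ratio * n_prior)`` false edges are drawn
    from the non-truth ordered pairs (targets never stimulated).  All
    confidences are Uniform(0, 1); true edges keep the truth's signs, noise
    edges get random signs.
    """
    if prior_ratio < 0 or noise_ratio < 0:
        raise ValueError("ratios must be non-negative")
    rng = np.random.default_rng(seed)
    truth_edges = sorted(truth.edge_set())
    n_prior = int(np.floor(prior_ratio * len(truth_edges) + 0.5))
    chosen = [
        truth_edges[int(k)]
        for k in (rng.choice(len(truth_edges), size=n_prior, replace=False)
                  if n_prior else [])
    ]
    n_noise = int(np.floor(noise_ratio * n_prior + 0.5))
    stim = set(truth.stimulated)
    pool = sorted(
        (s, t)
        for s in truth.nodes
        for t in truth.nodes
        if s != t and t not in stim and (s, t) not in set(truth_edges)
    )
    if n_noise > len(pool):
        raise ValueError("noise pool exhausted: too many noise edges requested")
    noise = [pool[int(k)] for k in (rng.choice(len(pool), size=n_noise, replace=False)
                                    if n_noise else [])]
    edges = []
    for (s, t) in chosen:
        i, j = truth.index(s), truth.index(t)
        sign = 1 if truth.R[i, j] else -1
        edges.append(Edge(s, t, sign, float(rng.uniform(0.0, 1.0))))
    for (s, t) in noise:
        sign = 1 if rng.random() < 0.5 else -1
        edges.append(Edge(s, t, sign, float(rng.uniform(0.0, 1.0))))
    return PriorNetwork(
        nodes=list(truth.nodes),
        roles=dict(truth.roles),
        edges=edges,
        d_max={},
        d_max_default=d_max_default,
    )
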