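"""Executable fuzzy logic networks.

A network over ``m`` nodes is encoded by three ``m x m`` matrices:

``B``
    binary adjacency, ``B[i, j] = 1`` iff node ``i`` regulates node ``j``;
``R``
    regulation sign, ``R[i, j] = 1`` for activation, 0 for inhibition;
``C``
    clause membership: regulators of ``j`` sharing the same integer label
    ``C[i, j]`` are AND-ed together, and the AND clauses are OR-ed.  This is
    a disjunctive normal form in which each regulator appears in exactly one
    clause — the biologically-motivated restriction that in a given cellular
    context a regulator acts through one specific complex of co-regulators.

Inputs are filtered through a Hill transfer function
``f(x) = x^p / (x^p + h^p)`` with integer steepness ``p`` and midpoint
``h`` (``f(h) = 1/2``); an inhibiting input contributes ``1 - f(x)``.  AND
and OR are the fuzzy ``min`` and ``max`` operators, so states stay in
``[0, 1]``.  With the transfer replaced by the identity the very same
network runs as a synchronous Boolean network on binary states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HILL_GRID",
    "HillParams",
    "SimulationConfig",
    "LogicModel",
    "hill_transfer",
    "node_update",
    "enumerate_gate_encodings",
    "compile_plan",
    "synchronous_step",
    "simulate_steady_state",
    "simulate_timeseries",
]

#: Discrete grid of Hill midpoints searched during inference.
HILL_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class HillParams:
    """Hill transfer parameters: steepness ``p`` (integer) and midpoint ``h``."""

    p: int = 2
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("Hill coefficient p must be >= 1")
        if not 0.0 < self.h < 1.0:
            raise ValueError("sensitivity h must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Synchronous simulation settings.

    ``epsilon`` is the convergence tolerance on the max absolute change
    between successive states; the iteration cap for steady-state search is
    ``max_iter_factor`` times the node count; time-series simulations run
    ``ts_length_factor`` times the experimental number of time points.
    """

    epsilon: float = 1.0e-6
    max_iter_factor: int = 5
    ts_length_factor: int = 3
    mode: str = "fuzzy"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.mode not in ("fuzzy", "boolean"):
            raise ValueError(f"mode must be 'fuzzy' or 'boolean', got {self.mode!r}")


def hill_transfer(x, hill: HillParams):
    """Hill activation effect ``x^p / (x^p + h^p)``, mapping [0,1] into [0,1).

    Strictly increasing with midpoint ``f(h) = 0.5``.  Callers obtain the
    inhibition effect as ``1 - hill_transfer(x, hill)``.  Accepts scalars or
    arrays.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("hill_transfer input must lie in [0, 1]")
    xp = arr ** hill.p
    out = xp / (xp + hill.h ** hill.p)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class LogicModel:
    """A fuzzy logic network in B/C/R matrix form.

    ``roles`` uses the prior-network vocabulary; stimulated nodes are model
    inputs and must have empty ``B`` columns.  ``C[i, j]`` is meaningful
    only where ``B[i, j] == 1`` and takes values in ``1..indegree(j)``.
    """

    nodes: list[str]
    B: np.ndarray
    R: np.ndarray
    C: np.ndarray
    hill: HillParams = field(default_factory=HillParams)
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.nodes)
        if len(set(self.nodes)) != m:
            raise ValueError("node identifiers must be unique")
        self.B = np.asarray(self.B, dtype=np.int8)
        self.R = np.asarray(self.R, dtype=np.int8)
        self.C = np.asarray(self.C, dtype=np.int32)
        for name, mat in (("B", self.B), ("R", self.R), ("C", self.C)):
            if mat.shape != (m, m):
                raise ValueError(f"{name} must be {m}x{m}, got {mat.shape}")
        if np.any((self.B != 0) & (self.B != 1)):
            raise ValueError("B must be binary")
        if np.any(np.diag(self.B)):
            raise ValueError("self-regulation (diagonal of B) is not supported")
        for j in range(m):
            parents = np.flatnonzero(self.B[:, j])
            k = parents.size
            if k and self.roles.get(self.nodes[j]) == "stimulated":
                raise ValueError(f"stimulated node {self.nodes[j]!r} has incoming edges")
            labels = self.C[parents, j]
            if k and (np.any(labels < 1) or np.any(labels > k)):
                raise ValueError(
                    f"clause labels of node {self.nodes[j]!r} must lie in 1..{k}"
                )
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self._plan = None

    @property
    def m(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self._index[node]

    @property
    def stimulated(self) -> list[str]:
        return [n for n in self.nodes if self.roles.get(n) == "stimulated"]

    @property
    def measured(self) -> list[str]:
        return [n for n in self.nodes if self.roles.get(n) == "measured"]

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            (self.nodes[i], self.nodes[j])
            for i, j in zip(*np.nonzero(self.B))
        }

    def plan(self):
        if self._plan is None:
            self._plan = compile_plan(self)
        return self._plan

    @classmethod
    def from_edges(
        cls,
        nodes: list[str],
        edges,
        hill: HillParams | None = None,
        roles: dict[str, str] | None = None,
    ) -> "LogicModel":
        """Build from ``(source, target, sign, clause_label)`` records.

        ``sign`` is +1/-1; ``clause_label`` groups regulators of the same
        target into AND clauses (labels are per-target and normalized to
        1..k in order of first appearance).
        """
        m = len(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        B = np.zeros((m, m), dtype=np.int8)
        R = np.zeros((m, m), dtype=np.int8)
        Craw = np.zeros((m, m), dtype=np.int32)
        for (s, t, sign, label) in edges:
            i, j = idx[s], idx[t]
            B[i, j] = 1
            R[i, j] = 1 if sign == 1 else 0
            Craw[i, j] = label
        C = np.zeros((m, m), dtype=np.int32)
        for j in range(m):
            parents = np.flatnonzero(B[:, j])
            relabel: dict[int, int] = {}
            for i in parents:
                lab = int(Craw[i, j])
                C[i, j] = relabel.setdefault(lab, len(relabel) + 1)
        return cls(nodes=list(nodes), B=B, R=R, C=C,
                   hill=hill or HillParams(), roles=dict(roles or {}))

    def edge_records(self) -> list[tuple[str, str, int, int]]:
        """Inverse of :meth:`from_edges` (canonical clause labels)."""
        recs = []
        for j in range(self.m):
            for i in np.flatnonzero(self.B[:, j]):
                sign = 1 if self.R[i, j] else -1
                recs.append((self.nodes[i], self.nodes[j], sign, int(self.C[i, j])))
        return recs


def compile_plan(model: LogicModel):
    """Flatten the gate structure into CSR-style integer arrays.

    Returns ``(node_ptr, clause_ptr, parents, signs)``: the clauses of node
    ``j`` are ``clause_ptr[node_ptr[j]:node_ptr[j+1]+1]`` boundaries into
    ``parents``/``signs``.  Shared by the reference simulator and the
    compiled kernels.
    """
    node_ptr = [0]
    clause_ptr = [0]
    parents: list[int] = []
    signs: list[int] = []
    n_clauses = 0
    for j in range(model.m):
        pars = np.flatnonzero(model.B[:, j])
        labels = model.C[pars, j]
        seen: list[int] = []
        for lab in labels:
            if lab not in seen:
                seen.append(int(lab))
        for lab in seen:
            members = pars[labels == lab]
            parents.extend(int(i) for i in members)
            signs.extend(int(model.R[i, j]) for i in members)
            clause_ptr.append(len(parents))
            n_clauses += 1
        node_ptr.append(n_clauses)
    return (
        np.asarray(node_ptr, dtype=np.int32),
        np.asarray(clause_ptr, dtype=np.int32),
        np.asarray(parents, dtype=np.int32),
        np.asarray(signs, dtype=np.int32),
    )


def node_update(state, j: int, model: LogicModel, mode: str = "fuzzy") -> float:
    """Next state of node ``j`` given the previous global ``state``.

    Evaluates the node's DNF gate: each AND clause is the ``min`` over its
    members of the (possibly inhibition-flipped) transfer output, and the
    clauses are combined by ``max``.  In boolean mode the transfer is the
    identity.  Nodes without parents are inputs and must be held by callers.
    """
    x = np.asarray(state, dtype=float)
    parents = np.flatnonzero(model.B[:, j])
    if parents.size == 0:
        raise ValueError(f"node {model.nodes[j]!r} has no parents; hold it fixed instead")
    if mode == "fuzzy":
        fx = hill_transfer(x, model.hill)
    else:
        fx = x
    labels = model.C[parents, j]
    best = 0.0
    for lab in np.unique(labels):
        members = parents[labels == lab]
        val = min(
            fx[i] if model.R[i, j] else 1.0 - fx[i]
            for i in members
        )
        best = max(best, val)
    return float(best)


def enumerate_gate_encodings(k: int):
    """All distinct AND/OR gate shapes over ``k`` regulators.

    Each regulator belongs to exactly one AND clause, so a gate shape is a
    set partition of the ``k`` regulators (Bell(k) of them); clause labels
    are canonical (block of element 0 is clause 1, etc.).  Returns a list of
    label tuples of length ``k``.
    """
    if k < 0:
        raise ValueError("indegree must be non-negative")
    if k == 0:
        return []
    partitions: list[tuple[int, ...]] = []

    def _extend(labels: tuple[int, ...], n_blocks: int) -> None:
        if len(labels) == k:
            partitions.append(labels)
            return
        for b in range(1, n_blocks + 2):
            _extend(labels + (b,), max(n_blocks, b))

    _extend((1,), 1)
    return partitions


def _resolve_clamps(model: LogicModel, inputs: dict[str, float] | None):
    clamp = np.zeros(model.m, dtype=bool)
    vals = np.zeros(model.m)
    for node, v in (inputs or {}).items():
        i = model.index(node)
        if not 0.0 <= float(v) <= 1.0:
            raise ValueError(f"clamp value for {node!r} must lie in [0, 1]")
        clamp[i] = True
        vals[i] = float(v)
    return clamp, vals


def synchronous_step(x, model: LogicModel, clamp_mask, clamp_vals, mode: str = "fuzzy"):
    """One synchronous update of every non-clamped node (reference path).

    Parentless non-clamped nodes hold their state.
    """
    node_ptr, clause_ptr, parents, signs = model.plan()
    if mode == "fuzzy":
        p, h = model.hill.p, model.hill.h
        fx = x ** p / (x ** p + h ** p)
    else:
        fx = x
    new = np.where(clamp_mask, clamp_vals, x)
    for j in range(model.m):
        c0, c1 = node_ptr[j], node_ptr[j + 1]
        if c0 == c1 or clamp_mask[j]:
            continue
        best = 0.0
        for c in range(c0, c1):
            v = 1.0
            for t in range(clause_ptr[c], clause_ptr[c + 1]):
                i = parents[t]
                e = fx[i] if signs[t] else 1.0 - fx[i]
                if e < v:
                    v = e
            if v > best:
                best = v
        new[j] = best
    return new


def simulate_steady_state(
    model: LogicModel,
    inputs: dict[str, float] | None = None,
    config: SimulationConfig | None = None,
):
    """Synchronously iterate from the all-zero state until convergence.

    Clamped nodes (stimuli; inhibited nodes at 0) stay fixed.  Convergence
    means the max absolute difference of two successive states dropped below
    ``config.epsilon`` within ``config.max_iter_factor * m`` iterations;
    otherwise the last state is returned with ``converged=False`` (feedback
    loops can oscillate forever under synchronous updates).

    Returns ``(state, converged, iterations)``.
    """
    cfg = config or SimulationConfig()
    clamp_mask, clamp_vals = _resolve_clamps(model, inputs)
    x = np.where(clamp_mask, clamp_vals, 0.0)
    max_iter = cfg.max_iter_factor * model.m
    for it in range(1, max_iter + 1):
        nxt = synchronous_step(x, model, clamp_mask, clamp_vals, mode=cfg.mode)
        delta = float(np.max(np.abs(nxt - x))) if model.m else 0.0
        x = nxt
        if delta < cfg.epsilon:
            return x, True, it
    return x, False, max_iter


def simulate_timeseries(
    model: LogicModel,
    init,
    inputs: dict[str, float] | None = None,
    n_points: int = 1,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Synchronous trajectory ``[init, x(1), ..., x(n_points - 1)]``.

    Clamps are held fixed for the whole simulation (and override ``init``).
    Returns an ``(n_points, m)`` array.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    cfg = config or SimulationConfig()
    clamp_mask, clamp_vals = _resolve_clamps(model, inputs)
    x = np.asarray(init, dtype=float).copy()
    if x.shape != (model.m,):
        raise ValueError(f"init must have shape ({model.m},)")
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("initial state must lie in [0, 1]")
    x = np.where(clamp_mask, clamp_vals, x)
    out = np.empty((n_points, model.m))
    out[0] = x
    for t in range(1, n_points):
        x = synchronous_step(x, model, clamp_mask, clamp_vals, mode=cfg.mode)
        out[t] = x
    return out
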