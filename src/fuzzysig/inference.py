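"""Structure learning as a constrained nonlinear integer program.

The unknowns are the adjacency matrix ``B``, the clause-membership matrix
``C``, the sign matrix ``R`` and the Hill midpoint ``h`` (one global gene
drawn from a discrete grid).  A chromosome holds, for every candidate edge
``(i, j)`` (ordered pairs with ``j`` not stimulated and ``i != j``), an
include bit, a sign bit and a clause gene, plus the ``h`` index.  Decoding
is deterministic: clause genes are reduced modulo the realized indegree and
renumbered canonically, so label permutations decode to the same gate.

The program is solved by a generational genetic algorithm (tournament
selection, uniform crossover, per-gene mutation, elitism) restarted from
independent seeds; :func:`exhaustive_fit` enumerates the same model space
exactly and serves as the optimality oracle on small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .logic import HILL_GRID, HillParams, LogicModel, SimulationConfig, enumerate_gate_encodings
from .objective import (
    DatasetSimulator,
    ObjectiveConfig,
    PerturbationDataset,
    caps_for_nodes,
    indegree_penalty,
    prior_penalty,
)
from .prior import PriorNetwork

__all__ = [
    "SearchSpace",
    "GAConfig",
    "InferenceResult",
    "decode",
    "fit",
    "exhaustive_fit",
    "edge_diff",
]


@dataclass
class SearchSpace:
    """Candidate edge universe and gene layout for one inference problem."""

    nodes: list[str]
    candidate_edges: list[tuple[int, int]]
    h_grid: tuple[float, ...] = HILL_GRID
    p: int = 2
    roles: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_prior(
        cls,
        prior: PriorNetwork,
        restrict_to_prior: bool = False,
        extra_edges=(),
        h_grid=HILL_GRID,
        p: int = 2,
    ) -> "SearchSpace":
        """Full ordered-pair universe by default; optionally the prior's
        support plus a user-supplied addition set (for large problems)."""
        nodes = list(prior.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        stimulated = {index[n] for n in prior.stimulated}
        if restrict_to_prior:
            pairs = {(index[e.source], index[e.target]) for e in prior.edges}
            pairs |= {(index[s], index[t]) for s, t in extra_edges}
        else:
            m = len(nodes)
            pairs = {(i, j) for i in range(m) for j in range(m) if i != j}
        edges = sorted(
            (i, j) for (i, j) in pairs if j not in stimulated and i != j
        )
        if not edges:
            raise ValueError("infeasible search space: no admissible candidate edge")
        return cls(nodes=nodes, candidate_edges=edges, h_grid=tuple(h_grid), p=p,
                   roles=dict(prior.roles))

    def __post_init__(self) -> None:
        self.sources_per_target: dict[int, list[int]] = {}
        for i, j in self.candidate_edges:
            self.sources_per_target.setdefault(j, []).append(i)
        #: chromosome length: 3 genes per edge + 1 global h gene
        self.length = 3 * len(self.candidate_edges) + 1
        #: upper bound of each clause gene (max possible indegree of the target)
        self.clause_bound = [
            max(1, len(self.sources_per_target[j])) for (_, j) in self.candidate_edges
        ]

    def gene_bounds(self) -> np.ndarray:
        """Exclusive upper bound of every gene (genes are 0-based ints)."""
        bounds = np.empty(self.length, dtype=np.int64)
        for e in range(len(self.candidate_edges)):
            bounds[3 * e] = 2
            bounds[3 * e + 1] = 2
            bounds[3 * e + 2] = self.clause_bound[e]
        bounds[-1] = len(self.h_grid)
        return bounds


def decode(chromosome, space: SearchSpace) -> LogicModel:
    """Deterministically map a chromosome to a :class:`LogicModel`.

    Clause genes of excluded edges are ignored; labels of included edges are
    reduced modulo the realized indegree and renumbered in order of first
    appearance, so chromosomes differing by a label permutation decode to
    semantically identical gates.
    """
    chrom = np.asarray(chromosome, dtype=np.int64)
    if chrom.shape != (space.length,):
        raise ValueError(f"chromosome length must be {space.length}, got {chrom.shape}")
    m = len(space.nodes)
    B = np.zeros((m, m), dtype=np.int8)
    R = np.zeros((m, m), dtype=np.int8)
    C = np.zeros((m, m), dtype=np.int32)
    raw: dict[int, list[tuple[int, int, int]]] = {}
    for e, (i, j) in enumerate(space.candidate_edges):
        if chrom[3 * e]:
            raw.setdefault(j, []).append((i, int(chrom[3 * e + 1]), int(chrom[3 * e + 2])))
    for j, entries in raw.items():
        k = len(entries)
        relabel: dict[int, int] = {}
        for i, sign, cgene in entries:  # entries are in ascending source order
            B[i, j] = 1
            R[i, j] = sign
            lab = cgene % k
            C[i, j] = relabel.setdefault(lab, len(relabel) + 1)
    h = space.h_grid[int(chrom[-1])]
    return LogicModel(nodes=list(space.nodes), B=B, R=R, C=C,
                      hill=HillParams(p=space.p, h=h), roles=dict(space.roles))


@dataclass(frozen=True)
class GAConfig:
    """Genetic algorithm settings (all configurable; sensible defaults)."""

    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1 / chromosome length
    elitism: int = 2
    tournament_size: int = 3
    init_include_prob: float = 0.2
    n_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        for name in ("crossover_rate", "init_include_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class InferenceResult:
    """Best model found, its objective decomposition and diagnostics."""

    model: LogicModel
    chromosome: tuple[int, ...] | None
    total: float
    parts: dict[str, float]
    restart_traces: list[list[float]]
    added_edges: list[tuple[str, str]]
    removed_edges: list[tuple[str, str]]
    n_evaluations: int = 0
    n_models_enumerated: int | None = None


class _Evaluator:
    """Caches fitness of decoded chromosomes within one fit call."""

    def __init__(self, dataset, prior, space, obj_cfg, sim_cfg):
        self.space = space
        self.prior = prior
        self.obj_cfg = obj_cfg
        self.simulator = DatasetSimulator(dataset, space.nodes, sim_cfg) if dataset else None
        self.caps = caps_for_nodes(prior, space.nodes)
        self.W = prior.confidence_matrix(space.nodes)
        self.cache: dict[tuple[int, ...], tuple] = {}
        self.n_evaluations = 0

    def parts_for_model(self, model: LogicModel) -> tuple[float, float, float]:
        loss = self.simulator.loss(model, self.obj_cfg) if self.simulator else 0.0
        pp = prior_penalty(model.B, self.prior, self.space.nodes)
        ip = indegree_penalty(model.B, self.caps)
        return loss, pp, ip

    def key_for_model(self, model: LogicModel, tie=()):
        loss, pp, ip = self.parts_for_model(model)
        total = loss + self.obj_cfg.gamma * pp + self.obj_cfg.lam * ip
        n_edges = int(model.B.sum())
        # Lexicographic fitness: objective, then prior agreement, then
        # sparsity, then a deterministic tail (chromosome / enumeration order).
        return (total, pp, n_edges) + tuple(tie), (loss, pp, ip, total)

    def evaluate(self, chrom: tuple[int, ...]):
        hit = self.cache.get(chrom)
        if hit is not None:
            return hit
        model = decode(chrom, self.space)
        self.n_evaluations += 1
        key, parts = self.key_for_model(model, tie=chrom)
        self.cache[chrom] = (key, parts)
        return key, parts


def _parts_dict(parts, obj_cfg) -> dict[str, float]:
    loss, pp, ip, total = parts
    return {
        "loss": loss,
        "prior_penalty": pp,
        "indegree_penalty": ip,
        "gamma_prior": obj_cfg.gamma * pp,
        "lambda_indegree": obj_cfg.lam * ip,
        "total": total,
    }


def edge_diff(model: LogicModel, prior: PriorNetwork):
    """Edges added to / removed from the prior support by the learned model."""
    learned = model.edge_set()
    known = prior.edge_set()
    return sorted(learned - known), sorted(known - learned)


def _random_population(rng, space: SearchSpace, size: int, include_prob: float):
    bounds = space.gene_bounds()
    pop = np.empty((size, space.length), dtype=np.int64)
    ne = len(space.candidate_edges)
    pop[:, 0:3 * ne:3] = rng.random((size, ne)) < include_prob
    pop[:, 1:3 * ne:3] = rng.integers(0, 2, (size, ne))
    for e in range(ne):
        pop[:, 3 * e + 2] = rng.integers(0, bounds[3 * e + 2], size)
    pop[:, -1] = rng.integers(0, bounds[-1], size)
    return pop


def fit(
    dataset: PerturbationDataset,
    prior: PriorNetwork,
    obj_config: ObjectiveConfig | None = None,
    ga_config: GAConfig | None = None,
    space: SearchSpace | None = None,
    sim_config: SimulationConfig | None = None,
    pin_prior_signs: bool = False,
) -> InferenceResult:
    """Knowledge-guided model inference by multi-restart genetic algorithm.

    Runs ``ga_config.n_restarts`` independent GA runs seeded ``seed``,
    ``seed + 1``, ... and returns the best-of-restarts model; ties are
    broken by lower prior penalty, fewer edges, then lexicographically
    smaller chromosome, so results are a pure function of inputs and seed.
    With ``pin_prior_signs`` the sign genes of edges present in the prior
    are fixed to the prior's signs.
    """
    obj_cfg = obj_config or ObjectiveConfig()
    ga_cfg = ga_config or GAConfig()
    space = space or SearchSpace.from_prior(prior)
    ev = _Evaluator(dataset, prior, space, obj_cfg, sim_config)

    pinned: dict[int, int] = {}
    if pin_prior_signs:
        index = {n: i for i, n in enumerate(space.nodes)}
        prior_signs = {
            (index[e.source], index[e.target]): (1 if e.sign == 1 else 0)
            for e in prior.edges
        }
        for e, pair in enumerate(space.candidate_edges):
            if pair in prior_signs:
                pinned[3 * e + 1] = prior_signs[pair]

    bounds = space.gene_bounds()
    mut_rate = ga_cfg.mutation_rate or 1.0 / space.length
    best_key = None
    best_parts = None
    traces: list[list[float]] = []

    for restart in range(ga_cfg.n_restarts):
        rng = np.random.default_rng(ga_cfg.seed + restart)
        pop = _random_population(rng, space, ga_cfg.population_size, ga_cfg.init_include_prob)
        for pos, val in pinned.items():
            pop[:, pos] = val
        trace: list[float] = []
        run_best = None
        for _gen in range(ga_cfg.generations):
            scored = [ev.evaluate(tuple(ind)) for ind in pop]
            order = sorted(range(len(pop)), key=lambda idx: scored[idx][0])
            gen_best = scored[order[0]]
            if run_best is None or gen_best[0] < run_best[0]:
                run_best = gen_best
            trace.append(run_best[1][3])
            # Next generation: elites + tournament / crossover / mutation.
            elite = [pop[i].copy() for i in order[: ga_cfg.elitism]]
            children = []
            while len(children) < ga_cfg.population_size - len(elite):
                def pick():
                    contenders = rng.integers(0, len(pop), ga_cfg.tournament_size)
                    winner = min(contenders, key=lambda idx: scored[idx][0])
                    return pop[winner].copy()

                a, b = pick(), pick()
                if rng.random() < ga_cfg.crossover_rate:
                    swap = rng.random(space.length) < 0.5
                    a[swap], b[swap] = b[swap], a[swap].copy()
                for child in (a, b):
                    mut = rng.random(space.length) < mut_rate
                    for pos in np.flatnonzero(mut):
                        child[pos] = rng.integers(0, bounds[pos])
                    for pos, val in pinned.items():
                        child[pos] = val
                    children.append(child)
            pop = np.asarray(elite + children[: ga_cfg.population_size - len(elite)])
        # Score the final generation too.
        for ind in pop:
            key, parts = ev.evaluate(tuple(ind))
            if key < run_best[0]:
                run_best = (key, parts)
        trace.append(run_best[1][3])
        traces.append(trace)
        if best_key is None or run_best[0] < best_key:
            best_key, best_parts = run_best

    chrom = tuple(int(g) for g in best_key[3:])
    model = decode(chrom, space)
    added, removed = edge_diff(model, prior)
    return InferenceResult(
        model=model,
        chromosome=chrom,
        total=best_parts[3],
        parts=_parts_dict(best_parts, obj_cfg),
        restart_traces=traces,
        added_edges=added,
        removed_edges=removed,
        n_evaluations=ev.n_evaluations,
    )


def _target_options(space: SearchSpace, j: int):
    """Every (parents, signs, labels) gate choice for target ``j``."""
    sources = space.sources_per_target.get(j, [])
    options = [((), (), ())]
    for mask in range(1, 1 << len(sources)):
        parents = tuple(sources[b] for b in range(len(sources)) if mask >> b & 1)
        k = len(parents)
        for signs in product((1, 0), repeat=k):
            for labels in enumerate_gate_encodings(k):
                options.append((parents, signs, labels))
    return options


def exhaustive_fit(
    dataset: PerturbationDataset | None,
    prior: PriorNetwork,
    obj_config: ObjectiveConfig | None = None,
    space: SearchSpace | None = None,
    sim_config: SimulationConfig | None = None,
    max_models: int = 2_000_000,
) -> InferenceResult:
    """Enumerate every admissible (B, C, R, h) model and return the optimum.

    The exact oracle used to validate the genetic algorithm on small
    problems; refuses spaces larger than ``max_models``.  ``dataset=None``
    scores the penalty-only objective.
    """
    obj_cfg = obj_config or ObjectiveConfig()
    space = space or SearchSpace.from_prior(prior)
    ev = _Evaluator(dataset, prior, space, obj_cfg, sim_config)

    m = len(space.nodes)
    targets = sorted(space.sources_per_target)
    per_target = [_target_options(space, j) for j in targets]
    n_models = len(space.h_grid)
    for opts in per_target:
        n_models *= len(opts)
        if n_models > max_models:
            raise ValueError(
                f"search space exceeds max_models={max_models}; use the GA instead"
            )

    best_key = None
    best_parts = None
    best_model = None
    count = 0
    for combo in product(*per_target):
        B = np.zeros((m, m), dtype=np.int8)
        R = np.zeros((m, m), dtype=np.int8)
        C = np.zeros((m, m), dtype=np.int32)
        struct_tie = []
        for j, (parents, signs, labels) in zip(targets, combo):
            for i, s, lab in zip(parents, signs, labels):
                B[i, j] = 1
                R[i, j] = s
                C[i, j] = lab
            struct_tie.extend((j,) + parents + signs + labels)
        for hi, h in enumerate(space.h_grid):
            count += 1
            model = LogicModel(
                nodes=list(space.nodes), B=B.copy(), R=R.copy(), C=C.copy(),
                hill=HillParams(p=space.p, h=h), roles=dict(space.roles),
            )
            key, parts = ev.key_for_model(model, tie=tuple(struct_tie) + (hi,))
            if best_key is None or key < best_key:
                best_key, best_parts, best_model = key, parts, model

    added, removed = edge_diff(best_model, prior)
    return InferenceResult(
        model=best_model,
        chromosome=None,
        total=best_parts[3],
        parts=_parts_dict(best_parts, obj_cfg),
        restart_traces=[],
        added_edges=added,
        removed_edges=removed,
        n_evaluations=ev.n_evaluations,
        n_models_enumerated=count,
    )
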