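"""Evaluating learned models: structure recovery, significance, cell fates.

* :func:`structural_distance` — edit distance (additions + deletions)
  between directed edge sets, the headline metric of the synthetic study.
* :func:`run_prior_ratio_experiment` — the prior/noise-ratio harness:
  repeatedly perturb the prior, refit, and record structural distances.
* :func:`random_prior_null` — significance of a learned model against
  degree-constrained random prior networks (z-score and empirical p).
* :func:`predict_cell_fates` — Boolean cell-fate sampling: binarized
  phosphoproteomic states seed repeated synchronous Boolean runs and the
  fraction of runs whose attractor switches each fate node on is reported
  per experimental time point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .inference import GAConfig, InferenceResult, fit
from .logic import HillParams, LogicModel, SimulationConfig
from .objective import ObjectiveConfig, PerturbationDataset
from .prior import Edge, PriorNetwork
from .synthetic import perturb_prior

__all__ = [
    "ExperimentGrid",
    "NullTestResult",
    "structural_distance",
    "run_prior_ratio_experiment",
    "random_prior_like",
    "random_prior_null",
    "binarize",
    "predict_cell_fates",
    "fate_correlation",
]


def _edge_set(obj) -> set[tuple[str, str]]:
    if isinstance(obj, (LogicModel, PriorNetwork)):
        return obj.edge_set()
    if isinstance(obj, InferenceResult):
        return obj.model.edge_set()
    return {(s, t) for (s, t) in obj}


def structural_distance(learned, truth) -> int:
    """Edge additions plus deletions converting ``learned`` into ``truth``.

    Operates on directed (source, target) pairs; signs and gate structure
    are ignored.  Accepts models, prior networks, inference results or bare
    edge collections.
    """
    a, b = _edge_set(learned), _edge_set(truth)
    return len(a - b) + len(b - a)


@dataclass(frozen=True)
class ExperimentGrid:
    """Grid of prior/noise ratios for the structure-recovery experiment."""

    prior_ratios: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    noise_ratios: tuple = (0.0,)
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 or r > 1 for r in self.prior_ratios):
            raise ValueError("prior ratios must lie in [0, 1]")
        if any(r < 0 for r in self.noise_ratios):
            raise ValueError("noise ratios must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def run_prior_ratio_experiment(
    truth: LogicModel,
    dataset: PerturbationDataset,
    grid: ExperimentGrid,
    obj_config: ObjectiveConfig | None = None,
    ga_config: GAConfig | None = None,
    sim_config: SimulationConfig | None = None,
    d_max_default: int | None = 2,
) -> pd.DataFrame:
    """Structure recovery as a function of prior completeness and noise.

    For every (prior_ratio, noise_ratio) cell and repeat, a prior is drawn
    (true edges sampled uniformly, noise edges added, Uniform(0,1)
    confidences), the model is refit, and the structural distance to the
    truth recorded.  Returns a tidy table with one row per repeat; all
    randomness derives deterministically from ``grid.seed``.
    """
    obj_cfg = obj_config or ObjectiveConfig()
    ga_cfg = ga_config or GAConfig()
    rows = []
    for ci, pr in enumerate(grid.prior_ratios):
        for cj, nr in enumerate(grid.noise_ratios):
            for rep in range(grid.n_repeats):
                ss = np.random.SeedSequence([grid.seed, ci, cj, rep])
                prior_seed, ga_seed = (int(s) % 2**31 for s in ss.generate_state(2))
                prior = perturb_prior(truth, pr, nr, seed=prior_seed,
                                      d_max_default=d_max_default)
                result = fit(dataset, prior, obj_cfg,
                             replace(ga_cfg, seed=ga_seed), sim_config=sim_config)
                rows.append({
                    "prior_ratio": pr,
                    "noise_ratio": nr,
                    "repeat": rep,
                    "sd": structural_distance(result.model, truth),
                    "total": result.total,
                    "loss": result.parts["loss"],
                })
    return pd.DataFrame(rows)


def random_prior_like(prior: PriorNetwork, seed: int = 0, retry_cap: int = 10_000) -> PriorNetwork:
    """A random network sharing the prior's node set and edge count.

    Constraints: every node is incident to at least one edge; stimulated
    nodes have no incoming edge but at least one outgoing edge; confidence
    scores are resampled (with replacement) from the original prior's
    scores.  Uses rejection sampling with a deterministic seed stream.
    """
    rng = np.random.default_rng(seed)
    stim = set(prior.stimulated)
    n_edges = len(prior.edges)
    pool = sorted(
        (s, t) for s in prior.nodes for t in prior.nodes
        if s != t and t not in stim
    )
    if n_edges > len(pool):
        raise ValueError("prior has more edges than admissible ordered pairs")
    scores = [e.confidence for e in prior.edges]
    for _ in range(retry_cap):
        picked = [pool[int(k)] for k in rng.choice(len(pool), size=n_edges, replace=False)]
        incident: dict[str, int] = {n: 0 for n in prior.nodes}
        outgoing: dict[str, int] = {n: 0 for n in prior.nodes}
        for (s, t) in picked:
            incident[s] += 1
            incident[t] += 1
            outgoing[s] += 1
        if any(c == 0 for c in incident.values()):
            continue
        if any(outgoing[s] == 0 for s in stim):
            continue
        confs = rng.choice(scores, size=n_edges, replace=True)
        signs = rng.integers(0, 2, size=n_edges)
        edges = [
            Edge(s, t, 1 if sg else -1, float(c))
            for (s, t), sg, c in zip(picked, signs, confs)
        ]
        return PriorNetwork(nodes=list(prior.nodes), roles=dict(prior.roles),
                            edges=edges, d_max=dict(prior.d_max),
                            d_max_default=prior.d_max_default)
    raise ValueError("could not satisfy the random-network constraints "
                     f"within {retry_cap} attempts")


@dataclass
class NullTestResult:
    z_score: float
    empirical_p: float
    loss_true: float
    random_losses: np.ndarray


def random_prior_null(
    prior: PriorNetwork,
    dataset: PerturbationDataset,
    obj_config: ObjectiveConfig | None = None,
    ga_config: GAConfig | None = None,
    n_random: int = 500,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
) -> NullTestResult:
    """Significance of the knowledge-guided fit against random priors.

    Fits the model once with the true prior and ``n_random`` times with
    random networks from :func:`random_prior_like` used as the prior, and
    compares the best data losses: ``z = (mean_random - loss_true) /
    sd_random``; the empirical p-value is the fraction of random losses at
    or below the true loss.
    """
    if not prior.stimulated:
        raise ValueError("the prior must declare at least one stimulated node")
    obj_cfg = obj_config or ObjectiveConfig()
    ga_cfg = ga_config or GAConfig()
    true_fit = fit(dataset, prior, obj_cfg, ga_cfg, sim_config=sim_config)
    loss_true = true_fit.parts["loss"]
    losses = np.empty(n_random)
    for k in range(n_random):
        ss = np.random.SeedSequence([seed, k])
        net_seed, ga_seed = (int(s) % 2**31 for s in ss.generate_state(2))
        rand_net = random_prior_like(prior, seed=net_seed)
        res = fit(dataset, rand_net, obj_cfg, replace(ga_cfg, seed=ga_seed),
                  sim_config=sim_config)
        losses[k] = res.parts["loss"]
    sd = float(np.std(losses, ddof=1)) if n_random > 1 else float("nan")
    z = (float(np.mean(losses)) - loss_true) / sd if sd else float("inf")
    p = float(np.mean(losses <= loss_true))
    return NullTestResult(z_score=z, empirical_p=p, loss_true=loss_true,
                          random_losses=losses)


def binarize(values, threshold: float = 0.5):
    """Binarize normalized data: values >= threshold map to 1, else 0."""
    if isinstance(values, pd.DataFrame):
        return (values >= threshold).astype(int)
    return (np.asarray(values) >= threshold).astype(int)


def _boolean_plan(model: LogicModel, extra_nodes, fate_edges):
    """Per-node clause lists for the model extended with fate nodes."""
    names = list(model.nodes) + list(extra_nodes)
    index = {n: k for k, n in enumerate(names)}
    clauses: list[list[list[tuple[int, bool]]]] = [[] for _ in names]
    node_ptr, clause_ptr, parents, signs = model.plan()
    for j in range(model.m):
        for c in range(node_ptr[j], node_ptr[j + 1]):
            clauses[j].append([
                (int(parents[t]), bool(signs[t]))
                for t in range(clause_ptr[c], clause_ptr[c + 1])
            ])
    for (src, fate, sign) in fate_edges:
        clauses[index[fate]].append([(index[src], sign == 1)])  # OR-of-inputs
    return names, index, clauses


def _attractor_fate(state: int, clauses, mask_bits, cap: int = 10_000):
    """Run a synchronous Boolean simulation to its attractor.

    States are bitmask integers.  Returns ``(cycle_states,)`` — the list of
    states in the reached attractor (length 1 for a fixed point).
    """
    seen: dict[int, int] = {}
    history: list[int] = []
    x = state
    for step in range(cap):
        if x in seen:
            return history[seen[x]:]
        seen[x] = step
        history.append(x)
        new = x
        for j, cls in enumerate(clauses):
            if not cls:
                continue
            val = 0
            for clause in cls:
                v = 1
                for (i, act) in clause:
                    bit = (x >> i) & 1
                    if (bit if act else 1 - bit) == 0:
                        v = 0
                        break
                if v:
                    val = 1
                    break
            if val:
                new |= 1 << j
            else:
                new &= ~(1 << j)
        x = new
    raise RuntimeError("no attractor found within the step cap")  # pragma: no cover


def predict_cell_fates(
    model: LogicModel,
    fate_edges,
    phospho: pd.DataFrame,
    n_runs: int = 10_000,
    seed: int = 0,
    threshold: float = 0.5,
    cycle_rule: str = "majority",
) -> pd.DataFrame:
    """Boolean cell-fate fractions per experimental time point.

    ``fate_edges`` is a list of ``(signaling_node, fate_node, sign)``; fate
    nodes must not belong to the model and are attached with OR-of-inputs
    gates.  For each time point of ``phospho`` (rows = time, columns =
    measured nodes), the measured nodes are initialized to their binarized
    values and every other node (including fates) to an independent
    Bernoulli(0.5) state; the synchronous Boolean dynamics runs to its
    attractor.  A fate counts as true at a fixed point iff its bit is set;
    on a cycle, under ``cycle_rule="majority"`` iff it is set in at least
    half of the cycle's states (``"strict"`` never counts cycles).  Returns
    fractions over ``n_runs`` runs, one row per time point.
    """
    fate_nodes: list[str] = []
    for (_, fate, sign) in fate_edges:
        if sign not in (1, -1):
            raise ValueError("fate edge signs must be +1 or -1")
        if fate in model.nodes:
            raise ValueError(f"fate node {fate!r} already belongs to the model")
        if fate not in fate_nodes:
            fate_nodes.append(fate)
    if not fate_nodes:
        raise ValueError("at least one fate edge is required")
    if cycle_rule not in ("majority", "strict"):
        raise ValueError("cycle_rule must be 'majority' or 'strict'")

    names, index, clauses = _boolean_plan(model, fate_nodes, fate_edges)
    missing = [c for c in phospho.columns if c not in index]
    if missing:
        raise ValueError(f"phospho columns absent from the model: {missing}")
    data = binarize(phospho, threshold)
    measured_idx = [index[c] for c in phospho.columns]
    free_idx = [k for k in range(len(names)) if k not in set(measured_idx)]

    rng = np.random.default_rng(seed)
    fate_bits = [index[f] for f in fate_nodes]
    out = np.zeros((len(data), len(fate_nodes)))
    for row, (_, values) in enumerate(data.iterrows()):
        base = 0
        for i, v in zip(measured_idx, values.to_numpy()):
            if v:
                base |= 1 << i
        free_states = rng.integers(0, 2, size=(n_runs, len(free_idx)))
        for run in range(n_runs):
            x = base
            for i, v in zip(free_idx, free_states[run]):
                if v:
                    x |= 1 << i
            cycle = _attractor_fate(x, clauses, len(names))
            for fi, bit in enumerate(fate_bits):
                if len(cycle) == 1:
                    on = (cycle[0] >> bit) & 1
                elif cycle_rule == "majority":
                    on = sum((s >> bit) & 1 for s in cycle) * 2 >= len(cycle)
                else:
                    on = False
                if on:
                    out[row, fi] += 1
    return pd.DataFrame(out / n_runs, index=data.index, columns=fate_nodes)


def fate_correlation(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    drop_points=(),
) -> dict[str, float]:
    """Per-fate Pearson correlation after dropping predicted time points.

    ``drop_points`` are positional indices into ``predicted`` excluded
    before alignment (e.g. to absorb the delay between signaling changes
    and observable fate changes); afterwards the series lengths must match.
    """
    keep = [k for k in range(len(predicted)) if k not in set(drop_points)]
    pred = predicted.iloc[keep]
    if len(pred) != len(observed):
        raise ValueError(
            f"length mismatch after alignment: {len(pred)} vs {len(observed)}"
        )
    result = {}
    for fate in predicted.columns:
        if fate not in observed.columns:
            continue
        r, _ = stats.pearsonr(pred[fate].to_numpy(), observed[fate].to_numpy())
        result[fate] = float(r)
    return result
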