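"""Scoring candidate models against perturbation data.

The objective minimized during inference is

    sum_j L(y_j, z_j)  +  gamma * sum_ij |B_ij - W_ij|  +  lambda * sum_j max(0, indeg_j - dmax_j)

where ``L`` is the mean squared error for steady-state data or a dynamic
time warping (DTW) loss for time series, ``W`` is the prior confidence
matrix (0 off the prior), and ``dmax_j`` is the knowledge-derived cap on
direct regulators.  The quantitative prior term makes including a
confidence-``w`` prior edge cost ``1 - w``, excluding it cost ``w``, and
including a non-prior edge cost 1; on binary confidences it reduces to the
classical qualitative edge-disagreement count against the prior edge set.

DTW aligns an experimental series of ``n_y`` points against a denser
simulated series (``n_z = 3 n_y`` by default) under monotone, continuous,
endpoint-pinned warping; the accumulated squared cost is normalized by the
alignment length so losses are comparable across paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .logic import LogicModel, SimulationConfig, simulate_steady_state, simulate_timeseries
from .prior import PriorNetwork

__all__ = [
    "Condition",
    "PerturbationDataset",
    "WarpPath",
    "ObjectiveConfig",
    "mse_loss",
    "dtw_align",
    "dtw_loss",
    "timeseries_loss",
    "prior_penalty",
    "indegree_penalty",
    "DatasetSimulator",
    "objective",
    "per_node_error_table",
]


@dataclass(frozen=True)
class Condition:
    """One experimental condition: stimulus clamps and inhibited nodes."""

    stimuli: tuple = ()
    inhibited: frozenset = frozenset()

    @classmethod
    def make(cls, stimuli: dict[str, float] | None = None, inhibited=()) -> "Condition":
        return cls(tuple(sorted((stimuli or {}).items())), frozenset(inhibited))

    def clamp_map(self) -> dict[str, float]:
        """Stimulus clamps plus inhibited nodes clamped to 0."""
        clamps = {n: float(v) for n, v in self.stimuli}
        for n in self.inhibited:
            clamps[n] = 0.0
        return clamps


@dataclass
class PerturbationDataset:
    """Measured node values under perturbation, steady-state or time series.

    For ``kind == "steady_state"``, ``values[c, k]`` is the measurement of
    ``measured_nodes[k]`` under ``conditions[c]``.  For
    ``kind == "time_series"``, ``series[c][t, k]`` is the value at the
    ``t``-th experimental time point (``times[c][t]``) of the series
    recorded under ``conditions[c]``.  All values lie in [0, 1].
    """

    kind: str
    measured_nodes: list[str]
    conditions: list[Condition]
    values: np.ndarray | None = None
    series: list[np.ndarray] | None = None
    times: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("steady_state", "time_series"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if self.kind == "steady_state":
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (len(self.conditions), len(self.measured_nodes)):
                raise ValueError("values must be (n_conditions, n_measured)")
            self._check_range(self.values)
        else:
            if not self.series or len(self.series) != len(self.conditions):
                raise ValueError("one series per condition is required")
            self.series = [np.asarray(s, dtype=float) for s in self.series]
            for s in self.series:
                if s.ndim != 2 or s.shape[1] != len(self.measured_nodes):
                    raise ValueError("each series must be (n_y, n_measured)")
                if s.shape[0] < 2:
                    raise ValueError("time series need at least 2 time points")
                self._check_range(s)
            if self.times is None:
                self.times = [np.arange(s.shape[0], dtype=float) for s in self.series]

    @staticmethod
    def _check_range(arr: np.ndarray) -> None:
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError("measured values must lie in [0, 1]; normalize first")

    @classmethod
    def steady_state(cls, measured_nodes, conditions, values) -> "PerturbationDataset":
        return cls("steady_state", list(measured_nodes), list(conditions), values=values)

    @classmethod
    def time_series(cls, measured_nodes, conditions, series, times=None) -> "PerturbationDataset":
        return cls("time_series", list(measured_nodes), list(conditions),
                   series=list(series), times=times)


@dataclass(frozen=True)
class WarpPath:
    """A DTW alignment: paired 0-based index vectors into y and z."""

    a: np.ndarray
    b: np.ndarray

    @property
    def S(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights of the two knowledge regularizers and DTW window settings.

    ``gamma`` weighs prior-edge violations, ``lam`` weighs indegree-cap
    excess; holding equal confidence in both kinds of prior knowledge they
    are set equal by default.  ``window_factor * n_y`` is the DTW window
    length; with the default simulated length of ``3 n_y`` this is one
    window covering the whole simulation.  Setting ``window_stride`` slides
    the window along a longer simulation and keeps the minimum loss.
    """

    gamma: float = 0.5
    lam: float = 0.5
    window_factor: int = 3
    window_stride: int | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("gamma and lambda must be non-negative")


def mse_loss(y, z) -> float:
    """Mean squared error between experimental and predicted values."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {z.shape}")
    return float(np.mean((y - z) ** 2))


def dtw_align(y, z) -> tuple[WarpPath, float]:
    """Optimal warping path and normalized loss between two sequences.

    Dynamic program minimizing the accumulated squared difference over all
    paths that start at ``(0, 0)``, end at ``(n_y-1, n_z-1)`` and advance
    one or both indices by exactly 1 per step (continuity + monotonicity).
    The returned loss is the minimum total cost divided by the path length
    ``S``; ties are broken toward the shorter path, then toward advancing
    both indices.
    """
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    ny, nz = len(y), len(z)
    if ny == 0 or nz == 0:
        raise ValueError("sequences must be non-empty")
    D = np.empty((ny, nz))
    L = np.empty((ny, nz), dtype=np.int64)
    back = np.zeros((ny, nz), dtype=np.int8)  # 0 diag, 1 up (i-1), 2 left (j-1)
    D[0, 0] = (y[0] - z[0]) ** 2
    L[0, 0] = 1
    for j in range(1, nz):
        D[0, j] = D[0, j - 1] + (y[0] - z[j]) ** 2
        L[0, j] = j + 1
        back[0, j] = 2
    for i in range(1, ny):
        D[i, 0] = D[i - 1, 0] + (y[i] - z[0]) ** 2
        L[i, 0] = i + 1
        back[i, 0] = 1
    for i in range(1, ny):
        for j in range(1, nz):
            c = (y[i] - z[j]) ** 2
            best, blen, move = D[i - 1, j - 1], L[i - 1, j - 1], 0
            if D[i - 1, j] < best or (D[i - 1, j] == best and L[i - 1, j] < blen):
                best, blen, move = D[i - 1, j], L[i - 1, j], 1
            if D[i, j - 1] < best or (D[i, j - 1] == best and L[i, j - 1] < blen):
                best, blen, move = D[i, j - 1], L[i, j - 1], 2
            D[i, j] = best + c
            L[i, j] = blen + 1
            back[i, j] = move
    # Backtrack.
    i, j = ny - 1, nz - 1
    ai, bi = [i], [j]
    while i or j:
        move = back[i, j]
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
        ai.append(i)
        bi.append(j)
    path = WarpPath(np.asarray(ai[::-1]), np.asarray(bi[::-1]))
    return path, float(D[ny - 1, nz - 1] / L[ny - 1, nz - 1])


def dtw_loss(y, z) -> float:
    """Normalized DTW loss only (compiled fast path when available)."""
    y = np.ascontiguousarray(y, dtype=float).ravel()
    z = np.ascontiguousarray(z, dtype=float).ravel()
    if len(y) == 0 or len(z) == 0:
        raise ValueError("sequences must be non-empty")
    if _fast.HAVE_NUMBA:
        return float(_fast.dtw_loss(y, z))
    return dtw_align(y, z)[1]


def timeseries_loss(
    dataset: PerturbationDataset,
    simulated,
    window_factor: int = 3,
    window_stride: int | None = None,
) -> float:
    """Total DTW loss of a dataset against simulated series.

    ``simulated`` is one ``(n_z, n_measured)`` array per dataset series
    (columns in dataset order).  Per measured node the experimental series
    is aligned against the simulated window (the full series by default;
    with ``window_stride`` the minimum over sliding window placements is
    used) and the per-node losses are summed over nodes and series.
    """
    if dataset.kind != "time_series":
        raise ValueError("timeseries_loss requires a time-series dataset")
    if isinstance(simulated, np.ndarray):
        simulated = [simulated]
    if len(simulated) != len(dataset.series):
        raise ValueError("need one simulated series per experimental series")
    total = 0.0
    for ys, zs in zip(dataset.series, simulated):
        zs = np.asarray(zs, dtype=float)
        if zs.ndim != 2 or zs.shape[1] != len(dataset.measured_nodes):
            raise ValueError("simulated series must be (n_z, n_measured)")
        win = window_factor * ys.shape[0]
        starts = [0]
        if window_stride and zs.shape[0] > win:
            starts = list(range(0, zs.shape[0] - win + 1, window_stride))
        for k in range(ys.shape[1]):
            total += min(
                dtw_loss(ys[:, k], zs[s:s + win, k]) for s in starts
            )
    return total


def prior_penalty(B, prior: PriorNetwork, nodes: list[str] | None = None) -> float:
    """Quantitative prior violation: sum over ordered pairs of |B_ij - w_ij|.

    ``w_ij`` is the prior confidence (0 for pairs absent from the prior).
    Diagonal entries are excluded (self-regulation is outside the model
    class).  With all confidences in {0, 1} this equals the number of edge
    disagreements with the qualitative prior edge set.
    """
    B = np.asarray(B, dtype=float)
    W = prior.confidence_matrix(nodes)
    if B.shape != W.shape:
        raise ValueError("B and prior are over different node sets")
    diff = np.abs(B - W)
    np.fill_diagonal(diff, 0.0)
    return float(diff.sum())


def indegree_penalty(B, d_max) -> float:
    """Hinge penalty on nodes whose indegree exceeds their cap.

    ``d_max`` is a per-column sequence of caps; ``None`` entries are
    uncapped.
    """
    B = np.asarray(B)
    indeg = B.sum(axis=0)
    total = 0.0
    for j, cap in enumerate(d_max):
        if cap is None:
            continue
        if cap < 0:
            raise ValueError("indegree caps must be non-negative")
        total += max(0.0, float(indeg[j]) - cap)
    return total


def caps_for_nodes(prior: PriorNetwork, nodes: list[str]) -> list[int | None]:
    return [prior.indegree_cap(n) for n in nodes]


class DatasetSimulator:
    """Precompiled simulation harness for repeatedly scoring models.

    Binds a dataset to a fixed node ordering, precomputing per-condition
    clamp arrays and initial states so a genetic-algorithm inner loop only
    pays for the simulation itself.  All candidate models must share the
    node ordering given here.
    """

    def __init__(
        self,
        dataset: PerturbationDataset,
        nodes: list[str],
        sim_config: SimulationConfig | None = None,
    ):
        self.dataset = dataset
        self.nodes = list(nodes)
        self.sim_config = sim_config or SimulationConfig()
        index = {n: i for i, n in enumerate(self.nodes)}
        missing = [n for n in dataset.measured_nodes if n not in index]
        if missing:
            raise ValueError(f"measured nodes absent from the model: {missing}")
        self.measured_idx = np.asarray(
            [index[n] for n in dataset.measured_nodes], dtype=np.int64
        )
        m = len(self.nodes)
        self._clamps = []
        for cond in dataset.conditions:
            mask = np.zeros(m, dtype=bool)
            vals = np.zeros(m)
            for n, v in cond.clamp_map().items():
                if n not in index:
                    raise ValueError(f"condition refers to unknown node {n!r}")
                mask[index[n]] = True
                vals[index[n]] = v
            self._clamps.append((mask, vals))
        if dataset.kind == "time_series":
            self._inits = []
            self._n_points = []
            for (mask, vals), ys in zip(self._clamps, dataset.series):
                x0 = np.zeros(m)
                x0[self.measured_idx] = ys[0]
                x0 = np.where(mask, vals, x0)
                self._inits.append(x0)
                self._n_points.append(self.sim_config.ts_length_factor * ys.shape[0])

    def _check(self, model: LogicModel) -> None:
        if model.nodes != self.nodes:
            raise ValueError("model node ordering differs from the simulator's")

    def simulate(self, model: LogicModel):
        """Simulated measured values: an array (steady state) or list of
        series arrays (time series), plus convergence flags for steady state."""
        self._check(model)
        cfg = self.sim_config
        boolean = cfg.mode == "boolean"
        plan = model.plan()
        p, h = model.hill.p, model.hill.h
        if self.dataset.kind == "steady_state":
            Z = np.empty((len(self._clamps), len(self.measured_idx)))
            flags = []
            max_iter = cfg.max_iter_factor * model.m
            for c, (mask, vals) in enumerate(self._clamps):
                x0 = np.where(mask, vals, 0.0)
                if _fast.HAVE_NUMBA:
                    x, conv, _ = _fast.sim_steady_state(
                        x0, *plan, mask, vals, p, h, boolean, cfg.epsilon, max_iter
                    )
                else:
                    clamp = {self.nodes[i]: vals[i] for i in np.flatnonzero(mask)}
                    x, conv, _ = simulate_steady_state(model, clamp, cfg)
                    x = np.asarray(x)
                Z[c] = x[self.measured_idx]
                flags.append(bool(conv))
            return Z, flags
        out = []
        for (mask, vals), x0, n_pts in zip(self._clamps, self._inits, self._n_points):
            if _fast.HAVE_NUMBA:
                traj = _fast.sim_timeseries(x0, *plan, mask, vals, p, h, boolean, n_pts)
            else:
                clamp = {self.nodes[i]: vals[i] for i in np.flatnonzero(mask)}
                traj = simulate_timeseries(model, x0, clamp, n_pts, cfg)
            out.append(traj[:, self.measured_idx])
        return out, None

    def loss(self, model: LogicModel, obj_config: "ObjectiveConfig | None" = None) -> float:
        sim, _ = self.simulate(model)
        cfg = obj_config or ObjectiveConfig()
        if self.dataset.kind == "steady_state":
            return mse_loss(self.dataset.values, sim)
        return timeseries_loss(self.dataset, sim, cfg.window_factor, cfg.window_stride)


def objective(
    model: LogicModel,
    dataset: PerturbationDataset,
    prior: PriorNetwork,
    config: ObjectiveConfig | None = None,
    sim_config: SimulationConfig | None = None,
) -> tuple[float, dict[str, float]]:
    """Full knowledge-guided objective and its decomposition.

    Returns ``(total, parts)`` with parts ``loss``, ``prior_penalty``,
    ``indegree_penalty`` (unweighted) and ``gamma_prior`` /
    ``lambda_indegree`` (weighted contributions).
    """
    cfg = config or ObjectiveConfig()
    simulator = DatasetSimulator(dataset, model.nodes, sim_config)
    loss = simulator.loss(model, cfg)
    pp = prior_penalty(model.B, prior, model.nodes)
    ip = indegree_penalty(model.B, caps_for_nodes(prior, model.nodes))
    total = loss + cfg.gamma * pp + cfg.lam * ip
    parts = {
        "loss": loss,
        "prior_penalty": pp,
        "indegree_penalty": ip,
        "gamma_prior": cfg.gamma * pp,
        "lambda_indegree": cfg.lam * ip,
        "total": total,
    }
    return total, parts


def per_node_error_table(dataset: PerturbationDataset, simulated) -> pd.DataFrame:
    """Per-measured-node squared-error summary for steady-state fits.

    Columns: ``LSE`` (sum of squared errors over conditions) and ``MSE``
    (``LSE / n_conditions``); the final ``total`` row sums both columns.
    """
    if dataset.kind != "steady_state":
        raise ValueError("per-node error tables are defined for steady-state data")
    Z = np.asarray(simulated, dtype=float)
    if Z.shape != dataset.values.shape:
        raise ValueError("simulated values must match the dataset shape")
    sq = (dataset.values - Z) ** 2
    lse = sq.sum(axis=0)
    mse = lse / sq.shape[0]
    table = pd.DataFrame({"LSE": lse, "MSE": mse}, index=dataset.measured_nodes)
    table.loc["total"] = [lse.sum(), mse.sum()]
    return table
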