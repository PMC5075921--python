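"""Readers and writers for the package's plain-text formats.

* Network TSV: ``source  sign  target  confidence`` (SIF plus a confidence
  column, sign in {1, -1}); roles TSV: ``node  role``.
* Endorsement TSV: ``source  sign  target  n_low  n_high``.
* Steady-state data: MIDAS-style CSV (``TR:`` treatments, ``DA:`` time,
  ``DV:`` values; a ``TR:<node>:i`` column flags an inhibitor) or a wide
  dialect with ``<node>:stim`` / ``<node>:inh`` columns.
* Time-series data: CSV with a strictly increasing ``time`` column and one
  column per measured node.
* Logic models: YAML with nodes, roles, Hill parameters and edge records
  ``(source, target, sign, clause)``.

All writers use a fixed ``%.6g`` float format and stable ordering so
identical inputs produce byte-identical files.  Inputs are expected to be
normalized to [0, 1] already; :func:`minmax_normalize` is offered as a
convenience only.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .logic import HillParams, LogicModel
from .objective import Condition, PerturbationDataset
from .prior import ROLES, Edge, EndorsementRecord, PriorNetwork

__all__ = [
    "read_network_tsv",
    "write_network_tsv",
    "read_roles_tsv",
    "write_roles_tsv",
    "read_endorsements_tsv",
    "read_midas_csv",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_model_yaml",
    "write_model_yaml",
    "minmax_normalize",
    "write_manifest",
]

_NET_HEADER = ["source", "sign", "target", "confidence"]


def _fmt(x: float) -> str:
    return f"{float(x):.6g}"


def read_network_tsv(path, roles: dict[str, str] | None = None) -> PriorNetwork:
    """Read a 4-column network TSV into a :class:`PriorNetwork`."""
    edges = []
    nodes: list[str] = []
    seen: set[str] = set()

    def add(n: str) -> None:
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (ln == 1 and row == _NET_HEADER):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            s, sign_s, t, conf_s = row
            if sign_s not in ("1", "-1"):
                raise ValueError(f"{path}:{ln}: sign must be 1 or -1, got {sign_s!r}")
            try:
                conf = float(conf_s)
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: bad confidence {conf_s!r}") from err
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"{path}:{ln}: confidence must be in [0, 1]")
            add(s)
            add(t)
            edges.append(Edge(s, t, int(sign_s), conf))
    roles = dict(roles or {})
    for n in roles:
        add(n)
    return PriorNetwork(nodes=nodes, roles=roles, edges=edges)


def write_network_tsv(net: PriorNetwork, path) -> None:
    lines = ["\t".join(_NET_HEADER)]
    for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.sign)):
        lines.append(f"{e.source}\t{e.sign}\t{e.target}\t{_fmt(e.confidence)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_roles_tsv(path) -> dict[str, str]:
    roles = {}
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (ln == 1 and row == ["node", "role"]):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{ln}: expected 'node<TAB>role'")
            node, role = row
            if role not in ROLES:
                raise ValueError(f"{path}:{ln}: unknown role {role!r}")
            roles[node] = role
    return roles


def write_roles_tsv(roles: dict[str, str], path) -> None:
    lines = ["node\trole"]
    for node in sorted(roles):
        lines.append(f"{node}\t{roles[node]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_endorsements_tsv(path) -> list[EndorsementRecord]:
    """Read ``source sign target n_low n_high`` endorsement records."""
    records = []
    header = ["source", "sign", "target", "n_low", "n_high"]
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (ln == 1 and row == header):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 tab-separated fields")
            s, sign_s, t, nl, nh = row
            if sign_s not in ("1", "-1"):
                raise ValueError(f"{path}:{ln}: sign must be 1 or -1")
            try:
                records.append(
                    EndorsementRecord(s, t, int(sign_s), int(nl), int(nh))
                )
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from err
    return records


def read_midas_csv(path) -> PerturbationDataset:
    """Read steady-state perturbation data.

    MIDAS convention: ``TR:<node>`` columns are stimuli (value 1 clamps the
    node to 1), ``TR:<node>:i`` columns flag inhibitors, ``DA:`` columns
    carry time stamps (ignored for steady state) and ``DV:<node>`` columns
    the measured values.  Alternatively a wide dialect with ``<node>:stim``
    and ``<node>:inh`` treatment columns, all remaining columns measured.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    midas = any(c.startswith(("TR:", "DV:", "DA:")) for c in cols)
    if midas:
        tr = [c for c in cols if c.startswith("TR:")]
        dv = [c for c in cols if c.startswith("DV:")]
        if not dv:
            raise ValueError(f"{path}: no DV: (measured value) columns found")
        measured = [c[3:] for c in dv]
        stim_cols = [(c, c[3:]) for c in tr if not c.endswith(":i")]
        inh_cols = [(c, c[3:-2]) for c in tr if c.endswith(":i")]
    else:
        stim_cols = [(c, c[:-5]) for c in cols if c.endswith(":stim")]
        inh_cols = [(c, c[:-4]) for c in cols if c.endswith(":inh")]
        treatment = {c for c, _ in stim_cols} | {c for c, _ in inh_cols}
        measured = [c for c in cols if c not in treatment]
        dv = measured
        if not measured:
            raise ValueError(f"{path}: no measured columns found")
    values = df[dv].to_numpy(dtype=float) if midas else df[measured].to_numpy(dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError(
            f"{path}: measured values outside [0, 1]; normalize the data first"
        )
    conditions = []
    for _, row in df.iterrows():
        stimuli = {
            node: float(row[c]) for c, node in stim_cols if float(row[c]) != 0.0
        }
        inhibited = [node for c, node in inh_cols if float(row[c]) != 0.0]
        conditions.append(Condition.make(stimuli, inhibited))
    return PerturbationDataset.steady_state(measured, conditions, values)


def read_timeseries_csv(path, stimuli: dict[str, float] | None = None,
                        inhibited=()) -> PerturbationDataset:
    """Read one temporally-ordered series (a ``time`` column + node columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"{path}: duplicate columns {dupes}")
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: a 'time' column is required")
    times = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: 'time' must be strictly increasing")
    measured = [c for c in df.columns if c != "time"]
    series = df[measured].to_numpy(dtype=float)
    if series.shape[0] < 2:
        raise ValueError(f"{path}: time series need at least 2 rows")
    cond = Condition.make(stimuli, inhibited)
    return PerturbationDataset.time_series(measured, [cond], [series], [times])


def write_timeseries_csv(times, values, columns, path) -> None:
    lines = [",".join(["time"] + list(columns))]
    for t, row in zip(times, np.asarray(values)):
        lines.append(",".join([_fmt(t)] + [_fmt(v) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_model_yaml(model: LogicModel, path) -> None:
    doc = {
        "nodes": list(model.nodes),
        "roles": {n: r for n, r in sorted(model.roles.items())},
        "hill": {"p": int(model.hill.p), "h": float(model.hill.h)},
        "edges": [
            {"source": s, "target": t, "sign": int(sign), "clause": int(c)}
            for (s, t, sign, c) in model.edge_records()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model_yaml(path) -> LogicModel:
    doc = yaml.safe_load(Path(path).read_text())
    edges = [
        (e["source"], e["target"], int(e["sign"]), int(e.get("clause", 1)))
        for e in doc.get("edges", [])
    ]
    hill = HillParams(p=int(doc["hill"]["p"]), h=float(doc["hill"]["h"]))
    return LogicModel.from_edges(doc["nodes"], edges, hill, doc.get("roles", {}))


def minmax_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min-max scaling to [0, 1] (constant columns map to 0)."""
    out = df.copy()
    for c in out.columns:
        col = out[c].astype(float)
        span = col.max() - col.min()
        out[c] = (col - col.min()) / span if span > 0 else 0.0
    return out


def write_manifest(output_path, command: str, params: dict) -> None:
    """Machine-readable run manifest written next to an output file."""
    manifest = {"command": command, "parameters": params}
    p = Path(str(output_path) + ".manifest.json")
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
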