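"""Confidence-scored prior knowledge networks.

A prior knowledge network (PKN) is a signed, directed graph of signaling
reactions harvested from the literature.  Each edge carries a confidence
score in [0, 0.95] derived from how many low-throughput and high-throughput
publications endorse the reaction: low-throughput studies have lower false
positive rates and therefore contribute more confidence per endorsement.

Nodes are annotated with experimental roles.  A node is *designated* when it
is stimulated, inhibited or measured in the experiment at hand; everything
else is *undesignated* and may be compressed away before inference, because
a protein that is neither perturbed nor observed is not identifiable from
the data.  Compression merges tandem edges through an undesignated node,
keeping the smaller of the two confidences (the bottleneck of the pathway)
and composing signs multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EndorsementRecord",
    "PriorNetwork",
    "DESIGNATED_ROLES",
    "ROLES",
    "classify_publication",
    "ht_threshold_from_counts",
    "score_reaction",
    "build_prior",
    "compress_network",
]

ROLES = ("stimulated", "inhibited", "measured", "undesignated")
DESIGNATED_ROLES = frozenset({"stimulated", "inhibited", "measured"})

#: Table of confidence scores for a reaction endorsed by exactly one class of
#: study; index = number of endorsing publications, saturating at the last row.
LOW_THROUGHPUT_SCORES = (0.0, 0.8, 0.9, 0.95, 0.95)
HIGH_THROUGHPUT_SCORES = (0.0, 0.25, 0.5, 0.75, 0.85)
#: Confidence added per high-throughput endorsement when both classes endorse.
HT_INCREMENT = 0.05
#: No reaction ever gets more confidence than this.
MAX_CONFIDENCE = 0.95
#: Default cutoff on reactions-per-publication above which a publication is
#: treated as high-throughput (the 90th percentile of a large pathway
#: database snapshot; recompute with :func:`ht_threshold_from_counts` for
#: other snapshots).
DEFAULT_HT_THRESHOLD = 111


@dataclass(frozen=True)
class EndorsementRecord:
    """Publication support for one signed reaction.

    ``sign`` is +1 for activation, -1 for inhibition.
    """

    source: str
    target: str
    sign: int
    n_low: int = 0
    n_high: int = 0

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign!r}")
        if self.n_low < 0 or self.n_high < 0:
            raise ValueError("endorsement counts must be non-negative")


@dataclass(frozen=True)
class Edge:
    """A signed, confidence-weighted directed edge."""

    source: str
    target: str
    sign: int
    confidence: float

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class PriorNetwork:
    """Signed, directed, confidence-weighted graph with node roles.

    Parameters
    ----------
    nodes:
        Unique node identifiers (order is preserved and meaningful: it fixes
        matrix layouts downstream).
    roles:
        Mapping node -> role, role in :data:`ROLES`.  Missing nodes default
        to ``"undesignated"``.
    edges:
        List of :class:`Edge`.
    d_max:
        Optional per-node cap on the number of incoming edges a context-
        specific model is expected to have; exceeding it is penalized (not
        forbidden) during inference.
    d_max_default:
        Cap applied to nodes absent from ``d_max``; ``None`` means no cap.
    """

    nodes: list[str]
    roles: dict[str, str] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    d_max: dict[str, int] = field(default_factory=dict)
    d_max_default: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node identifiers must be unique")
        known = set(self.nodes)
        for node, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for node {node!r}")
            if node not in known:
                raise ValueError(f"role given for undeclared node {node!r}")
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e.source}->{e.target} uses undeclared node")
        for node, cap in self.d_max.items():
            if cap < 0:
                raise ValueError(f"d_max for {node!r} must be non-negative")

    def role(self, node: str) -> str:
        return self.roles.get(node, "undesignated")

    def is_designated(self, node: str) -> bool:
        return self.role(node) in DESIGNATED_ROLES

    @property
    def stimulated(self) -> list[str]:
        return [n for n in self.nodes if self.role(n) == "stimulated"]

    @property
    def measured(self) -> list[str]:
        return [n for n in self.nodes if self.role(n) == "measured"]

    @property
    def inhibited(self) -> list[str]:
        return [n for n in self.nodes if self.role(n) == "inhibited"]

    def indegree_cap(self, node: str) -> int | None:
        return self.d_max.get(node, self.d_max_default)

    def edge_set(self) -> set[tuple[str, str]]:
        """Directed (source, target) pairs, signs ignored."""
        return {(e.source, e.target) for e in self.edges}

    def confidence_matrix(self, nodes: list[str] | None = None) -> np.ndarray:
        """Dense w[i, j] matrix (max over parallel signs), 0 where no edge."""
        nodes = self.nodes if nodes is None else nodes
        idx = {n: k for k, n in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for e in self.edges:
            i, j = idx[e.source], idx[e.target]
            w[i, j] = max(w[i, j], e.confidence)
        return w


def classify_publication(n_reactions: int, ht_threshold: int = DEFAULT_HT_THRESHOLD) -> str:
    """Classify a publication as high- or low-throughput.

    A publication endorsing strictly more than ``ht_threshold`` unique
    reactions is classified ``"high_throughput"``, otherwise
    ``"low_throughput"``.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be a positive integer")
    if ht_threshold < 1:
        raise ValueError("ht_threshold must be a positive integer")
    return "high_throughput" if n_reactions > ht_threshold else "low_throughput"


def ht_threshold_from_counts(reaction_counts, quantile: float = 0.9) -> int:
    """Derive the high-throughput cutoff from reactions-per-publication counts.

    Returns the smallest integer ``t`` such that at least ``quantile`` of
    publications endorse fewer than ``t`` reactions, so that
    ``classify_publication(count, t)`` labels roughly the top
    ``1 - quantile`` of publications high-throughput.
    """
    counts = np.asarray(list(reaction_counts))
    if counts.size == 0:
        raise ValueError("need at least one publication count")
    if np.any(counts < 1):
        raise ValueError("reaction counts must be positive")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    counts = np.sort(counts)
    n = counts.size
    for t in np.unique(counts):
        if np.count_nonzero(counts < t) / n >= quantile:
            return int(t)
    return int(counts[-1] + 1)


def score_reaction(n_low: int, n_high: int) -> float:
    """Confidence score of a reaction from its endorsement counts.

    If only one class of study endorses the reaction, the score is read
    directly from the per-class table (saturating at 4 endorsements).  If
    both classes endorse it, the low-throughput table value is incremented by
    :data:`HT_INCREMENT` per high-throughput endorsement.  The score never
    exceeds :data:`MAX_CONFIDENCE`.
    """
    if n_low < 0 or n_high < 0:
        raise ValueError("endorsement counts must be non-negative")
    lt = LOW_THROUGHPUT_SCORES[min(n_low, 4)]
    if n_high == 0:
        return lt
    if n_low == 0:
        return HIGH_THROUGHPUT_SCORES[min(n_high, 4)]
    return min(lt + HT_INCREMENT * n_high, MAX_CONFIDENCE)


def build_prior(
    records,
    roles: dict[str, str] | None = None,
    d_max: dict[str, int] | int | None = None,
    extra_nodes=(),
) -> PriorNetwork:
    """Aggregate endorsement records into a scored :class:`PriorNetwork`.

    Duplicate records for the same (source, target, sign) have their counts
    summed before scoring.  Edges scoring 0 (no endorsements) are dropped.
    ``d_max`` may be a per-node dict or a single cap applied to every node.
    """
    roles = dict(roles or {})
    for node, role in roles.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for node {node!r}")

    counts: dict[tuple[str, str, int], list[int]] = {}
    order: list[str] = []
    seen: set[str] = set()

    def _add_node(n: str) -> None:
        if n not in seen:
            seen.add(n)
            order.append(n)

    for rec in records:
        _add_node(rec.source)
        _add_node(rec.target)
        key = (rec.source, rec.target, rec.sign)
        c = counts.setdefault(key, [0, 0])
        c[0] += rec.n_low
        c[1] += rec.n_high
    for n in list(roles) + list(extra_nodes):
        _add_node(n)

    edges = []
    for (s, t, sign), (nl, nh) in sorted(counts.items()):
        w = score_reaction(nl, nh)
        if w > 0.0:
            edges.append(Edge(s, t, sign, w))

    if isinstance(d_max, int):
        caps, default = {}, d_max
    else:
        caps, default = dict(d_max or {}), None
    return PriorNetwork(nodes=order, roles=roles, edges=edges, d_max=caps, d_max_default=default)


def _compress_once(net: PriorNetwork) -> PriorNetwork | None:
    """Apply one compression step; return the new network or None if stable."""
    # Edge store keyed by (source, target, sign); parallel duplicates keep the
    # larger confidence (stronger evidence dominates).
    edges: dict[tuple[str, str, int], float] = {}
    for e in net.edges:
        key = (e.source, e.target, e.sign)
        edges[key] = max(edges.get(key, 0.0), e.confidence)

    changed = len(edges) != len(net.edges)

    # Stimulated nodes are inputs: they cannot have upstream regulators in an
    # executable model, so their incoming edges are unidentifiable.
    for key in [k for k in edges if net.role(k[1]) == "stimulated"]:
        del edges[key]
        changed = True

    removed_nodes: set[str] = set()
    for node in sorted(net.nodes):
        if net.is_designated(node) or node in removed_nodes:
            continue
        ins = [k for k in edges if k[1] == node and k[0] != node]
        outs = [k for k in edges if k[0] == node and k[1] != node]
        has_self = any(k[0] == node and k[1] == node for k in edges)
        if has_self:
            continue  # cannot merge through a self-regulating node
        if not ins or not outs:
            # Non-controllable or non-observable undesignated node: no signal
            # identifiable through it, drop it with its edges.
            for k in ins + outs:
                del edges[k]
            removed_nodes.add(node)
            changed = True
            continue
        if len(ins) > 1 and len(outs) > 1:
            continue  # crossroads node: merging would inflate the edge count
        # Pass-through node (linear cascade, convergence to a dispatcher, or
        # divergence from a cascade): merge every in/out pair of tandem edges.
        for (s, _, sg_in) in ins:
            for (_, t, sg_out) in outs:
                if s == t:
                    continue  # merge would create a self-loop; drop it
                key = (s, t, sg_in * sg_out)
                conf = min(edges[(s, node, sg_in)], edges[(node, t, sg_out)])
                edges_new = max(edges.get(key, 0.0), conf)
                edges[key] = edges_new
        for k in ins + outs:
            del edges[k]
        removed_nodes.add(node)
        changed = True

    if not changed:
        return None
    kept_nodes = [n for n in net.nodes if n not in removed_nodes]
    new_edges = [Edge(s, t, sg, c) for (s, t, sg), c in sorted(edges.items())]
    return replace(
        net,
        nodes=kept_nodes,
        roles={n: r for n, r in net.roles.items() if n in set(kept_nodes)},
        edges=new_edges,
        d_max={n: c for n, c in net.d_max.items() if n in set(kept_nodes)},
    )


def compress_network(net: PriorNetwork) -> PriorNetwork:
    """Remove undesignated pass-through nodes, merging tandem edges.

    Iterates to a fixed point.  Each merge keeps ``min`` of the two merged
    confidences (the pathway bottleneck) and the product of the two signs
    (two inhibitions compose to an activation).  Designated nodes are always
    preserved; the operation is idempotent and never increases the edge
    count.
    """
    current = net
    while True:
        nxt = _compress_once(current)
        if nxt is None:
            return current
        current = nxt
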