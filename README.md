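# fuzzysig

Knowledge-guided fuzzy logic modeling of cellular signaling networks from
perturbation (phospho)proteomic data.

Canonical signaling pathways curated from the literature are generic maps:
they say which reactions *can* happen, not which ones are active in a given
cell type under a given treatment. `fuzzysig` calibrates such a prior
knowledge network (PKN) against perturbation data — steady-state panels or
temporally-ordered phosphoproteomic series — to infer a context-specific,
executable network model. It is aimed at systems biologists who have a
literature-derived signed network, a modest perturbation dataset, and want
an interpretable logic model rather than a black-box fit.

## The model

A network over $m$ proteins is encoded by three $m \times m$ matrices: the
adjacency $B$ ($b_{ij}=1$ iff $i$ regulates $j$), the sign matrix $R$
(activation vs. inhibition) and a clause-membership matrix $C$ that groups
each node's regulators into AND clauses which are then OR-ed — a
disjunctive normal form in which each regulator appears in exactly one
clause. Inputs pass through a Hill transfer
$f(x) = x^p / (x^p + h^p)$ (steepness $p$, midpoint $h$, $f(h)=\tfrac12$);
inhibition contributes $1-f(x)$; AND/OR are fuzzy $\min$/$\max$, so states
stay in $[0,1]$, and with the transfer replaced by the identity the same
model runs as a synchronous Boolean network.

Edges of the PKN carry confidences $w_{ij} \in [0, 0.95]$ derived from
publication endorsements (low-throughput studies earn more confidence than
high-throughput ones), and unidentifiable "undesignated" proteins are
compressed away, merged tandem edges keeping the bottleneck
($\min$) confidence. Inference then minimizes

$$\sum_j L(\mathbf{y}_j, \mathbf{z}_j)
  \;+\; \gamma \sum_{ij} |b_{ij} - w_{ij}|
  \;+\; \lambda \sum_j \max(0,\, d_j - d_j^{\max})$$

where $L$ is the mean squared error for steady-state data or a dynamic
time warping (DTW) loss for time series (experimental series of $n_y$
points aligned against a $3 n_y$-point simulation under monotone,
continuous, endpoint-pinned warping), $d_j$ is the indegree and
$d_j^{\max}$ a knowledge-derived cap. The quantitative prior term reduces
to the classical qualitative edge-disagreement count when all $w \in
\{0,1\}$. The discrete program over $(B, C, R, h)$ is solved by a
multi-restart genetic algorithm, validated against an exhaustive
enumeration oracle on small problems.

## Worked example

Infer a 3-node cascade from a noise-free steady-state panel with one
spurious prior edge (`examples/03_infer_from_steady_state.py`):

```
exhaustive: objective=0.5000 (loss=0.00e+00, prior=0.500) structural distance to truth = 0
  learned edges: [('A', 'B'), ('S', 'A')]
genetic algorithm: objective=0.5000 (loss=0.00e+00, prior=0.500) structural distance to truth = 0
  learned edges: [('A', 'B'), ('S', 'A')]
```

Both solvers recover the true wiring exactly (structural distance 0 — no
edge additions or deletions needed); the residual objective of 0.5 is the
unavoidable prior cost $\gamma\sum(1-w)$ of including the true edges plus
$w$ of dropping the spurious one. A scaled-down sweep over prior
completeness on the bundled 9-node `toy9` benchmark
(`examples/04_prior_ratio_sweep.py`) prints

```
              mean  min  max
prior_ratio
0.0          10.75   10   12
0.5           8.00    7    9
1.0           6.75    6    7
```

mean structural distance to the truth falls as the prior covers more of
the true network — the central claim the full test suite verifies with 20
repeats per ratio and a one-sided rank test.

Other entry points: `examples/01` (confidence scoring and compression),
`examples/02` (fuzzy/Boolean simulation), `examples/05` (Boolean cell-fate
sampling), and the `fuzzysig` CLI (`score-prior`, `compress`, `simulate`,
`fit`, `evaluate-sd`, `prior-sweep`, `null-test`, `cellfate`, `synth`).

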