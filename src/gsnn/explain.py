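"""Edge-importance explanation of GSNN predictions.

Given a trained model, an observation x and a baseline observation x_b (for
drug-response questions: the same cell context at zero dose), the explainer
learns a discrete edge mask M that preserves the model's *differential*
prediction f(x) - f(x_b). Excluded edges (M=0) are pinned, after every layer,
to the layerwise edge activations recorded on the baseline — not to zero,
because edges carry endogenous context-driven signal even without drug.

Masks are relaxed binary-concrete samples: per-edge logits theta, inclusion
probability sigmoid(theta), samples sigmoid((theta + logistic noise) / tau)
with the temperature tau annealed geometrically. The loss is the mean squared
error of the differential prediction plus a hinged mask-size penalty
beta * max(0, sum(M) - E_free) and an optional logit weight-decay term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .graph import StructuralGraph
from .model import GSNN

logger = logging.getLogger("gsnn")


@dataclass
class ExplainerConfig:
    iterations: int = 150
    beta: float = 0.01            # mask-size penalty coefficient
    gamma: float = 0.0            # weight decay on mask logits
    free_edges: int = 0           # edges exempt from the size penalty
    lr: float = 0.1
    init_prior: float = 0.9       # initial inclusion probability per edge
    mask_samples: int = 8         # concrete samples per iteration
    tau_start: float = 5.0
    tau_end: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.init_prior < 1.0:
            raise ValueError("init_prior must be in (0, 1)")
        if not self.tau_start > self.tau_end > 0:
            raise ValueError("need tau_start > tau_end > 0")


@dataclass
class EdgeImportance:
    scores: np.ndarray                 # inclusion probability per edge, in [0,1]
    graph: StructuralGraph
    variance_retained: float = np.nan  # 1 - MSE(hard mask)/Var(target)
    meta: dict = field(default_factory=dict)


def baseline_activations(model: GSNN, x_b: np.ndarray) -> List[np.ndarray]:
    """Layerwise edge states of the model run on the baseline observation."""
    _, states = model.forward(np.atleast_2d(x_b), return_states=True)
    return [s.data for s in states]


def masked_forward(model: GSNN, x: np.ndarray, x_b: np.ndarray,
                   mask, a_b: Optional[List[np.ndarray]] = None) -> np.ndarray:
    """Forward pass in which edges with mask 0 carry the baseline activations.

    mask=1 everywhere reproduces f(x) exactly; mask=0 everywhere reproduces
    f(x_b) exactly.
    """
    if a_b is None:
        a_b = baseline_activations(model, x_b)
    mask_t = mask if isinstance(mask, Tensor) else Tensor(np.asarray(mask, float))
    if mask_t.data.shape[-1] != model.graph.n_edges:
        raise ValueError("mask length != number of edges")
    pred = model.forward(np.atleast_2d(x), mask=mask_t, baseline_states=a_b)
    return pred if isinstance(mask, Tensor) else pred.data


def explain(model: GSNN, x: np.ndarray, x_b: np.ndarray,
            cfg: ExplainerConfig) -> EdgeImportance:
    """Learn edge-inclusion probabilities preserving f(x) - f(x_b)."""
    rng = np.random.default_rng(cfg.seed)
    E = model.graph.n_edges
    x = np.atleast_2d(x)
    x_b = np.atleast_2d(x_b)

    f_x = model.predict(x)
    f_b = model.predict(x_b)
    target = f_x - f_b
    a_b = baseline_activations(model, x_b)

    theta = Tensor(np.full(E, np.log(cfg.init_prior / (1 - cfg.init_prior))),
                   requires_grad=True)
    opt = Adam([theta], lr=cfg.lr)
    anneal = (cfg.tau_end / cfg.tau_start) ** (1.0 / max(cfg.iterations - 1, 1))
    tau = cfg.tau_start
    for it in range(cfg.iterations):
        opt.zero_grad()
        total = None
        for _ in range(cfg.mask_samples):
            u = rng.uniform(1e-6, 1 - 1e-6, size=E)
            noise = np.log(u) - np.log1p(-u)
            m = ((theta + noise) * (1.0 / tau)).sigmoid()
            out = model.forward(x, mask=m, baseline_states=a_b) - f_b
            err = out - target
            loss = (err * err).mean()
            loss = loss + cfg.beta * (m.sum() - float(cfg.free_edges)).relu()
            if cfg.gamma:
                loss = loss + cfg.gamma * (theta * theta).sum()
            total = loss if total is None else total + loss
        total = total * (1.0 / cfg.mask_samples)
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite explainer loss at iteration {it}")
        total.backward()
        opt.step()
        tau *= anneal

    scores = 1.0 / (1.0 + np.exp(-theta.data))
    hard = (scores > 0.5).astype(float)
    hard_out = masked_forward(model, x, x_b, hard, a_b) - f_b
    var = float(np.var(target))
    retained = 1.0 - float(np.mean((hard_out - target) ** 2)) / var if var > 0 else np.nan
    return EdgeImportance(scores=scores, graph=model.graph,
                          variance_retained=retained,
                          meta={"config": cfg})


def average_replicates(replicates: Sequence[EdgeImportance]) -> EdgeImportance:
    """Elementwise mean of replicate edge-importance scores."""
    if not replicates:
        raise ValueError("no replicates")
    n = replicates[0].scores.shape
    if any(r.scores.shape != n for r in replicates):
        raise ValueError("replicates disagree on edge space")
    scores = np.mean([r.scores for r in replicates], axis=0)
    return EdgeImportance(scores=scores, graph=replicates[0].graph,
                          variance_retained=float(np.mean(
                              [r.variance_retained for r in replicates])),
                          meta={"n_replicates": len(replicates)})


def subgraph_from_scores(imp: EdgeImportance, g: StructuralGraph,
                         threshold: float) -> StructuralGraph:
    """Graph restricted to edges scoring >= threshold, plus incident nodes.

    Explanation subgraphs may strand nodes, so role invariants are not
    enforced (the export is a fragment, not a modeling graph).
    """
    keep = imp.scores >= threshold
    if not keep.any():
        logger.warning("explanation subgraph is empty at threshold %.3f",
                       threshold)
    edges = [(g.node_names[int(s)], g.node_names[int(t)])
             for s, t in zip(g.edge_src[keep], g.edge_dst[keep])]
    incident = {n for e in edges for n in e}
    nodes = [(n, c) for n, c in zip(g.node_names, g.entity_classes)
             if n in incident]
    return StructuralGraph.from_lists(nodes, edges, validate=False)
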