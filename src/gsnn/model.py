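"""The graph-structured neural network (GSNN).

The model's hidden representation lives on the *edges* of a structural graph.
Each function node n is a one-hidden-layer neural map from its incoming-edge
values (D_in(n) of them) to its outgoing-edge values (D_out(n)), with C_n
hidden channels, per-node layer normalization, and an elementwise
nonlinearity. Parameters are never shared between function nodes. One GSNN
layer applies every node map at once — realized as two sparse linear
operations, a gather (E -> sum C_n) and a scatter (sum C_n -> E) — followed by
a residual connection, so signal accumulates and propagates one hop per
layer; L layers reach descendants up to L hops away. Edges leaving input
nodes are written by no function node, so the residual stream holds them at
the encoded stimulus for the whole depth.

Weight initialization is degree-aware: node n's weights are drawn from
Normal(0, 2 / D_in(n)) (kaiming) or Normal(0, 2 / (D_in(n) + D_out(n)))
(xavier), using graph degrees as fan values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .autodiff import Adam, Tensor, right_spmm, sparse_linear
from .graph import (ROLE_FUNCTION, ROLE_INPUT, ROLE_OUTPUT, StructuralGraph,
                    add_self_edges)

logger = logging.getLogger("gsnn")


@dataclass
class GsnnConfig:
    channels: int = 8                    # hidden channels per function node
    layers: int = 4                      # residual layers = propagation depth
    dropout: float = 0.0
    share_layer_params: bool = False
    add_self_edges: bool = False
    scale_channels_by_degree: bool = False
    init_scheme: str = "kaiming"         # kaiming | xavier
    activation: str = "elu"              # elu | tanh
    norm: str = "layer"                  # layer | none
    seed: int = 0

    def __post_init__(self):
        if self.channels < 1 or self.layers < 1:
            raise ValueError("channels and layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.init_scheme not in ("kaiming", "xavier"):
            raise ValueError(f"unknown init scheme {self.init_scheme!r}")
        if self.norm not in ("layer", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")


def node_channels(d_in: int, d_out: int, cfg: GsnnConfig) -> int:
    if cfg.scale_channels_by_degree:
        return max(1, min(cfg.channels, max(d_in, d_out)))
    return cfg.channels


def count_parameters(g: StructuralGraph, cfg: GsnnConfig) -> int:
    """Closed-form trainable parameter count for a graph + configuration."""
    if cfg.add_self_edges:
        g = add_self_edges(g)
    d_in, d_out = g.in_degrees(), g.out_degrees()
    per_node_core, per_node_norm = 0, 0
    for i in g.nodes_with_role(ROLE_FUNCTION):
        c = node_channels(int(d_in[i]), int(d_out[i]), cfg)
        per_node_core += int(d_in[i]) * c + c + c * int(d_out[i]) + int(d_out[i])
        per_node_norm += 2 * c
    n_core_blocks = 1 if cfg.share_layer_params else cfg.layers
    total = n_core_blocks * per_node_core
    if cfg.norm == "layer":
        total += cfg.layers * per_node_norm  # norm stays per-layer even when shared
    return total


class GSNN:
    """Graph-structured residual network over edge latents.

    Parameters live in per-layer blocks: sparse gather weights (W1), hidden
    bias, per-node norm scale/shift, sparse scatter weights (W2), and a bias
    per writable (function-sourced) edge.
    """

    def __init__(self, g: StructuralGraph, cfg: GsnnConfig):
        if cfg.add_self_edges:
            g = add_self_edges(g)
        self.graph = g
        self.cfg = cfg
        self._build_indices()
        self._init_parameters()
        self._rng = np.random.default_rng(cfg.seed + 1)

    # ----------------------------------------------------------------- layout
    def _build_indices(self) -> None:
        g, cfg = self.graph, self.cfg
        roles = g.roles()
        E = g.n_edges
        d_in = g.in_degrees()
        d_out = g.out_degrees()

        self.input_node_idx = np.flatnonzero(roles == ROLE_INPUT)
        self.output_node_idx = np.flatnonzero(roles == ROLE_OUTPUT)
        self.function_node_idx = np.flatnonzero(roles == ROLE_FUNCTION)
        self.input_names = [g.node_names[i] for i in self.input_node_idx]
        self.output_names = [g.node_names[i] for i in self.output_node_idx]

        # edges leaving input nodes carry the stimulus
        is_input_edge = np.isin(g.edge_src, self.input_node_idx)
        self.input_edge_ids = np.flatnonzero(is_input_edge)
        inp_pos = {int(i): j for j, i in enumerate(self.input_node_idx)}
        self.input_edge_srcpos = np.array(
            [inp_pos[int(g.edge_src[k])] for k in self.input_edge_ids],
            dtype=np.int64)

        # each output node has exactly one incoming edge
        out_edge = {}
        for k in range(E):
            t = int(g.edge_dst[k])
            if roles[t] == ROLE_OUTPUT:
                out_edge[t] = k
        self.output_edge_ids = np.array(
            [out_edge[int(i)] for i in self.output_node_idx], dtype=np.int64)

        in_edges: Dict[int, List[int]] = {int(n): [] for n in self.function_node_idx}
        out_edges: Dict[int, List[int]] = {int(n): [] for n in self.function_node_idx}
        for k in range(E):
            s, t = int(g.edge_src[k]), int(g.edge_dst[k])
            if t in in_edges:
                in_edges[t].append(k)
            if s in out_edges:
                out_edges[s].append(k)

        # active nodes: inert function nodes (possible in randomized control
        # graphs) compute nothing
        self.active_nodes = [int(n) for n in self.function_node_idx
                             if in_edges[int(n)] and out_edges[int(n)]]
        self.channels_of = {n: node_channels(int(d_in[n]), int(d_out[n]), cfg)
                            for n in self.active_nodes}
        self.hidden_size = int(sum(self.channels_of.values()))

        r1, c1, n1 = [], [], []   # W1: (hidden, edge) coordinates + owner node
        r2, c2, n2 = [], [], []   # W2: (edge, hidden)
        seg = []                  # hidden unit -> dense node ordinal
        offset = 0
        writable: List[int] = []
        for ordinal, n in enumerate(self.active_nodes):
            cn = self.channels_of[n]
            for c in range(cn):
                h = offset + c
                seg.append(ordinal)
                for e in in_edges[n]:
                    r1.append(h)
                    c1.append(e)
                    n1.append(n)
                for e in out_edges[n]:
                    r2.append(e)
                    c2.append(h)
                    n2.append(n)
            writable.extend(out_edges[n])
            offset += cn
        self.w1_rows = np.array(r1, dtype=np.int64)
        self.w1_cols = np.array(c1, dtype=np.int64)
        self.w1_node = np.array(n1, dtype=np.int64)
        self.w2_rows = np.array(r2, dtype=np.int64)
        self.w2_cols = np.array(c2, dtype=np.int64)
        self.w2_node = np.array(n2, dtype=np.int64)
        self.writable_edges = np.array(sorted(writable), dtype=np.int64)
        self.seg = np.array(seg, dtype=np.int64)
        self.d_in, self.d_out = d_in, d_out

        nf, H = len(self.active_nodes), self.hidden_size
        counts = np.bincount(self.seg, minlength=nf).astype(float)
        self._seg_mean = sp.csr_matrix(
            (1.0 / counts[self.seg], (self.seg, np.arange(H))), shape=(nf, H))
        self._seg_bcast = sp.csr_matrix(
            (np.ones(H), (np.arange(H), self.seg)), shape=(H, nf))
        # per-node normalization is skipped for single-channel nodes
        self._norm_mask = (counts[self.seg] > 1).astype(float)

    # ------------------------------------------------------------- parameters
    def _init_parameters(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        H, E = self.hidden_size, self.graph.n_edges

        def w_std(node_ids: np.ndarray) -> np.ndarray:
            din = np.maximum(self.d_in[node_ids], 1)
            dout = np.maximum(self.d_out[node_ids], 1)
            if cfg.init_scheme == "kaiming":
                return np.sqrt(2.0 / din)
            return np.sqrt(2.0 / (din + dout))

        n_blocks = 1 if cfg.share_layer_params else cfg.layers
        self.layer_params: List[Dict[str, Tensor]] = []
        blocks = []
        for _ in range(n_blocks):
            blocks.append({
                "w1": Tensor(rng.normal(0.0, w_std(self.w1_node)),
                             requires_grad=True),
                "b1": Tensor(np.zeros(H), requires_grad=True),
                "w2": Tensor(rng.normal(0.0, w_std(self.w2_node)),
                             requires_grad=True),
                "b2": Tensor(np.zeros((1, len(self.writable_edges))),
                             requires_grad=True),
            })
        for l in range(cfg.layers):
            p = dict(blocks[0 if cfg.share_layer_params else l])
            if cfg.norm == "layer":
                p["ln_g"] = Tensor(np.ones(H), requires_grad=True)
                p["ln_b"] = Tensor(np.zeros(H), requires_grad=True)
            self.layer_params.append(p)

    def parameters(self) -> List[Tensor]:
        seen, out = set(), []
        for p in self.layer_params:
            for t in p.values():
                if id(t) not in seen:
                    seen.add(id(t))
                    out.append(t)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for l, p in enumerate(self.layer_params):
            for k, t in p.items():
                out[f"layer{l}.{k}"] = t.data.copy()
        return out

    def load_state_dict(self, d: Dict[str, np.ndarray]) -> None:
        for l, p in enumerate(self.layer_params):
            for k, t in p.items():
                t.data = d[f"layer{l}.{k}"].copy()

    # ----------------------------------------------------------------- layers
    def _activate(self, h: Tensor) -> Tensor:
        if self.cfg.activation == "elu":
            return h.elu()
        if self.cfg.activation == "tanh":
            return h.tanh()
        raise ValueError(f"unknown activation {self.cfg.activation!r}")

    def _layernorm(self, h: Tensor, p: Dict[str, Tensor]) -> Tensor:
        m = right_spmm(h, self._seg_mean)                 # per-node mean
        mb = right_spmm(m, self._seg_bcast)
        v = right_spmm(h * h, self._seg_mean) - m * m     # per-node variance
        vb = right_spmm(v, self._seg_bcast)
        normed = (h - mb) / (vb + 1e-5).sqrt()
        mask = self._norm_mask
        out = normed * mask + h * (1.0 - mask)
        return out * p["ln_g"] + p["ln_b"]

    def layer_forward(self, state: Tensor, layer: int,
                      training: bool = False) -> Tensor:
        """One residual edge update: gather -> node nets -> scatter -> add."""
        if not np.isfinite(state.data).all():
            raise FloatingPointError(f"non-finite edge state entering layer {layer}")
        p = self.layer_params[layer]
        E, H = self.graph.n_edges, self.hidden_size
        h = sparse_linear(state, p["w1"], self.w1_rows, self.w1_cols, (H, E))
        h = h + p["b1"]
        if self.cfg.norm == "layer":
            h = self._layernorm(h, p)
        h = self._activate(h)
        if training and self.cfg.dropout > 0:
            keep = (self._rng.random(h.data.shape) >= self.cfg.dropout)
            h = h * (keep / (1.0 - self.cfg.dropout))
        out = sparse_linear(h, p["w2"], self.w2_rows, self.w2_cols, (E, H))
        out = out + p["b2"].put_cols(self.writable_edges, E)
        return state + out

    # ---------------------------------------------------------------- forward
    def initial_state(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        xe = x.take_cols(self.input_edge_srcpos)
        return xe.put_cols(self.input_edge_ids, self.graph.n_edges)

    def forward(self, x, training: bool = False, return_states: bool = False,
                mask: Optional[Tensor] = None,
                baseline_states: Optional[Sequence[np.ndarray]] = None):
        """Run L residual layers; return predictions over output nodes.

        With ``mask``/``baseline_states``, after the initial state and after
        every layer each edge e is mixed as m_e * state + (1 - m_e) *
        baseline, realizing the explainer's masked forward operation.
        """
        state = self.initial_state(x)
        if mask is not None:
            state = mask * state + (1.0 - mask) * baseline_states[0]
        states = [state]
        for l in range(self.cfg.layers):
            state = self.layer_forward(state, l, training=training)
            if mask is not None:
                state = mask * state + (1.0 - mask) * baseline_states[l + 1]
            states.append(state)
        if not np.isfinite(state.data).all():
            raise FloatingPointError("non-finite prediction")
        preds = state.take_cols(self.output_edge_ids)
        return (preds, states) if return_states else preds

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.atleast_2d(X)
        chunks = [self.forward(X[i:i + batch_size]).data
                  for i in range(0, len(X), batch_size)]
        return np.concatenate(chunks, axis=0)

    # ----------------------------------------------------------------- fitting
    def fit(self, X: np.ndarray, Y: np.ndarray,
            X_val: Optional[np.ndarray] = None,
            Y_val: Optional[np.ndarray] = None,
            epochs: int = 50, lr: float = 1e-2, batch_size: int = 32,
            patience: int = 10, seed: Optional[int] = None,
            verbose: bool = False) -> Dict[str, list]:
        """Minimize mean squared error over output nodes with Adam.

        Small batches are the norm for this architecture. When validation data
        is given, training tracks validation mean-Pearson with early stopping
        and restores the best parameters.
        """
        from .evaluate import mean_pearson

        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        opt = Adam(self.parameters(), lr=lr)
        hist = {"train_mse": [], "val_pearson": []}
        best_score, best_state, since_best = -np.inf, None, 0
        for epoch in range(epochs):
            order = rng.permutation(len(X))
            losses = []
            for i in range(0, len(X), batch_size):
                idx = order[i:i + batch_size]
                pred = self.forward(X[idx], training=True)
                err = pred - Y[idx]
                loss = (err * err).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            hist["train_mse"].append(float(np.mean(losses)))
            if X_val is not None and len(X_val):
                score = mean_pearson(self.predict(X_val), Y_val).mean_pearson
                hist["val_pearson"].append(score)
                if score > best_score:
                    best_score, best_state, since_best = score, self.state_dict(), 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
            if verbose:
                logger.info("epoch %d train_mse=%.5f val=%s", epoch,
                            hist["train_mse"][-1],
                            hist["val_pearson"][-1] if hist["val_pearson"] else "-")
        if best_state is not None:
            self.load_state_dict(best_state)
        return hist


def init_parameters(g: StructuralGraph, cfg: GsnnConfig) -> GSNN:
    """Construct a GSNN with freshly initialized parameter blocks."""
    return GSNN(g, cfg)
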