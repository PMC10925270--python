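"""GSNN core: initialization, sparse forward vs dense oracle, structure."""

import numpy as np
import pytest

import gsnn
from gsnn.autodiff import Tensor


def dense_oracle_forward(model: gsnn.GSNN, X: np.ndarray) -> np.ndarray:
    """Independent forward pass through explicit dense masked matrices.

    Builds the full (hidden x E) and (E x hidden) weight matrices with zeros
    at masked positions and applies plain numpy operations, looping over
    function nodes for the per-node normalization.
    """
    g, cfg = model.graph, model.cfg
    E, H = g.n_edges, model.hidden_size
    X = np.atleast_2d(X)
    state = np.zeros((len(X), E))
    state[:, model.input_edge_ids] = X[:, model.input_edge_srcpos]

    def elu(v):
        return np.where(v > 0, v, np.exp(np.minimum(v, 0)) - 1)

    for l in range(cfg.layers):
        p = model.layer_params[l]
        W1 = np.zeros((H, E))
        W1[model.w1_rows, model.w1_cols] = p["w1"].data
        W2 = np.zeros((E, H))
        W2[model.w2_rows, model.w2_cols] = p["w2"].data
        h = state @ W1.T + p["b1"].data
        if cfg.norm == "layer":
            out_h = np.empty_like(h)
            for node in range(model.seg.max() + 1):
                cols = np.flatnonzero(model.seg == node)
                block = h[:, cols]
                if len(cols) > 1:
                    m = block.mean(axis=1, keepdims=True)
                    v = block.var(axis=1, keepdims=True)
                    block = (block - m) / np.sqrt(v + 1e-5)
                out_h[:, cols] = block
            h = out_h * p["ln_g"].data + p["ln_b"].data
        h = elu(h)
        out = h @ W2.T
        out[:, model.writable_edges] += p["b2"].data[0]
        state = state + out
    return state[:, model.output_edge_ids]


class TestParameterCount:
    def test_single_node_closed_form(self):
        g = gsnn.StructuralGraph.from_lists(
            [("d1", "DRUG"), ("d2", "DRUG"), ("p", "PROTEIN"), ("o", "LINCS")],
            [("d1", "p"), ("d2", "p"), ("p", "o")])
        cfg = gsnn.GsnnConfig(channels=2, layers=1, norm="layer")
        # D_in=2, D_out=1, C=2: 2*2 + 2 + 2*1 + 1 + 2*2 = 13
        assert gsnn.count_parameters(g, cfg) == 13
        assert gsnn.GSNN(g, cfg).n_parameters() == 13

    def test_shared_params_independent_of_depth(self, smoke_graph):
        cfg1 = gsnn.GsnnConfig(channels=4, layers=1, share_layer_params=True,
                               norm="none")
        cfg10 = gsnn.GsnnConfig(channels=4, layers=10, share_layer_params=True,
                                norm="none")
        assert gsnn.count_parameters(smoke_graph, cfg1) == \
            gsnn.count_parameters(smoke_graph, cfg10)
        # per-layer norm parameters stay unshared
        cfg10n = gsnn.GsnnConfig(channels=4, layers=10,
                                 share_layer_params=True, norm="layer")
        m = gsnn.GSNN(smoke_graph, cfg10n)
        assert m.n_parameters() == gsnn.count_parameters(smoke_graph, cfg10n)

    def test_fixture_store_matches_formula(self, smoke_graph):
        for kw in ({}, {"scale_channels_by_degree": True},
                   {"add_self_edges": True}, {"norm": "none"}):
            cfg = gsnn.GsnnConfig(channels=5, layers=3, **kw)
            assert gsnn.GSNN(smoke_graph, cfg).n_parameters() == \
                gsnn.count_parameters(smoke_graph, cfg)


class TestInitialization:
    def test_kaiming_variance(self):
        # D_in=2 -> Normal(0, 2/2): empirical variance ~= 1 on >= 1e5 draws
        g = gsnn.StructuralGraph.from_lists(
            [("d1", "DRUG"), ("d2", "DRUG"), ("p", "PROTEIN"), ("o", "LINCS")],
            [("d1", "p"), ("d2", "p"), ("p", "o")])
        cfg = gsnn.GsnnConfig(channels=50000, layers=1, seed=0,
                              init_scheme="kaiming")
        m = gsnn.GSNN(g, cfg)
        w1 = m.layer_params[0]["w1"].data
        assert len(w1) == 100000
        assert abs(w1.var() - 1.0) < 0.05

    def test_xavier_variance_parameter(self):
        # D_in=3, D_out=1 -> variance 2/(3+1) = 0.5
        g = gsnn.StructuralGraph.from_lists(
            [("d1", "DRUG"), ("d2", "DRUG"), ("d3", "DRUG"),
             ("p", "PROTEIN"), ("o", "LINCS")],
            [("d1", "p"), ("d2", "p"), ("d3", "p"), ("p", "o")])
        cfg = gsnn.GsnnConfig(channels=40000, layers=1, seed=0,
                              init_scheme="xavier")
        m = gsnn.GSNN(g, cfg)
        w1 = m.layer_params[0]["w1"].data
        assert abs(w1.var() - 0.5) < 0.5 * 0.05

    def test_seed_reproducibility(self, smoke_graph):
        cfg = gsnn.GsnnConfig(channels=4, layers=2, seed=11)
        a, b = gsnn.GSNN(smoke_graph, cfg), gsnn.GSNN(smoke_graph, cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_degree_scaled_channels(self, smoke_graph):
        cfg = gsnn.GsnnConfig(channels=8, layers=1,
                              scale_channels_by_degree=True)
        m = gsnn.GSNN(smoke_graph, cfg)
        d_in, d_out = smoke_graph.in_degrees(), smoke_graph.out_degrees()
        for n, c in m.channels_of.items():
            assert c == max(1, min(8, max(int(d_in[n]), int(d_out[n]))))


class TestForward:
    def test_residual_identity_at_zero_weights(self, smoke_graph, smoke_dataset):
        _, X, _ = smoke_dataset
        cfg = gsnn.GsnnConfig(channels=3, layers=4, seed=0)
        m = gsnn.GSNN(smoke_graph, cfg)
        for p in m.parameters():
            p.data[...] = 0.0
        state0 = m.initial_state(X[:5]).data
        _, states = m.forward(X[:5], return_states=True)
        # with all weights, biases, and norm gains zero, F(x) = 0 each layer
        assert np.allclose(states[-1].data, state0)
        assert np.allclose(m.forward(X[:5]).data,
                           state0[:, m.output_edge_ids])

    def test_zero_input_zero_params_zero_prediction(self, smoke_graph):
        cfg = gsnn.GsnnConfig(channels=3, layers=3, seed=0)
        m = gsnn.GSNN(smoke_graph, cfg)
        for p in m.parameters():
            p.data[...] = 0.0
        x = np.zeros((1, len(m.input_names)))
        assert np.allclose(m.forward(x).data, 0.0)

    @pytest.mark.parametrize("kw", [
        {}, {"norm": "none"}, {"scale_channels_by_degree": True},
        {"add_self_edges": True}, {"share_layer_params": True},
    ])
    def test_sparse_equals_dense_oracle(self, smoke_graph, smoke_dataset, kw):
        _, X, _ = smoke_dataset
        cfg = gsnn.GsnnConfig(channels=4, layers=3, seed=2, **kw)
        m = gsnn.GSNN(smoke_graph, cfg)
        got = m.predict(X[:16])
        want = dense_oracle_forward(m, X[:16])
        assert np.abs(got - want).max() <= 1e-5

    def test_nonfinite_state_raises_with_layer(self, smoke_graph):
        cfg = gsnn.GsnnConfig(channels=3, layers=2, seed=0)
        m = gsnn.GSNN(smoke_graph, cfg)
        x = np.full((1, len(m.input_names)), np.nan)
        with pytest.raises(FloatingPointError, match="layer"):
            m.forward(x)


class TestStructuralFaithfulness:
    def test_nonancestor_gradients_exactly_zero(self, smoke_graph):
        g = smoke_graph
        cfg = gsnn.GsnnConfig(channels=3, layers=4, seed=1)
        m = gsnn.GSNN(g, cfg)
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(1, len(m.input_names))),
                   requires_grad=True)
        preds = m.forward(x)
        for o_pos, o_name in enumerate(m.output_names):
            x.grad = None
            grad_out = np.zeros_like(preds.data)
            grad_out[0, o_pos] = 1.0
            preds.backward(grad_out)
            for i_pos, i_name in enumerate(m.input_names):
                is_ancestor = o_name in g.descendants({i_name})
                if not is_ancestor:
                    assert x.grad[0, i_pos] == 0.0, (i_name, o_name)

    def test_some_ancestor_gradient_nonzero(self, smoke_graph):
        m = gsnn.GSNN(smoke_graph, gsnn.GsnnConfig(channels=3, layers=4, seed=1))
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(1, len(m.input_names))),
                   requires_grad=True)
        preds = m.forward(x)
        preds.backward(np.ones_like(preds.data))
        assert np.abs(x.grad).max() > 0

    def test_depth_probe_signal_arrival(self):
        """On a 3-function-node chain the drug needs 3 layers to reach the
        readout; at L=2 the prediction is independent of the dose."""
        nodes = [("d", "DRUG"), ("p1", "PROTEIN"), ("p2", "PROTEIN"),
                 ("r1", "RNA"), ("o", "LINCS"), ("EXPR_p1", "EXPR"),
                 ("EXPR_p2", "EXPR"), ("EXPR_r1", "EXPR")]
        edges = [("d", "p1"), ("p1", "p2"), ("p2", "r1"), ("r1", "o"),
                 ("EXPR_p1", "p1"), ("EXPR_p2", "p2"), ("EXPR_r1", "r1")]
        g = gsnn.StructuralGraph.from_lists(nodes, edges)
        x0 = gsnn.encode_observation(gsnn.Observation(omics={
            "EXPR_p1": 0.3, "EXPR_p2": -0.2, "EXPR_r1": 0.5}), g)
        x1 = gsnn.encode_observation(gsnn.Observation(
            drug_doses={"d": 1.0},
            omics={"EXPR_p1": 0.3, "EXPR_p2": -0.2, "EXPR_r1": 0.5}), g)
        m2 = gsnn.GSNN(g, gsnn.GsnnConfig(channels=3, layers=2, seed=3))
        assert np.allclose(m2.predict(x0), m2.predict(x1))
        m3 = gsnn.GSNN(g, gsnn.GsnnConfig(channels=3, layers=3, seed=3))
        assert not np.allclose(m3.predict(x0), m3.predict(x1))

    def test_one_layer_locality(self, smoke_graph):
        """Perturbing one input edge changes only edges one function hop away."""
        g = smoke_graph
        m = gsnn.GSNN(g, gsnn.GsnnConfig(channels=3, layers=1, seed=4))
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, len(m.input_names)))
        _, states = m.forward(x, return_states=True)
        base = states[-1].data
        k = m.input_edge_ids[0]
        target_node = int(g.edge_dst[k])
        x2 = x.copy()
        x2[0, m.input_edge_srcpos[0]] += 1.0
        src_node = int(g.edge_src[k])
        _, states2 = m.forward(x2, return_states=True)
        changed = set(np.flatnonzero(
            np.abs(states2[-1].data - base).max(axis=0) > 1e-12))
        reachable = set()
        for e in np.flatnonzero(g.edge_src == src_node):  # perturbed input edges
            reachable.add(int(e))
            reachable |= set(np.flatnonzero(
                g.edge_src == int(g.edge_dst[e])).tolist())
        assert changed <= reachable


class TestTrainability:
    def test_short_training_halves_mse(self, smoke_graph, smoke_dataset):
        _, X, Y = smoke_dataset
        m = gsnn.GSNN(smoke_graph, gsnn.GsnnConfig(channels=6, layers=4, seed=0))
        mse0 = float(np.mean((m.predict(X) - Y) ** 2))
        # 200 optimizer steps
        epochs = max(1, int(np.ceil(200 / np.ceil(len(X) / 32))))
        m.fit(X, Y, epochs=epochs, lr=1e-2, batch_size=32)
        mse1 = float(np.mean((m.predict(X) - Y) ** 2))
        assert mse1 <= 0.5 * mse0
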