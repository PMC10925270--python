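"""Beta-likelihood viability head, p_sens statistic, ranking evaluation."""

import numpy as np
import pandas as pd
import pytest

import gsnn
from gsnn.viability import BetaEnsemble, BetaHead


class _IdentityModel:
    """Stands in for the frozen expression predictor in head-only tests."""

    def predict(self, X):
        return np.atleast_2d(X)


class TestBetaPrediction:
    def test_member_mean(self):
        p = gsnn.BetaPrediction(a=np.array([2.0]), b=np.array([2.0]))
        assert p.mean == pytest.approx(0.5)

    def test_mixture_mean(self):
        p = gsnn.BetaPrediction(a=np.array([2.0, 6.0]), b=np.array([2.0, 2.0]))
        assert p.mean == pytest.approx(0.625)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            gsnn.BetaPrediction(a=np.array([0.0]), b=np.array([1.0]))


class TestHeadTraining:
    @pytest.mark.parametrize("a,b", [(2.0, 5.0), (5.0, 2.0), (1.0, 1.0)])
    def test_intercept_only_parameter_recovery(self, a, b):
        """With uninformative features, maximum likelihood recovers the data's
        Beta parameters within 15% at n = 5000."""
        rng = np.random.default_rng(int(a * 10 + b))
        y = rng.beta(a, b, size=5000)
        X = np.zeros((5000, 1))
        ens = gsnn.train_viability_head(X, y, ensemble_size=1, epochs=60,
                                        lr=0.05, seed=0)
        ab = ens.members[0].predict_ab(np.zeros((1, 1)))[0]
        assert abs(ab[0] - a) / a < 0.15
        assert abs(ab[1] - b) / b < 0.15

    def test_ensemble_size_one_degenerates_to_single_beta(self):
        rng = np.random.default_rng(0)
        y = rng.beta(3, 3, size=200)
        ens = gsnn.train_viability_head(np.zeros((200, 1)), y,
                                        ensemble_size=1, epochs=5, seed=0)
        pred = ens.predict(np.zeros((1, 1)))
        assert pred.a.shape == (1,)

    def test_members_differ(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        y = rng.beta(2, 2, size=300)
        ens = gsnn.train_viability_head(X, y, ensemble_size=3, epochs=10, seed=0)
        w = [m.W.data for m in ens.members]
        assert not np.allclose(w[0], w[1])

    def test_expression_model_untouched_by_head_training(self, smoke_graph):
        """Freeze contract: head training never writes gradients into, or
        changes, the expression predictor's parameters."""
        m = gsnn.GSNN(smoke_graph, gsnn.GsnnConfig(channels=3, layers=2, seed=0))
        before = {k: v.copy() for k, v in m.state_dict().items()}
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, len(m.input_names)))
        feats = m.predict(X)
        y = rng.beta(2, 3, size=100)
        gsnn.train_viability_head(feats, y, ensemble_size=2, epochs=5, seed=0)
        after = m.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k])
        assert all(p.grad is None for p in m.parameters())


class TestPredictViability:
    def test_composition_and_determinism(self):
        head = BetaHead(3, seed=0)
        ens = BetaEnsemble([head])
        x = np.array([[0.1, -0.2, 0.3]])
        p1 = gsnn.predict_viability(ens, _IdentityModel(), x)
        p2 = gsnn.predict_viability(ens, _IdentityModel(), x)
        assert np.array_equal(p1.a, p2.a) and np.array_equal(p1.b, p2.b)


class _TableEncoder:
    """Encoder stub: features depend only on (cell line, drug, dose)."""

    def __init__(self, table):
        self.table = table  # (cell, frozen drug items) -> feature vector

    def encode(self, cell_line, doses=None):
        key = (cell_line, tuple(sorted((doses or {}).items())))
        return self.table[key]


def _forced_beta_setup(a_target, b_target, a_back, b_back):
    """Ensemble + encoder where target/background lines get fixed Betas.

    The head has one input feature; weights are solved so that
    softplus(w * feat + bias) hits the requested concentrations.
    """
    def inv_softplus(v):
        return float(np.log(np.expm1(v)))

    head = BetaHead(1, seed=0)
    # feature +1 -> (a_target, b_target); feature -1 -> (a_back, b_back)
    wa = (inv_softplus(a_target) - inv_softplus(a_back)) / 2
    ba = (inv_softplus(a_target) + inv_softplus(a_back)) / 2
    wb = (inv_softplus(b_target) - inv_softplus(b_back)) / 2
    bb = (inv_softplus(b_target) + inv_softplus(b_back)) / 2
    head.W.data = np.array([[wa, wb]])
    head.b.data = np.array([ba, bb])
    lines = [f"T{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
    table = {}
    for line in lines:
        feat = 1.0 if line.startswith("T") else -1.0
        table[(line, (("drugX", 1.0),))] = np.array([feat])
    return BetaEnsemble([head]), _TableEncoder(table), lines


class TestPsens:
    def test_symmetric_mixtures_give_half(self):
        ens, enc, lines = _forced_beta_setup(3.0, 3.0, 3.0, 3.0)
        spec = gsnn.PrioritizationSpec(target_lines={"T0", "T1", "T2"},
                                       background_lines={"B0", "B1", "B2"},
                                       n_mc=1000, seed=0)
        p = gsnn.psens(ens, _IdentityModel(), enc, "drugX", 1.0, spec)
        assert abs(p - 0.5) <= 0.05

    def test_stochastic_dominance_gives_one(self):
        ens, enc, lines = _forced_beta_setup(2.0, 50.0, 50.0, 2.0)
        spec = gsnn.PrioritizationSpec(target_lines={"T0", "T1", "T2"},
                                       background_lines={"B0", "B1", "B2"},
                                       n_mc=1000, seed=0)
        p = gsnn.psens(ens, _IdentityModel(), enc, "drugX", 1.0, spec)
        assert p >= 0.99

    def test_swap_antisymmetry(self):
        ens, enc, lines = _forced_beta_setup(2.0, 6.0, 4.0, 3.0)
        fwd = gsnn.PrioritizationSpec(target_lines={"T0", "T1", "T2"},
                                      background_lines={"B0", "B1", "B2"},
                                      n_mc=2000, seed=3)
        rev = gsnn.PrioritizationSpec(target_lines={"B0", "B1", "B2"},
                                      background_lines={"T0", "T1", "T2"},
                                      n_mc=2000, seed=3)
        p1 = gsnn.psens(ens, _IdentityModel(), enc, "drugX", 1.0, fwd)
        p2 = gsnn.psens(ens, _IdentityModel(), enc, "drugX", 1.0, rev)
        assert p1 + p2 == pytest.approx(1.0)  # per-line seeding makes it exact

    def test_seed_determinism(self):
        ens, enc, lines = _forced_beta_setup(2.0, 6.0, 4.0, 3.0)
        spec = gsnn.PrioritizationSpec(target_lines={"T0", "T1"},
                                       background_lines={"B0", "B1"},
                                       n_mc=500, seed=9)
        args = (ens, _IdentityModel(), enc, "drugX", 1.0, spec)
        assert gsnn.psens(*args) == gsnn.psens(*args)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            gsnn.PrioritizationSpec(target_lines={"A"},
                                    background_lines={"A", "B"})


class TestRanking:
    def _ranking_setup(self):
        ens, enc, lines = _forced_beta_setup(2.0, 10.0, 10.0, 2.0)
        for d in ("drugA", "drugB", "drugC"):
            for line in lines:
                feat = (1.0 if (line.startswith("T") and d == "drugA")
                        else -1.0 if d == "drugA" else 0.0)
                enc.table[(line, ((d, 1.0),))] = np.array([feat])
        spec = gsnn.PrioritizationSpec(target_lines={"T0", "T1", "T2"},
                                       background_lines={"B0", "B1", "B2"},
                                       n_mc=500, seed=0)
        return ens, enc, spec

    def test_single_drug_rank_one(self):
        ens, enc, spec = self._ranking_setup()
        r = gsnn.rank_drugs(ens, _IdentityModel(), enc, ["drugA"], 1.0, spec)
        assert r.top(1) == ["drugA"]

    def test_selective_drug_ranks_first_and_order_invariance(self):
        ens, enc, spec = self._ranking_setup()
        r1 = gsnn.rank_drugs(ens, _IdentityModel(), enc,
                             ["drugA", "drugB", "drugC"], 1.0, spec)
        r2 = gsnn.rank_drugs(ens, _IdentityModel(), enc,
                             ["drugC", "drugA", "drugB"], 1.0, spec)
        assert r1.top(1) == ["drugA"]
        assert r1.table["drug"].tolist() == r2.table["drug"].tolist()


class TestRankingAuroc:
    @staticmethod
    def _ranking(scores):
        df = pd.DataFrame({"drug": [f"d{i}" for i in range(len(scores))],
                           "p_sens": scores}).sort_values(
            "p_sens", ascending=False).reset_index(drop=True)
        return gsnn.DrugRanking(df)

    def test_perfect_ranking(self):
        r = self._ranking([0.9, 0.8, 0.2, 0.1])
        auroc, p = gsnn.evaluate_ranking_auroc(
            r, {"d0": 1, "d1": 1, "d2": 0, "d3": 0}, n_null=200, seed=0)
        assert auroc == 1.0

    def test_reversed_ranking(self):
        r = self._ranking([0.9, 0.8, 0.2, 0.1])
        auroc, _ = gsnn.evaluate_ranking_auroc(
            r, {"d0": 0, "d1": 0, "d2": 1, "d3": 1}, n_null=200, seed=0)
        assert auroc == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        r = self._ranking(rng.uniform(size=n))
        labels = {f"d{i}": int(i < n // 2) for i in range(n)}
        auroc, _ = gsnn.evaluate_ranking_auroc(r, labels, n_null=10, seed=0)
        assert abs(auroc - 0.5) <= 0.02

    def test_single_class_errors(self):
        r = self._ranking([0.9, 0.1])
        with pytest.raises(ValueError):
            gsnn.evaluate_ranking_auroc(r, {"d0": 1, "d1": 1}, n_null=10)

    def test_unlabeled_drugs_excluded(self):
        r = self._ranking([0.9, 0.5, 0.1])
        auroc, _ = gsnn.evaluate_ranking_auroc(
            r, {"d0": 1, "d2": 0}, n_null=10, seed=0)
        assert auroc == 1.0
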