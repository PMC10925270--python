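"""Probabilistic cell-viability prediction and selective-drug prioritization.

A deep ensemble of single-linear-layer heads maps a frozen expression
predictor's output to the two concentration parameters (a, b) of a Beta
distribution over cell viability in [0, 1]; each member is trained by Beta
negative log-likelihood on its own initialization and data order, and the
ensemble prediction is the uniform mixture of member Betas.

Drug prioritization asks for *selective* response: given target lines T and
background lines B, p_sens is the probability that the mean predicted
viability over T is lower than over B, estimated by Monte Carlo — each round
draws one ensemble member per line, samples that member's Beta once, and
compares the two group means. Ranked lists are evaluated against known drug
indications by AUROC with a permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor

logger = logging.getLogger("gsnn")

_POSITIVITY_EPS = 1e-6   # softplus(z) + eps keeps (a, b) strictly positive
_CLIP_DELTA = 1e-4       # likelihood evaluated on y clipped into (delta, 1-delta)


@dataclass
class BetaPrediction:
    """Uniform mixture of per-member Beta(a, b) viability distributions."""

    a: np.ndarray  # (n_members,)
    b: np.ndarray  # (n_members,)

    def __post_init__(self):
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("Beta concentrations must be positive")

    @property
    def member_means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    @property
    def mean(self) -> float:
        return float(self.member_means.mean())


@dataclass
class PrioritizationSpec:
    target_lines: Set[str]
    background_lines: Set[str]
    n_mc: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.target_lines or not self.background_lines:
            raise ValueError("target and background line sets must be nonempty")
        if self.target_lines & self.background_lines:
            raise ValueError("target and background lines must be disjoint")


class BetaHead:
    """One ensemble member: linear map from features to (a, b) via softplus."""

    def __init__(self, n_in: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = Tensor(rng.normal(0, 0.1, size=(n_in, 2)), requires_grad=True)
        self.b = Tensor(np.zeros(2), requires_grad=True)

    def forward(self, x) -> Tensor:
        z = (x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x)))
        return (z @ self.W + self.b).softplus() + _POSITIVITY_EPS

    def predict_ab(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.atleast_2d(X)).data


def beta_nll(ab: Tensor, y: np.ndarray) -> Tensor:
    """Mean Beta negative log-likelihood; y pre-clipped into (0, 1)."""
    y = np.clip(np.asarray(y, float), _CLIP_DELTA, 1 - _CLIP_DELTA)
    a = ab.take_cols(np.array([0]))
    b = ab.take_cols(np.array([1]))
    log_y = np.log(y)[:, None]
    log_1my = np.log1p(-y)[:, None]
    ll = ((a - 1.0) * log_y + (b - 1.0) * log_1my
          + (a + b).lgamma() - a.lgamma() - b.lgamma())
    return -ll.mean()


@dataclass
class BetaEnsemble:
    members: List[BetaHead]

    def predict(self, features: np.ndarray) -> BetaPrediction:
        feats = np.atleast_2d(features)
        ab = np.stack([m.predict_ab(feats)[0] for m in self.members])
        return BetaPrediction(a=ab[:, 0], b=ab[:, 1])


def train_viability_head(features: np.ndarray, y: np.ndarray,
                         ensemble_size: int = 10, epochs: int = 200,
                         lr: float = 0.05, batch_size: int = 256,
                         seed: int = 0) -> BetaEnsemble:
    """Fit the Beta-likelihood ensemble on (features, viability) pairs.

    ``features`` are the frozen expression predictor's outputs for the
    corresponding (drug, cell, dose) observations — the predictor itself is
    never updated here (its parameters do not enter this computation graph).
    Viability is clipped to [0, 1]. Members differ by initialization seed and
    shuffling order.
    """
    X = np.atleast_2d(features)
    y = np.clip(np.asarray(y, float), 0.0, 1.0)
    members = []
    for k in range(ensemble_size):
        head = BetaHead(X.shape[1], seed=seed * 1000 + k)
        rng = np.random.default_rng(seed * 1000 + 500 + k)
        opt = Adam([head.W, head.b], lr=lr)
        for _ in range(epochs):
            order = rng.permutation(len(X))
            for i in range(0, len(X), batch_size):
                idx = order[i:i + batch_size]
                loss = beta_nll(head.forward(X[idx]), y[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError("non-finite Beta NLL")
                opt.zero_grad()
                loss.backward()
                opt.step()
        members.append(head)
    return BetaEnsemble(members)


def predict_viability(ensemble: BetaEnsemble, expr_model, x: np.ndarray
                      ) -> BetaPrediction:
    """Compose the frozen expression predictor with the viability ensemble."""
    feats = expr_model.predict(np.atleast_2d(x))
    return ensemble.predict(feats)


def _group_predictions(ensemble: BetaEnsemble, expr_model, encoder,
                       drug_doses: Mapping[str, float],
                       lines: Sequence[str]) -> List[BetaPrediction]:
    X = np.stack([encoder.encode(cell_line=line, doses=drug_doses)
                  for line in lines])
    feats = expr_model.predict(X)
    return [ensemble.predict(feats[i]) for i in range(len(lines))]


def psens(ensemble: BetaEnsemble, expr_model, encoder,
          drug: str, dose_uM: float, spec: PrioritizationSpec) -> float:
    """P(mean viability of target lines < mean viability of background lines).

    Monte Carlo over the ensemble mixture: each round samples, per line, one
    member uniformly and one viability draw from its Beta. Each line's draws
    are seeded by (spec.seed, line), so swapping the target and background
    sets reproduces the same per-line samples and maps p_sens to 1 - p_sens.
    """
    from zlib import crc32

    doses = {drug: dose_uM}
    t_lines = sorted(spec.target_lines)
    b_lines = sorted(spec.background_lines)
    preds = _group_predictions(ensemble, expr_model, encoder, doses,
                               t_lines + b_lines)
    n_members = len(ensemble.members)
    samples = np.empty((spec.n_mc, len(preds)))
    for j, (line, p) in enumerate(zip(t_lines + b_lines, preds)):
        rng = np.random.default_rng([spec.seed, crc32(line.encode())])
        member = rng.integers(0, n_members, size=spec.n_mc)
        samples[:, j] = rng.beta(p.a[member], p.b[member])
    mean_t = samples[:, :len(t_lines)].mean(axis=1)
    mean_b = samples[:, len(t_lines):].mean(axis=1)
    return float(np.mean(mean_t < mean_b))


@dataclass
class DrugRanking:
    table: pd.DataFrame  # columns: drug, p_sens; sorted descending

    def top(self, k: int = 1) -> List[str]:
        return list(self.table["drug"].head(k))


def rank_drugs(ensemble: BetaEnsemble, expr_model, encoder,
               drugs: Sequence[str], dose_uM: float,
               spec: PrioritizationSpec) -> DrugRanking:
    """One p_sens per drug at a fixed dose; descending, ties broken by name."""
    if not drugs:
        raise ValueError("empty drug set")
    rows = []
    for d in sorted(set(drugs)):
        rows.append({"drug": d,
                     "p_sens": psens(ensemble, expr_model, encoder, d,
                                     dose_uM, spec)})
    df = pd.DataFrame(rows).sort_values(
        ["p_sens", "drug"], ascending=[False, True]).reset_index(drop=True)
    return DrugRanking(df)


def evaluate_ranking_auroc(ranking: DrugRanking, labels: Mapping[str, int],
                           n_null: int = 1000, seed: int = 0
                           ) -> Tuple[float, float]:
    """AUROC of p_sens against indication labels, with a permutation null.

    Unlabeled drugs are excluded. The p-value is the proportion of ``n_null``
    random score permutations whose AUROC is >= the observed one.
    """
    df = ranking.table[ranking.table["drug"].isin(labels)]
    y = np.array([labels[d] for d in df["drug"]])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative label")
    scores = df["p_sens"].to_numpy()
    auroc = float(roc_auc_score(y, scores))
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = roc_auc_score(y, rng.permutation(scores))
    return auroc, float(np.mean(null >= auroc))
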