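"""Evaluation metrics, significance testing, baselines, and grid search.

Performance is summarized by the mean Pearson correlation: the correlation
between predicted and measured values is computed per output gene across
observations and averaged over genes (zero-variance columns are skipped and
counted). Method comparisons use two-sided paired t-tests across
cross-validation folds with Bonferroni adjustment; grouped local-performance
analyses control the false discovery rate with Benjamini-Hochberg or
Benjamini-Yekutieli.

The reference predictor is a two-hidden-layer fully connected network with
ELU activations and batch normalization; its "cell-agnostic" variant consumes
the encoding with all cellular-context inputs zeroed and therefore can only
learn each drug's average response.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .autodiff import Adam, Tensor


@dataclass
class MetricsReport:
    mean_pearson: float
    per_output_pearson: np.ndarray
    n_skipped: int = 0
    fold: Optional[int] = None


def mean_pearson(yhat: np.ndarray, y: np.ndarray,
                 fold: Optional[int] = None) -> MetricsReport:
    """Per-output-column Pearson correlation, averaged over defined columns."""
    yhat, y = np.atleast_2d(yhat), np.atleast_2d(y)
    if yhat.shape != y.shape:
        raise ValueError("shape mismatch")
    if yhat.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    yc = y - y.mean(axis=0)
    pc = yhat - yhat.mean(axis=0)
    sy = np.sqrt((yc ** 2).sum(axis=0))
    sp_ = np.sqrt((pc ** 2).sum(axis=0))
    defined = (sy > 0) & (sp_ > 0)
    if not defined.any():
        raise ValueError("all output columns have zero variance")
    r = np.full(y.shape[1], np.nan)
    r[defined] = (yc[:, defined] * pc[:, defined]).sum(axis=0) / (
        sy[defined] * sp_[defined])
    return MetricsReport(float(np.nanmean(r)), r,
                         n_skipped=int((~defined).sum()), fold=fold)


@dataclass
class PairedTestResult:
    t: float
    p: float
    p_adjusted: float
    valid: bool = True


def paired_test(scores_a: Sequence[float], scores_b: Sequence[float],
                n_tests: int = 1) -> PairedTestResult:
    """Two-sided paired t-test with Bonferroni adjustment (p * n_tests)."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length score vectors of length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return PairedTestResult(np.nan, np.nan, np.nan, valid=False)
        # constant nonzero difference: the t statistic diverges
        t = math.copysign(math.inf, diff.mean())
        return PairedTestResult(t, 0.0, 0.0, valid=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), min(1.0, float(p) * n_tests))


def grouped_performance(preds_by_method: Dict[str, List[Tuple[np.ndarray, np.ndarray]]],
                        grouping: List[np.ndarray],
                        min_group_size: int = 5,
                        fdr_method: str = "BH",
                        fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Local (per-group) performance comparison between two methods.

    ``preds_by_method`` maps each method name to a list of per-fold
    ``(yhat, y)`` matrices; ``grouping`` gives a per-fold label array over
    observations. Groups with fewer than ``min_group_size`` observations in
    any fold are dropped. The first two methods are compared by a paired
    two-sided t-test across folds, FDR-adjusted across groups.
    """
    if fdr_method not in ("BH", "BY"):
        raise ValueError("fdr_method must be BH or BY")
    methods = list(preds_by_method)
    if len(methods) < 2:
        raise ValueError("need two methods to compare")
    m1, m2 = methods[0], methods[1]
    n_folds = len(grouping)

    eligible = None
    for labels in grouping:
        vals, counts = np.unique(labels, return_counts=True)
        ok = set(vals[counts >= min_group_size])
        eligible = ok if eligible is None else eligible & ok
    eligible = sorted(eligible or set())
    rows = []
    for gname in eligible:
        scores = {}
        for m in (m1, m2):
            s = []
            for f in range(n_folds):
                sel = grouping[f] == gname
                yhat, y = preds_by_method[m][f]
                s.append(mean_pearson(yhat[sel], y[sel]).mean_pearson)
            scores[m] = np.array(s)
        res = paired_test(scores[m1], scores[m2])
        rows.append({"group": gname,
                     f"mean_{m1}": scores[m1].mean(),
                     f"mean_{m2}": scores[m2].mean(),
                     "t": res.t, "p_value": res.p, "valid": res.valid})
    df = pd.DataFrame(rows)
    if df.empty:
        import logging
        logging.getLogger("gsnn").warning("no groups pass the size filter")
        return df
    ok = df["valid"] & df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(
            df.loc[ok, "p_value"],
            method="fdr_bh" if fdr_method == "BH" else "fdr_by")[1]
    df["q_value"] = q
    df["significant"] = df["q_value"] < fdr_threshold
    return df


# ----------------------------------------------------------------- NN baseline
class MLPBaseline:
    """Fully connected regressor: two hidden ELU layers with batch norm."""

    def __init__(self, n_in: int, n_out: int, hidden: int = 100, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [(n_in, hidden), (hidden, hidden), (hidden, n_out)]
        self.weights = [Tensor(rng.normal(0, np.sqrt(2.0 / d[0]), size=d),
                               requires_grad=True) for d in dims]
        self.biases = [Tensor(np.zeros(d[1]), requires_grad=True) for d in dims]
        self.bn_g = [Tensor(np.ones(hidden), requires_grad=True) for _ in range(2)]
        self.bn_b = [Tensor(np.zeros(hidden), requires_grad=True) for _ in range(2)]
        self._run_m = [np.zeros(hidden) for _ in range(2)]
        self._run_v = [np.ones(hidden) for _ in range(2)]
        self.momentum = 0.1

    def parameters(self) -> List[Tensor]:
        return self.weights + self.biases + self.bn_g + self.bn_b

    def forward(self, x, training: bool = False) -> Tensor:
        z = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        for i in range(2):
            z = z @ self.weights[i] + self.biases[i]
            if training and z.data.shape[0] > 1:
                m = z.mean(axis=0)
                v = ((z - m) * (z - m)).mean(axis=0)
                self._run_m[i] = ((1 - self.momentum) * self._run_m[i]
                                  + self.momentum * m.data)
                self._run_v[i] = ((1 - self.momentum) * self._run_v[i]
                                  + self.momentum * v.data)
                z = (z - m) / (v + 1e-5).sqrt()
            else:
                z = (z - self._run_m[i]) / np.sqrt(self._run_v[i] + 1e-5)
            z = (z * self.bn_g[i] + self.bn_b[i]).elu()
        return z @ self.weights[2] + self.biases[2]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).data

    def fit(self, X, Y, X_val=None, Y_val=None, epochs: int = 100,
            lr: float = 1e-2, batch_size: int = 32, patience: int = 10,
            seed: int = 0) -> Dict[str, list]:
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=lr)
        hist = {"train_mse": [], "val_pearson": []}
        best, best_state, since = -np.inf, None, 0
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
                if score > best:
                    best, best_state, since = score, self._state(), 0
                else:
                    since += 1
                    if since >= patience:
                        break
        if best_state is not None:
            self._load(best_state)
        return hist

    def _state(self):
        return ([p.data.copy() for p in self.parameters()],
                [m.copy() for m in self._run_m],
                [v.copy() for v in self._run_v])

    def _load(self, s):
        for p, d in zip(self.parameters(), s[0]):
            p.data = d.copy()
        self._run_m = [m.copy() for m in s[1]]
        self._run_v = [v.copy() for v in s[2]]


def train_baseline_nn(X: np.ndarray, Y: np.ndarray,
                      X_val: Optional[np.ndarray] = None,
                      Y_val: Optional[np.ndarray] = None,
                      hidden: int = 100, seed: int = 0,
                      **fit_kw) -> MLPBaseline:
    """Train the fully connected baseline on encoded observations.

    For the cell-agnostic variant, encode the inputs with
    ``cell_agnostic=True`` (all non-drug positions zeroed) before calling.
    """
    model = MLPBaseline(X.shape[1], Y.shape[1], hidden=hidden, seed=seed)
    model.fit(X, Y, X_val, Y_val, seed=seed, **fit_kw)
    return model


# ------------------------------------------------------------------ grid search
@dataclass
class GridResult:
    fold: int
    best_config: dict
    val_scores: List[Tuple[dict, float]]
    test_score: float


def expand_grid(grid: Dict[str, Sequence]) -> List[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search(grid: Dict[str, Sequence], folds: Sequence,
                train_fn: Callable[[dict, object], object],
                score_fn: Callable[[object, object, str], float]
                ) -> List[GridResult]:
    """Select the best configuration per fold by validation mean-Pearson.

    ``train_fn(config, fold)`` fits a model; ``score_fn(model, fold, part)``
    scores it on partition ``"val"`` or ``"test"``. The test partition is
    scored exactly once per fold, for the selected configuration only.
    """
    configs = expand_grid(grid)
    if not configs:
        raise ValueError("empty grid")
    results = []
    for f, fold in enumerate(folds):
        val_scores = []
        models = {}
        for i, cfg in enumerate(configs):
            model = train_fn(cfg, fold)
            val_scores.append((cfg, score_fn(model, fold, "val")))
            models[i] = model
        best_i = int(np.argmax([s for _, s in val_scores]))
        test = score_fn(models[best_i], fold, "test")
        results.append(GridResult(f, configs[best_i], val_scores, test))
    return results
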