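"""Random-forest SNP selection with three importance measures.

A regression random forest is fitted to the structure-adjusted phenotype
(hyperparameters tunable by Gaussian-process Bayesian optimisation on the
out-of-bag R²). SNPs are then ranked three ways:

* **Gini importance** (mean decrease impurity): per-SNP sum of variance
  reductions at the nodes splitting on it, averaged over trees, normalized to
  sum to 1.
* **SHAP importance**: mean |Shapley value| per SNP over accessions, computed
  exactly by the path-dependent tree algorithm in :mod:`aiopheno._treeshap`.
* **Boruta**: each SNP is iteratively compared against the best "shadow"
  (column-shuffled) importance; confirmed/rejected by a two-sided binomial
  test on the hit count.

Gini and SHAP rankings are thresholded by the elbow rule (maximum discrete
second difference of the sorted score curve; ties toward the earliest index);
Boruta's selection is its confirmed set. The cross set is the intersection of
all three selections; the union set is the union of the pairwise
intersections (SNPs found by at least two methods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest, norm
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from ._treeshap import forest_shap_values


@dataclass
class RFConfig:
    """Random-forest hyperparameters and the Bayesian-optimisation search
    space (bounds are inclusive; integer dimensions are rounded)."""

    n_estimators: int = 300
    max_depth: int | None = None
    min_samples_split: int = 2
    min_impurity_decrease: float = 0.0
    max_features: float | str = "sqrt"
    tune: bool = False
    budget: int = 50
    n_initial: int = 10
    seed: int = 0
    space: dict = field(default_factory=lambda: {
        "n_estimators": (100, 500),
        "max_depth": (3, 20),
        "min_samples_split": (2, 20),
        "min_impurity_decrease": (0.0, 0.01),
        "max_features": (0.05, 1.0),
    })


@dataclass
class SNPSets:
    """cross = selected by all three methods; union = selected by ≥ 2."""

    cross_set: set
    union_set: set

    def __post_init__(self):
        if not self.cross_set <= self.union_set:
            raise ValueError("cross set must be a subset of the union set")


@dataclass
class ImportanceReport:
    gini: np.ndarray
    shap: np.ndarray
    boruta_decisions: np.ndarray          # "confirmed" / "tentative" / "rejected"
    gini_cutoff: int
    shap_cutoff: int
    gini_selected: set
    shap_selected: set
    boruta_selected: set
    sets: SNPSets


def _make_forest(cfg: RFConfig, seed=None) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        min_samples_split=cfg.min_samples_split,
        min_impurity_decrease=cfg.min_impurity_decrease,
        max_features=cfg.max_features,
        oob_score=True,
        bootstrap=True,
        random_state=cfg.seed if seed is None else seed,
        n_jobs=1,
    )


def _decode_point(u: np.ndarray, space: dict) -> dict:
    """Map a unit-cube point to hyperparameter values."""
    params = {}
    for ui, (name, (lo, hi)) in zip(u, space.items()):
        val = lo + ui * (hi - lo)
        if name in ("n_estimators", "max_depth", "min_samples_split"):
            val = int(round(val))
        params[name] = val
    return params


def tune_and_fit_rf(X, y, cfg: RFConfig | None = None):
    """Fit a regression forest, optionally tuning hyperparameters by Bayesian
    optimisation (Gaussian process surrogate, expected-improvement
    acquisition) on the out-of-bag R².

    Returns ``(forest, info)`` where ``info`` holds the OOB R² and, when
    tuned, the best hyperparameters and the evaluation trace.
    """
    cfg = cfg or RFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute first")
    if np.std(y) == 0:
        raise ValueError("phenotype is constant; nothing to fit")
    if cfg.budget < 1:
        raise ValueError("tuning budget must be ≥ 1")

    if not cfg.tune:
        forest = _make_forest(cfg).fit(X, y)
        return forest, {"oob_r2": float(forest.oob_score_)}

    rng = np.random.default_rng(cfg.seed)
    dims = len(cfg.space)
    evaluated_u: list[np.ndarray] = []
    scores: list[float] = []

    def evaluate(u):
        params = _decode_point(u, cfg.space)
        trial = RFConfig(**{**params, "seed": cfg.seed})
        forest = _make_forest(trial).fit(X, y)
        return float(forest.oob_score_)

    n_init = min(cfg.n_initial, cfg.budget)
    for _ in range(n_init):
        u = rng.random(dims)
        evaluated_u.append(u)
        scores.append(evaluate(u))

    for _ in range(cfg.budget - n_init):
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-4,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(np.array(evaluated_u), -np.array(scores))  # GP minimizes
        cand = rng.random((256, dims))
        mu, sd = gp.predict(cand, return_std=True)
        best = (-np.array(scores)).min()
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        evaluated_u.append(u)
        scores.append(evaluate(u))

    best_idx = int(np.argmax(scores))
    best_params = _decode_point(evaluated_u[best_idx], cfg.space)
    forest = _make_forest(RFConfig(**{**best_params, "seed": cfg.seed})).fit(X, y)
    return forest, {
        "oob_r2": float(forest.oob_score_),
        "best_params": best_params,
        "trace": list(map(float, scores)),
    }


def gini_importance(forest) -> np.ndarray:
    """Mean-decrease-impurity importance, normalized to sum to 1 (all-zero
    vector if the forest never splits)."""
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def shap_importance(forest, X) -> np.ndarray:
    """Global SHAP importance: mean |Shapley value| per SNP over accessions."""
    phi, _ = forest_shap_values(forest, np.asarray(X, dtype=float))
    return np.abs(phi).mean(axis=0)


def boruta_select(X, y, cfg: RFConfig | None = None, max_iter: int = 25,
                  alpha: float = 0.05, seed: int = 0):
    """Boruta feature screening against shadow (permuted) attributes.

    Each iteration appends a shuffled copy of every SNP column, fits a forest
    on the doubled matrix, and scores a "hit" for every real SNP whose Gini
    importance exceeds the maximum shadow importance. After all iterations a
    two-sided binomial test (p = 0.5) classifies each SNP: *confirmed* if the
    hit count is significantly high, *rejected* if significantly low,
    *tentative* otherwise.

    Returns an array of decisions and the hit counts. The input matrix is
    never modified.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be ≥ 10 for the binomial test to resolve")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n, m = X.shape
    cfg = cfg or RFConfig(n_estimators=100, max_features="sqrt")
    hits = np.zeros(m, dtype=int)
    for it in range(max_iter):
        shadow = X.copy()
        for j in range(m):
            rng.shuffle(shadow[:, j])
        Xext = np.hstack([X, shadow])
        forest = _make_forest(cfg, seed=int(rng.integers(2**31))).fit(Xext, y)
        imp = forest.feature_importances_
        shadow_max = imp[m:].max()
        hits += imp[:m] > shadow_max
    decisions = np.full(m, "tentative", dtype=object)
    for j in range(m):
        res = binomtest(int(hits[j]), max_iter, 0.5)
        if res.pvalue < alpha:
            decisions[j] = "confirmed" if hits[j] > max_iter / 2 else "rejected"
    return decisions, hits


def elbow_threshold(scores) -> int:
    """Cutoff index on a descending score curve: position of the maximum
    discrete second difference s[i−1] − 2s[i] + s[i+1], ties broken toward
    the earliest index. Scores at or above the cutoff value are selected.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or len(s) < 3:
        raise ValueError("need at least 3 scores for the elbow rule")
    if (np.diff(s) > 1e-12).any():
        raise ValueError("scores must be sorted in descending order")
    d2 = s[:-2] - 2 * s[1:-1] + s[2:]
    return int(np.argmax(d2)) + 1


def select_by_elbow(scores) -> tuple[set, int]:
    """Apply the elbow rule to an unsorted score vector; returns the selected
    index set (scores ≥ the elbow value) and the cutoff position in the
    sorted order."""
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    cutoff = elbow_threshold(scores[order])
    thresh = scores[order][cutoff]
    return set(np.flatnonzero(scores >= thresh).tolist()), cutoff


def combine_sets(sel_a, sel_b, sel_c) -> SNPSets:
    """cross = A∩B∩C; union = (A∩B) ∪ (A∩C) ∪ (B∩C)."""
    a, b, c = set(sel_a), set(sel_b), set(sel_c)
    return SNPSets(cross_set=a & b & c, union_set=(a & b) | (a & c) | (b & c))


class RandomForestSNPSelector(BaseEstimator):
    """Estimator ranking SNPs by random-forest importance three ways and
    forming cross/union selection sets.

    Parameters
    ----------
    config : :class:`RFConfig` controlling the forest and optional Bayesian
        hyperparameter tuning.
    boruta_max_iter, boruta_alpha : Boruta iteration count and binomial test
        level.
    shap_sample : number of accessions used to estimate mean |SHAP| (None =
        all; attributions are exact either way, subsampling only trades the
        Monte-Carlo precision of the global mean for speed).

    Attributes (after ``fit``)
    --------------------------
    forest_ : fitted RandomForestRegressor.
    report_ : :class:`ImportanceReport` with scores, cutoffs and sets.
    cross_set_, union_set_ : selected SNP index sets.
    """

    def __init__(self, config: RFConfig | None = None, boruta_max_iter: int = 25,
                 boruta_alpha: float = 0.05, shap_sample: int | None = None):
        self.config = config
        self.boruta_max_iter = boruta_max_iter
        self.boruta_alpha = boruta_alpha
        self.shap_sample = shap_sample

    def fit(self, X, y) -> "RandomForestSNPSelector":
        cfg = self.config or RFConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.forest_, self.fit_info_ = tune_and_fit_rf(X, y, cfg)

        gini = gini_importance(self.forest_)
        if self.shap_sample is not None and self.shap_sample < X.shape[0]:
            rng = np.random.default_rng(cfg.seed)
            idx = rng.choice(X.shape[0], self.shap_sample, replace=False)
            shap = shap_importance(self.forest_, X[idx])
        else:
            shap = shap_importance(self.forest_, X)

        gini_sel, gini_cut = select_by_elbow(gini)
        shap_sel, shap_cut = select_by_elbow(shap)
        decisions, hits = boruta_select(
            X, y, cfg=RFConfig(n_estimators=min(cfg.n_estimators, 150), seed=cfg.seed),
            max_iter=self.boruta_max_iter, alpha=self.boruta_alpha, seed=cfg.seed,
        )
        boruta_sel = set(np.flatnonzero(decisions == "confirmed").tolist())
        sets = combine_sets(gini_sel, shap_sel, boruta_sel)
        self.report_ = ImportanceReport(
            gini=gini, shap=shap, boruta_decisions=decisions,
            gini_cutoff=gini_cut, shap_cutoff=shap_cut,
            gini_selected=gini_sel, shap_selected=shap_sel, boruta_selected=boruta_sel,
            sets=sets,
        )
        self.boruta_hits_ = hits
        self.cross_set_ = sets.cross_set
        self.union_set_ = sets.union_set
        return self

    def get_support(self, which: str = "union") -> np.ndarray:
        """Sorted selected SNP indices (``which`` ∈ {"cross", "union"})."""
        sets = {"cross": self.cross_set_, "union": self.union_set_}
        return np.array(sorted(sets[which]), dtype=int)

    def report_frame(self, snp_ids=None):
        """Importance report as a DataFrame (one row per SNP)."""
        import pandas as pd
        r = self.report_
        m = len(r.gini)
        return pd.DataFrame({
            "snp_id": snp_ids if snp_ids is not None else np.arange(m),
            "gini": r.gini,
            "shap": r.shap,
            "boruta_decision": r.boruta_decisions,
            "gini_selected": [j in r.gini_selected for j in range(m)],
            "shap_selected": [j in r.shap_selected for j in range(m)],
            "boruta_selected": [j in r.boruta_selected for j in range(m)],
            "cross_set": [j in r.sets.cross_set for j in range(m)],
            "union_set": [j in r.sets.union_set for j in range(m)],
        })
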