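"""Training, tuning and evaluation of the AIO flowering-time classifier.

Protocol
--------
* 90/10 stratified split into a cross-validation pool and a control
  (holdout) set.
* Stratified k-fold cross-validation (default 10 folds) on the pool; within
  each fold, the last ``validation_split`` fraction of the training part
  monitors validation accuracy per epoch. The best model across folds (the
  one with maximal validation accuracy) is retained.
* Loss: categorical cross-entropy L = −Σ T_i log S_i; optimizer Adam.
* Evaluation: multiclass accuracy (correct / total) plus per-class TP/TN/
  FP/FN; per-accession error in days uses the class maximum as each class's
  representative day value (configurable to class midpoints); the median
  absolute day error is reported together with Mann–Whitney U and Wilcoxon W
  rank tests comparing train vs validation error distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import mannwhitneyu, wilcoxon
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io import ClassScheme
from .nn import ArchSpec, Network, Adam, build_model


@dataclass
class TrainConfig:
    folds: int = 10
    epochs: int = 100
    validation_split: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be ≥ 2")
        if not 0.0 < self.validation_split < 1.0:
            raise ValueError("validation_split must be in (0, 1)")


@dataclass
class EvalReport:
    accuracy: float
    confusion: dict          # class → {"TP","TN","FP","FN"}
    day_errors: np.ndarray   # signed per-accession error in days
    median_abs_error: float
    rank_tests: dict | None = None

    def to_dict(self):
        out = {
            "accuracy": self.accuracy,
            "confusion": self.confusion,
            "median_abs_error": self.median_abs_error,
        }
        if self.rank_tests:
            out["rank_tests"] = self.rank_tests
        return out


def _onehot(y, k):
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def _train_one(net: Network, X, y, Xval, yval, cfg: TrainConfig, rng):
    """Adam + minibatch training; returns per-epoch validation accuracy."""
    k = net.n_classes
    opt = Adam(net.params, lr=cfg.learning_rate)
    Y = _onehot(y, k)
    n = len(y)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            net.loss_and_backward(X[idx], Y[idx])
            opt.step(net.grads)
        val_acc = float((net.predict(Xval) == yval).mean()) if len(yval) else np.nan
        history.append(val_acc)
    return history


def train_cv(arch: ArchSpec, X, y, cfg: TrainConfig | None = None):
    """Stratified k-fold cross-validation training.

    Returns ``(best_net, info)``: the model with maximal end-of-training
    validation accuracy over folds, plus per-fold histories and the train/
    validation day-error vectors of the best fold.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=arch.n_classes)
    present = counts > 0
    n_splits = cfg.folds
    min_count = counts[present].min()
    if min_count < n_splits:
        warnings.warn(
            f"smallest class has {min_count} members < {n_splits} folds; "
            "stratifying on a merged label", stacklevel=2)
        strat = _merge_rare(y, n_splits)
    else:
        strat = y
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
    best = (-np.inf, None, None)
    histories = []
    for fold, (tr, va) in enumerate(skf.split(X, strat)):
        rng = np.random.default_rng(cfg.seed + 1000 * fold)
        net = Network(arch, seed=cfg.seed + fold)
        # validation_split carves a monitor set out of the fold's training part
        n_val = max(1, int(round(cfg.validation_split * len(tr))))
        monitor, inner = tr[:n_val], tr[n_val:]
        hist = _train_one(net, X[inner], y[inner], X[monitor], y[monitor], cfg, rng)
        fold_val_acc = float((net.predict(X[va]) == y[va]).mean())
        histories.append({"fold": fold, "history": hist, "val_accuracy": fold_val_acc})
        if fold_val_acc > best[0]:
            best = (fold_val_acc, net, (inner, va))
    best_acc, best_net, (tr_idx, va_idx) = best
    info = {
        "fold_histories": histories,
        "best_val_accuracy": best_acc,
        "best_train_idx": tr_idx,
        "best_val_idx": va_idx,
    }
    return best_net, info


def _merge_rare(y, n_splits):
    """Merge classes with fewer members than folds into their nearest
    populated neighbor for stratification purposes only."""
    y = y.copy()
    counts = np.bincount(y)
    ok = np.flatnonzero(counts >= n_splits)
    if len(ok) == 0:
        return np.zeros_like(y)
    for cls in np.flatnonzero((counts > 0) & (counts < n_splits)):
        nearest = ok[np.argmin(np.abs(ok - cls))]
        y[y == cls] = nearest
    return y


def _day_values(scheme: ClassScheme, representative: str):
    bounds = np.asarray(scheme.upper_bounds, dtype=float)
    if representative == "maximum":
        return bounds
    if representative == "midpoint":
        lower = np.concatenate([[0.0], bounds[:-1]])
        return (lower + bounds) / 2.0
    raise ValueError("representative must be 'maximum' or 'midpoint'")


def day_errors(y_pred, y_true, scheme: ClassScheme, representative: str = "maximum"):
    """Signed per-accession error in days between the representative day of
    the predicted and the true class."""
    days = _day_values(scheme, representative)
    return days[np.asarray(y_pred)] - days[np.asarray(y_true)]


def evaluate(net, X, y, scheme: ClassScheme | None = None,
             train_errors=None, val_errors=None,
             representative: str = "maximum") -> EvalReport:
    """Accuracy, per-class confusion counts, day errors, and (optionally)
    rank tests comparing supplied train vs validation error samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("holdout set is empty")
    pred = net.predict(X)
    acc = float((pred == y).mean())
    scheme = scheme or ClassScheme()
    confusion = {}
    for cls in range(net.n_classes):
        tp = int(((pred == cls) & (y == cls)).sum())
        fp = int(((pred == cls) & (y != cls)).sum())
        fn = int(((pred != cls) & (y == cls)).sum())
        tn = int(((pred != cls) & (y != cls)).sum())
        confusion[cls] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    errors = day_errors(pred, y, scheme, representative)
    rank_tests = None
    if train_errors is not None and val_errors is not None:
        tr = np.abs(np.asarray(train_errors, dtype=float))
        va = np.abs(np.asarray(val_errors, dtype=float))
        if np.all(tr == tr[0]) and np.all(va == va[0]) and tr[0] == va[0]:
            # identical constant samples: no evidence of any difference
            rank_tests = {"mannwhitney_U": float(len(tr) * len(va) / 2), "mannwhitney_p": 1.0,
                          "wilcoxon_W": 0.0, "wilcoxon_p": 1.0}
        else:
            u = mannwhitneyu(tr, va, alternative="two-sided")
            rank_tests = {"mannwhitney_U": float(u.statistic), "mannwhitney_p": float(u.pvalue)}
            k = min(len(tr), len(va))
            diff = tr[:k] - va[:k]
            if np.any(diff != 0):
                w = wilcoxon(tr[:k], va[:k])
                rank_tests.update({"wilcoxon_W": float(w.statistic), "wilcoxon_p": float(w.pvalue)})
            else:
                rank_tests.update({"wilcoxon_W": 0.0, "wilcoxon_p": 1.0})
    return EvalReport(
        accuracy=acc, confusion=confusion, day_errors=errors,
        median_abs_error=float(np.median(np.abs(errors))), rank_tests=rank_tests,
    )


def tune_architecture(space, X, y, budget: int = 10, seed: int = 0,
                      epochs: int = 15, validation_split: float = 0.2):
    """Pick the architecture with maximal validation accuracy from a discrete
    candidate space within an evaluation budget.

    ``space`` is a sequence of :class:`ArchSpec`; invalid candidates (shape
    errors, zero filters) are skipped. Deterministic under ``seed``.
    """
    specs = list(space)
    if not specs:
        raise ValueError("architecture search space is empty")
    if budget < 1:
        raise ValueError("budget must be ≥ 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    if len(specs) > budget:
        chosen = rng.choice(len(specs), budget, replace=False)
        specs = [specs[i] for i in chosen]
    tr, va = train_test_split(np.arange(len(y)), test_size=validation_split,
                              random_state=seed, stratify=y)
    best = (-np.inf, None)
    for spec in specs:
        try:
            from .nn import count_params
            count_params(spec)  # validates shapes before building
            net = Network(spec, seed=seed)
        except (ValueError, KeyError):
            continue
        cfg = TrainConfig(folds=2, epochs=epochs, validation_split=validation_split,
                          seed=seed)
        _train_one(net, X[tr], y[tr], X[va], y[va], cfg, np.random.default_rng(seed))
        acc = float((net.predict(X[va]) == y[va]).mean())
        if acc > best[0]:
            best = (acc, spec)
    if best[1] is None:
        raise ValueError("no valid architecture in the search space")
    return best[1]


class AIOClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn-style CNN classifier over AIO tensors.

    Parameters
    ----------
    arch : :class:`ArchSpec` or None — None derives the standard conv-pool
        ×2 + dense architecture from the input width and class count.
    train_config : :class:`TrainConfig` (folds, epochs, validation split,
        batch size, learning rate, seed).
    cv : if True (default) run stratified k-fold cross-validation and keep
        the best-validation model; if False, a single train/validation split.

    Attributes (after ``fit``)
    --------------------------
    net_ : trained :class:`~aiopheno.nn.Network`.
    cv_info_ : fold histories and best-fold indices (cv=True).
    classes_ : sorted class labels seen in ``fit``.
    """

    def __init__(self, arch: ArchSpec | None = None,
                 train_config: TrainConfig | None = None, cv: bool = True):
        self.arch = arch
        self.train_config = train_config
        self.cv = cv

    def _resolve_arch(self, X, n_classes):
        if self.arch is not None:
            return self.arch
        from .nn import union_set_architecture
        width = X.shape[2]
        return union_set_architecture(width=width, n_classes=n_classes)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.arch is not None:
            # labels are class indices into a fixed scheme; some classes may
            # be absent from this sample but the output layer keeps them all
            y_idx = y.astype(int)
            if y_idx.min() < 0 or y_idx.max() >= self.arch.n_classes:
                raise ValueError("labels must be indices into the architecture's classes")
            self.classes_ = np.arange(self.arch.n_classes)
        else:
            self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = self.train_config or TrainConfig()
        arch = self._resolve_arch(X, len(self.classes_))
        if self.cv:
            self.net_, self.cv_info_ = train_cv(arch, X, y_idx, cfg)
        else:
            rng = np.random.default_rng(cfg.seed)
            tr, va = train_test_split(np.arange(len(y_idx)), test_size=cfg.validation_split,
                                      random_state=cfg.seed, stratify=_merge_rare(y_idx, 2))
            self.net_ = Network(arch, seed=cfg.seed)
            hist = _train_one(self.net_, X[tr], y_idx[tr], X[va], y_idx[va], cfg, rng)
            self.cv_info_ = {"history": hist}
        self.arch_ = arch
        return self

    def predict(self, X):
        return self.classes_[self.net_.predict(np.asarray(X, dtype=float))]

    def predict_proba(self, X):
        return self.net_.predict_proba(np.asarray(X, dtype=float))

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())

    def evaluate(self, X, y, scheme: ClassScheme | None = None, **kwargs) -> EvalReport:
        """Holdout evaluation with predictions mapped back to the original
        class labels (safe when some classes were absent from training)."""
        clf = self

        class _Mapped:
            n_classes = scheme.n_classes if scheme is not None else len(clf.classes_)

            @staticmethod
            def predict(Xq):
                return clf.predict(Xq)

        return evaluate(_Mapped(), X, y, scheme, **kwargs)
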