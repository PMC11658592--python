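"""Pairwise multi-output classifier evaluation under nested cross-validation.

For every admissible pair of terms, a two-output classifier (binary
relevance: one RBF-kernel SVM per term) is trained to decide, from a
protein's feature vector, which of the two terms annotate it — a protein
annotated with both gets the label (1, 1). Admissibility requires each
term to have at least ``m`` *unique* proteins (not annotated with the
other term), which excludes near-subset pairs such as parent/child terms.

Evaluation is a nested cross-validation: an outer stratified K-fold yields
held-out test sets; an inner stratified K-fold on each training part picks
the feature-reduction percentage and SVM hyperparameters by mean macro-F1.
The pair's score is the macro-averaged F1 on the outer test folds — the
arithmetic mean of the two per-term F1 scores. Scores for all admissible
pairs form a sparse symmetric matrix consumed by the greedy reduction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from gosubset.dataset import AnnotationTable
from gosubset.features import FeatureMatrix
from gosubset.simmatrix import PairScoreMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairEvalConfig:
    """Configuration for pairwise nested-CV evaluation.

    ``min_unique`` is the m threshold: minimum unique proteins per term per
    pair. ``gamma_grid`` entries are multiples of 1/d for d feature
    dimensions after reduction. ``leaky_standardize`` reproduces the
    standardize-before-CV ordering some published pipelines use; the
    default fits the scaler on each training fold only.
    """

    min_unique: int = 15
    outer_folds: int = 5
    inner_folds: int = 5
    reducer: str = "anova"  # anova | pca | none
    reducer_grid: tuple[float, ...] = (10, 25, 50, 100)
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    kernel: str = "rbf"
    seed: int = 0
    leaky_standardize: bool = False

    def __post_init__(self):
        if self.min_unique < self.outer_folds:
            raise ValueError("min_unique must be >= outer_folds (each class needs one unique sample per fold)")


@dataclass
class PairResult:
    term_i: str
    term_j: str
    f1_i: float
    f1_j: float
    macro_f1: float
    train_f1: float
    precision_i: float
    precision_j: float
    recall_i: float
    recall_j: float
    n_unique_i: int
    n_unique_j: int
    n_shared: int
    chosen_params: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def pair_dataset(t1: str, t2: str, table: AnnotationTable) -> tuple[list[str], np.ndarray]:
    """Sample ids and 2-column binary labels for the union of two terms."""
    p1 = table.proteins_of(t1)
    p2 = table.proteins_of(t2)
    ids = sorted(p1 | p2)
    labels = np.array([[int(p in p1), int(p in p2)] for p in ids], dtype=int)
    return ids, labels


def admissible(t1: str, t2: str, table: AnnotationTable, m: int) -> bool:
    """True iff each term has >= m proteins not annotated with the other."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p1 = table.proteins_of(t1)
    p2 = table.proteins_of(t2)
    return len(p1 - p2) >= m and len(p2 - p1) >= m


def anova_f(column: np.ndarray, labels: np.ndarray) -> float:
    """One-way two-group ANOVA F statistic for a single feature dimension.

    Between-group mean square over within-group mean square. Zero within-
    variance yields +inf when the group means differ (the dimension ranks
    first) and 0.0 when the groups are identical constants.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    g0, g1 = column[labels == 0], column[labels == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both classes must be non-empty")
    grand = column.mean()
    ssb = len(g0) * (g0.mean() - grand) ** 2 + len(g1) * (g1.mean() - grand) ** 2
    ssw = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
    if ssw == 0.0:
        return float("inf") if ssb > 0 else 0.0
    msb = ssb / 1.0  # k - 1 = 1
    msw = ssw / (len(column) - 2)
    return float(msb / msw)


def _anova_f_columns(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized two-group F over all columns (same formula as anova_f)."""
    m0, m1 = labels == 0, labels == 1
    n0, n1 = m0.sum(), m1.sum()
    mu0 = X[m0].mean(axis=0)
    mu1 = X[m1].mean(axis=0)
    grand = X.mean(axis=0)
    ssb = n0 * (mu0 - grand) ** 2 + n1 * (mu1 - grand) ** 2
    ssw = ((X[m0] - mu0) ** 2).sum(axis=0) + ((X[m1] - mu1) ** 2).sum(axis=0)
    msw = ssw / (len(X) - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / msw
    f[(ssw == 0) & (ssb > 0)] = np.inf
    f[(ssw == 0) & (ssb == 0)] = 0.0
    return f


class _OutputModel:
    """Reducer + SVM for one output (one term) of the pair."""

    def __init__(self, reducer: str, pct: float, c: float, gamma_mult: float, kernel: str):
        self.reducer = reducer
        self.pct = pct
        self.c = c
        self.gamma_mult = gamma_mult
        self.kernel = kernel
        self.keep_: np.ndarray | None = None
        self.pca_: PCA | None = None
        self.svc_: SVC | None = None

    def _reduce_fit(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.reducer == "anova" and self.pct < 100:
            f = _anova_f_columns(X, y)
            k = max(1, int(np.ceil(self.pct / 100.0 * X.shape[1])))
            self.keep_ = np.sort(np.argsort(-f, kind="stable")[:k])
            return X[:, self.keep_]
        if self.reducer == "pca" and self.pct < 100:
            self.pca_ = PCA(n_components=self.pct / 100.0, svd_solver="full")
            return self.pca_.fit_transform(X)
        return X

    def _reduce_apply(self, X: np.ndarray) -> np.ndarray:
        if self.keep_ is not None:
            return X[:, self.keep_]
        if self.pca_ is not None:
            return self.pca_.transform(X)
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OutputModel":
        Xr = self._reduce_fit(X, y)
        d = max(1, Xr.shape[1])
        self.svc_ = SVC(C=self.c, kernel=self.kernel, gamma=self.gamma_mult / d)
        self.svc_.fit(Xr, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.predict(self._reduce_apply(X))


def _standardize(train: np.ndarray, *apply_to: np.ndarray) -> list[np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = []
    for X in (train,) + apply_to:
        Z = (X - mu) / sd_safe
        Z[:, sd == 0] = 0.0
        out.append(Z)
    return out


def _grid(cfg: PairEvalConfig):
    """Hyperparameter combinations in tie-break preference order.

    Earlier entries win ties: smaller C first, then larger reduction
    percentage (more features retained), then smaller kernel width.
    """
    pcts = cfg.reducer_grid if cfg.reducer != "none" else (100,)
    gammas = cfg.gamma_grid if cfg.kernel == "rbf" else (1.0,)
    return [
        (c, pct, gm)
        for c in sorted(cfg.c_grid)
        for pct in sorted(pcts, reverse=True)
        for gm in sorted(gammas)
    ]


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean([f1_score(y_true[:, k], y_pred[:, k], zero_division=0) for k in range(y_true.shape[1])]))


def _fit_predict(Xtr, ytr, Xte, cfg, combo) -> np.ndarray:
    c, pct, gm = combo
    preds = []
    for k in range(ytr.shape[1]):
        model = _OutputModel(cfg.reducer, pct, c, gm, cfg.kernel).fit(Xtr, ytr[:, k])
        preds.append(model.predict(Xte))
    return np.column_stack(preds)


def _split_ok(y: np.ndarray, train_idx: np.ndarray) -> bool:
    ytr = y[train_idx]
    return all(0 < ytr[:, k].sum() < len(ytr) for k in range(y.shape[1]))


def evaluate_pair(
    t1: str,
    t2: str,
    features: FeatureMatrix,
    table: AnnotationTable,
    cfg: PairEvalConfig,
) -> PairResult:
    """Nested-CV macro-F1 for one admissible term pair.

    Deterministic given ``cfg.seed``: outer and inner folds are seeded,
    the hyperparameter search order is fixed, and ties resolve to the
    earliest grid entry.
    """
    if not admissible(t1, t2, table, cfg.min_unique):
        raise ValueError(f"pair ({t1}, {t2}) is not admissible at m={cfg.min_unique}")
    ids, y = pair_dataset(t1, t2, table)
    X = features.rows(ids)
    strat = y[:, 0] * 2 + y[:, 1]

    outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed)
    splits = list(outer.split(X, strat))
    if not all(_split_ok(y, tr) for tr, _ in splits):
        outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed + 1)
        splits = list(outer.split(X, strat))
        if not all(_split_ok(y, tr) for tr, _ in splits):
            raise RuntimeError(f"pair ({t1}, {t2}): a fold lacks a class even after one re-draw")

    fold_f1 = np.zeros((cfg.outer_folds, 2))
    fold_prec = np.zeros((cfg.outer_folds, 2))
    fold_rec = np.zeros((cfg.outer_folds, 2))
    fold_train_f1 = np.zeros(cfg.outer_folds)
    chosen = []

    for fold_no, (tr, te) in enumerate(splits):
        if cfg.leaky_standardize or features.standardized:
            Xtr, Xte = X[tr], X[te]
        else:
            Xtr, Xte = _standardize(X[tr], X[te])
        ytr, yte = y[tr], y[te]

        # inner model selection by mean macro-F1
        inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed)
        inner_splits = [s for s in inner.split(Xtr, strat[tr]) if _split_ok(ytr, s[0])]
        best_combo, best_score = None, -1.0
        for combo in _grid(cfg):
            scores = []
            for itr, ite in inner_splits:
                pred = _fit_predict(Xtr[itr], ytr[itr], Xtr[ite], cfg, combo)
                scores.append(_macro_f1(ytr[ite], pred))
            mean = float(np.mean(scores)) if scores else 0.0
            if mean > best_score:
                best_combo, best_score = combo, mean
        chosen.append({"C": best_combo[0], "pct": best_combo[1], "gamma_mult": best_combo[2], "inner_f1": best_score})

        pred_te = _fit_predict(Xtr, ytr, Xte, cfg, best_combo)
        pred_tr = _fit_predict(Xtr, ytr, Xtr, cfg, best_combo)
        for k in range(2):
            fold_f1[fold_no, k] = f1_score(yte[:, k], pred_te[:, k], zero_division=0)
            fold_prec[fold_no, k] = precision_score(yte[:, k], pred_te[:, k], zero_division=0)
            fold_rec[fold_no, k] = recall_score(yte[:, k], pred_te[:, k], zero_division=0)
        fold_train_f1[fold_no] = _macro_f1(ytr, pred_tr)

    p1, p2 = table.proteins_of(t1), table.proteins_of(t2)
    f1_i, f1_j = fold_f1.mean(axis=0)
    return PairResult(
        term_i=t1,
        term_j=t2,
        f1_i=float(f1_i),
        f1_j=float(f1_j),
        macro_f1=float((f1_i + f1_j) / 2.0),
        train_f1=float(fold_train_f1.mean()),
        precision_i=float(fold_prec[:, 0].mean()),
        precision_j=float(fold_prec[:, 1].mean()),
        recall_i=float(fold_rec[:, 0].mean()),
        recall_j=float(fold_rec[:, 1].mean()),
        n_unique_i=len(p1 - p2),
        n_unique_j=len(p2 - p1),
        n_shared=len(p1 & p2),
        chosen_params=chosen,
    )


def pairwise_f1_matrix(
    terms: Sequence[str],
    features: FeatureMatrix,
    table: AnnotationTable,
    cfg: PairEvalConfig,
    results_out: list | None = None,
) -> PairScoreMatrix:
    """Sparse symmetric macro-F1 matrix over all admissible term pairs.

    Inadmissible pairs (and the diagonal) are masked. Per-pair results are
    appended to ``results_out`` when given, for downstream statistics.
    """
    terms = list(terms)
    k = len(terms)
    vals = np.zeros((k, k))
    mask = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            if not admissible(terms[i], terms[j], table, cfg.min_unique):
                continue
            t0 = time.perf_counter()
            res = evaluate_pair(terms[i], terms[j], features, table, cfg)
            logger.info("pair (%s, %s): macro_f1=%.3f [%.2fs]", terms[i], terms[j], res.macro_f1, time.perf_counter() - t0)
            vals[i, j] = vals[j, i] = res.macro_f1
            mask[i, j] = mask[j, i] = False
            if results_out is not None:
                results_out.append(res)
    return PairScoreMatrix(terms=terms, values=vals, mask=mask, symmetric=True)
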