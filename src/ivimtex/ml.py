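"""Chi-square feature ranking, ANN classification and cross-validation.

The classifier is a fully connected feed-forward network with five hidden
layers of sizes (221, 16, 3, 2, 2), tanh hidden activations and a softmax
output, trained by full-batch quasi-Newton (L-BFGS) minimization of the
L2-penalized cross-entropy (λ = 0.0061374). Weights use He
initialization; biases start at one. Continuous features are ranked by a
chi-square test of independence between their discretized values and the
class label, and only the top-k features are kept.

The evaluation harness is a stratified 5-fold cross-validation repeated
with fresh seeded partitions; feature scaling and selection are re-fit
inside each training fold, so no test-fold information leaks into the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureTable",
    "AnnConfig",
    "AnnModel",
    "CvReport",
    "chi2_importance",
    "select_top_k",
    "ann_train",
    "ann_predict",
    "repeated_stratified_cv",
    "classification_metrics",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1",
                "auc", "error")


@dataclass
class FeatureTable:
    """Cases × named features with one label per case."""

    X: pd.DataFrame
    y: np.ndarray
    positive_label: str | int = 1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have equal length")
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.X.isna().any().any():
            raise ValueError("missing values in feature table")

    @property
    def y_binary(self) -> np.ndarray:
        return (self.y == self.positive_label).astype(int)


@dataclass
class AnnConfig:
    """Fixed architecture and training hyperparameters of the classifier."""

    hidden_layer_sizes: tuple[int, ...] = (221, 16, 3, 2, 2)
    l2_lambda: float = 0.0061374
    max_iterations: int = 1000
    grad_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")


@dataclass
class AnnModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: np.ndarray
    feat_mean: np.ndarray
    feat_std: np.ndarray
    converged: bool


def chi2_importance(
    table: FeatureTable, bins: int = 10
) -> list[tuple[str, float, float]]:
    """Rank features by a chi-square test of independence with the label.

    Each continuous feature is discretized into ``bins`` equal-frequency
    bins over all cases (empty/duplicate bins dropped); the chi-square
    statistic of the bin × class contingency table is computed without
    continuity correction. Features are ranked by ascending p-value, ties
    by descending statistic. A constant feature gets (0, 1) and ranks
    last.
    """
    classes, y_codes = np.unique(table.y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >=2 classes")
    if np.min(np.bincount(y_codes)) < 2:
        raise ValueError("need >=2 cases per class")
    results = []
    for name in table.X.columns:
        v = table.X[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            results.append((name, 0.0, 1.0))
            continue
        uniq = np.unique(v)
        if uniq.size <= bins:
            # few-valued feature: each distinct value is its own bin
            # (qcut would merge them into a single degenerate bin)
            codes = np.searchsorted(uniq, v)
        else:
            codes = pd.qcut(v, q=bins, labels=False, duplicates="drop")
        cont = pd.crosstab(codes, y_codes).to_numpy()
        cont = cont[cont.sum(axis=1) > 0]
        if cont.shape[0] < 2:
            results.append((name, 0.0, 1.0))
            continue
        stat, p, _, _ = scipy.stats.chi2_contingency(cont, correction=False)
        results.append((name, float(stat), float(p)))
    return sorted(results, key=lambda t: (t[2], -t[1]))


def select_top_k(
    table: FeatureTable, ranked: Sequence[tuple[str, float, float]], k: int = 10
) -> FeatureTable:
    """Restrict the table to the k best-ranked features (rank order kept)."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} ranked features")
    names = [name for name, _, _ in ranked[:k]]
    return FeatureTable(table.X[names], table.y, table.positive_label)


def _init_params(cfg: AnnConfig, n_in: int, n_out: int, rng: np.random.Generator):
    sizes = [n_in, *cfg.hidden_layer_sizes, n_out]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out))
                       * np.sqrt(2.0 / fan_in))
        biases.append(np.ones(fan_out))
    return weights, biases


def _pack(weights, biases):
    return np.concatenate([w.ravel() for w in weights]
                          + [b.ravel() for b in biases])


def _unpack(theta, shapes_w, shapes_b):
    ws, bs, off = [], [], 0
    for s in shapes_w:
        n = s[0] * s[1]
        ws.append(theta[off:off + n].reshape(s))
        off += n
    for s in shapes_b:
        bs.append(theta[off:off + s])
        off += s
    return ws, bs


def _forward(X, weights, biases):
    a = X
    acts = [a]
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w + b)
        acts.append(a)
    z = a @ weights[-1] + biases[-1]
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    return acts, probs


def _loss_grad(theta, X, Y, lam, shapes_w, shapes_b):
    ws, bs = _unpack(theta, shapes_w, shapes_b)
    acts, probs = _forward(X, ws, bs)
    n = X.shape[0]
    ce = -np.sum(Y * np.log(np.clip(probs, 1e-300, None))) / n
    loss = ce + lam * sum(float((w ** 2).sum()) for w in ws)

    gw = [np.empty_like(w) for w in ws]
    gb = [np.empty_like(b) for b in bs]
    delta = (probs - Y) / n
    for li in range(len(ws) - 1, -1, -1):
        gw[li] = acts[li].T @ delta + 2.0 * lam * ws[li]
        gb[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ ws[li].T) * (1.0 - acts[li] ** 2)
    return loss, _pack(gw, gb)


def ann_train(
    X: np.ndarray | pd.DataFrame | FeatureTable,
    y: np.ndarray | None = None,
    cfg: AnnConfig | None = None,
) -> AnnModel:
    """Train the fixed-architecture network on standardized features.

    Accepts a :class:`FeatureTable` or an (X, y) pair. Features are
    z-scored with the training statistics (stored in the model, so
    prediction applies the same transform). Deterministic given
    ``cfg.seed``.
    """
    if isinstance(X, FeatureTable):
        y = X.y
        X = X.X
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cfg = cfg or AnnConfig()

    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training fold contains a single class")
    y_idx = np.searchsorted(classes, y)
    Y = np.eye(classes.size)[y_idx]

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    rng = np.random.default_rng(cfg.seed)
    ws, bs = _init_params(cfg, X.shape[1], classes.size, rng)
    shapes_w = [w.shape for w in ws]
    shapes_b = [b.size for b in bs]
    theta0 = _pack(ws, bs)

    res = scipy.optimize.minimize(
        _loss_grad, theta0, args=(Xs, Y, cfg.l2_lambda, shapes_w, shapes_b),
        jac=True, method="L-BFGS-B",
        options={"maxiter": cfg.max_iterations, "gtol": cfg.grad_tol},
    )
    ws, bs = _unpack(res.x, shapes_w, shapes_b)
    return AnnModel(ws, bs, classes, mean, std, bool(res.success))


def ann_predict(
    model: AnnModel, X: np.ndarray | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (softmax) and argmax labels for new cases."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.feat_mean.size:
        raise ValueError(
            f"feature count {X.shape[1]} != training {model.feat_mean.size}"
        )
    Xs = (X - model.feat_mean) / model.feat_std
    _, probs = _forward(Xs, model.weights, model.biases)
    return probs, model.classes[np.argmax(probs, axis=1)]


def classification_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Binary metrics from a confusion matrix [[TP, FN], [FP, TN]].

    Ratios with zero denominators are returned as nan (flagged missing),
    never silently zero.
    """
    (tp, fn), (fp, tn) = np.asarray(confusion, dtype=float)
    if min(tp, fn, fp, tn) < 0 or tp + fn + fp + tn == 0:
        raise ValueError("confusion counts must be nonnegative with total > 0")
    div = lambda a, b: a / b if b > 0 else float("nan")
    acc = (tp + tn) / (tp + fn + fp + tn)
    prec = div(tp, tp + fp)
    rec = div(tp, tp + fn)
    spec = div(tn, tn + fp)
    f1 = div(2 * prec * rec, prec + rec) if np.isfinite(prec) and np.isfinite(rec) \
        else float("nan")
    return {"accuracy": acc, "precision": prec, "recall": rec,
            "specificity": spec, "f1": f1, "error": 1.0 - acc}


@dataclass
class CvReport:
    """Aggregate metrics (mean ± SD) of a repeated cross-validation."""

    mean: dict[str, float]
    sd: dict[str, float]
    per_repeat: pd.DataFrame
    n_repeats: int
    k: int
    test_counts: np.ndarray = field(repr=False, default=None)


def repeated_stratified_cv(
    table: FeatureTable,
    cfg: AnnConfig | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    *,
    select_k: int | None = None,
    chi2_bins: int = 10,
    selection: Literal["per_fold", "global"] = "per_fold",
    aggregate: Literal["per_repeat", "per_fold"] = "per_repeat",
) -> CvReport:
    """Repeated stratified k-fold cross-validation of the ANN.

    Per repeat, a fresh seeded stratified partition is drawn; feature
    scaling, chi-square ranking and top-k selection (when ``select_k`` is
    set) are re-fit inside each training fold (``selection="global"``
    instead performs a one-shot pre-CV selection on all cases). Metrics
    are pooled over the test folds of each repeat (default) or kept per
    fold, then aggregated as mean ± SD. Every case appears in a test set
    exactly ``repeats`` times.
    """
    cfg = cfg or AnnConfig()
    y = table.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} cases; needs >= k={k}"
        )
    y_bin = table.y_binary
    if len(np.unique(y_bin)) < 2:
        raise ValueError("positive_label yields a single class")

    work = table
    if select_k is not None and selection == "global":
        work = select_top_k(table, chi2_importance(table, bins=chi2_bins),
                            k=select_k)

    rows = []
    test_counts = np.zeros(len(y), dtype=int)
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        fold_rows = []
        pooled_true, pooled_pred, pooled_prob = [], [], []
        for tr_idx, te_idx in skf.split(work.X, y_bin):
            test_counts[te_idx] += 1
            tr = FeatureTable(work.X.iloc[tr_idx], y[tr_idx],
                              table.positive_label)
            if select_k is not None and selection == "per_fold":
                tr = select_top_k(tr, chi2_importance(tr, bins=chi2_bins),
                                  k=select_k)
            model = ann_train(tr, cfg=AnnConfig(
                hidden_layer_sizes=cfg.hidden_layer_sizes,
                l2_lambda=cfg.l2_lambda,
                max_iterations=cfg.max_iterations,
                grad_tol=cfg.grad_tol,
                seed=cfg.seed + rep,
            ))
            te_X = work.X.iloc[te_idx][tr.X.columns]
            probs, pred = ann_predict(model, te_X)
            pos_col = int(np.nonzero(
                model.classes == np.asarray(table.positive_label))[0][0]) \
                if np.asarray(table.positive_label) in model.classes else None
            prob_pos = probs[:, pos_col] if pos_col is not None else probs[:, -1]
            yt = y_bin[te_idx]
            yp = (pred == np.asarray(table.positive_label)).astype(int)
            pooled_true.append(yt)
            pooled_pred.append(yp)
            pooled_prob.append(prob_pos)
            if aggregate == "per_fold":
                fold_rows.append(_fold_metrics(yt, yp, prob_pos))
        if aggregate == "per_fold":
            rows.extend(fold_rows)
        else:
            rows.append(_fold_metrics(np.concatenate(pooled_true),
                                      np.concatenate(pooled_pred),
                                      np.concatenate(pooled_prob)))

    per = pd.DataFrame(rows, columns=METRIC_NAMES)
    return CvReport(
        mean={m: float(per[m].mean()) for m in METRIC_NAMES},
        sd={m: float(per[m].std(ddof=1)) for m in METRIC_NAMES},
        per_repeat=per, n_repeats=repeats, k=k, test_counts=test_counts,
    )


def _fold_metrics(y_true, y_pred, prob_pos) -> list[float]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    m = classification_metrics(np.array([[tp, fn], [fp, tn]]))
    if len(np.unique(y_true)) == 2:
        ranks = scipy.stats.rankdata(prob_pos)
        n_pos = int(y_true.sum())
        n_neg = y_true.size - n_pos
        u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
        auc = u / (n_pos * n_neg)
    else:
        auc = float("nan")
    return [m["accuracy"], m["precision"], m["recall"], m["specificity"],
            m["f1"], auc, m["error"]]
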