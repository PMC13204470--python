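"""Three-class blood-pressure classification by softmax regression.

SBP and DBP are discretized into three clinical bins each (SBP: <120,
120–135, >135 mmHg; DBP: <80, 80–85, >85 mmHg) and separate multinomial
logistic regression models map window feature vectors to class
probabilities through the softmax. The optimizer is written here —
full-batch gradient descent on the L2-regularized multinomial
cross-entropy with zero initialization — so the fit is transparent and
deterministic; established libraries serve only as cross-check oracles
in the test suite. Evaluation reports a 3×3 confusion matrix, overall
accuracy and one-vs-rest ROC curves with trapezoid AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CLASSES = 3

SBP_EDGES_MMHG = (120.0, 135.0)
DBP_EDGES_MMHG = (80.0, 85.0)


def discretize_bp(sbp_mmhg: float, dbp_mmhg: float) -> tuple[int, int]:
    """Map SBP/DBP values to their three-class labels.

    Boundary convention: both bin edges belong to the middle class
    (120 and 135 → SBP class 1; 80 and 85 → DBP class 1).
    """
    if sbp_mmhg <= 0 or dbp_mmhg <= 0:
        raise ValueError("blood pressure values must be positive")

    def classify(v: float, lo: float, hi: float) -> int:
        if v < lo:
            return 0
        if v <= hi:
            return 1
        return 2

    return (
        classify(sbp_mmhg, *SBP_EDGES_MMHG),
        classify(dbp_mmhg, *DBP_EDGES_MMHG),
    )


def train_test_split(
    X: np.ndarray, y: np.ndarray, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified random split, reproducible by seed.

    Per-class test counts are rounded so the total matches
    round(test_fraction × n) as closely as stratification allows; every
    class present in the input appears in both partitions.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test fraction must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < N_CLASSES:
        raise ValueError(
            f"all {N_CLASSES} classes must be present, found {classes.tolist()}"
        )
    rng = np.random.default_rng(np.uint32(seed))
    test_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        n_test = int(round(test_fraction * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test].tolist())
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[test_idx] = True
    return X[~test_mask], X[test_mask], y[~test_mask], y[test_mask]


@dataclass
class Hyperparams:
    l2: float = 1e-3
    learning_rate: float = 0.1
    max_iter: int = 5000
    tol: float = 1e-8
    seed: int = 0


@dataclass
class ModelWeights:
    """Fitted softmax-regression parameters.

    ``coef`` is (classes × features) on standardized features;
    ``feature_mean``/``feature_sd`` reproduce the standardization at
    prediction time. ``loss_history`` records the training objective.
    """

    coef: np.ndarray
    intercept: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    hyper: Hyperparams
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_grad(W, b, Xs, Y, l2):
    n = len(Xs)
    P = _softmax(Xs @ W.T + b)
    eps = 1e-300
    loss = -np.sum(Y * np.log(P + eps)) / n + 0.5 * l2 * np.sum(W**2)
    D = (P - Y) / n
    gW = D.T @ Xs + l2 * W
    gb = D.sum(axis=0)
    return loss, gW, gb, P


def fit_multinomial_lr(
    X: np.ndarray, y: np.ndarray, hyper: Hyperparams | None = None
) -> ModelWeights:
    """Fit the softmax model by full-batch gradient descent.

    Features are standardized internally (mean/SD stored in the model);
    weights start at zero, so the fit is deterministic. The step size
    is halved whenever a step would increase the objective, keeping the
    loss history non-increasing; iteration stops when the loss change
    drops below the tolerance.
    """
    hyper = hyper or Hyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if len(classes) < N_CLASSES:
        raise ValueError("all 3 classes must be present for training")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    n, d = Xs.shape
    Y = np.zeros((n, N_CLASSES))
    Y[np.arange(n), y] = 1.0

    W = np.zeros((N_CLASSES, d))
    b = np.zeros(N_CLASSES)
    lr = hyper.learning_rate
    losses = []
    loss, gW, gb, _ = _loss_grad(W, b, Xs, Y, hyper.l2)
    losses.append(loss)
    for _ in range(hyper.max_iter):
        W_new = W - lr * gW
        b_new = b - lr * gb
        new_loss, gW_new, gb_new, _ = _loss_grad(W_new, b_new, Xs, Y, hyper.l2)
        if new_loss > loss:
            lr *= 0.5
            if lr < 1e-12:
                break
            continue
        converged = abs(loss - new_loss) < hyper.tol
        W, b, loss, gW, gb = W_new, b_new, new_loss, gW_new, gb_new
        losses.append(loss)
        if converged:
            break
    return ModelWeights(
        coef=W,
        intercept=b,
        feature_mean=mu,
        feature_sd=sd,
        hyper=hyper,
        loss_history=np.asarray(losses),
    )


def predict_proba(model: ModelWeights, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; each row sums to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.coef.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.coef.shape[1]})"
        )
    Xs = (X - model.feature_mean) / model.feature_sd
    return _softmax(Xs @ model.coef.T + model.intercept)


def predict(model: ModelWeights, X: np.ndarray) -> np.ndarray:
    return np.argmax(predict_proba(model, X), axis=1)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvalReport:
    """Test-set evaluation: confusion matrix, accuracy, per-class ROC."""

    confusion: np.ndarray  # rows = true class, columns = predicted
    accuracy: float
    roc: dict[int, ROCCurve]
    n_test: int
    test_fraction: float | None = None
    seed: int | None = None


def _roc_one_vs_rest(y_bin: np.ndarray, scores: np.ndarray) -> ROCCurve:
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_bin[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    n_pos = int(y_bin.sum())
    n_neg = len(y_bin) - n_pos
    # collapse threshold ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / max(n_pos, 1)]
    fpr = np.r_[0.0, fp[distinct] / max(n_neg, 1)]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def evaluate(y_true: np.ndarray, proba: np.ndarray) -> EvalReport:
    """Confusion matrix, accuracy and one-vs-rest ROC/AUC per class."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty evaluation input")
    if len(y_true) != len(proba):
        raise ValueError("y_true and proba lengths differ")
    y_pred = np.argmax(proba, axis=1)
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    acc = float(np.trace(cm) / len(y_true))
    roc = {
        k: _roc_one_vs_rest((y_true == k).astype(int), proba[:, k])
        for k in range(N_CLASSES)
    }
    return EvalReport(confusion=cm, accuracy=acc, roc=roc, n_test=len(y_true))


def train_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.3,
    seed: int = 0,
    hyper: Hyperparams | None = None,
) -> tuple[ModelWeights, EvalReport]:
    """Split, fit and evaluate one target in a single call."""
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_fraction, seed)
    model = fit_multinomial_lr(X_tr, y_tr, hyper)
    report = evaluate(y_te, predict_proba(model, X_te))
    report.test_fraction = test_fraction
    report.seed = seed
    return model, report


def weights_to_dict(model: ModelWeights) -> dict:
    """JSON-serializable form of the fitted model."""
    return {
        "coef": model.coef.tolist(),
        "intercept": model.intercept.tolist(),
        "feature_mean": model.feature_mean.tolist(),
        "feature_sd": model.feature_sd.tolist(),
        "hyper": {
            "l2": model.hyper.l2,
            "learning_rate": model.hyper.learning_rate,
            "max_iter": model.hyper.max_iter,
            "tol": model.hyper.tol,
            "seed": model.hyper.seed,
        },
    }


def weights_from_dict(d: dict) -> ModelWeights:
    return ModelWeights(
        coef=np.asarray(d["coef"], dtype=float),
        intercept=np.asarray(d["intercept"], dtype=float),
        feature_mean=np.asarray(d["feature_mean"], dtype=float),
        feature_sd=np.asarray(d["feature_sd"], dtype=float),
        hyper=Hyperparams(**d["hyper"]),
    )
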