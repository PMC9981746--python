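"""A three-layer fully connected classifier (input -> 3 ReLU -> softmax).

The network is deliberately tiny: a single hidden layer of 3 units keeps it
hard to overfit and makes the hidden activations directly plottable as 3-D
latent coordinates.  Training follows a specific recipe:

* cost J = 1/(2m) [ sum_i ||p(x_i) - y_i||^2 + lambda * sum_j theta_j^2 ]
  — squared error on the softmax outputs (not cross-entropy), with the
  regularization term inside the 1/(2m) factor and biases excluded,
* minibatch SGD with a harmonically decaying learning rate
  alpha_ep = alpha0 / (1 + ep) (ep is the 1-based epoch number),
* early stopping once validation accuracy exceeds 98% for 50 consecutive
  epochs, max 10,000 epochs,
* stratified 70/15/15 train/validation/test splits and stratified 5-fold
  cross-validation.

All math is plain numpy and exactly reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .preprocess import FeatureDataset

__all__ = [
    "FCNNModel",
    "TrainConfig",
    "Prediction",
    "SplitPlan",
    "init_model",
    "forward",
    "hidden_activations",
    "cost",
    "gradients",
    "train",
    "fit",
    "predict",
    "uncertainty_from_probs",
    "make_split",
    "kfold",
    "cross_validate",
    "save_model",
    "load_model",
]


@dataclass
class FCNNModel:
    W1: np.ndarray  # (D, H)
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (H, C)
    b2: np.ndarray  # (C,)
    class_names: list[str]
    feature_ids: list[str] = field(default_factory=list)

    @property
    def D(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def C(self) -> int:
        return self.W2.shape[1]

    def copy(self) -> "FCNNModel":
        return FCNNModel(
            W1=self.W1.copy(),
            b1=self.b1.copy(),
            W2=self.W2.copy(),
            b2=self.b2.copy(),
            class_names=list(self.class_names),
            feature_ids=list(self.feature_ids),
        )


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the recipe: alpha0 = 0.05, minibatch 8 for the 4-state
    sleep task and 6 for the 2-state movement task, up to 10,000 epochs with
    early stopping at 98% validation accuracy held for 50 epochs, no
    regularization.
    """

    alpha0: float = 0.05
    minibatch: int = 8
    max_epochs: int = 10_000
    lam: float = 0.0
    early_stop_acc: float = 0.98
    early_stop_epochs: int = 50
    decay: str = "closed_form"  # alpha0/(1+ep); "recursive": alpha /= (1+ep)
    restarts: int = 1  # independent seeded inits; best validation accuracy wins
    alpha_grid: tuple[float, ...] | None = None  # per-problem LR candidates
    restart_val_target: float = 0.90  # val accuracy that ends the restart search
    seed: int = 0

    def validate(self) -> None:
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if not (0 < self.early_stop_acc <= 1):
            raise ValueError("early_stop_acc must be in (0, 1]")


@dataclass
class Prediction:
    probs: np.ndarray  # (N, C)
    label: np.ndarray  # (N,) class-name strings
    uncertainty: np.ndarray  # (N,) in [0, 1]


@dataclass
class SplitPlan:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fold: int = 0
    k: int = 1
    seed: int = 0


def init_model(
    D: int,
    C: int,
    seed: int,
    hidden: int = 3,
    class_names: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> FCNNModel:
    """Glorot-uniform weights (Uniform(-r, r), r = sqrt(6/(fan_in+fan_out))),
    zero biases."""
    if D < 1 or C < 1:
        raise ValueError("D and C must be >= 1")
    rng = np.random.default_rng(seed)
    r1 = np.sqrt(6.0 / (D + hidden))
    r2 = np.sqrt(6.0 / (hidden + C))
    return FCNNModel(
        W1=rng.uniform(-r1, r1, (D, hidden)),
        b1=np.zeros(hidden),
        W2=rng.uniform(-r2, r2, (hidden, C)),
        b2=np.zeros(C),
        class_names=list(class_names) if class_names else [str(i) for i in range(C)],
        feature_ids=list(feature_ids) if feature_ids else [],
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)  # overflow-safe
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: FCNNModel, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    if X.shape[1] != model.D:
        raise ValueError(f"expected {model.D} features, got {X.shape[1]}")
    h = np.maximum(X @ model.W1 + model.b1, 0.0)
    return _softmax(h @ model.W2 + model.b2)


def hidden_activations(model: FCNNModel, X: np.ndarray) -> np.ndarray:
    """ReLU hidden-layer activations (the 3-D latent coordinates)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.maximum(X @ model.W1 + model.b1, 0.0)


def onehot(y: np.ndarray, class_names: list[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(class_names)}
    Y = np.zeros((len(y), len(class_names)))
    for i, lab in enumerate(y):
        Y[i, idx[str(lab)]] = 1.0
    return Y


def cost(model: FCNNModel, X: np.ndarray, Y_onehot: np.ndarray, lam: float = 0.0) -> float:
    """J = 1/(2m) [ sum_i ||p_i - y_i||^2 + lam * (||W1||^2 + ||W2||^2) ].

    Squared error over the softmax outputs summed over components and
    samples; the regularization sums squared weights only (not biases).
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y_onehot)
    if X.shape[0] != Y.shape[0] or Y.shape[1] != model.C:
        raise ValueError("X and Y_onehot shapes are inconsistent")
    m = X.shape[0]
    P = forward(model, X)
    sq = float(((P - Y) ** 2).sum())
    reg = lam * (float((model.W1**2).sum()) + float((model.W2**2).sum()))
    return (sq + reg) / (2.0 * m)


def gradients(
    model: FCNNModel, X: np.ndarray, Y_onehot: np.ndarray, lam: float = 0.0
) -> dict[str, np.ndarray]:
    """Exact analytic gradient of the cost; ReLU subgradient at 0 is 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(Y_onehot)
    m = X.shape[0]
    Z1 = X @ model.W1 + model.b1
    A1 = np.maximum(Z1, 0.0)
    P = _softmax(A1 @ model.W2 + model.b2)
    G = (P - Y) / m  # dJ/dP
    # softmax Jacobian: dJ/dz_k = p_k (g_k - sum_j g_j p_j)
    dZ2 = P * (G - (G * P).sum(axis=1, keepdims=True))
    dW2 = A1.T @ dZ2 + (lam / m) * model.W2
    db2 = dZ2.sum(axis=0)
    dA1 = dZ2 @ model.W2.T
    dZ1 = dA1 * (Z1 > 0)
    dW1 = X.T @ dZ1 + (lam / m) * model.W1
    db1 = dZ1.sum(axis=0)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def _accuracy(model: FCNNModel, X: np.ndarray, y: np.ndarray) -> float:
    P = forward(model, X)
    pred = np.argmax(P, axis=1)
    idx = {c: i for i, c in enumerate(model.class_names)}
    truth = np.array([idx[str(v)] for v in y])
    return float(np.mean(pred == truth))


def train(
    model: FCNNModel,
    train_ds: FeatureDataset,
    val_ds: FeatureDataset,
    cfg: TrainConfig,
) -> tuple[FCNNModel, pd.DataFrame]:
    """Minibatch SGD with harmonic learning-rate decay and early stopping.

    Per 1-based epoch ep: alpha_ep = alpha0 / (1 + ep); the training rows are
    reshuffled (seeded) into minibatches and each minibatch applies
    theta <- theta - alpha_ep * grad J(minibatch).  Training stops early once
    validation accuracy exceeds ``early_stop_acc`` for ``early_stop_epochs``
    consecutive epochs.  Returns the trained model and a per-epoch history
    (train/val cost and accuracy).
    """
    cfg.validate()
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)
    Xtr, ytr = train_ds.X, train_ds.y
    Ytr = onehot(ytr, model.class_names)
    Xva, yva = val_ds.X, val_ds.y
    Yva = onehot(yva, model.class_names)
    n = Xtr.shape[0]
    hist: dict[str, list[float]] = {
        "epoch": [], "alpha": [], "train_cost": [], "val_cost": [],
        "train_acc": [], "val_acc": [],
    }
    streak = 0
    alpha = cfg.alpha0
    for ep in range(1, cfg.max_epochs + 1):
        if cfg.decay == "recursive":
            alpha = alpha / (1.0 + ep)
        else:
            alpha = cfg.alpha0 / (1.0 + ep)
        order = rng.permutation(n)
        for start in range(0, n, cfg.minibatch):
            sel = order[start : start + cfg.minibatch]
            g = gradients(model, Xtr[sel], Ytr[sel], cfg.lam)
            model.W1 -= alpha * g["W1"]
            model.b1 -= alpha * g["b1"]
            model.W2 -= alpha * g["W2"]
            model.b2 -= alpha * g["b2"]
        jtr = cost(model, Xtr, Ytr, cfg.lam)
        jva = cost(model, Xva, Yva, cfg.lam)
        if not (np.isfinite(jtr) and np.isfinite(jva)):
            raise FloatingPointError(
                f"training diverged at epoch {ep} (cost train={jtr}, val={jva})"
            )
        atr = _accuracy(model, Xtr, ytr)
        ava = _accuracy(model, Xva, yva)
        hist["epoch"].append(ep)
        hist["alpha"].append(alpha)
        hist["train_cost"].append(jtr)
        hist["val_cost"].append(jva)
        hist["train_acc"].append(atr)
        hist["val_acc"].append(ava)
        streak = streak + 1 if ava > cfg.early_stop_acc else 0
        if streak >= cfg.early_stop_epochs:
            break
    return model, pd.DataFrame(hist)


def uncertainty_from_probs(P: np.ndarray) -> np.ndarray:
    """1 - (p_top1 - p_top2): 0 when certain, 1 when the leaders tie."""
    P = np.atleast_2d(P)
    top2 = np.sort(P, axis=1)[:, -2:]
    return np.clip(1.0 - (top2[:, 1] - top2[:, 0]), 0.0, 1.0)


def predict(model: FCNNModel, X: np.ndarray) -> Prediction:
    """Class probabilities, argmax labels and the uncertainty metric.

    Argmax ties break toward the lowest class index.
    """
    P = forward(model, X)
    idx = np.argmax(P, axis=1)  # argmax takes the first (lowest) on ties
    names = np.asarray(model.class_names, dtype=object)
    return Prediction(probs=P, label=names[idx], uncertainty=uncertainty_from_probs(P))


def make_split(
    ds: FeatureDataset,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SplitPlan:
    """Stratified 70/15/15 train/validation/test split (by row index)."""
    f_tr, f_va, f_te = fractions
    y = ds.y.astype(str)
    idx = np.arange(len(ds))
    n_test = int(round(f_te * len(ds)))
    n_val = int(round(f_va * len(ds)))
    rest, test = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed
    )
    train_idx, val = train_test_split(
        rest, test_size=n_val, stratify=y[rest], random_state=seed
    )
    return SplitPlan(
        train=np.sort(train_idx), val=np.sort(val), test=np.sort(test),
        fold=0, k=1, seed=seed,
    )


def kfold(
    ds: FeatureDataset,
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.15,
) -> list[SplitPlan]:
    """Stratified k-fold plans; each frame is in exactly one test fold.

    Validation (15% of the total by default) is carved, stratified, out of
    each fold's training portion.
    """
    y = ds.y.astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        raise ValueError(f"every class needs >= {k} frames for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    plans = []
    for fold, (rest, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_idx, val = train_test_split(
            rest,
            test_size=int(round(val_fraction * len(y))),
            stratify=y[rest],
            random_state=seed + fold,
        )
        plans.append(
            SplitPlan(
                train=np.sort(train_idx), val=np.sort(val), test=np.sort(test),
                fold=fold, k=k, seed=seed,
            )
        )
    return plans


def fit(
    train_ds: FeatureDataset,
    val_ds: FeatureDataset,
    cfg: TrainConfig | None = None,
    hidden: int = 3,
    seed: int = 0,
) -> tuple[FCNNModel, pd.DataFrame]:
    """Initialize and train, with seeded restarts against stuck optima.

    The squared-error-on-softmax cost has persistent poor optima in which
    two states are merged (validation accuracy plateaus near (C-1)/C and
    the decaying learning rate cannot escape); successful runs instead
    reach high validation accuracy quickly.  ``fit`` therefore trains up to
    ``cfg.restarts`` independent Glorot initializations, each over the
    per-problem learning-rate candidates in ``cfg.alpha_grid`` (selected on
    validation data, as the recipe prescribes), keeps the model with the
    best final validation accuracy and stops searching as soon as a run
    clears ``cfg.restart_val_target``.
    """
    cfg = cfg or TrainConfig()
    classes = sorted(set(train_ds.y.astype(str)) | set(val_ds.y.astype(str)))
    grid = cfg.alpha_grid or (cfg.alpha0,)
    best: tuple[FCNNModel, pd.DataFrame] | None = None
    best_val = -1.0
    done = False
    for r in range(max(1, cfg.restarts)):
        for alpha0 in grid:
            m0 = init_model(
                train_ds.n_features, len(classes),
                seed=(seed + 1_000_003 * r) % 2**31, hidden=hidden,
                class_names=classes, feature_ids=train_ds.feature_ids,
            )
            rcfg = dataclasses.replace(
                cfg, alpha0=alpha0, seed=(cfg.seed + 7 * r) % 2**31
            )
            model, history = train(m0, train_ds, val_ds, rcfg)
            val_acc = float(history["val_acc"].iloc[-1])
            if val_acc > best_val:
                best, best_val = (model, history), val_acc
            if val_acc >= cfg.restart_val_target:
                done = True
                break
        if done:
            break
    assert best is not None
    return best


@dataclass
class FoldResult:
    model: FCNNModel
    plan: SplitPlan
    history: pd.DataFrame
    test_pred: Prediction
    test_accuracy: float


def cross_validate(
    ds: FeatureDataset,
    k: int = 5,
    hidden: int = 3,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> list[FoldResult]:
    """Train and test one model per stratified fold; the workhorse wrapper."""
    cfg = cfg or TrainConfig()
    results = []
    for plan in kfold(ds, k=k, seed=seed):
        fold_cfg = dataclasses.replace(cfg, seed=(cfg.seed + 13 * plan.fold) % 2**31)
        model, history = fit(
            ds.subset(plan.train), ds.subset(plan.val), fold_cfg,
            hidden=hidden, seed=(seed + 101 * plan.fold) % 2**31,
        )
        pred = predict(model, ds.X[plan.test])
        acc = float(np.mean(pred.label == ds.y[plan.test].astype(str)))
        results.append(FoldResult(model, plan, history, pred, acc))
    return results


def save_model(model: FCNNModel, path: str | Path) -> None:
    payload = {
        "D": model.D,
        "hidden": model.hidden,
        "C": model.C,
        "class_names": model.class_names,
        "feature_ids": model.feature_ids,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FCNNModel:
    d = json.loads(Path(path).read_text())
    return FCNNModel(
        W1=np.asarray(d["W1"], dtype=float),
        b1=np.asarray(d["b1"], dtype=float),
        W2=np.asarray(d["W2"], dtype=float),
        b2=np.asarray(d["b2"], dtype=float),
        class_names=list(d["class_names"]),
        feature_ids=list(d.get("feature_ids", [])),
    )
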