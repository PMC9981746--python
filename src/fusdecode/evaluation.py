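"""Quantitative assessment of the decoder.

Covers overall accuracy, per-state precision/recall, permutation-test
significance, the temporal-leakage control (accuracy vs distance to the
nearest training frame), the transition analysis (error enrichment and the
uncertainty rise around state changes), uncertainty-rise event detection,
cross-animal transfer ("accuracy lost"), and the 3-D latent-space view of
the hidden layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fcnn import FCNNModel, Prediction, SplitPlan, hidden_activations, predict
from .preprocess import FeatureDataset
from .synthetic import StateSequence

__all__ = [
    "accuracy",
    "precision_recall",
    "permutation_test",
    "leakage_analysis",
    "transition_error_stats",
    "uncertainty_rise_events",
    "transfer_evaluate",
    "latent_coordinates",
    "TransitionStats",
    "LatentCloud",
    "EvalReport",
]


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of frames classified into the right state."""
    pred = np.asarray(pred).astype(str)
    truth = np.asarray(truth).astype(str)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    return float(np.mean(pred == truth))


def precision_recall(
    pred: np.ndarray, truth: np.ndarray
) -> dict[str, tuple[float | None, float]]:
    """Per-state precision P = TP/PredPos and recall R = TP/Pos.

    A state never predicted has undefined precision, reported as None (not
    0) so averages are not silently deflated.
    """
    pred = np.asarray(pred).astype(str)
    truth = np.asarray(truth).astype(str)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    out: dict[str, tuple[float | None, float]] = {}
    for c in sorted(set(truth)):
        tp = float(np.sum((pred == c) & (truth == c)))
        pred_pos = float(np.sum(pred == c))
        pos = float(np.sum(truth == c))
        p = tp / pred_pos if pred_pos > 0 else None
        r = tp / pos
        out[c] = (p, r)
    return out


def permutation_test(
    pred: np.ndarray,
    truth: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Significance of the observed accuracy against label permutations.

    The test labels are permuted ``n_perm`` times (model predictions fixed)
    and p = (1 + #{permuted accuracy >= observed}) / (n_perm + 1); the +1
    correction keeps p > 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pred = np.asarray(pred).astype(str)
    truth = np.asarray(truth).astype(str)
    obs = np.mean(pred == truth)
    rng = np.random.default_rng(seed)
    count = 0
    t = truth.copy()
    for _ in range(n_perm):
        rng.shuffle(t)
        if np.mean(pred == t) >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def leakage_analysis(
    model: FCNNModel,
    ds_all_frames: FeatureDataset,
    split: SplitPlan,
    max_dist: int = 10,
) -> pd.DataFrame:
    """Accuracy vs temporal distance to the nearest training frame.

    Evaluates every frame not used for training or validation; distance is
    min |frame_index - training frame_index| in frames (the last bin pools
    distances >= max_dist).  A flat profile indicates no information leaks
    from temporally adjacent training frames.
    """
    used = set(ds_all_frames.frame_index[split.train]) | set(
        ds_all_frames.frame_index[split.val]
    )
    train_frames = np.sort(ds_all_frames.frame_index[split.train])
    eval_rows = np.array(
        [i for i, f in enumerate(ds_all_frames.frame_index) if f not in used]
    )
    if eval_rows.size == 0:
        raise ValueError("no frames left outside train/val")
    pred = predict(model, ds_all_frames.X[eval_rows])
    correct = pred.label == ds_all_frames.y[eval_rows].astype(str)
    pos = np.searchsorted(train_frames, ds_all_frames.frame_index[eval_rows])
    left = np.abs(
        ds_all_frames.frame_index[eval_rows]
        - train_frames[np.clip(pos - 1, 0, len(train_frames) - 1)]
    )
    right = np.abs(
        ds_all_frames.frame_index[eval_rows]
        - train_frames[np.clip(pos, 0, len(train_frames) - 1)]
    )
    dist = np.minimum(left, right)
    binned = np.clip(dist, 1, max_dist)
    rows = []
    for d in range(1, max_dist + 1):
        sel = binned == d
        n = int(sel.sum())
        rows.append(
            {
                "distance_frames": d,
                "distance_s": d / ds_all_frames.frame_rate_hz,
                "accuracy": float(correct[sel].mean()) if n else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TransitionStats:
    n_transitions: int
    n_errors: int
    window_s: float
    error_frac_within: float
    expected_uniform: float
    perm_p: float
    profiles: pd.DataFrame  # transition type x time offset
    near_uncertainty: np.ndarray  # per-transition mean, +/- unc_window_s
    away_uncertainty: float
    uncertainty_p: float


def transition_error_stats(
    pred: Prediction,
    states: StateSequence,
    window_s: float,
    frame_rate_hz: float,
    unc_window_s: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
    profile_halfwidth_s: float = 10.0,
) -> TransitionStats:
    """How classification errors and uncertainty relate to state changes.

    * error_frac_within: fraction of error frames within ``window_s`` of the
      nearest transition, with a uniform-placement permutation p-value,
    * per-transition-type mean uncertainty / error-rate profiles aligned on
      the transition frame,
    * a paired one-sided (Wilcoxon) test of whether mean uncertainty within
      +/- unc_window_s of each transition exceeds the away-from-transition
      mean.
    """
    labels = states.labels.astype(str)
    T = len(labels)
    if len(pred.label) != T:
        raise ValueError("prediction must cover every frame of the recording")
    tf = states.transition_frames
    if tf.size == 0:
        raise ValueError("no transitions in the state sequence")
    frames = np.arange(T)
    dist_frames = np.min(np.abs(frames[:, None] - tf[None, :]), axis=1)
    dist_s = dist_frames / frame_rate_hz
    errors = pred.label.astype(str) != labels
    n_err = int(errors.sum())
    if n_err > 0:
        frac = float(np.mean(dist_s[errors] <= window_s))
    else:
        frac = float("nan")
    expected = float(np.mean(dist_s <= window_s))
    rng = np.random.default_rng(seed)
    if n_err > 0:
        count = 0
        for _ in range(n_perm):
            fake = rng.choice(T, size=n_err, replace=False)
            if np.mean(dist_s[fake] <= window_s) >= frac:
                count += 1
        perm_p = (1 + count) / (n_perm + 1)
    else:
        perm_p = 1.0

    half = int(round(profile_halfwidth_s * frame_rate_hz))
    rows = []
    for off in range(-half, half + 1):
        for kind in sorted({f"{a}->{b}" for _, a, b in states.transitions}):
            pts_u, pts_e = [], []
            for f0, a, b in states.transitions:
                if f"{a}->{b}" != kind:
                    continue
                t = f0 + off
                if 0 <= t < T:
                    pts_u.append(pred.uncertainty[t])
                    pts_e.append(float(errors[t]))
            if pts_u:
                rows.append(
                    {
                        "transition": kind,
                        "offset_s": off / frame_rate_hz,
                        "mean_uncertainty": float(np.mean(pts_u)),
                        "error_rate": float(np.mean(pts_e)),
                        "n": len(pts_u),
                    }
                )
    profiles = pd.DataFrame(rows)

    near_w = unc_window_s
    near_means = []
    for f0, _, _ in states.transitions:
        sel = np.abs(frames - f0) / frame_rate_hz <= near_w
        near_means.append(float(pred.uncertainty[sel].mean()))
    near_means = np.asarray(near_means)
    away = dist_s > 2.0 * near_w
    away_mean = float(pred.uncertainty[away].mean()) if away.any() else float("nan")
    diffs = near_means - away_mean
    if np.all(diffs == 0) or len(diffs) < 5:
        unc_p = 1.0
    else:
        unc_p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    return TransitionStats(
        n_transitions=len(tf),
        n_errors=n_err,
        window_s=window_s,
        error_frac_within=frac,
        expected_uniform=expected,
        perm_p=perm_p,
        profiles=profiles,
        near_uncertainty=near_means,
        away_uncertainty=away_mean,
        uncertainty_p=unc_p,
    )


def uncertainty_rise_events(
    uncertainty: np.ndarray,
    states: StateSequence,
    frame_rate_hz: float,
    rise_frac: float = 0.6,
    window_s: float = 2.0,
    baseline_horizon_s: float = 30.0,
    baseline_mode: str = "median",
) -> tuple[np.ndarray, float]:
    """Detect rises of the network uncertainty and relate them to transitions.

    An event fires at the frame where u(t) crosses above
    (1 + rise_frac) * baseline(t) from below; the baseline is a trailing
    moving median over ``baseline_horizon_s`` ("previous" mode uses just
    the preceding frame).  Crossing (not level) detection plus a
    refractory period of ``window_s`` make one sustained rise one event.
    Returns (event frames, fraction of events within ``window_s`` of a
    true transition).
    """
    u = np.asarray(uncertainty, dtype=float)
    T = len(u)
    h = max(1, int(round(baseline_horizon_s * frame_rate_hz)))
    refractory = max(1, int(round(window_s * frame_rate_hz)))

    def threshold(t: int) -> float:
        if baseline_mode == "previous":
            base = u[t - 1]
        else:
            base = float(np.median(u[max(0, t - h) : t]))
        return (1.0 + rise_frac) * base if base > 0 else np.inf

    events = []
    last = -(10**9)
    for t in range(1, T):
        above = u[t] >= threshold(t)
        was_above = t >= 2 and u[t - 1] >= threshold(t - 1)
        if above and not was_above and t - last >= refractory:
            events.append(t)
            last = t
    events = np.asarray(events, dtype=int)
    tf = states.transition_frames
    if events.size == 0 or tf.size == 0:
        return events, float("nan")
    d = np.min(np.abs(events[:, None] - tf[None, :]), axis=1) / frame_rate_hz
    return events, float(np.mean(d <= window_s))


def transfer_evaluate(
    models: dict[str, FCNNModel],
    datasets: dict[str, FeatureDataset],
    heldout: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cross-animal transfer matrix and the "accuracy lost" summary.

    matrix[i, j] = accuracy of animal i's model on animal j's dataset
    (j == i uses held-out rows when given); features are aligned by ROI name,
    so consistent reordering of a dataset's columns cannot change the result.
    accuracy_lost = mean intra-animal (diagonal) - mean inter-animal accuracy.
    """
    names = list(models)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i in names:
        model = models[i]
        if not model.feature_ids:
            raise ValueError(f"model {i!r} has no feature names for alignment")
        for j in names:
            ds = datasets[j]
            try:
                pos = [ds.feature_ids.index(f) for f in model.feature_ids]
            except ValueError as exc:
                raise ValueError(
                    f"dataset {j!r} lacks a feature required by model {i!r}"
                ) from exc
            X = ds.X[:, pos]
            y = ds.y
            if i == j and heldout is not None and i in heldout:
                X, y = X[heldout[i]], y[heldout[i]]
            pred = predict(model, X)
            mat.loc[i, j] = accuracy(pred.label, y)
    diag = np.array([mat.loc[i, i] for i in names], dtype=float)
    off = np.array(
        [mat.loc[i, j] for i in names for j in names if i != j], dtype=float
    )
    lost = float(diag.mean() - off.mean()) if off.size else 0.0
    return mat, lost


@dataclass
class LatentCloud:
    """Frames embedded in the 3-D hidden-activation (latent) space."""

    coords: np.ndarray  # (N, hidden), >= 0 by ReLU
    labels: np.ndarray
    predicted: np.ndarray
    error_flags: np.ndarray
    centroids: dict[str, np.ndarray]
    centroid_distances: pd.DataFrame


def latent_coordinates(
    model: FCNNModel,
    X: np.ndarray,
    truth: np.ndarray,
    pred: Prediction | None = None,
) -> LatentCloud:
    """Hidden activations as coordinates, with per-class centroids."""
    coords = hidden_activations(model, X)
    if pred is None:
        pred = predict(model, X)
    truth = np.asarray(truth).astype(str)
    errors = pred.label.astype(str) != truth
    classes = sorted(set(truth))
    cents = {c: coords[truth == c].mean(axis=0) for c in classes}
    dmat = pd.DataFrame(index=classes, columns=classes, dtype=float)
    for a in classes:
        for b in classes:
            dmat.loc[a, b] = float(np.linalg.norm(cents[a] - cents[b]))
    return LatentCloud(
        coords=coords,
        labels=truth,
        predicted=pred.label,
        error_flags=errors,
        centroids=cents,
        centroid_distances=dmat,
    )


@dataclass
class EvalReport:
    """Serializable container for one evaluation run."""

    accuracy: float
    per_class: dict[str, tuple[float | None, float]]
    perm_p: float
    n_perm: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c: {"precision": p, "recall": r}
                for c, (p, r) in self.per_class.items()
            },
            "perm_p": self.perm_p,
            "n_perm": self.n_perm,
            "extras": self.extras,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        d = json.loads(Path(path).read_text())
        per_class = {
            c: (v["precision"], v["recall"]) for c, v in d["per_class"].items()
        }
        return cls(
            accuracy=d["accuracy"],
            per_class=per_class,
            perm_p=d["perm_p"],
            n_perm=d["n_perm"],
            extras=d.get("extras", {}),
        )
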