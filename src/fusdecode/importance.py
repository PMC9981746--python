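"""Holdback Input Randomization (HIR) importance scoring and map rendering.

With the trained weights frozen, one input at a time is replaced by values
drawn uniformly from [-1, 1] (the feature range after scaling) and the
resulting drop in accuracy — and, per class, in the predicted probability of
that class — measures how much the classifier relies on that input.  Scores
are scattered back onto the imaging plane as pixel maps or painted over ROI
masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fcnn import FCNNModel, _softmax
from .preprocess import FeatureDataset

__all__ = [
    "ImportanceResult",
    "hir_scores",
    "render_pixel_map",
    "render_roi_map",
    "save_importance_csv",
]

SENTINEL = np.nan  # out-of-mask pixels in rendered maps


@dataclass
class ImportanceResult:
    feature_ids: list[str]
    class_names: list[str]
    per_input_overall: np.ndarray  # (D,) accuracy drop
    per_input_per_class: np.ndarray  # (D, C) mean probability drop
    n_rand: int
    seed: int

    def ranking(self) -> np.ndarray:
        """Feature indices sorted by decreasing overall importance."""
        return np.argsort(-self.per_input_overall, kind="stable")


def hir_scores(
    model: FCNNModel,
    test_ds: FeatureDataset,
    n_rand: int = 20,
    seed: int = 0,
    condition_on: str = "true",
) -> ImportanceResult:
    """Accuracy and per-class probability drops per randomized input.

    For each input d, ``n_rand`` replicates replace column d with iid
    Uniform(-1, 1) draws and rerun the (frozen) network.  The overall score
    is baseline accuracy minus the mean randomized accuracy; the per-class
    score for class c averages the drop of the softmax probability of c over
    the frames whose true label is c (``condition_on="predicted"`` uses the
    baseline-predicted label instead).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    X, y = test_ds.X, test_ds.y.astype(str)
    if X.min() < -1.0 - 1e-9 or X.max() > 1.0 + 1e-9:
        raise ValueError("features must be scaled into [-1, 1] before HIR")
    m, D = X.shape
    C = model.C
    rng = np.random.default_rng(seed)
    cls_idx = {c: k for k, c in enumerate(model.class_names)}
    truth_idx = np.array([cls_idx[v] for v in y])

    # baseline pass; keep Z1 so each randomized column is a rank-1 update
    Z1 = X @ model.W1 + model.b1
    P0 = _softmax(np.maximum(Z1, 0.0) @ model.W2 + model.b2)
    base_pred = np.argmax(P0, axis=1)
    if condition_on == "predicted":
        cond_idx = base_pred
    elif condition_on == "true":
        cond_idx = truth_idx
    else:
        raise ValueError("condition_on must be 'true' or 'predicted'")
    base_correct = int(np.sum(base_pred == truth_idx))
    overall = np.zeros(D)
    per_class = np.zeros((D, C))
    class_rows = [np.flatnonzero(cond_idx == k) for k in range(C)]
    for d in range(D):
        # integer counts / accumulated differences keep an input the model
        # ignores at exactly 0
        correct_total = 0
        drop_sum = np.zeros((m, C))
        for _ in range(n_rand):
            new_col = rng.uniform(-1.0, 1.0, m)
            Z1r = Z1 + np.outer(new_col - X[:, d], model.W1[d])
            P = _softmax(np.maximum(Z1r, 0.0) @ model.W2 + model.b2)
            correct_total += int(np.sum(np.argmax(P, axis=1) == truth_idx))
            drop_sum += P0 - P
        mean_drop = drop_sum / n_rand
        overall[d] = (base_correct - correct_total / n_rand) / m
        for k in range(C):
            rows = class_rows[k]
            if rows.size:
                per_class[d, k] = float(np.mean(mean_drop[rows, k]))
    return ImportanceResult(
        feature_ids=list(test_ds.feature_ids),
        class_names=list(model.class_names),
        per_input_overall=overall,
        per_input_per_class=per_class,
        n_rand=n_rand,
        seed=seed,
    )


def _parse_pixel_id(fid: str) -> tuple[int, int]:
    parts = fid.split("_")
    if len(parts) != 3 or parts[0] != "px":
        raise ValueError(f"not a pixel feature id: {fid!r}")
    return int(parts[1]), int(parts[2])


def render_pixel_map(
    result: ImportanceResult,
    grid_shape: tuple[int, int],
    brain_mask: np.ndarray,
    per_class: bool = False,
) -> np.ndarray:
    """Scatter pixel scores back to their coordinates on the downsampled grid.

    Returns (H', W') for overall scores or (C, H', W') with ``per_class``;
    out-of-mask pixels hold NaN, not zero, so "unimportant" and "not brain"
    stay distinguishable.
    """
    coords = [_parse_pixel_id(f) for f in result.feature_ids]
    if len(coords) != int(brain_mask.sum()):
        raise ValueError("feature count does not match in-mask pixel count")
    if per_class:
        out = np.full((len(result.class_names), *grid_shape), SENTINEL)
        for d, (r, c) in enumerate(coords):
            out[:, r, c] = result.per_input_per_class[d]
    else:
        out = np.full(grid_shape, SENTINEL)
        for d, (r, c) in enumerate(coords):
            out[r, c] = result.per_input_overall[d]
    return out


def regather_pixel_scores(map2d: np.ndarray, result: ImportanceResult) -> np.ndarray:
    """Inverse of render_pixel_map for the overall map (round-trip check)."""
    coords = [_parse_pixel_id(f) for f in result.feature_ids]
    return np.array([map2d[r, c] for r, c in coords])


def render_roi_map(
    result: ImportanceResult,
    roi_map: np.ndarray,
    roi_names: dict[int, str],
    per_class: bool = False,
    hemisphere_groups: dict[str, list[str]] | None = None,
) -> np.ndarray:
    """Paint each ROI's score over its mask; label-0 pixels hold NaN.

    ``hemisphere_groups`` optionally maps a group name to the ROI names it
    merges (e.g. bilateral pairs); grouped ROIs are painted with the mean of
    their members' scores.
    """
    score_by_name = dict(zip(result.feature_ids, result.per_input_overall))
    if per_class:
        score_by_name = {
            f: result.per_input_per_class[d]
            for d, f in enumerate(result.feature_ids)
        }
    if hemisphere_groups:
        for group, members in hemisphere_groups.items():
            vals = [score_by_name[m] for m in members if m in score_by_name]
            if vals:
                gv = np.mean(vals, axis=0)
                for m in members:
                    score_by_name[m] = gv
    shape = (
        (len(result.class_names), *roi_map.shape) if per_class else roi_map.shape
    )
    out = np.full(shape, SENTINEL)
    for lab, name in roi_names.items():
        if name not in score_by_name:
            raise ValueError(f"ROI {name!r} has no importance score")
        sel = roi_map == lab
        if per_class:
            out[:, sel] = np.asarray(score_by_name[name])[:, None]
        else:
            out[sel] = score_by_name[name]
    return out


def save_importance_csv(result: ImportanceResult, path: str | Path) -> None:
    df = pd.DataFrame({"feature": result.feature_ids, "overall": result.per_input_overall})
    for k, c in enumerate(result.class_names):
        df[f"drop_{c}"] = result.per_input_per_class[:, k]
    df.to_csv(path, index=False)
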