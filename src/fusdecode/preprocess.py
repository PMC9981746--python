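"""Turn a CBV Recording into classifier-ready feature datasets.

Pipeline order is fixed: dF/F normalization (optional) -> 2x2 max-pool
downsampling (pixel mode only) -> brain masking -> feature extraction
(in-mask pixels or per-ROI means) -> per-frame scaling into [-1, 1] ->
class balancing.  ROI-mode features are computed on full-resolution frames.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import Recording

__all__ = [
    "BaselineModel",
    "FeatureDataset",
    "compute_baseline",
    "normalize_dff",
    "downsample_maxpool",
    "downsample_mask",
    "apply_brain_mask",
    "extract_pixel_features",
    "extract_roi_means",
    "merge_small_rois",
    "harmonize_rois",
    "scale_features",
    "build_balanced_dataset",
    "make_feature_dataset",
    "write_feature_dataset",
    "read_feature_dataset",
]


@dataclass
class BaselineModel:
    """Per-pixel mean CBV over a quiet baseline window (default first 3 min)."""

    mean_image: np.ndarray  # (H, W)
    window: tuple[float, float]  # (start_s, end_s)


@dataclass
class FeatureDataset:
    """An N x D feature matrix with provenance.

    ``feature_ids`` name each column: "px_<row>_<col>" coordinates in pixel
    mode (coordinates on the downsampled grid), ROI names in ROI mode.
    ``frame_index`` maps rows back to original acquisition frames so temporal
    leakage can be analyzed after balancing and splitting.
    """

    X: np.ndarray
    feature_ids: list[str]
    y: np.ndarray  # length-N state-name labels
    frame_index: np.ndarray  # length-N original frame positions
    normalization_mode: str = "ndcbv"  # "dcbv" raw | "ndcbv" dF/F
    frame_rate_hz: float = 1.0
    animal_id: str = ""

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(map(str, self.y)))

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            X=self.X[idx],
            y=self.y[idx],
            frame_index=self.frame_index[idx],
            feature_ids=list(self.feature_ids),
        )


def compute_baseline(rec: Recording, window_s: float = 180.0) -> BaselineModel:
    """Per-pixel arithmetic mean over frames in [0, window_s).

    The baseline window is assumed to be a stable condition; its mean defines
    the denominator of the dF/F transform.
    """
    n = int(round(window_s * rec.frame_rate_hz))
    n = min(n, rec.n_frames)
    if n < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    mean = rec.frames[:n].mean(axis=0)
    bad = (mean <= 0) & rec.brain_mask
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-positive baseline mean at brain pixel ({r}, {c})")
    return BaselineModel(mean_image=mean, window=(0.0, n / rec.frame_rate_hz))


def normalize_dff(rec: Recording, base: BaselineModel) -> Recording:
    """dF/F: (x - baseline_mean) / baseline_mean, per pixel.

    Expresses activity as fractional change relative to the baseline window,
    removing the strong pixel-to-pixel differences in absolute CBV.
    Outside-mask pixels are transformed too; masking handles them later.
    """
    if base.mean_image.shape != rec.grid_shape:
        raise ValueError("baseline geometry does not match recording")
    mean = base.mean_image
    safe = np.where(mean == 0, 1.0, mean)
    out = (rec.frames - mean[None]) / safe[None]
    return dataclasses.replace(rec, frames=out, normalization="ndcbv")


def downsample_maxpool(frame: np.ndarray) -> np.ndarray:
    """2x2 max-pooling with stride 2; trailing odd row/column dropped."""
    h, w = frame.shape[-2], frame.shape[-1]
    if h < 2 or w < 2:
        raise ValueError("frame must be at least 2x2")
    h2, w2 = h // 2, w // 2
    v = frame[..., : 2 * h2, : 2 * w2]
    v = v.reshape(*frame.shape[:-2], h2, 2, w2, 2)
    return v.max(axis=(-3, -1))


def downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Logical-AND 2x2 pooling: a block is brain only if all four pixels are."""
    h2, w2 = mask.shape[0] // 2, mask.shape[1] // 2
    v = mask[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2)
    return v.all(axis=(1, 3))


def apply_brain_mask(rec: Recording) -> Recording:
    """Set every outside-mask pixel to the global minimum of the stack."""
    if rec.brain_mask.shape != rec.grid_shape:
        raise ValueError("mask geometry does not match frames")
    if not rec.brain_mask.any():
        raise ValueError("brain mask is empty")
    gmin = float(rec.frames.min())
    out = rec.frames.copy()
    out[:, ~rec.brain_mask] = gmin
    return dataclasses.replace(rec, frames=out)


def _downsample_recording(rec: Recording) -> Recording:
    frames = downsample_maxpool(rec.frames)
    mask = downsample_mask(rec.brain_mask)
    h2, w2 = mask.shape
    roi = rec.roi_map[0 : 2 * h2 : 2, 0 : 2 * w2 : 2]
    return dataclasses.replace(rec, frames=frames, brain_mask=mask, roi_map=roi)


def extract_pixel_features(rec: Recording) -> tuple[np.ndarray, list[str]]:
    """One feature per in-mask pixel; ids carry the pixel coordinates."""
    coords = np.argwhere(rec.brain_mask)
    X = rec.frames[:, rec.brain_mask]
    ids = [f"px_{r}_{c}" for r, c in coords]
    return X, ids


def extract_roi_means(rec: Recording) -> tuple[np.ndarray, list[str]]:
    """Mean CBV per ROI per frame, columns in ascending ROI-label order."""
    if rec.roi_map is None:
        raise ValueError("recording has no ROI map")
    labels = np.unique(rec.roi_map)
    labels = labels[labels >= 1]
    flat = rec.frames.reshape(rec.n_frames, -1)
    roi_flat = rec.roi_map.ravel()
    X = np.empty((rec.n_frames, len(labels)))
    ids = []
    for j, lab in enumerate(labels):
        sel = roi_flat == lab
        if not sel.any():
            raise ValueError(f"ROI label {lab} is empty")
        X[:, j] = flat[:, sel].mean(axis=1)
        ids.append(rec.roi_names.get(int(lab), f"roi{int(lab):02d}"))
    return X, ids


def merge_small_rois(
    roi_map: np.ndarray,
    roi_names: dict[int, str],
    min_px: int = 20,
) -> tuple[np.ndarray, dict[int, str], list[tuple[int, int]]]:
    """Absorb ROIs smaller than ``min_px`` into their dominant neighbor.

    Without an atlas, "closest in location and function" is operationalized
    as the neighboring ROI sharing the longest boundary (4-connectivity);
    ties break toward the lowest label.  Repeats until no small ROI remains.
    Returns the new map, the surviving name table and a merge log of
    (absorbed_label, into_label) pairs.
    """
    roi = roi_map.copy()
    log: list[tuple[int, int]] = []
    while True:
        labels, counts = np.unique(roi[roi >= 1], return_counts=True)
        small = labels[counts < min_px]
        if small.size == 0:
            break
        if small.size == labels.size:
            raise ValueError("no ROI reaches the minimum size; nothing to merge into")
        lab = int(small[np.argmin(counts[np.isin(labels, small)])])
        target = _dominant_neighbor(roi, lab)
        roi[roi == lab] = target
        log.append((lab, target))
    surviving = set(int(v) for v in np.unique(roi[roi >= 1]))
    names = {k: v for k, v in roi_names.items() if k in surviving}
    return roi, names, log


def _dominant_neighbor(roi: np.ndarray, lab: int) -> int:
    sel = roi == lab
    counts: dict[int, int] = {}
    for shift, axis in (((1, 0), 0), ((-1, 0), 0), ((0, 1), 1), ((0, -1), 1)):
        shifted = np.roll(roi, shift, axis=(0, 1))
        edge = sel & (shifted != lab) & (shifted >= 1)
        # roll wraps around; drop the wrapped border row/column
        if shift[axis] == 1:
            if axis == 0:
                edge[0, :] = False
            else:
                edge[:, 0] = False
        else:
            if axis == 0:
                edge[-1, :] = False
            else:
                edge[:, -1] = False
        for v, c in zip(*np.unique(shifted[edge], return_counts=True)):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    if counts:
        best = max(sorted(counts), key=lambda k: counts[k])
        return best
    # isolated region: fall back to the nearest labeled pixel
    own = np.argwhere(sel)
    others = np.argwhere((roi >= 1) & ~sel)
    if others.size == 0:
        raise ValueError("cannot merge the only ROI")
    d2 = ((own[:, None, :] - others[None, :, :]) ** 2).sum(axis=2)
    return int(roi[tuple(others[np.argmin(d2.min(axis=0))])])


def harmonize_rois(datasets: list[FeatureDataset]) -> list[FeatureDataset]:
    """Restrict every dataset to the shared ROI names, in sorted order.

    Cross-acquisition transfer needs one feature space; correspondence is by
    ROI name only (no image registration).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to harmonize")
    common = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        common &= set(ds.feature_ids)
    if not common:
        raise ValueError("no ROI names shared by all datasets")
    order = sorted(common)
    out = []
    for ds in datasets:
        pos = [ds.feature_ids.index(name) for name in order]
        out.append(
            dataclasses.replace(ds, X=ds.X[:, pos], feature_ids=list(order))
        )
    return out


def scale_features(X_raw: np.ndarray) -> np.ndarray:
    """Affine-map each row (frame) onto [-1, 1] with exact endpoints.

    Rows already spanning [-1, 1] with both endpoints present are returned
    unchanged, which makes the operation idempotent.
    """
    X = np.asarray(X_raw, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        row = int(np.flatnonzero((hi == lo).ravel())[0])
        raise ValueError(f"constant frame (row {row}) cannot be scaled")
    out = 2.0 * (X - lo) / (hi - lo) - 1.0
    done = (lo == -1.0) & (hi == 1.0)
    if np.any(done):
        out = np.where(done, X, out)
    return out


def build_balanced_dataset(ds: FeatureDataset, seed: int) -> FeatureDataset:
    """Randomly undersample every class to the minority-class count.

    Selection is without replacement and seeded; surviving rows keep their
    original temporal order and frame_index for leakage bookkeeping.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(ds.y.astype(str), return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("every class needs at least one frame")
    n_min = int(counts.min())
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(ds.y.astype(str) == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    sel = np.sort(np.concatenate(keep))
    return ds.subset(sel)


def make_feature_dataset(
    rec: Recording,
    labels: np.ndarray,
    mode: str = "roi",
    normalize: bool = True,
    baseline_window_s: float = 180.0,
    discard_label: str = "discarded",
) -> FeatureDataset:
    """Run the full preprocessing pipeline on one recording.

    ``labels`` is a length-T array of state names (``discard_label`` rows are
    dropped from the dataset but keep their frame positions in the original
    acquisition, so frame_index remains meaningful).
    """
    if len(labels) != rec.n_frames:
        raise ValueError("labels length must match frame count")
    work = rec
    if normalize:
        base = compute_baseline(work, baseline_window_s)
        work = normalize_dff(work, base)
    if mode == "pixel":
        work = _downsample_recording(work)
        work = apply_brain_mask(work)
        X, ids = extract_pixel_features(work)
    elif mode == "roi":
        X, ids = extract_roi_means(work)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    X = scale_features(X)
    labels = np.asarray(labels, dtype=object)
    valid = labels != discard_label
    return FeatureDataset(
        X=X[valid],
        feature_ids=ids,
        y=labels[valid],
        frame_index=np.flatnonzero(valid),
        normalization_mode="ndcbv" if normalize else "dcbv",
        frame_rate_hz=rec.frame_rate_hz,
        animal_id=rec.animal_id,
    )


def write_feature_dataset(ds: FeatureDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(ds.X, columns=ds.feature_ids)
    df.insert(0, "frame_index", ds.frame_index)
    df.insert(1, "label", ds.y)
    df.to_csv(path, index=False)
    sidecar = {
        "normalization_mode": ds.normalization_mode,
        "frame_rate_hz": float(ds.frame_rate_hz),
        "animal_id": ds.animal_id,
        "n_frames": int(len(ds)),
        "n_features": int(ds.n_features),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_feature_dataset(path: str | Path) -> FeatureDataset:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = path.with_suffix(".yaml")
    if side.exists():
        meta = yaml.safe_load(side.read_text())
    feats = [c for c in df.columns if c not in ("frame_index", "label")]
    return FeatureDataset(
        X=df[feats].to_numpy(dtype=float),
        feature_ids=feats,
        y=df["label"].to_numpy(dtype=object),
        frame_index=df["frame_index"].to_numpy(dtype=int),
        normalization_mode=str(meta.get("normalization_mode", "ndcbv")),
        frame_rate_hz=float(meta.get("frame_rate_hz", 1.0)),
        animal_id=str(meta.get("animal_id", "")),
    )
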