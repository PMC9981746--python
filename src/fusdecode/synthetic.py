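"""Synthetic functional-ultrasound (fUS) recordings with known behavioral structure.

Real fUS experiments produce a T x H x W stack of cerebral-blood-volume (CBV)
frames at 1-2.5 Hz together with behavior signals used for labeling (track
position for locomotion; EMG, head acceleration and an LFP theta/delta ratio
for sleep scoring).  This module emulates the statistical structure such
recordings are assumed to have, so the whole decoding pipeline is testable
from first principles:

* per-pixel absolute CBV baselines that differ strongly across pixels
  (log-normal),
* state-dependent regional activation: each behavioral state drives a
  configurable fractional CBV change (dF/F amplitude) in each region of
  interest (ROI),
* slow vascular dynamics: the state drive is convolved with a causal
  unit-area hemodynamic kernel (exponential by default, time constant
  ``hemo_tau_s``), so transitions are smeared by ~1.5-2 s as neurovascular
  coupling smears them in vivo,
* a first-order Markov behavioral state sequence with geometric dwell times,
* behavior traces from which the labeling rules can recover the ground truth.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.signal import lfilter

__all__ = [
    "SimConfig",
    "Recording",
    "StateSequence",
    "BehaviorTrace",
    "SLEEP_STATES",
    "LOCOMOTION_STATES",
    "simulate_state_sequence",
    "simulate_recording",
    "simulate_behavior",
    "make_brain_mask",
    "make_roi_map",
    "hemodynamic_kernel",
    "sleep_signal_map",
    "locomotion_signal_map",
    "write_recording",
    "read_recording",
    "write_states",
    "read_states",
    "write_behavior",
    "read_behavior",
]

SLEEP_STATES = ("AW", "QW", "NREMS", "REMS")
LOCOMOTION_STATES = ("static", "moving")


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Full description of one synthetic recording.

    Parameters
    ----------
    n_states : number of behavioral states (>= 1).
    state_names : one name per state.
    duration_s : recording length in seconds.
    frame_rate_hz : imaging frame rate (1-2.5 Hz typical for fUS).
    grid_shape : (H, W) of the imaging plane in pixels.
    n_rois : number of regions the brain is partitioned into.
    roi_signal_map : (n_states, n_rois) array of dF/F effect amplitudes —
        the steady-state fractional CBV change each state drives in each ROI.
    hemo_tau_s : hemodynamic kernel time constant in seconds (default 1.5,
        the transition lag neurovascular coupling imposes on CBV signals).
    dwell_mean_s : mean state dwell time in seconds (scalar or per state).
    baseline_mu, baseline_sigma : log-normal parameters of the per-pixel
        absolute CBV baseline (arbitrary linear units).
    noise_sigma : per-pixel additive noise SD as a fraction of baseline.
    noise_tau_s : optional time constant for temporally correlated pixel
        noise; 0 means iid frame-to-frame noise.
    roi_noise_sigma : SD of slow region-wide vasomotion fluctuations (dF/F
        units); unlike pixel noise these do not average away over an ROI.
    roi_noise_tau_s : time constant of the vasomotion fluctuations (the
        ~1 s decorrelation CBV signals show in vivo).
    initial_state : state the recording starts in (None = random), held for
        ``initial_hold_s`` seconds — acquisitions begin with a stable
        condition so the dF/F baseline window is well defined.
    kernel : "exp" (causal exponential) or "gamma" (shape-3 gamma).
    track_length_m : linear-track length for locomotion behavior.
    seed : RNG seed; identical configs + seed give bit-identical output.
    """

    n_states: int
    state_names: tuple[str, ...]
    duration_s: float
    frame_rate_hz: float
    grid_shape: tuple[int, int]
    n_rois: int
    roi_signal_map: np.ndarray
    hemo_tau_s: float = 1.5
    dwell_mean_s: float | tuple[float, ...] = 20.0
    baseline_mu: float = 5.0
    baseline_sigma: float = 0.5
    noise_sigma: float = 0.05
    noise_tau_s: float = 0.0
    roi_noise_sigma: float = 0.01
    roi_noise_tau_s: float = 1.0
    initial_state: str | None = None
    initial_hold_s: float = 0.0
    kernel: str = "exp"
    track_length_m: float = 2.35
    animal_id: str = "sim01"
    plane_id: str = "plane01"
    seed: int = 0

    def __post_init__(self) -> None:
        self.roi_signal_map = np.asarray(self.roi_signal_map, dtype=float)
        self.state_names = tuple(self.state_names)
        self.grid_shape = tuple(int(v) for v in self.grid_shape)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def dwell_frames(self) -> np.ndarray:
        dwell = np.broadcast_to(
            np.asarray(self.dwell_mean_s, dtype=float), (self.n_states,)
        )
        return dwell * self.frame_rate_hz

    def validate(self) -> None:
        if self.n_states < 1:
            raise ConfigError("n_states must be >= 1")
        if len(self.state_names) != self.n_states:
            raise ConfigError("state_names must have one entry per state")
        if self.roi_signal_map.shape != (self.n_states, self.n_rois):
            raise ConfigError(
                f"roi_signal_map shape {self.roi_signal_map.shape} != "
                f"({self.n_states}, {self.n_rois})"
            )
        if not np.all(np.isfinite(self.roi_signal_map)):
            raise ConfigError("roi_signal_map must be finite")
        dwell = np.broadcast_to(
            np.asarray(self.dwell_mean_s, dtype=float), (self.n_states,)
        )
        if np.any(dwell <= 1.0 / self.frame_rate_hz):
            raise ConfigError("dwell_mean_s must exceed one frame period")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigError("duration_s and frame_rate_hz must be positive")
        h, w = self.grid_shape
        if h < 2 or w < 2:
            raise ConfigError("grid_shape must be at least 2x2")
        if self.n_rois < 1:
            raise ConfigError("n_rois must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_signal_map"] = self.roi_signal_map.tolist()
        d["state_names"] = list(self.state_names)
        d["grid_shape"] = list(self.grid_shape)
        if isinstance(d["dwell_mean_s"], tuple):
            d["dwell_mean_s"] = list(d["dwell_mean_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("dwell_mean_s"), list):
            d["dwell_mean_s"] = tuple(d["dwell_mean_s"])
        return cls(**d)


@dataclass
class StateSequence:
    """Ground-truth per-frame behavioral labels.

    ``labels`` holds state names; ``transitions`` enumerates every label
    change as (frame_index, from_state, to_state), where frame_index is the
    first frame of the new state.
    """

    labels: np.ndarray  # length-T array of state-name strings
    times_s: np.ndarray  # length-T, strictly increasing at 1/frame_rate
    transitions: list[tuple[int, str, str]]
    state_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def transition_frames(self) -> np.ndarray:
        return np.array([t[0] for t in self.transitions], dtype=int)


@dataclass
class Recording:
    """A CBV frame stack plus the geometry needed to interpret it."""

    frames: np.ndarray  # (T, H, W), arbitrary linear CBV units
    frame_rate_hz: float
    brain_mask: np.ndarray  # (H, W) bool
    roi_map: np.ndarray  # (H, W) int, 0 = outside brain
    roi_names: dict[int, str]  # label -> name
    animal_id: str = "sim01"
    plane_id: str = "plane01"
    normalization: str = "dcbv"  # "dcbv" raw | "ndcbv" dF/F

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class BehaviorTrace:
    """Surrogate behavior signals the labeling rules consume."""

    position_m: np.ndarray | None = None  # locomotion mode
    emg: np.ndarray | None = None  # sleep mode
    accel: np.ndarray | None = None
    theta_delta: np.ndarray | None = None

    def __len__(self) -> int:
        for tr in (self.position_m, self.emg, self.accel, self.theta_delta):
            if tr is not None:
                return len(tr)
        return 0


# ---------------------------------------------------------------------------
# state sequence


def simulate_state_sequence(cfg: SimConfig) -> StateSequence:
    """First-order Markov chain over the configured states.

    Dwell times are geometric with per-state mean ``dwell_mean_s`` converted
    to frames (switch probability 1/mean_dwell_frames); on a switch the next
    state is uniform among the other states.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_frames
    n = cfg.n_states
    p_switch = np.clip(1.0 / cfg.dwell_frames, 0.0, 1.0)
    states = np.empty(T, dtype=int)
    hold = 0
    if cfg.initial_state is not None:
        if cfg.initial_state not in cfg.state_names:
            raise ConfigError(f"unknown initial_state {cfg.initial_state!r}")
        s0 = cfg.state_names.index(cfg.initial_state)
        hold = min(T, int(round(cfg.initial_hold_s * cfg.frame_rate_hz)))
        states[:hold] = s0
    if n == 1:
        states[:] = 0
    else:
        s = (
            cfg.state_names.index(cfg.initial_state)
            if cfg.initial_state is not None
            else int(rng.integers(n))
        )
        u = rng.random(T)
        for t in range(hold, T):
            states[t] = s
            if u[t] < p_switch[s]:
                others = [k for k in range(n) if k != s]
                s = others[int(rng.integers(n - 1))]
    names = np.asarray(cfg.state_names, dtype=object)
    labels = names[states]
    times = np.arange(T) / cfg.frame_rate_hz
    transitions = _transitions_from_labels(labels)
    return StateSequence(labels=labels, times_s=times,
                         transitions=transitions,
                         state_names=cfg.state_names)


def _transitions_from_labels(labels: np.ndarray) -> list[tuple[int, str, str]]:
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return [(int(i), str(labels[i - 1]), str(labels[i])) for i in change]


# ---------------------------------------------------------------------------
# geometry


def make_brain_mask(grid_shape: tuple[int, int]) -> np.ndarray:
    """Axis-aligned ellipse inscribed in the grid (True = brain)."""
    h, w = grid_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0


def make_roi_map(
    brain_mask: np.ndarray, n_rois: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition the brain mask into ``n_rois`` regions by seeded Voronoi.

    For even ``n_rois`` the seeds are drawn in the left half and mirrored
    across the vertical midline, giving bilaterally symmetric regions the
    way anatomical ROI maps are.  Label 0 marks outside-brain pixels.
    """
    h, w = brain_mask.shape
    in_pix = np.argwhere(brain_mask)
    if n_rois > len(in_pix):
        raise ConfigError("more ROIs than brain pixels")
    if n_rois % 2 == 0:
        left = in_pix[in_pix[:, 1] < w / 2.0]
        if len(left) < n_rois // 2:
            raise ConfigError("mask too small for mirrored tessellation")
        idx = rng.choice(len(left), size=n_rois // 2, replace=False)
        seeds_l = left[idx]
        seeds_r = seeds_l.copy()
        seeds_r[:, 1] = w - 1 - seeds_r[:, 1]
        seeds = np.vstack([seeds_l, seeds_r])
    else:
        idx = rng.choice(len(in_pix), size=n_rois, replace=False)
        seeds = in_pix[idx]
    d2 = (
        (in_pix[:, None, 0] - seeds[None, :, 0]) ** 2
        + (in_pix[:, None, 1] - seeds[None, :, 1]) ** 2
    )
    nearest = np.argmin(d2, axis=1)  # ties -> lowest seed index
    roi_map = np.zeros((h, w), dtype=np.uint16)
    roi_map[in_pix[:, 0], in_pix[:, 1]] = nearest + 1
    # a mirrored seed can fall on its own mirror image; guarantee non-empty
    for lab in range(1, n_rois + 1):
        if not np.any(roi_map == lab):
            sy, sx = seeds[lab - 1]
            roi_map[sy, sx] = lab
    return roi_map


def hemodynamic_kernel(tau_s: float, dt_s: float, kind: str = "exp") -> np.ndarray:
    """Causal unit-area kernel modeling the vascular impulse response.

    The unit-area normalization makes the steady-state response to a
    sustained drive equal the drive amplitude, so configured dF/F effect
    sizes are realized exactly after the transient.
    """
    if tau_s <= dt_s * 1e-6:
        return np.array([1.0])
    n = max(1, int(np.ceil(10.0 * tau_s / dt_s)))
    t = np.arange(n) * dt_s
    if kind == "exp":
        k = np.exp(-t / tau_s)
    elif kind == "gamma":
        shape = 3.0
        scale = tau_s / shape
        k = t ** (shape - 1) * np.exp(-t / scale)
    else:
        raise ConfigError(f"unknown kernel kind {kind!r}")
    return k / k.sum()


# ---------------------------------------------------------------------------
# recording


def simulate_recording(states: StateSequence, cfg: SimConfig) -> Recording:
    """Render a CBV stack for a given state sequence.

    pixel(t, h, w) = baseline(h, w) * (1 + s(t, roi(h, w)) + eps) where ``s``
    is the state's ROI amplitude convolved with the causal unit-area
    hemodynamic kernel and eps ~ Normal(0, noise_sigma) (optionally filtered
    by the same kernel when ``noise_tau_s`` > 0, variance-preserving).
    """
    cfg.validate()
    T = cfg.n_frames
    if len(states) != T:
        raise ConfigError(
            f"state sequence length {len(states)} != configured {T} frames"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    h, w = cfg.grid_shape
    dt = 1.0 / cfg.frame_rate_hz

    brain_mask = make_brain_mask(cfg.grid_shape)
    roi_map = make_roi_map(brain_mask, cfg.n_rois, rng)
    roi_names = {lab: f"roi{lab:02d}" for lab in range(1, cfg.n_rois + 1)}

    baseline = np.exp(rng.normal(cfg.baseline_mu, cfg.baseline_sigma, (h, w)))

    name_to_idx = {nm: i for i, nm in enumerate(cfg.state_names)}
    state_idx = np.array([name_to_idx[s] for s in states.labels])
    drive = cfg.roi_signal_map[state_idx]  # (T, n_rois)
    k = hemodynamic_kernel(cfg.hemo_tau_s, dt, cfg.kernel)
    sig = lfilter(k, [1.0], drive, axis=0)  # causal, unit steady-state gain

    # slow region-wide vasomotion: fluctuations shared by all pixels of an
    # ROI, so they survive ROI averaging (unlike iid pixel noise)
    if cfg.roi_noise_sigma > 0:
        kv = hemodynamic_kernel(cfg.roi_noise_tau_s, dt, "exp")
        vaso = rng.normal(0.0, cfg.roi_noise_sigma, (T, cfg.n_rois))
        vaso = lfilter(kv, [1.0], vaso, axis=0) / np.sqrt(np.sum(kv**2))
        sig = sig + vaso

    # map per-ROI signal onto pixels; label 0 (outside brain) gets 0 drive
    sig_full = np.concatenate([np.zeros((T, 1)), sig], axis=1)
    sig_px = sig_full[:, roi_map.ravel()].reshape(T, h, w)

    if cfg.noise_sigma > 0:
        eps = rng.normal(0.0, cfg.noise_sigma, (T, h, w))
        if cfg.noise_tau_s > 0:
            kn = hemodynamic_kernel(cfg.noise_tau_s, dt, "exp")
            eps = lfilter(kn, [1.0], eps, axis=0) / np.sqrt(np.sum(kn**2))
    else:
        eps = 0.0

    frames = baseline[None, :, :] * (1.0 + sig_px + eps)
    np.maximum(frames, 1e-6, out=frames)  # CBV is strictly positive
    return Recording(
        frames=frames,
        frame_rate_hz=cfg.frame_rate_hz,
        brain_mask=brain_mask,
        roi_map=roi_map,
        roi_names=roi_names,
        animal_id=cfg.animal_id,
        plane_id=cfg.plane_id,
        normalization="dcbv",
    )


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    states: StateSequence, cfg: SimConfig, mode: str
) -> BehaviorTrace:
    """Emit the signals the labeling rules consume, consistent with states.

    locomotion: per-frame step speed is uniform in [0.15, 0.30] m/s during
    "moving" and [0, 0.05] m/s during "static", so the 0.1 m/s rule recovers
    the labels with margin; the position reflects off the track ends by
    flipping the running direction before a step would leave the track.

    sleep: EMG is high in wake (AW/QW), low in sleep; head acceleration high
    only in AW; theta/delta ratio high only in REMS.  Additive Gaussian noise
    stays below the inter-state gaps.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    T = len(states)
    if mode == "locomotion":
        needed = {"static", "moving"}
        if not needed.issubset(set(cfg.state_names)):
            raise ConfigError("locomotion mode needs states 'static' and 'moving'")
        dt = 1.0 / cfg.frame_rate_hz
        moving = states.labels == "moving"
        speed = np.where(
            moving,
            rng.uniform(0.15, 0.30, T),
            rng.uniform(0.0, 0.05, T),
        )
        L = cfg.track_length_m
        pos = np.empty(T)
        x = L / 2.0
        direction = 1.0
        pos[0] = x
        for t in range(1, T):
            step = speed[t] * dt
            if not (0.0 <= x + direction * step <= L):
                direction = -direction
            x = x + direction * step
            pos[t] = x
        return BehaviorTrace(position_m=pos)
    if mode == "sleep":
        if set(cfg.state_names) != set(SLEEP_STATES):
            raise ConfigError("sleep mode needs states AW, QW, NREMS, REMS")
        lab = states.labels
        wake = (lab == "AW") | (lab == "QW")
        noise = 0.05
        emg = np.where(wake, 1.0, 0.1) + rng.normal(0, noise, T)
        accel = np.where(lab == "AW", 1.0, 0.05) + rng.normal(0, noise, T)
        theta_delta = np.where(lab == "REMS", 1.0, 0.2) + rng.normal(0, noise, T)
        return BehaviorTrace(emg=emg, accel=accel, theta_delta=theta_delta)
    raise ConfigError(f"unknown behavior mode {mode!r}")


def sleep_signal_map(
    n_rois: int,
    informative: tuple[int, ...] = (0, 1, 2),
    amp: float = 0.10,
) -> np.ndarray:
    """Canonical 4-state (AW, QW, NREMS, REMS) dF/F effect map.

    Only the ``informative`` ROI columns carry state information.  The four
    states form a tetrahedral +/-amp code over the three ROIs: every pair
    of states differs in exactly two ROIs (uniform pairwise margin
    amp * 2*sqrt(2)), every state drives all three ROIs (so the per-frame
    scaling is anchored by real signal, never by noise alone), and each ROI
    contributes equally to every state contrast.  Activation and
    deactivation relative to the baseline condition are both physiological.
    """
    if len(informative) != 3:
        raise ConfigError("sleep_signal_map expects exactly 3 informative ROIs")
    m = np.zeros((4, n_rois))
    patterns = np.array(
        [
            [1.0, 1.0, 1.0],  # AW
            [1.0, -1.0, -1.0],  # QW
            [-1.0, 1.0, -1.0],  # NREMS
            [-1.0, -1.0, 1.0],  # REMS
        ]
    )
    for j, roi in enumerate(informative):
        m[:, roi] = amp * patterns[:, j]
    return m


def locomotion_signal_map(
    n_rois: int,
    informative: tuple[int, ...] = (0, 1, 2),
    amp: float = 0.10,
) -> np.ndarray:
    """2-state (static, moving) map: moving activates the informative ROIs."""
    m = np.zeros((2, n_rois))
    for roi in informative:
        m[1, roi] = amp
    return m


# ---------------------------------------------------------------------------
# on-disk format: TIFF stacks + CSV tables + YAML config


def write_recording(rec: Recording, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "frames.tif", rec.frames.astype(np.float32))
    tifffile.imwrite(out / "brain_mask.tif", rec.brain_mask.astype(np.uint8))
    tifffile.imwrite(out / "roi_map.tif", rec.roi_map.astype(np.uint16))
    pd.DataFrame(
        {"label": list(rec.roi_names), "name": list(rec.roi_names.values())}
    ).to_csv(out / "roi_names.csv", index=False)
    meta = {
        "frame_rate_hz": float(rec.frame_rate_hz),
        "animal_id": rec.animal_id,
        "plane_id": rec.plane_id,
        "normalization": rec.normalization,
    }
    (out / "recording.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_recording(in_dir: str | Path) -> Recording:
    p = Path(in_dir)
    meta = yaml.safe_load((p / "recording.yaml").read_text())
    names = pd.read_csv(p / "roi_names.csv")
    return Recording(
        frames=tifffile.imread(p / "frames.tif").astype(np.float64),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        brain_mask=tifffile.imread(p / "brain_mask.tif").astype(bool),
        roi_map=tifffile.imread(p / "roi_map.tif").astype(np.int64),
        roi_names=dict(zip(names["label"].astype(int), names["name"])),
        animal_id=str(meta["animal_id"]),
        plane_id=str(meta["plane_id"]),
        normalization=str(meta.get("normalization", "dcbv")),
    )


def write_states(states: StateSequence, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(states)),
            "time_s": states.times_s,
            "label": states.labels,
        }
    ).to_csv(path, index=False)


def read_states(path: str | Path, frame_rate_hz: float | None = None) -> StateSequence:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype=object)
    times = df["time_s"].to_numpy(dtype=float)
    return StateSequence(
        labels=labels,
        times_s=times,
        transitions=_transitions_from_labels(labels),
        state_names=tuple(pd.unique(labels)),
    )


def write_behavior(trace: BehaviorTrace, path: str | Path) -> None:
    cols = {}
    for name in ("position_m", "emg", "accel", "theta_delta"):
        v = getattr(trace, name)
        if v is not None:
            cols[name] = v
    pd.DataFrame(cols).to_csv(path, index=False)


def read_behavior(path: str | Path) -> BehaviorTrace:
    df = pd.read_csv(path)
    kw = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    return BehaviorTrace(**kw)
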