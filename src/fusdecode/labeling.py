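"""Per-frame behavioral labels from behavior traces.

Locomotion: the along-track speed (one coordinate only) is thresholded at
0.1 m/s; frames inside a configurable near-threshold band are discarded so
the two classes stay distinct.

Sleep/wake: a simplified implementation of classical rule-based sleep
scoring.  Wake whenever EMG is high; sleep begins only after EMG has stayed
below threshold for more than a persistence period (default 10 s).  Within
wake, head acceleration separates active (AW) from quiet (QW) wake; within
sleep, the theta/delta ratio separates REMS from NREMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import BehaviorTrace, StateSequence, _transitions_from_labels

__all__ = [
    "LabelingConfig",
    "compute_speed",
    "label_locomotion",
    "score_sleep",
    "auto_threshold",
]

DISCARDED = "discarded"


@dataclass
class LabelingConfig:
    speed_threshold_mps: float = 0.1
    discard_band_mps: tuple[float, float] = (0.1, 0.1)
    emg_threshold: float = 0.55
    accel_threshold: float = 0.5
    theta_delta_threshold: float = 0.6
    sleep_persistence_s: float = 10.0

    def validate(self) -> None:
        low, high = self.discard_band_mps
        if not (low <= self.speed_threshold_mps <= high):
            raise ValueError("discard band must bracket the speed threshold")
        if self.sleep_persistence_s <= 0:
            raise ValueError("sleep persistence must be positive")


def compute_speed(position_m: np.ndarray, frame_rate_hz: float) -> np.ndarray:
    """|difference in position between consecutive frames| x frame rate.

    The first frame has no predecessor; it inherits the second frame's speed.
    """
    pos = np.asarray(position_m, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least 2 frames to compute speed")
    speed = np.empty_like(pos)
    speed[1:] = np.abs(np.diff(pos)) * frame_rate_hz
    speed[0] = speed[1]
    return speed


def label_locomotion(
    speed: np.ndarray, cfg: LabelingConfig | None = None
) -> np.ndarray:
    """static below the band, moving above it, discarded inside it.

    With the degenerate default band (0.1, 0.1) only frames whose speed is
    exactly 0.1 m/s are discarded.  Discarded frames are excluded from
    training/testing downstream but keep their frame positions.
    """
    cfg = cfg or LabelingConfig()
    cfg.validate()
    low, high = cfg.discard_band_mps
    speed = np.asarray(speed, dtype=float)
    labels = np.full(speed.shape, DISCARDED, dtype=object)
    labels[speed < low] = "static"
    labels[speed > high] = "moving"
    return labels


def score_sleep(
    trace: BehaviorTrace,
    cfg: LabelingConfig,
    frame_rate_hz: float,
) -> StateSequence:
    """Rule-based scoring into AW, QW, NREMS, REMS.

    Wake is declared whenever EMG >= emg_threshold.  Sleep begins only once
    EMG has been continuously below threshold for more than
    ``sleep_persistence_s``; the waiting frames stay labeled wake (QW/AW by
    the acceleration rule).  Within sleep, REMS iff theta/delta >= threshold.
    """
    cfg.validate()
    for name in ("emg", "accel", "theta_delta"):
        if getattr(trace, name) is None:
            raise ValueError(f"sleep scoring needs the {name!r} trace")
    emg = np.asarray(trace.emg, dtype=float)
    accel = np.asarray(trace.accel, dtype=float)
    td = np.asarray(trace.theta_delta, dtype=float)
    T = len(emg)
    dt = 1.0 / frame_rate_hz

    labels = np.empty(T, dtype=object)
    below_run = 0  # consecutive sub-threshold frames ending at t
    for t in range(T):
        if emg[t] >= cfg.emg_threshold:
            below_run = 0
            asleep = False
        else:
            below_run += 1
            asleep = below_run * dt > cfg.sleep_persistence_s
        if asleep:
            labels[t] = "REMS" if td[t] >= cfg.theta_delta_threshold else "NREMS"
        else:
            labels[t] = "AW" if accel[t] >= cfg.accel_threshold else "QW"
    times = np.arange(T) * dt
    return StateSequence(
        labels=labels,
        times_s=times,
        transitions=_transitions_from_labels(labels),
        state_names=("AW", "QW", "NREMS", "REMS"),
    )


def auto_threshold(signal: np.ndarray) -> float:
    """Midpoint of a bimodal signal's two modes, for synthetic traces.

    Uses the midpoint between robust extremes (5th and 95th percentiles),
    which lands between the two modes whenever the modes are separated by
    more than the within-mode spread.
    """
    lo, hi = np.percentile(np.asarray(signal, dtype=float), [5, 95])
    return float((lo + hi) / 2.0)
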