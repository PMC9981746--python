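"""End-to-end orchestration over synthetic recordings.

One YAML-able config dict fully determines a run: simulate -> label ->
preprocess -> train (stratified k-fold) -> evaluate -> importance, with a
``transfer`` scenario that trains one model per synthetic animal and
cross-applies them after ROI harmonization.  Every run writes a provenance
record (config hash, seeds, package version) and a deterministic
report.json: rerunning with the same config reproduces it byte-for-byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fcnn import TrainConfig, cross_validate, fit, make_split, predict, save_model
from .evaluation import (
    leakage_analysis,
    latent_coordinates,
    permutation_test,
    precision_recall,
    transfer_evaluate,
    transition_error_stats,
    uncertainty_rise_events,
)
from .importance import hir_scores, save_importance_csv
from .labeling import LabelingConfig, compute_speed, label_locomotion, score_sleep
from .preprocess import (
    build_balanced_dataset,
    harmonize_rois,
    make_feature_dataset,
    write_feature_dataset,
)
from .synthetic import (
    LOCOMOTION_STATES,
    SLEEP_STATES,
    SimConfig,
    locomotion_signal_map,
    simulate_behavior,
    simulate_recording,
    simulate_state_sequence,
    sleep_signal_map,
    write_behavior,
    write_recording,
    write_states,
)

__all__ = ["default_config", "build_sim_config", "simulate_animal", "run_pipeline"]


def default_config(mode: str = "locomotion") -> dict:
    """A small, fast demo configuration (single CPU, minutes)."""
    is_loc = mode == "locomotion"
    return {
        "mode": mode,
        "scenario": "single",  # or "transfer"
        "seed": 0,
        "n_animals": 2,
        "sim": {
            "duration_s": 900.0 if is_loc else 1800.0,
            "frame_rate_hz": 2.5 if is_loc else 1.0,
            "grid_shape": [32, 40],
            "n_rois": 12,
            "informative_rois": [0, 1, 2],
            "amp": 0.10,
            "noise_sigma": 0.02,
            "roi_noise_sigma": 0.01,
            "hemo_tau_s": 1.5,
            # recordings open with a stable baseline condition for dF/F
            "initial_state": "static" if is_loc else "QW",
            "initial_hold_s": 180.0,
            # locomotion run/stop bouts last tens of seconds; sleep bouts
            # (NREM/REM episodes in rat) last minutes
            "dwell_mean_s": 20.0 if is_loc else 90.0,
        },
        "features": {"mode": "roi", "normalize": True, "baseline_window_s": 180.0},
        # learning-rate candidates selected per problem on validation data
        "train": {"alpha0": 0.05, "alpha_grid": [0.5, 0.05],
                  "minibatch": 6 if is_loc else 8,
                  "max_epochs": 300, "hidden": 3, "restarts": 10},
        "eval": {"k": 5, "n_perm": 200, "transition_window_s": 5.0,
                 "leakage_max_dist": 8},
        "importance": {"n_rand": 20},
    }


def build_sim_config(cfg: dict, animal: int = 0) -> SimConfig:
    sim = cfg["sim"]
    mode = cfg["mode"]
    informative = tuple(sim.get("informative_rois", (0, 1, 2)))
    amp = float(sim.get("amp", 0.10))
    n_rois = int(sim["n_rois"])
    if mode == "locomotion":
        names = LOCOMOTION_STATES
        smap = locomotion_signal_map(n_rois, informative, amp)
    elif mode == "sleep":
        names = SLEEP_STATES
        smap = sleep_signal_map(n_rois, informative, amp)
    else:
        raise ValueError(f"unknown mode {cfg['mode']!r}")
    gain = 1.0 + 0.2 * (animal - (cfg.get("n_animals", 1) - 1) / 2.0) * 2.0 / max(
        1, cfg.get("n_animals", 1) - 1
    ) if cfg.get("scenario") == "transfer" and cfg.get("n_animals", 1) > 1 else 1.0
    return SimConfig(
        n_states=len(names),
        state_names=names,
        duration_s=float(sim["duration_s"]),
        frame_rate_hz=float(sim["frame_rate_hz"]),
        grid_shape=tuple(sim["grid_shape"]),
        n_rois=n_rois,
        roi_signal_map=smap * gain,
        hemo_tau_s=float(sim.get("hemo_tau_s", 1.5)),
        dwell_mean_s=float(sim.get("dwell_mean_s", 20.0)),
        noise_sigma=float(sim.get("noise_sigma", 0.02)),
        noise_tau_s=float(sim.get("noise_tau_s", 0.0)),
        roi_noise_sigma=float(sim.get("roi_noise_sigma", 0.01)),
        roi_noise_tau_s=float(sim.get("roi_noise_tau_s", 1.0)),
        initial_state=sim.get("initial_state"),
        initial_hold_s=float(sim.get("initial_hold_s", 0.0)),
        animal_id=f"animal{animal:02d}",
        seed=(int(cfg.get("seed", 0)) + 7919 * animal) % 2**31,
    )


def simulate_animal(cfg: dict, animal: int = 0):
    """Simulate one animal: (recording, ground-truth states, behavior)."""
    sc = build_sim_config(cfg, animal)
    states = simulate_state_sequence(sc)
    rec = simulate_recording(states, sc)
    mode = "locomotion" if cfg["mode"] == "locomotion" else "sleep"
    trace = simulate_behavior(states, sc, mode)
    return sc, rec, states, trace


def _label_frames(cfg: dict, rec, trace) -> np.ndarray:
    lcfg = LabelingConfig()
    if cfg["mode"] == "locomotion":
        speed = compute_speed(trace.position_m, rec.frame_rate_hz)
        return label_locomotion(speed, lcfg)
    return score_sleep(trace, lcfg, rec.frame_rate_hz).labels


def _stage_done(out: Path, marker: str, resume: bool) -> bool:
    return resume and (out / marker).exists()


def run_pipeline(cfg: dict, out_dir: str | Path, resume: bool = False) -> dict:
    """Execute the configured scenario and write the artifact tree.

    Returns the report dict (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = copy.deepcopy(cfg)
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "package_version": __version__,
        "seed": int(cfg.get("seed", 0)),
    }
    (out / "config.yaml").write_text(cfg_text)
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))

    scenario = cfg.get("scenario", "single")
    n_animals = int(cfg.get("n_animals", 1)) if scenario == "transfer" else 1
    tcfg = TrainConfig(
        alpha0=float(cfg["train"].get("alpha0", 0.05)),
        minibatch=int(cfg["train"].get("minibatch", 8)),
        max_epochs=int(cfg["train"].get("max_epochs", 10_000)),
        restarts=int(cfg["train"].get("restarts", 1)),
        alpha_grid=tuple(cfg["train"]["alpha_grid"])
        if cfg["train"].get("alpha_grid")
        else None,
        seed=int(cfg.get("seed", 0)),
    )
    hidden = int(cfg["train"].get("hidden", 3))
    fcfg = cfg["features"]
    ecfg = cfg["eval"]
    seed = int(cfg.get("seed", 0))

    datasets, balanced, recs, states_all = {}, {}, {}, {}
    for a in range(n_animals):
        adir = out / f"animal{a:02d}"
        sc, rec, states, trace = simulate_animal(cfg, a)
        if not _stage_done(adir, "recording.yaml", resume):
            write_recording(rec, adir)
            write_states(states, adir / "true_states.csv")
            write_behavior(trace, adir / "behavior.csv")
        labels = _label_frames(cfg, rec, trace)
        ds = make_feature_dataset(
            rec,
            labels,
            mode=fcfg.get("mode", "roi"),
            normalize=bool(fcfg.get("normalize", True)),
            baseline_window_s=float(fcfg.get("baseline_window_s", 180.0)),
        )
        bal = build_balanced_dataset(ds, seed=seed + a)
        if not _stage_done(adir, "features.csv", resume):
            write_feature_dataset(bal, adir / "features.csv")
        key = f"animal{a:02d}"
        datasets[key], balanced[key] = ds, bal
        recs[key], states_all[key] = rec, states

    report: dict = {"mode": cfg["mode"], "scenario": scenario, "seed": seed}

    # --- per-acquisition k-fold training and evaluation (first animal) -----
    key0 = "animal00"
    bal0 = balanced[key0]
    folds = cross_validate(bal0, k=int(ecfg.get("k", 5)), hidden=hidden,
                           cfg=tcfg, seed=seed)
    fold_accs = [f.test_accuracy for f in folds]
    best = folds[int(np.argmax(fold_accs))]
    save_model(best.model, out / "model.json")
    best.history.to_csv(out / "history.csv", index=False)
    report["kfold_accuracy_mean"] = float(np.mean(fold_accs))
    report["kfold_accuracy_sd"] = float(np.std(fold_accs))
    report["fold_accuracies"] = [round(a, 6) for a in fold_accs]

    truth_test = bal0.y[best.plan.test].astype(str)
    pr = precision_recall(best.test_pred.label, truth_test)
    report["per_class"] = {
        c: {"precision": None if p is None else round(p, 6), "recall": round(r, 6)}
        for c, (p, r) in pr.items()
    }
    report["perm_p"] = permutation_test(
        best.test_pred.label, truth_test,
        n_perm=int(ecfg.get("n_perm", 200)), seed=seed,
    )

    # transition analysis on every labeled frame of the acquisition
    # (datasets[key0] holds all non-discarded frames, in temporal order)
    from .synthetic import StateSequence, _transitions_from_labels

    pred_full = predict(best.model, datasets[key0].X)
    seq_valid = StateSequence(
        labels=datasets[key0].y,
        times_s=datasets[key0].frame_index / recs[key0].frame_rate_hz,
        transitions=_transitions_from_labels(datasets[key0].y),
        state_names=tuple(sorted(set(datasets[key0].y.astype(str)))),
    )
    tstats = transition_error_stats(
        pred_full,
        seq_valid,
        window_s=float(ecfg.get("transition_window_s", 5.0)),
        frame_rate_hz=recs[key0].frame_rate_hz,
        n_perm=int(ecfg.get("n_perm", 200)),
        seed=seed,
    )
    tstats.profiles.to_csv(out / "transition_profiles.csv", index=False)
    report["transition"] = {
        "n_transitions": tstats.n_transitions,
        "n_errors": tstats.n_errors,
        "error_frac_within_window": None
        if np.isnan(tstats.error_frac_within)
        else round(tstats.error_frac_within, 6),
        "expected_uniform": round(tstats.expected_uniform, 6),
        "perm_p": round(tstats.perm_p, 6),
        "uncertainty_p": round(tstats.uncertainty_p, 6),
    }
    events, frac_near = uncertainty_rise_events(
        pred_full.uncertainty, seq_valid, recs[key0].frame_rate_hz
    )
    report["uncertainty_rises"] = {
        "n_events": int(len(events)),
        "frac_near_transition": None if np.isnan(frac_near) else round(frac_near, 6),
    }

    # leakage control
    leak = leakage_analysis(
        best.model, bal0, best.plan, max_dist=int(ecfg.get("leakage_max_dist", 8))
    )
    leak.to_csv(out / "leakage.csv", index=False)

    # latent space
    cloud = latent_coordinates(best.model, bal0.X[best.plan.test], truth_test,
                               best.test_pred)
    report["latent_centroid_distances"] = {
        f"{a}|{b}": round(float(cloud.centroid_distances.loc[a, b]), 6)
        for a in cloud.centroid_distances.index
        for b in cloud.centroid_distances.columns
        if a < b
    }

    # importance
    hir = hir_scores(
        best.model,
        bal0.subset(best.plan.test),
        n_rand=int(cfg["importance"].get("n_rand", 20)),
        seed=seed,
    )
    save_importance_csv(hir, out / "importance.csv")
    order = hir.ranking()
    report["importance_top3"] = [hir.feature_ids[i] for i in order[:3]]

    # --- transfer scenario -------------------------------------------------
    if scenario == "transfer" and n_animals > 1:
        harmonized = harmonize_rois([balanced[k] for k in sorted(balanced)])
        models, heldout = {}, {}
        for k, ds in zip(sorted(balanced), harmonized):
            plan = make_split(ds, seed=seed)
            m, _ = fit(ds.subset(plan.train), ds.subset(plan.val), tcfg,
                       hidden=hidden, seed=seed)
            models[k] = m
            heldout[k] = plan.test
        mat, lost = transfer_evaluate(
            models, dict(zip(sorted(balanced), harmonized)), heldout
        )
        mat.to_csv(out / "transfer_matrix.csv")
        report["transfer"] = {
            "matrix": {i: {j: round(float(mat.loc[i, j]), 6) for j in mat.columns}
                       for i in mat.index},
            "accuracy_lost": round(lost, 6),
        }

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
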