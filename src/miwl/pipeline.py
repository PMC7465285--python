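"""End-to-end glue: from a raw session to aligned feature matrices and labels.

Ties the module chain together the way the deployment story runs: EEG is
preprocessed into the 45-band and 187-bin ROI matrices, the vehicular
telemetry is resampled and reduced onto exactly the kept-epoch grid, both
are min-max scaled on the training rows, the MI template is estimated on
the training rows, and MI-projected features are produced for every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from . import mi_fusion, vehicle
from .simulate import SessionRecording, label_epochs, synthesize_resting_eeg


@dataclass
class SessionFeatures:
    """Row-aligned per-epoch feature matrices and labels for one session."""

    band45: np.ndarray
    roi187: np.ndarray
    eligible99: np.ndarray
    vehicular4: np.ndarray         # raw per-epoch means (pre-scaling)
    labels: pd.DataFrame           # lap / segment / hour / event per epoch
    start_times_s: np.ndarray
    iaf: eeg_mod.IAFEstimate


def extract_session_features(
    rec: SessionRecording, resting_eeg: np.ndarray | None = None,
    iaf: eeg_mod.IAFEstimate | None = None,
) -> SessionFeatures:
    """Run the full preprocessing chain on one session.

    If neither ``resting_eeg`` nor ``iaf`` is given, a closed-eyes resting
    recording is synthesized from the session config (the simulator's
    counterpart of the one-minute resting acquisition).
    """
    if iaf is None and resting_eeg is None:
        resting_eeg = synthesize_resting_eeg(rec.config)
    feats = eeg_mod.preprocess(
        rec.eeg, rec.channel_names, resting_eeg=resting_eeg, iaf=iaf
    )
    veh4 = vehicle.align_session_vehicular(rec.vehicular, feats.start_times_s)
    labels = label_epochs(rec.annotations, feats.start_times_s)
    return SessionFeatures(
        band45=feats.band45, roi187=feats.roi187, eligible99=feats.eligible99,
        vehicular4=veh4, labels=labels, start_times_s=feats.start_times_s,
        iaf=feats.iaf,
    )


def mwl_class_labels(labels: pd.DataFrame, by: str = "segment") -> np.ndarray:
    """Binary workload labels: 1 = high demand (Hard or Rush), 0 = low."""
    if by == "segment":
        return (labels["segment"] == "Hard").to_numpy().astype(int)
    if by == "hour":
        return (labels["hour"] == "Rush").to_numpy().astype(int)
    raise ValueError(f"unknown labeling {by!r}")


def event_mask_and_labels(labels: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Epochs during Car/Pedestrian events and their binary labels (Car = 1)."""
    mask = labels["event"].isin(["Car", "Pedestrian"]).to_numpy()
    y = (labels.loc[mask, "event"] == "Car").to_numpy().astype(int)
    return mask, y


def grouped_event_auc(
    features: np.ndarray, labels: np.ndarray, groups: np.ndarray,
    seed: int = 0, n_folds: int = 4,
) -> float:
    """Mean held-out-event RF AUC with event-grouped, class-balanced folds.

    Overlapping epochs from one event are near-duplicates, so folds must
    split by event, not by epoch; each fold receives events of both classes
    so a per-fold AUC is defined.  Returns the mean AUC across folds.
    """
    from .evaluate import ModelSpec, build_model, roc_auc

    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    class_of = {g: int(labels[groups == g][0]) for g in uniq}
    folds: dict[int, list] = {i: [] for i in range(n_folds)}
    for cls in (0, 1):
        gs = rng.permutation([g for g in uniq if class_of[g] == cls])
        for i, g in enumerate(gs):
            folds[i % n_folds].append(g)
    aucs = []
    for i in range(n_folds):
        test = np.isin(groups, folds[i])
        model = build_model(ModelSpec("RF", "classification"), seed=seed)
        model.fit(features[~test], labels[~test])
        aucs.append(roc_auc(model.predict_proba(features[test])[:, 1], labels[test])["auc"])
    return float(np.mean(aucs))


def event_groups(labels: pd.DataFrame, mask: np.ndarray, config) -> np.ndarray:
    """Integer event-interval id for each masked epoch (by event onset)."""
    onsets = np.array([onset for _, onset, _ in config.events])
    starts = labels.loc[mask, "start_s"].to_numpy() + 1.0  # window midpoint
    return np.searchsorted(np.sort(onsets), starts, side="right") - 1


def vehicular_only_event_auc(
    coupling: float, seed: int, n_blocks: int = 30, segment_s: float = 40.0,
    event_s: float = 14.0, event_offset_s: float = 13.0,
    calibration_segment_s: float = 90.0, n_folds: int = 5,
) -> float:
    """Held-out-event RF AUC for Car vs Pedestrian from vehicular data alone.

    Mirrors the deployment story: an MI template is fitted on a short
    calibration session (EEG + vehicular, same coupling), then a long
    event-rich session is scored *without synthesizing any EEG* - its
    vehicular epochs are scaled with the template's training ranges and
    projected through the row norms.  Event types are balanced within each
    segment type so the only route from event type to vehicular features is
    the latent-trace coupling; folds split by event (see
    :func:`grouped_event_auc`).
    """
    from .simulate import (
        SimulationConfig, label_epochs, make_session, schedule_annotations,
        simulate_workload_trace, synthesize_vehicular,
    )

    cal_cfg = SimulationConfig(
        seed=seed + 50, coupling=coupling,
        lap_plan=[("Easy", calibration_segment_s), ("Hard", calibration_segment_s)],
    )
    cal_rec, _ = make_session(cal_cfg)
    cal = extract_session_features(cal_rec)
    _, template = build_mi_features(cal.vehicular4, cal.band45, cal.vehicular4)

    plan = [(seg, segment_s) for _ in range(n_blocks) for seg in ("Easy", "Hard")]
    rng = np.random.default_rng([seed, 99])
    easy_t = rng.permutation(["Car", "Pedestrian"] * (n_blocks // 2))
    hard_t = rng.permutation(["Car", "Pedestrian"] * (n_blocks // 2))
    events = [
        (str((easy_t if i % 2 == 0 else hard_t)[i // 2]), i * segment_s + event_offset_s, event_s)
        for i in range(2 * n_blocks)
    ]
    cfg = SimulationConfig(seed=seed, lap_plan=plan, events=events, coupling=coupling)
    trace = simulate_workload_trace(cfg)
    veh = synthesize_vehicular(trace, cfg)
    n_epochs = int((veh.shape[1] / 10.0 - 2.0) / 0.125) + 1
    starts = 0.125 * np.arange(n_epochs)
    veh4 = vehicle.align_session_vehicular(veh, starts)
    labels = label_epochs(schedule_annotations(cfg), starts)
    mask = labels["event"].isin(["Car", "Pedestrian"]).to_numpy()
    y = (labels.loc[mask, "event"] == "Car").to_numpy().astype(int)
    groups = event_groups(labels, mask, cfg)
    scaled, _ = vehicle.minmax_normalize(veh4[mask], ranges=template.scaling_ranges)
    mi_feats = mi_fusion.project_features(scaled, template)
    return grouped_event_auc(mi_feats, y, groups, seed=seed, n_folds=n_folds)


def build_mi_features(
    veh_train: np.ndarray, eeg45_train: np.ndarray, veh_apply: np.ndarray,
    estimator: str = "histogram", bins: int = 16, k: int = 3,
) -> tuple[np.ndarray, mi_fusion.MITemplate]:
    """Scale on training rows, fit the MI template, project new vehicular rows."""
    veh_scaled, ranges = vehicle.minmax_normalize(veh_train)
    eeg_scaled, _ = vehicle.minmax_normalize(eeg45_train)
    template = mi_fusion.build_template(
        veh_scaled, eeg_scaled, estimator=estimator, bins=bins, k=k,
        scaling_ranges=ranges,
    )
    veh_apply_scaled, _ = vehicle.minmax_normalize(veh_apply, ranges=ranges)
    return mi_fusion.project_features(veh_apply_scaled, template), template
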