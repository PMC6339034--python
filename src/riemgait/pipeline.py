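"""End-to-end orchestration: sequences -> cycles -> features -> CV report.

Within cross-validation the mean motion sequence is, by default, computed
from the training folds only, because the geodesic features of every
sample are measured against it — computing it on all data would leak test
information into the features.  ``leaky_mean=True`` reproduces the
all-data alternative for comparison.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .features import (
    compute_mean_sequence,
    geometric_features,
    temporal_hierarchy,
)
from .kernel_metric import (
    CVReport,
    build_query_columns,
    classify_knn,
    kernel_columns,
    train_metric,
)
from .manifold import PoseSequence, to_pose_sequence
from .preprocess import align_cycles, extract_cycles
from .skeleton_io import JointTrajectorySequence, SkeletonDefinition


def sequences_to_cycles(
    sequences: list[JointTrajectorySequence],
    skeleton: SkeletonDefinition,
    config: PipelineConfig,
) -> tuple[list[PoseSequence], list[str]]:
    """One aligned sample cycle per input sequence (the first complete one)."""
    cycles, labels = [], []
    for seq in sequences:
        pose = to_pose_sequence(seq, skeleton)
        try:
            cset = extract_cycles(
                pose, seq, skeleton.joint_names,
                config.preprocess.reference_joint,
                min_lag=config.preprocess.min_period)
        except Exception as exc:
            raise type(exc)(f"{seq.sequence_id}: {exc}") from exc
        cycles.append(cset.cycles[0])
        labels.append(seq.subject_label)
    aligned = align_cycles(cycles, config.preprocess.target_frames)
    return aligned, labels


def cycle_features(
    aligned_cycles: list[PoseSequence],
    config: PipelineConfig,
    train_idx: np.ndarray | None = None,
):
    """Spatial G(s) and temporal C(s) descriptors for every cycle.

    The mean sequence is computed over ``train_idx`` cycles (all cycles if
    None); features of every cycle are measured against that mean.
    """
    idx = (np.arange(len(aligned_cycles)) if train_idx is None
           else np.asarray(train_idx))
    mean_seq = compute_mean_sequence([aligned_cycles[i] for i in idx])
    spatial, temporal = [], []
    for cyc in aligned_cycles:
        g = geometric_features(cyc, mean_seq)
        c = temporal_hierarchy(
            g, scheme=config.hierarchy.scheme,
            window_length=config.hierarchy.window_length,
            n_windows=config.hierarchy.n_windows)
        spatial.append(g.flattened)
        temporal.append(c.flattened)
    return np.stack(spatial), np.stack(temporal), mean_seq


def cross_validate_cycles(
    aligned_cycles: list[PoseSequence],
    labels,
    config: PipelineConfig,
    mode: str = "fused",
    leaky_mean: bool = False,
    n_repeats: int | None = None,
    seed: int | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV with per-fold mean-sequence fitting."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    folds = config.cv.folds
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds")
    repeats = n_repeats if n_repeats is not None else config.cv.repeats
    base_seed = seed if seed is not None else config.cv.seed

    if leaky_mean:
        X_s_all, X_t_all, _ = cycle_features(aligned_cycles, config)

    class_order = list(classes)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_accs: list[list[float]] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=base_seed + rep)
        rep_accs = []
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            if leaky_mean:
                X_s, X_t = X_s_all, X_t_all
            else:
                X_s, X_t, _ = cycle_features(aligned_cycles, config, train_idx)
            cols, delta, beta = kernel_columns(
                X_s[train_idx], X_t[train_idx], mode)
            cfg = type(config.metric)(**{**config.metric.__dict__})
            if cfg.p is not None:
                cfg.p = min(cfg.p, cols.shape[1])
            model = train_metric(cols, y[train_idx], cfg)
            q = build_query_columns(
                X_s[train_idx], X_t[train_idx],
                X_s[test_idx], X_t[test_idx], delta, beta, mode)
            preds = classify_knn(model, q)
            rep_accs.append(float(np.mean(preds == y[test_idx])))
            for t, pr in zip(y[test_idx], preds):
                confusion[class_order.index(t), class_order.index(pr)] += 1
        fold_accs.append(rep_accs)
    return CVReport(mode=mode, fold_accuracies=fold_accs,
                    confusion=confusion, class_order=class_order)


def report_to_dict(report: CVReport) -> dict:
    return {
        "mode": report.mode,
        "mean_accuracy": report.mean_accuracy,
        "mean_of_repeat_means": report.mean_of_repeat_means,
        "std_accuracy": report.std_accuracy,
        "per_repeat_means": report.per_repeat_means,
        "fold_accuracies": report.fold_accuracies,
        "confusion": None if report.confusion is None
        else report.confusion.tolist(),
        "class_order": [str(c) for c in (report.class_order or [])],
    }
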