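"""Synthetic periodic locomotion with subject-specific style.

Each subject is a set of per-joint oscillation amplitudes, phases and
second-harmonic weights (the "style"); frames are produced by driving the
joint angles through a forward-kinematic chain with the subject's bone
lengths plus a forward root translation.  Within-subject trial noise
jitters the angles per frame.  The generator is the ground-truth test bed
for every pipeline stage: the subject signal can be dialled up
(between-subject spread), destroyed (spread = 0), or confined to bone
lengths only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import JointTrajectorySequence, SkeletonDefinition

# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

_TOY_JOINTS = [
    ("pelvis", None, (0.0, 0.0, 0.0), 0.0),
    ("spine", "pelvis", (0.0, 1.0, 0.0), 0.5),
    ("head", "spine", (0.0, 1.0, 0.0), 0.3),
    ("l_hip", "pelvis", (-1.0, -0.2, 0.0), 0.15),
    ("l_knee", "l_hip", (0.0, -1.0, 0.0), 0.45),
    ("l_ankle", "l_knee", (0.0, -1.0, 0.0), 0.45),
    ("r_hip", "pelvis", (1.0, -0.2, 0.0), 0.15),
    ("r_knee", "r_hip", (0.0, -1.0, 0.0), 0.45),
    ("r_ankle", "r_knee", (0.0, -1.0, 0.0), 0.45),
]

_CMU_LIKE_JOINTS = [
    ("pelvis", None, (0.0, 0.0, 0.0), 0.0),
    ("spine", "pelvis", (0.0, 1.0, 0.0), 0.25),
    ("chest", "spine", (0.0, 1.0, 0.0), 0.25),
    ("neck", "chest", (0.0, 1.0, 0.0), 0.12),
    ("head", "neck", (0.0, 1.0, 0.0), 0.15),
    ("l_shoulder", "chest", (-1.0, 0.1, 0.0), 0.2),
    ("l_elbow", "l_shoulder", (0.0, -1.0, 0.0), 0.3),
    ("l_wrist", "l_elbow", (0.0, -1.0, 0.0), 0.27),
    ("r_shoulder", "chest", (1.0, 0.1, 0.0), 0.2),
    ("r_elbow", "r_shoulder", (0.0, -1.0, 0.0), 0.3),
    ("r_wrist", "r_elbow", (0.0, -1.0, 0.0), 0.27),
    ("l_hip", "pelvis", (-1.0, -0.2, 0.0), 0.12),
    ("l_knee", "l_hip", (0.0, -1.0, 0.0), 0.45),
    ("l_ankle", "l_knee", (0.0, -1.0, 0.0), 0.45),
    ("l_toe", "l_ankle", (0.0, -0.2, 1.0), 0.18),
    ("r_hip", "pelvis", (1.0, -0.2, 0.0), 0.12),
    ("r_knee", "r_hip", (0.0, -1.0, 0.0), 0.45),
    ("r_ankle", "r_knee", (0.0, -1.0, 0.0), 0.45),
    ("r_toe", "r_ankle", (0.0, -0.2, 1.0), 0.18),
]

# template oscillation (amplitude rad, phase rad, 2nd-harmonic weight)
_TEMPLATE_OSC = {
    "spine": (0.06, 0.0, 0.02),
    "head": (0.03, 1.2, 0.01),
    "chest": (0.05, 0.3, 0.02),
    "neck": (0.03, 0.9, 0.01),
    "l_shoulder": (0.25, np.pi, 0.05),
    "l_elbow": (0.20, np.pi + 0.4, 0.04),
    "l_wrist": (0.10, np.pi + 0.8, 0.02),
    "r_shoulder": (0.25, 0.0, 0.05),
    "r_elbow": (0.20, 0.4, 0.04),
    "r_wrist": (0.10, 0.8, 0.02),
    "l_hip": (0.45, 0.0, 0.10),
    "l_knee": (0.55, 1.0, 0.18),
    "l_ankle": (0.25, 2.0, 0.08),
    "l_toe": (0.15, 2.4, 0.05),
    "r_hip": (0.45, np.pi, 0.10),
    "r_knee": (0.55, np.pi + 1.0, 0.18),
    "r_ankle": (0.25, np.pi + 2.0, 0.08),
    "r_toe": (0.15, np.pi + 2.4, 0.05),
}


def _build_skeleton(table) -> tuple[SkeletonDefinition, np.ndarray, np.ndarray]:
    names = [row[0] for row in table]
    parents = [None if row[1] is None else names.index(row[1]) for row in table]
    rest = np.array([row[2] for row in table], dtype=float)
    norms = np.linalg.norm(rest, axis=1)
    rest[1:] /= norms[1:, None]
    lengths = np.array([row[3] for row in table], dtype=float)
    return SkeletonDefinition(tuple(names), tuple(parents)), rest, lengths


def toy_skeleton() -> SkeletonDefinition:
    """9 joints / 8 bones; fast unit-test chain with ankles."""
    return _build_skeleton(_TOY_JOINTS)[0]


def cmu_like_skeleton() -> SkeletonDefinition:
    """19 joints / 18 bones echoing a full-body mocap skeleton."""
    return _build_skeleton(_CMU_LIKE_JOINTS)[0]


def _skeleton_table(name: str):
    if name == "toy":
        return _TOY_JOINTS
    if name == "cmu_like":
        return _CMU_LIKE_JOINTS
    raise ValueError(f"unknown skeleton '{name}'")


# ---------------------------------------------------------------------------
# Styles and configuration
# ---------------------------------------------------------------------------

@dataclass
class SubjectStyle:
    """Per-joint oscillation parameters plus bone lengths for one subject."""

    amplitudes: np.ndarray        # (J,) radians, >= 0
    phases: np.ndarray            # (J,) radians
    harmonic_weights: np.ndarray  # (J,) second-harmonic amplitude, radians
    harmonic_phases: np.ndarray   # (J,) radians
    stride_period: int            # frames
    bone_lengths: np.ndarray      # (J,) length units (root entry unused)
    phase_warp: float = 0.5       # swing/stance asymmetry in [0, 0.95)
    label: str = "subject"

    def __post_init__(self):
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.stride_period < 10:
            raise ValueError("stride period must be at least 10 frames")
        if np.any(self.bone_lengths[1:] <= 0):
            raise ValueError("bone lengths must be positive")


@dataclass
class GaitSimConfig:
    n_subjects: int = 7
    cycles_per_subject: int = 20
    frames_per_cycle: int = 30
    cycles_per_sequence: int = 3
    frame_rate: float = 60.0
    between_subject_spread: float = 0.35
    within_subject_noise: float = 0.003
    bone_length_spread: float = 0.0
    skeleton: str = "toy"          # {toy, cmu_like}
    forward_speed: float = 1.2     # length units / s
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.cycles_per_subject,
               self.frames_per_cycle, self.cycles_per_sequence) < 1:
            raise ValueError("all counts must be >= 1")
        if self.within_subject_noise < 0 or self.between_subject_spread < 0:
            raise ValueError("spread and noise must be >= 0")


def sample_subjects(config: GaitSimConfig) -> list[SubjectStyle]:
    """Draw subject styles around the shared template, seeded and deterministic."""
    rng = np.random.default_rng(config.seed)
    skel, _, lengths = _build_skeleton(_skeleton_table(config.skeleton))
    names = skel.joint_names
    amp0 = np.array([_TEMPLATE_OSC.get(n, (0.0, 0.0, 0.0))[0] for n in names])
    ph0 = np.array([_TEMPLATE_OSC.get(n, (0.0, 0.0, 0.0))[1] for n in names])
    h0 = np.array([_TEMPLATE_OSC.get(n, (0.0, 0.0, 0.0))[2] for n in names])
    styles = []
    spread = config.between_subject_spread
    for s in range(config.n_subjects):
        amps = np.clip(amp0 * (1.0 + spread * rng.standard_normal(len(names))),
                       0.0, None)
        phases = ph0 + 0.8 * spread * rng.standard_normal(len(names))
        harm = np.clip(h0 * (1.0 + spread * rng.standard_normal(len(names))),
                       0.0, None)
        hph = 2.0 * ph0 + 0.8 * spread * rng.standard_normal(len(names))
        bl = lengths.copy()
        if config.bone_length_spread > 0:
            bl = np.clip(
                bl * (1.0 + config.bone_length_spread
                      * rng.standard_normal(len(names))), 0.05, None)
        warp = float(np.clip(0.5 + 0.3 * spread * rng.standard_normal(),
                             0.0, 0.9))
        styles.append(SubjectStyle(
            amplitudes=amps, phases=phases, harmonic_weights=harm,
            harmonic_phases=hph, stride_period=config.frames_per_cycle,
            bone_lengths=bl, phase_warp=warp, label=f"subject{s:02d}"))
    return styles


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _rot_x(theta: np.ndarray) -> np.ndarray:
    """(T,) angles -> (T, 3, 3) rotations about the lateral (x) axis."""
    c, s = np.cos(theta), np.sin(theta)
    out = np.zeros(theta.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def simulate_sequence(
    style: SubjectStyle,
    n_cycles: int,
    config: GaitSimConfig,
    rng: np.random.Generator | None = None,
    sequence_id: str = "sim",
) -> JointTrajectorySequence:
    """Drive the kinematic chain with the style's joint-angle oscillations.

    theta_j(t) = a_j sin(P(t) + phi_j) + h_j sin(2 P(t) + psi_j) + noise,
    with a warped phase P(t) = wt + warp*sin(wt) (w = 2 pi / T) so every
    stride has a fast (swing) and a slow (stance) half — that asymmetry is
    what puts the fundamental period into a distal joint's speed signal.
    All rotations are sagittal (about x); the root advances along z with a
    slight vertical bob.  Length = n_cycles * frames_per_cycle.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    skel, rest, _ = _build_skeleton(_skeleton_table(config.skeleton))
    n_frames = n_cycles * config.frames_per_cycle
    t = np.arange(n_frames, dtype=float)
    T = float(style.stride_period)
    w = 2.0 * np.pi / T
    base = w * t + style.phase_warp * np.sin(w * t)
    theta = (style.amplitudes[None, :] * np.sin(base[:, None] + style.phases[None, :])
             + style.harmonic_weights[None, :]
             * np.sin(2 * base[:, None] + style.harmonic_phases[None, :]))
    if config.within_subject_noise > 0:
        theta = theta + config.within_subject_noise * rng.standard_normal(theta.shape)

    dt = 1.0 / config.frame_rate
    root_pos = np.zeros((n_frames, 3))
    root_pos[:, 2] = config.forward_speed * t * dt
    root_pos[:, 1] = 1.0 + 0.02 * np.sin(2 * w * t)  # double-support bob

    positions = np.zeros((n_frames, skel.n_joints, 3))
    world_rot = np.zeros((skel.n_joints, n_frames, 3, 3))
    root = skel.root
    positions[:, root] = root_pos
    world_rot[root] = _rot_x(theta[:, root])
    order = sorted(range(skel.n_joints),
                   key=lambda j: _depth(skel.parent_index, j))
    for j in order:
        p = skel.parent_index[j]
        if p is None:
            continue
        local = _rot_x(theta[:, j])
        world_rot[j] = world_rot[p] @ local
        offset = style.bone_lengths[j] * rest[j]
        positions[:, j] = positions[:, p] + (world_rot[j] @ offset)
    return JointTrajectorySequence(
        positions=positions, frame_rate=config.frame_rate,
        subject_label=style.label, sequence_id=sequence_id)


def _depth(parents, j: int) -> int:
    d = 0
    while parents[j] is not None:
        j = parents[j]
        d += 1
    return d


def generate_dataset(
    config: GaitSimConfig,
) -> tuple[list[JointTrajectorySequence], SkeletonDefinition]:
    """n_subjects x cycles_per_subject labeled sequences plus the skeleton.

    Each sequence holds ``cycles_per_sequence`` strides so the cycle
    extractor always sees at least two full periods.
    """
    skel = _build_skeleton(_skeleton_table(config.skeleton))[0]
    styles = sample_subjects(config)
    rng = np.random.default_rng(config.seed + 1)
    sequences = []
    for style in styles:
        for c in range(config.cycles_per_subject):
            seq = simulate_sequence(
                style, config.cycles_per_sequence, config, rng=rng,
                sequence_id=f"{style.label}_seq{c:03d}")
            sequences.append(seq)
    return sequences, skel


def permuted_labels(labels, seed: int = 0) -> list[str]:
    """Label permutation control: destroys the subject signal."""
    rng = np.random.default_rng(seed)
    labels = list(labels)
    perm = rng.permutation(len(labels))
    return [labels[i] for i in perm]
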