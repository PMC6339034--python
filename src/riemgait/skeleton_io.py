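"""Plain-text I/O for skeletons and joint-position sequences.

Supported formats
-----------------
* Skeleton definition: JSON ``{"joints": [names...], "parents": [idx|null...]}``.
* Position CSV (wide): header ``frame,<joint>_x,<joint>_y,<joint>_z,...``,
  one row per frame, 0-based frame index in the first column.  A sidecar
  JSON (``<stem>.meta.json``) carries ``{"subject": ..., "frame_rate": ...}``.
* BVH: a minimal subset — HIERARCHY/MOTION, channels restricted to the six
  standard position/rotation channels, rotations applied in the listed
  order, right-handed y-up convention.  Anything else raises.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, UnsupportedFormatError


@dataclass(frozen=True)
class SkeletonDefinition:
    """A tree-structured kinematic chain over named joints."""

    joint_names: tuple[str, ...]
    parent_index: tuple[int | None, ...]

    def __post_init__(self):
        object.__setattr__(self, "joint_names", tuple(self.joint_names))
        object.__setattr__(self, "parent_index", tuple(self.parent_index))
        names, parents = self.joint_names, self.parent_index
        if len(names) != len(parents):
            raise ValueError("joint_names and parent_index length mismatch")
        if len(set(names)) != len(names):
            raise ValueError("duplicate joint names")
        roots = [i for i, p in enumerate(parents) if p is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        # every non-root must reach the root without cycles
        for i, p in enumerate(parents):
            seen = set()
            j = i
            while parents[j] is not None:
                if j in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(j)
                j = parents[j]
                if not 0 <= j < len(names):
                    raise ValueError(f"parent index out of range at joint {i}")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def root(self) -> int:
        return self.parent_index.index(None)

    @property
    def bone_indices(self) -> list[tuple[int, int]]:
        """(parent, child) joint-index pairs, ordered by child index."""
        return [(p, c) for c, p in enumerate(self.parent_index) if p is not None]

    @property
    def bones(self) -> list[tuple[str, str]]:
        return [(self.joint_names[p], self.joint_names[c])
                for p, c in self.bone_indices]

    @property
    def n_bones(self) -> int:
        return self.n_joints - 1

    def to_json(self, path: str | Path) -> None:
        doc = {"joints": list(self.joint_names),
               "parents": [p for p in self.parent_index]}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SkeletonDefinition":
        doc = json.loads(Path(path).read_text())
        if "joints" not in doc or "parents" not in doc:
            raise FormatError("skeleton JSON must contain 'joints' and 'parents'")
        return cls(tuple(doc["joints"]), tuple(doc["parents"]))


@dataclass
class JointTrajectorySequence:
    """F x J x 3 joint positions with frame rate and labeling metadata."""

    positions: np.ndarray
    frame_rate: float
    subject_label: str = "unknown"
    sequence_id: str = "sequence"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 3:
            raise ValueError("positions must have shape (F, J, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_position_csv(
    seq: JointTrajectorySequence,
    skeleton: SkeletonDefinition,
    path: str | Path,
) -> None:
    """Write the wide-layout CSV plus the metadata sidecar."""
    path = Path(path)
    cols = {"frame": np.arange(seq.n_frames)}
    for j, name in enumerate(skeleton.joint_names):
        for a, axis in enumerate("xyz"):
            cols[f"{name}_{axis}"] = seq.positions[:, j, a]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps(
        {"subject": seq.subject_label, "frame_rate": seq.frame_rate,
         "sequence_id": seq.sequence_id}))


def read_position_csv(
    path: str | Path, skeleton: SkeletonDefinition
) -> JointTrajectorySequence:
    """Read the wide-layout CSV; validates the header against the skeleton."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # delegate row/col detail below when possible
        raise ParseError(f"{path}: {exc}") from exc
    expected = ["frame"] + [f"{n}_{a}" for n in skeleton.joint_names for a in "xyz"]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    data = df[expected[1:]]
    arr = data.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for r in range(len(df)):
            for v in data.iloc[r]:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value at data row {r}") from None
        raise ParseError(f"{path}: non-numeric data")
    if not np.all(np.isfinite(arr)):
        r = int(np.argwhere(~np.isfinite(arr))[0][0])
        raise ParseError(f"{path}: non-finite value at data row {r}")
    positions = arr.reshape(len(df), skeleton.n_joints, 3)

    meta_path = _sidecar_path(path)
    subject, frame_rate, seq_id = "unknown", 120.0, path.stem
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        subject = str(meta.get("subject", subject))
        frame_rate = float(meta.get("frame_rate", frame_rate))
        seq_id = str(meta.get("sequence_id", seq_id))
    return JointTrajectorySequence(positions, frame_rate, subject, seq_id)


# ---------------------------------------------------------------------------
# BVH subset
# ---------------------------------------------------------------------------

_POSITION_CHANNELS = {"Xposition": 0, "Yposition": 1, "Zposition": 2}
_ROTATION_CHANNELS = {"Xrotation": 0, "Yrotation": 1, "Zrotation": 2}


def _rot(axis: int, degrees: float) -> np.ndarray:
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class _BvhNode:
    name: str
    parent: int | None
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    channels: list[str] = field(default_factory=list)
    channel_slice: slice = field(default_factory=lambda: slice(0, 0))


def read_bvh(path: str | Path) -> tuple[SkeletonDefinition, JointTrajectorySequence]:
    """Parse the supported BVH subset and run forward kinematics.

    Returns world joint positions per frame; ``frame_rate = 1/FrameTime``.
    End Sites are ignored (they carry no degrees of freedom).
    """
    path = Path(path)
    text = path.read_text()
    tokens = re.findall(r"[^\s]+", text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise FormatError(f"{path}: unexpected end of file")
        tok = tokens[pos]
        pos += 1
        if expected is not None and tok.upper() != expected.upper():
            raise FormatError(f"{path}: expected '{expected}', got '{tok}'")
        return tok

    take("HIERARCHY")
    nodes: list[_BvhNode] = []
    n_channels = 0

    def parse_joint(parent: int | None):
        nonlocal n_channels
        kw = take()
        if kw.upper() not in {"ROOT", "JOINT"}:
            raise FormatError(f"{path}: expected ROOT/JOINT, got '{kw}'")
        name = take()
        node = _BvhNode(name=name, parent=parent)
        idx = len(nodes)
        nodes.append(node)
        take("{")
        while True:
            tok = peek()
            if tok is None:
                raise FormatError(f"{path}: unterminated joint block")
            if tok == "}":
                take()
                return
            if tok.upper() == "OFFSET":
                take()
                node.offset = np.array([float(take()) for _ in range(3)])
            elif tok.upper() == "CHANNELS":
                take()
                n = int(take())
                chans = [take() for _ in range(n)]
                for ch in chans:
                    if ch not in _POSITION_CHANNELS and ch not in _ROTATION_CHANNELS:
                        raise UnsupportedFormatError(
                            f"{path}: unsupported channel '{ch}'")
                node.channels = chans
                node.channel_slice = slice(n_channels, n_channels + n)
                n_channels += n
            elif tok.upper() in {"JOINT", "ROOT"}:
                parse_joint(idx)
            elif tok.upper() == "END":
                take()  # End
                take()  # Site
                take("{")
                take("OFFSET")
                for _ in range(3):
                    take()
                take("}")
            else:
                raise UnsupportedFormatError(f"{path}: unexpected token '{tok}'")

    parse_joint(None)
    take("MOTION")
    take("Frames:")
    n_frames = int(take())
    take("Frame")
    take("Time:")
    frame_time = float(take())
    values = tokens[pos:]
    if len(values) != n_frames * n_channels:
        raise FormatError(
            f"{path}: MOTION has {len(values)} values, expected "
            f"{n_frames} frames x {n_channels} channels")
    try:
        motion = np.array([float(v) for v in values]).reshape(n_frames, n_channels)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric motion value") from exc

    skeleton = SkeletonDefinition(
        tuple(n.name for n in nodes), tuple(n.parent for n in nodes))

    positions = np.zeros((n_frames, len(nodes), 3))
    for f in range(n_frames):
        world_rot: list[np.ndarray] = [np.eye(3)] * len(nodes)
        for i, node in enumerate(nodes):
            vals = motion[f, node.channel_slice]
            trans = np.zeros(3)
            local = np.eye(3)
            for ch, val in zip(node.channels, vals):
                if ch in _POSITION_CHANNELS:
                    trans[_POSITION_CHANNELS[ch]] = val
                else:
                    local = local @ _rot(_ROTATION_CHANNELS[ch], val)
            if node.parent is None:
                positions[f, i] = node.offset + trans
                world_rot[i] = local
            else:
                p = node.parent
                positions[f, i] = positions[f, p] + world_rot[p] @ (node.offset + trans)
                world_rot[i] = world_rot[p] @ local
    seq = JointTrajectorySequence(
        positions, frame_rate=1.0 / frame_time, sequence_id=path.stem)
    return skeleton, seq
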