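"""Cycle segmentation and alignment of locomotion sequences.

Cycles are found from the speed autocorrelation of a distal reference joint
(ankle/toe): the profile of a periodic gait peaks at lags equal to the
stride period.  Cut points are placed at successive speed minima spaced
about one period apart.  Cycles are then brought to a common length on the
manifold: each cycle is warped to a medoid reference with dynamic time
warping under a per-frame geodesic cost, duplicated frames introduced by
the warp are repaired by geodesic interpolation, and the result is
uniformly resampled to the target length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, NoPeriodicityError, TooShortError
from .manifold import PoseSequence, geodesic_distance_many, log_map, exp_map
from .skeleton_io import JointTrajectorySequence


@dataclass
class AutocorrelationProfile:
    """R(lag) for lag = 0..max_lag over a joint-speed series."""

    coefficients: np.ndarray
    source_joint: str
    n_speed_samples: int

    @property
    def max_lag(self) -> int:
        return len(self.coefficients) - 1


@dataclass
class CycleSet:
    """Locomotion cycles cut from one source sequence."""

    cycles: list[PoseSequence]
    boundaries: list[tuple[int, int]]
    detected_period: int

    def __post_init__(self):
        prev_end = 0
        for (a, b), cyc in zip(self.boundaries, self.cycles):
            if not a < b or a < prev_end:
                raise ValueError("cycle boundaries must be ordered and disjoint")
            prev_end = b  # consecutive cycles may share the cut frame
            if abs((b - a) - self.detected_period) > 0.2 * self.detected_period:
                raise ValueError("cycle length departs >20% from detected period")
            if cyc.n_frames != b - a:
                raise ValueError("cycle length does not match its boundary")


def joint_speed(seq: JointTrajectorySequence, joint_names, joint: str) -> np.ndarray:
    """Per-step speed of one joint: ||pos[i+1]-pos[i]|| * frame_rate (F-1 values)."""
    names = list(joint_names)
    if joint not in names:
        raise ValueError(f"unknown joint '{joint}'")
    j = names.index(joint)
    steps = np.diff(seq.positions[:, j, :], axis=0)
    return np.linalg.norm(steps, axis=-1) * seq.frame_rate


def speed_autocorrelation(
    speeds: np.ndarray, max_lag: int, source_joint: str = ""
) -> AutocorrelationProfile:
    """Raw (uncentered) autocorrelation: R(d) = mean over i of v_i * v_{i+d}."""
    v = np.asarray(speeds, dtype=float)
    n = len(v)
    if max_lag > n - 2:
        raise ValueError(f"max_lag={max_lag} too large for {n} speed samples")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    coeffs = np.array([float(v[: n - d] @ v[d:]) / (n - d) for d in range(max_lag + 1)])
    return AutocorrelationProfile(coeffs, source_joint, n)


def detect_period(profile: AutocorrelationProfile, min_lag: int = 5) -> int:
    """Stride period from the peaks of the speed autocorrelation profile.

    Candidate peaks (strict local maxima at lag >= min_lag, above the
    profile median) are ranked by range-normalized height weighted by the
    fraction of products actually averaged at that lag — long lags average
    few products and produce spurious high peaks otherwise.  The winner is
    the best-scoring peak, demoted to a divisor-lag peak whenever one of
    nearly equal score exists (so a 2T peak never masks the fundamental).
    """
    return _rank_periods(profile, min_lag)[0]


def _rank_periods(profile: AutocorrelationProfile, min_lag: int = 5) -> list[int]:
    """Candidate period lags, best first; raises if no usable peak exists."""
    r = profile.coefficients
    if len(r) < min_lag + 2:
        raise NoPeriodicityError("autocorrelation profile too short")
    interior = np.arange(1, len(r) - 1)
    is_peak = (r[interior] > r[interior - 1]) & (r[interior] > r[interior + 1])
    lags = interior[is_peak]
    lags = lags[lags >= min_lag]
    lags = lags[r[lags] > np.median(r)]
    if len(lags) == 0:
        raise NoPeriodicityError("no local maximum in speed autocorrelation")
    tail = r[min_lag:]
    lo, hi = float(tail.min()), float(tail.max())
    if hi - lo <= 1e-15:
        raise NoPeriodicityError("flat autocorrelation profile")
    height = (r[lags] - lo) / (hi - lo)
    # damp long lags: they average few products and peak spuriously
    score = height * (profile.n_speed_samples - lags) / profile.n_speed_samples
    order = np.argsort(score)[::-1]
    ranked = [int(lags[i]) for i in order]
    best_s = float(score[order[0]])
    for k in (2, 3):
        cand = ranked[0] / k
        near = np.abs(lags - cand) <= max(1, int(round(0.15 * cand)))
        good = near & (score >= 0.95 * best_s)
        if np.any(good):
            demoted = int(lags[good][0])
            ranked.remove(demoted)
            ranked.insert(0, demoted)
            break
    return ranked


def _local_minimum_near(speeds: np.ndarray, center: int, radius: int) -> int | None:
    lo = max(0, center - radius)
    hi = min(len(speeds), center + radius + 1)
    if hi - lo < 1:
        return None
    return int(lo + np.argmin(speeds[lo:hi]))


def extract_cycles(
    pose_seq: PoseSequence,
    raw_seq: JointTrajectorySequence,
    joint_names,
    reference_joint: str,
    min_lag: int = 5,
    max_lag: int | None = None,
) -> CycleSet:
    """Cut the pose sequence at successive speed minima ~one period apart."""
    speeds = joint_speed(raw_seq, joint_names, reference_joint)
    if max_lag is None:
        max_lag = min(len(speeds) - 2, int(0.5 * len(speeds)))
    profile = speed_autocorrelation(speeds, max_lag, reference_joint)
    candidates = _rank_periods(profile, min_lag=min_lag)

    # a correct period places every cut at the same gait phase, so the poses
    # at the cut frames should nearly coincide; use that to arbitrate among
    # autocorrelation peak candidates
    scored = []
    for period in candidates[:5]:
        if pose_seq.n_frames < 2 * period:
            continue
        cuts = _place_cuts(speeds, period)
        if len(cuts) < 2:
            continue
        starts = pose_seq.directions[np.asarray(cuts[:-1])]
        nexts = pose_seq.directions[np.asarray(cuts[1:])]
        mismatch = float(geodesic_distance_many(starts, nexts).mean())
        scored.append((mismatch, period, cuts))
    best = None
    if scored:
        floor = min(m for m, _, _ in scored)
        # multiples of the true period are phase-consistent too; among
        # near-minimal candidates take the shortest period
        best = min((p, m, c) for m, p, c in scored if m <= floor + 0.1)
        best = (best[1], best[0], best[2])
    if best is None:
        if pose_seq.n_frames < 2 * candidates[0]:
            raise TooShortError(
                f"sequence has {pose_seq.n_frames} frames < 2 periods "
                f"({2 * candidates[0]})")
        raise TooShortError("could not place two cycle boundaries")
    _, period, cuts = best

    # cut spacing is the realized stride length; re-estimate the period from
    # it and drop cycles whose length drifted beyond 20% of that estimate
    spacings = np.diff(cuts)
    period = int(round(float(np.median(spacings))))
    boundaries = [(a, b) for a, b in zip(cuts[:-1], cuts[1:])
                  if abs((b - a) - period) <= 0.2 * period]
    if not boundaries:
        # very jittery cuts: anchor the period on the most typical spacing
        period = int(spacings[np.argmin(np.abs(spacings - np.median(spacings)))])
        boundaries = [(a, b) for a, b in zip(cuts[:-1], cuts[1:])
                      if abs((b - a) - period) <= 0.2 * period]
    if not boundaries:
        raise TooShortError("no cycle length consistent with the period")
    cycles = [pose_seq.slice(a, b) for a, b in boundaries]
    return CycleSet(cycles=cycles, boundaries=boundaries, detected_period=period)


def _place_cuts(speeds: np.ndarray, period: int) -> list[int]:
    radius = max(1, int(round(0.2 * period)))
    first = int(np.argmin(speeds[:period]))
    cuts = [first]
    while True:
        target = cuts[-1] + period
        if target + radius > len(speeds):
            break
        nxt = _local_minimum_near(speeds, target, radius)
        if nxt is None or nxt <= cuts[-1]:
            break
        cuts.append(nxt)
    return cuts


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def resample_poses(directions: np.ndarray, target_f: int) -> np.ndarray:
    """Uniformly resample an (F, B, 3) pose trajectory to target_f frames.

    Fractional frames are filled by per-bone geodesic interpolation between
    the two neighbouring poses, so outputs stay on the sphere.
    """
    f = directions.shape[0]
    if f == target_f:
        return directions.copy()
    t = np.linspace(0.0, f - 1.0, target_f)
    return _sample_at(directions, t)


def _sample_at(directions: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Sample an (F, B, 3) trajectory at fractional frame times via slerp."""
    f = directions.shape[0]
    times = np.clip(np.asarray(times, dtype=float), 0.0, f - 1.0)
    i0 = np.minimum(times.astype(int), f - 2)
    frac = times - i0
    a = directions[i0]          # (T, B, 3)
    b = directions[i0 + 1]
    v = log_map(a, b)
    return exp_map(a, frac[:, None, None] * v)


def _pose_distance_per_frame(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Summed per-bone geodesic distance, frame by frame: (F,)."""
    return geodesic_distance_many(a, b).sum(axis=-1)


def _dtw_path(cost: np.ndarray) -> list[tuple[int, int]]:
    """Classic DTW with unit steps; returns the optimal path of index pairs."""
    n, m = cost.shape
    if n == 0 or m == 0:
        raise AlignmentError("empty sequence in DTW")
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            cands.append((acc[i - 1, j], i - 1, j))
        if j > 0:
            cands.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(cands)
        path.append((i, j))
    path.reverse()
    return path


def _warp_to_reference(cycle: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Warp a cycle onto the reference timeline (len(reference) frames).

    The DTW path gives, for every reference frame, the matched cycle
    frame(s); a fractional time map through the mean match is refined by
    projecting each reference pose onto the cycle's local geodesic segment
    (duplicated matches therefore become geodesic interpolants), made
    monotone, and the cycle is slerp-sampled along it.
    """
    fc, fr = cycle.shape[0], reference.shape[0]
    cost = np.zeros((fc, fr))
    for i in range(fc):
        cost[i] = geodesic_distance_many(cycle[i][None, :, :], reference).sum(axis=-1)
    path = _dtw_path(cost)

    sums = np.zeros(fr)
    counts = np.zeros(fr)
    for i, j in path:
        sums[j] += i
        counts[j] += 1
    tbar = sums / counts

    # sub-frame refinement: project the reference pose onto the geodesic
    # segment [cycle[a0], cycle[a0+1]] in the tangent space at cycle[a0]
    a0 = np.clip(np.floor(tbar).astype(int), 0, fc - 2)
    base = cycle[a0]                      # (fr, B, 3)
    v_next = log_map(base, cycle[a0 + 1])
    v_ref = log_map(base, reference)
    num = np.sum(v_ref * v_next, axis=(1, 2))
    den = np.sum(v_next * v_next, axis=(1, 2))
    u = np.clip(np.where(den > 1e-18, num / np.where(den > 1e-18, den, 1.0), 0.0),
                0.0, 1.0)
    raw = np.maximum.accumulate(a0 + u)
    # strictly increasing re-fit: keep rising anchors, pin the final frame to
    # the cycle end, and interpolate the rest (this spreads flat stretches,
    # so duplicated matches become genuine geodesic interpolants)
    anchors_b = [0]
    anchors_t = [min(float(raw[0]), fc - 1.0 - 1e-6)]
    for j in range(1, fr - 1):
        if anchors_t[-1] + 1e-9 < raw[j] < fc - 1.0 - 1e-9:
            anchors_b.append(j)
            anchors_t.append(float(raw[j]))
    anchors_b.append(fr - 1)
    anchors_t.append(fc - 1.0)
    times = np.interp(np.arange(fr), anchors_b, anchors_t)
    return _sample_at(cycle, times)


def align_cycles(
    cycles: list[PoseSequence], target_f: int
) -> list[PoseSequence]:
    """Bring all cycles to exactly ``target_f`` frames on the manifold.

    The reference is the medoid under summed per-frame, per-bone geodesic
    distance after uniform resampling; every cycle is DTW-warped to it and
    repaired/resampled geodesically.
    """
    if len(cycles) == 0:
        raise ValueError("align_cycles needs at least one cycle")
    for c in cycles:
        if c.n_frames < 4:
            raise ValueError("every cycle must have at least 4 frames")
    resampled = [resample_poses(c.directions, target_f) for c in cycles]
    if len(cycles) == 1:
        ref_idx = 0
    else:
        stack = np.stack(resampled)  # (S, F, B, 3)
        dist = np.zeros((len(cycles), len(cycles)))
        for i in range(len(cycles)):
            d = geodesic_distance_many(stack[i][None], stack).sum(axis=(1, 2))
            dist[i] = d
        ref_idx = int(np.argmin(dist.sum(axis=1)))
    reference = resampled[ref_idx]

    out = []
    for c, rs in zip(cycles, resampled):
        if c is cycles[ref_idx]:
            warped = reference
        else:
            warped = _warp_to_reference(c.directions, reference)
        out.append(PoseSequence(
            directions=warped,
            frame_rate=c.frame_rate,
            subject_label=c.subject_label,
            sequence_id=c.sequence_id + "#aligned",
            bone_names=list(c.bone_names),
        ))
    return out
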