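# riemgait

Individual recognition from 3D skeletal locomotion via Riemannian
spatio-temporal features.

A pose is represented as the tuple of unit bone-direction vectors, one
point on the 2-sphere per bone, so a motion sample lives on the product
manifold S² × … × S². The pipeline:

1. **Cycle extraction** — stride period from the speed autocorrelation of a
   distal joint (ankle/toe); cuts at successive speed minima.
2. **Alignment** — every cycle is warped to a medoid reference with dynamic
   time warping under a per-frame geodesic cost; duplicated frames are
   repaired by geodesic interpolation and the result is resampled on the
   manifold to a common length.
3. **Mean motion sequence** — per-frame, per-bone Karcher means over all
   aligned (training) cycles.
4. **Spatial features** — geodesic distances of each cycle to the mean
   sequence (an F × B matrix per sample).
5. **Temporal features** — a two-level hierarchy of covariance matrices of
   the per-frame feature vectors, upper triangles concatenated.
6. **Classification** — RBF kernels over both feature sets, fused by the
   Hadamard product; a low-rank metric learned by gradient descent on a
   large-margin nearest-neighbor loss (LDA-initialized); k-NN under the
   learned distance with repeated stratified cross-validation.

A seeded synthetic gait generator (forward kinematics driven by per-subject
oscillation styles) makes every stage testable without any dataset
download.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (geometry oracles,
hand-computed autocorrelation values, descriptor dimensions, gradient
finite-difference agreement, and a scaled end-to-end recognition experiment
on synthetic data: 7 subjects × 20 cycles, fused-feature CV accuracy
≥ 0.95 with label-permutation and bone-length-only controls at chance).

## CLI

```bash
# write a synthetic labeled dataset (position CSVs + skeleton + manifest)
riemgait simulate --out-dir data/ --seed 1

# extract aligned-cycle features (G and C descriptors + mean sequence)
riemgait features --data-dir data/ --out-dir feats/

# repeated stratified CV report for spatial / temporal / fused features
riemgait evaluate --data-dir data/ --out report.json --mode all

# train on the full dataset, then classify another directory
riemgait train --data-dir data/ --model model.json
riemgait predict --data-dir other/ --model model.json --out preds.json
```

All commands accept `--config config.yaml`; unknown keys are rejected.
Defaults follow the published protocol (`metric.mu = 0.2`,
`metric.lam = 0.1`, 40 epochs, gradient threshold 0.01, 150 target frames;
override `preprocess.target_frames` for lower frame rates). See
`riemgait.config` for the full key list. Within cross-validation the mean
sequence is fit on training folds only; `evaluate --leaky-mean` reproduces
the all-data alternative.

### File formats

- Skeleton: JSON `{"joints": [...], "parents": [index or null, ...]}`.
- Positions: wide CSV `frame,<joint>_x,<joint>_y,<joint>_z,...` with a
  `<stem>.meta.json` sidecar `{"subject": ..., "frame_rate": ...}`.
- BVH: minimal subset (HIERARCHY/MOTION, the six standard channels,
  rotations applied in listed order, right-handed y-up).

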