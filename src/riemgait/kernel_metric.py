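"""Kernel fusion and large-margin metric learning for gait descriptors.

Spatial and temporal feature vectors are mapped through RBF kernels whose
bandwidths are the mean pairwise training distances, fused by the Hadamard
(element-wise) product, and each training sample is represented by its
column of the fused kernel matrix.  A low-rank transform ``L`` of those
columns is then learned by gradient descent on a large-margin
nearest-neighbor loss: target neighbors (same class) are pulled together,
impostors (other classes inside the margin) are pushed out, and an
orthogonality penalty ``lambda * ||L^T L - I||_F`` keeps the embedding
coordinates independent.  Classification is k-NN under the learned
squared distance ``||L(k_i - k_j)||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateBandwidthError, NotTrainedError


@dataclass
class KernelMatrix:
    values: np.ndarray
    bandwidth: float
    feature_tag: str = "spatial"  # {spatial, temporal, fused}

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, i: int) -> np.ndarray:
        return self.values[:, i].copy()


@dataclass
class TrainConfig:
    mu: float = 0.2
    lam: float = 0.1
    zeta: float = 1.0
    p: int | None = None            # embedding dim; default = N (full rank)
    learning_rate: float = 1e-3
    max_epochs: int = 40
    grad_threshold: float = 0.01
    n_target_neighbors: int = 3
    k_classify: int = 3

    def validate(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.lam < 0 or self.zeta < 0:
            raise ValueError("lambda and zeta must be non-negative")


@dataclass
class MetricModel:
    """Learned transform plus everything needed to embed new samples."""

    L: np.ndarray
    config: TrainConfig
    train_columns: np.ndarray      # (N, d) rows = kernel feature vectors
    train_labels: np.ndarray
    loss_history: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.L.shape[0]


def estimate_bandwidth(feature_vectors: np.ndarray) -> float:
    """Mean Euclidean distance over all unordered distinct pairs."""
    x = np.asarray(feature_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    mean_d = float(pdist(x).mean())
    if mean_d <= 0.0:
        raise DegenerateBandwidthError("all feature vectors coincide")
    return mean_d


def rbf_kernel(
    feature_vectors: np.ndarray,
    bandwidth: float,
    feature_tag: str = "spatial",
) -> KernelMatrix:
    """k_ij = exp(-||x_i - x_j||^2 / (2 * bandwidth^2))."""
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(feature_vectors, dtype=float)
    sq = squareform(pdist(x, metric="sqeuclidean"))
    values = np.exp(-sq / (2.0 * bandwidth**2))
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(values=values, bandwidth=bandwidth, feature_tag=feature_tag)


def rbf_cross(
    queries: np.ndarray, train: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Out-of-sample kernel block: (n_query, n_train)."""
    sq = cdist(np.asarray(queries, float), np.asarray(train, float),
               metric="sqeuclidean")
    return np.exp(-sq / (2.0 * bandwidth**2))


def fuse_kernels(ks: KernelMatrix, kt: KernelMatrix) -> KernelMatrix:
    """Hadamard product; PSD by the Schur product theorem."""
    if ks.n != kt.n:
        raise ValueError(f"kernel sizes differ: {ks.n} vs {kt.n}")
    return KernelMatrix(values=ks.values * kt.values,
                        bandwidth=float("nan"), feature_tag="fused")


def learned_distance(L: np.ndarray, ki: np.ndarray, kj: np.ndarray) -> float:
    """Squared norm of the transformed difference, ||L(ki - kj)||^2."""
    ki = np.asarray(ki, float)
    kj = np.asarray(kj, float)
    if ki.shape != kj.shape or L.shape[1] != ki.shape[0]:
        raise ValueError("dimension mismatch in learned_distance")
    d = L @ (ki - kj)
    return float(d @ d)


# ---------------------------------------------------------------------------
# Loss / gradient
# ---------------------------------------------------------------------------

def _target_neighbors(columns: np.ndarray, labels: np.ndarray, k: int) -> list[np.ndarray]:
    """k nearest same-class neighbors per sample, fixed under Euclidean distance."""
    d = squareform(pdist(columns, metric="sqeuclidean"))
    targets = []
    for i in range(len(labels)):
        same = np.flatnonzero((labels == labels[i]) & (np.arange(len(labels)) != i))
        if len(same) < k:
            raise ValueError(
                f"class '{labels[i]}' has fewer than {k + 1} samples")
        order = same[np.argsort(d[i, same], kind="stable")]
        targets.append(order[:k])
    return targets


def _impostor_candidates(labels: np.ndarray) -> list[np.ndarray]:
    """All other-class indices per sample.

    Only samples inside the margin contribute to the hinge, so summing over
    all other-class candidates evaluates the exact loss; epoch-wise impostor
    pruning would be an optimization only.
    """
    return [np.flatnonzero(labels != labels[i]) for i in range(len(labels))]


def _sq_dists(Z: np.ndarray) -> np.ndarray:
    return squareform(pdist(Z, metric="sqeuclidean"))


def klmnn_loss(
    L: np.ndarray,
    columns: np.ndarray,
    labels: np.ndarray,
    targets: list[np.ndarray],
    impostors: list[np.ndarray],
    mu: float,
    lam: float,
    zeta: float,
) -> float:
    """Large-margin loss: mu*push + (1-mu)*pull + lam*||L^T L - I||_F."""
    _check_hyper(mu, lam, zeta)
    X = np.asarray(columns, float)
    D = _sq_dists(X @ L.T)
    pull = 0.0
    push = 0.0
    for i, (tg, im) in enumerate(zip(targets, impostors)):
        if len(tg) == 0:
            continue
        dt = D[i, tg]
        pull += float(dt.sum())
        if len(im):
            h = dt[:, None] - D[i, im][None, :] + zeta
            push += float(np.clip(h, 0.0, None).sum())
    a = L.T @ L - np.eye(L.shape[1])
    return mu * push + (1.0 - mu) * pull + lam * float(np.linalg.norm(a))


def klmnn_gradient(
    L: np.ndarray,
    columns: np.ndarray,
    labels: np.ndarray,
    targets: list[np.ndarray],
    impostors: list[np.ndarray],
    mu: float,
    lam: float,
    zeta: float,
) -> np.ndarray:
    """Exact gradient of :func:`klmnn_loss` with respect to ``L``.

    The hinge contributes only over active triplets (positive margin
    violation); the pull term over all target pairs.  Outer products are
    accumulated through a weighted Laplacian so the cost stays O(N^2 d).
    """
    _check_hyper(mu, lam, zeta)
    X = np.asarray(columns, float)
    n = X.shape[0]
    D = _sq_dists(X @ L.T)
    W = np.zeros((n, n))
    for i, (tg, im) in enumerate(zip(targets, impostors)):
        if len(tg) == 0:
            continue
        W[i, tg] += (1.0 - mu)
        if len(im):
            h = D[i, tg][:, None] - D[i, im][None, :] + zeta  # (k, m)
            active = h > 0
            W[i, tg] += mu * active.sum(axis=1)
            W[i, im] -= mu * active.sum(axis=0)
    # sum_ij W_ij (x_i - x_j)(x_i - x_j)^T via Laplacian form
    r = W.sum(axis=1)
    c = W.sum(axis=0)
    S = X.T @ (X * (r + c)[:, None]) - X.T @ W @ X - X.T @ W.T @ X
    grad = 2.0 * (L @ S)
    a = L.T @ L - np.eye(L.shape[1])
    na = float(np.linalg.norm(a))
    if na > 1e-15:
        grad += lam * 2.0 * (L @ a) / na
    return grad


def _check_hyper(mu: float, lam: float, zeta: float) -> None:
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if zeta < 0:
        raise ValueError("zeta must be non-negative")


# ---------------------------------------------------------------------------
# LDA initialization
# ---------------------------------------------------------------------------

def lda_init(columns: np.ndarray, labels: np.ndarray, p: int) -> np.ndarray:
    """Orthonormal p x d transform seeded with LDA discriminant directions.

    Rows 1..min(p, C-1) span the leading generalized eigenvectors of the
    between/within scatter pair; any remaining rows come from principal
    components of the (centered) feature matrix, orthonormalized against
    the LDA rows.
    """
    X = np.asarray(columns, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("lda_init needs at least two classes")
    n, d = X.shape
    if p > n and p > d:
        raise ValueError("p may not exceed the feature dimension")
    mu_all = X.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for cls in classes:
        xc = X[y == cls]
        mc = xc.mean(axis=0)
        diff = xc - mc
        sw += diff.T @ diff
        m = (mc - mu_all)[:, None]
        sb += len(xc) * (m @ m.T)
    ridge = 1e-8 * (np.trace(sw) / d + 1.0)
    from scipy.linalg import eigh

    evals, evecs = eigh(sb, sw + ridge * np.eye(d))
    order = np.argsort(evals)[::-1]
    lda_dirs = evecs[:, order[: min(p, len(classes) - 1)]]

    basis = [lda_dirs[:, i] for i in range(lda_dirs.shape[1])]
    if len(basis) < p:
        # PCA padding, then canonical basis as a last resort
        xc = X - mu_all
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        candidates = list(vt) + list(np.eye(d))
        for cand in candidates:
            if len(basis) >= p:
                break
            v = cand.astype(float).copy()
            for b in basis:
                v -= (v @ b) / (b @ b) * b
            if np.linalg.norm(v) > 1e-8:
                basis.append(v)
        if len(basis) < p:
            raise ValueError("could not build p independent directions")
    rows = np.stack(basis[:p])
    # orthonormalize preserving order (Gram-Schmidt via QR on the transpose)
    q, _ = np.linalg.qr(rows.T)
    return q.T[:p]


# ---------------------------------------------------------------------------
# Training and classification
# ---------------------------------------------------------------------------

def train_metric(
    columns: np.ndarray,
    labels,
    config: TrainConfig | None = None,
) -> MetricModel:
    """Gradient descent with backtracking line search from the LDA seed.

    Stops at ``max_epochs`` or when the gradient Frobenius norm drops
    below ``grad_threshold``; the recorded loss history is non-increasing
    because a step is only accepted when it decreases the loss.
    """
    config = config or TrainConfig()
    config.validate()
    X = np.asarray(columns, float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    p = config.p if config.p is not None else X.shape[1]
    if p > X.shape[1]:
        raise ValueError("p may not exceed the column dimension")

    targets = _target_neighbors(X, y, config.n_target_neighbors)
    impostors = _impostor_candidates(y)
    L = lda_init(X, y, p)

    args = (X, y, targets, impostors, config.mu, config.lam, config.zeta)
    loss = klmnn_loss(L, *args)
    history = [loss]
    grad_norms = []
    for _ in range(config.max_epochs):
        grad = klmnn_gradient(L, *args)
        gnorm = float(np.linalg.norm(grad))
        grad_norms.append(gnorm)
        if gnorm < config.grad_threshold:
            break
        lr = config.learning_rate
        improved = False
        while lr > 1e-14:
            cand = L - lr * grad
            cand_loss = klmnn_loss(cand, *args)
            if cand_loss < loss:
                L, loss = cand, cand_loss
                improved = True
                break
            lr *= 0.5
        history.append(loss)
        if not improved:
            break
    return MetricModel(L=L, config=config, train_columns=X, train_labels=y,
                       loss_history=history, grad_norms=grad_norms)


def classify_knn(model: MetricModel, query_columns: np.ndarray) -> np.ndarray:
    """Majority vote among the k nearest training samples under the metric.

    Ties are broken by the smaller summed distance to the tied class's
    voters, then by label sort order.
    """
    if model.L is None or model.train_columns is None:
        raise NotTrainedError("model has no learned transform")
    Q = np.atleast_2d(np.asarray(query_columns, float))
    if Q.shape[1] != model.train_columns.shape[1]:
        raise ValueError("query columns do not match the training basis")
    zq = Q @ model.L.T
    zt = model.train_columns @ model.L.T
    d = cdist(zq, zt, metric="sqeuclidean")
    k = min(model.config.k_classify, len(model.train_labels))
    preds = []
    for row in d:
        nn = np.argsort(row, kind="stable")[:k]
        votes: dict = {}
        for idx in nn:
            lab = model.train_labels[idx]
            cnt, tot = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, tot + float(row[idx]))
        # most votes, then smallest summed distance, then label order
        best = sorted(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1], str(kv[0])))
        preds.append(best[0][0])
    return np.array(preds)


def build_query_columns(
    train_spatial: np.ndarray,
    train_temporal: np.ndarray,
    query_spatial: np.ndarray,
    query_temporal: np.ndarray,
    delta: float,
    beta: float,
    mode: str = "fused",
) -> np.ndarray:
    """Kernel feature vectors of queries against the training basis."""
    if mode == "spatial":
        return rbf_cross(query_spatial, train_spatial, delta)
    if mode == "temporal":
        return rbf_cross(query_temporal, train_temporal, beta)
    if mode == "fused":
        return (rbf_cross(query_spatial, train_spatial, delta)
                * rbf_cross(query_temporal, train_temporal, beta))
    raise ValueError(f"unknown mode '{mode}'")


def kernel_columns(
    spatial: np.ndarray, temporal: np.ndarray, mode: str = "fused"
) -> tuple[np.ndarray, float, float]:
    """Training kernel columns plus the estimated bandwidths (delta, beta)."""
    delta = estimate_bandwidth(spatial) if mode in {"spatial", "fused"} else float("nan")
    beta = estimate_bandwidth(temporal) if mode in {"temporal", "fused"} else float("nan")
    if mode == "spatial":
        k = rbf_kernel(spatial, delta, "spatial")
    elif mode == "temporal":
        k = rbf_kernel(temporal, beta, "temporal")
    elif mode == "fused":
        k = fuse_kernels(rbf_kernel(spatial, delta, "spatial"),
                         rbf_kernel(temporal, beta, "temporal"))
    else:
        raise ValueError(f"unknown mode '{mode}'")
    # columns of the kernel matrix are the samples' feature vectors
    return k.values.T.copy(), delta, beta


@dataclass
class CVReport:
    mode: str
    fold_accuracies: list[list[float]]   # [repeat][fold]
    confusion: np.ndarray | None = None
    class_order: list | None = None

    @property
    def per_repeat_means(self) -> list[float]:
        return [float(np.mean(f)) for f in self.fold_accuracies]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([a for rep in self.fold_accuracies for a in rep]))

    @property
    def mean_of_repeat_means(self) -> float:
        return float(np.mean(self.per_repeat_means))

    @property
    def std_accuracy(self) -> float:
        return float(np.std([a for rep in self.fold_accuracies for a in rep]))


def cross_validate(
    spatial: np.ndarray,
    temporal: np.ndarray,
    labels,
    config: TrainConfig | None = None,
    mode: str = "fused",
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV on precomputed descriptors.

    Bandwidths and the metric are fit on the training portion of each fold
    only; test columns are built against the training basis.
    """
    config = config or TrainConfig()
    X_s = np.asarray(spatial, float)
    X_t = np.asarray(temporal, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {n_folds} folds")
    class_order = list(classes)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_accs: list[list[float]] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + rep)
        rep_accs = []
        for train_idx, test_idx in skf.split(X_s, y):
            acc, preds = _fit_and_score(
                X_s, X_t, y, train_idx, test_idx, config, mode)
            rep_accs.append(acc)
            for t, pr in zip(y[test_idx], preds):
                confusion[class_order.index(t), class_order.index(pr)] += 1
        fold_accs.append(rep_accs)
    return CVReport(mode=mode, fold_accuracies=fold_accs,
                    confusion=confusion, class_order=class_order)


def _fit_and_score(X_s, X_t, y, train_idx, test_idx, config, mode):
    cols, delta, beta = kernel_columns(X_s[train_idx], X_t[train_idx], mode)
    cfg = TrainConfig(**{**config.__dict__})
    if cfg.p is not None:
        cfg.p = min(cfg.p, cols.shape[1])
    model = train_metric(cols, y[train_idx], cfg)
    q = build_query_columns(X_s[train_idx], X_t[train_idx],
                            X_s[test_idx], X_t[test_idx], delta, beta, mode)
    preds = classify_knn(model, q)
    return float(np.mean(preds == y[test_idx])), preds
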