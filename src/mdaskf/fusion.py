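"""Similarity kernel fusion (SKF) with SNF and average-fusion comparators.

SKF integrates L kernels over one entity axis.  Each kernel is column
normalized (P) and k-nearest-neighbor sparsified with row renormalization
(S); the iteration

    P_l(t+1) = alpha * S_l @ mean_{r != l} P_r(t) @ S_l.T
               + (1 - alpha) * mean_{r != l} P_r(0)

keeps a fixed share (1 - alpha) of the initial normalized kernels, so the
map is a contraction and converges geometrically.  The fused kernel is the
mean of the final iterates, de-noised element-wise by a mutual-neighborhood
weight matrix w (1 for mutual neighbors, 0 when neither direction holds,
0.5 otherwise) and symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kernels import SimilarityKernel

__all__ = [
    "FusionConfig",
    "FusionState",
    "SimilarityKernelFusion",
    "normalize_kernel",
    "sparsify_kernel",
    "neighbor_sets",
    "weight_matrix",
    "skf_fuse",
    "snf_fuse",
    "avg_fuse",
]


@dataclass
class FusionConfig:
    """Parameters of the kernel-fusion step.

    alpha : diffusion share in (0, 1); the remaining (1 - alpha) anchors the
        iterate to the initial normalized kernels.  Default 0.1.
    neighbors : size k of the kNN neighborhoods used for sparsification and
        the weight matrix (self always included).  Default 36.
    iterations : number of fusion iterations T.  Default 10.
    method : one of "skf", "snf", "avg".
    """

    alpha: float = 0.1
    neighbors: int = 36
    iterations: int = 10
    method: str = "skf"

    def __post_init__(self) -> None:
        if self.method not in ("skf", "snf", "avg"):
            raise ValueError(f"unknown fusion method {self.method!r}")
        # alpha = 0 is the degenerate no-diffusion limit (pure anchor term),
        # useful for algebraic checks; normal operation uses 0 < alpha < 1
        if self.method == "skf" and not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.neighbors < 1:
            raise ValueError("neighbors must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class FusionState:
    """Intermediate quantities of one fusion run."""

    normalized: list[np.ndarray]  # P_l^0
    sparse: list[np.ndarray]  # S_l
    neighbor_sets: list[np.ndarray]  # N_i (indices), from the fused kernel
    weights: np.ndarray | None  # w
    fused_pre_weight: np.ndarray  # K = mean of final iterates
    fused: np.ndarray  # K* = w o K, symmetrized
    convergence: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    # convergence[t, l] = ||P_l^{t+1} - P_l^t||_F / ||P_l^t||_F


def _check_square_nonneg(K: np.ndarray) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be a square matrix")
    if (K < 0).any():
        raise ValueError("kernel entries must be non-negative")
    return K


def normalize_kernel(K: np.ndarray) -> np.ndarray:
    """Column normalization: P(i, j) = K(i, j) / sum_k K(k, j).

    Every column of the result sums to 1; an all-zero column is replaced by
    the unit column with 1 on the diagonal.
    """
    K = _check_square_nonneg(K)
    col_sums = K.sum(axis=0)
    P = np.zeros_like(K)
    ok = col_sums > 0
    P[:, ok] = K[:, ok] / col_sums[ok]
    for j in np.nonzero(~ok)[0]:
        P[j, j] = 1.0
    return P


def neighbor_sets(K: np.ndarray, k: int) -> list[np.ndarray]:
    """Top-k neighborhoods N_i by row value, self always included.

    Ties at the k-th rank are broken by lower index for determinism.
    """
    K = _check_square_nonneg(K)
    n = K.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"neighbors k={k} out of range [1, {n}]")
    sets = []
    for i in range(n):
        order = np.lexsort((np.arange(n), -K[i]))
        top = order[:k]
        if i not in top:
            top = np.concatenate([top[: k - 1], [i]])
        sets.append(np.sort(top))
    return sets


def sparsify_kernel(K: np.ndarray, k: int) -> np.ndarray:
    """kNN sparsification with row renormalization.

    S(i, j) = K(i, j) / sum_{m in N_i} K(i, m) for j in N_i, else 0; each row
    sums to 1.  A row whose neighborhood carries zero mass falls back to the
    unit row e_i.
    """
    K = _check_square_nonneg(K)
    n = K.shape[0]
    S = np.zeros_like(K)
    for i, top in enumerate(neighbor_sets(K, k)):
        mass = K[i, top].sum()
        if mass > 0:
            S[i, top] = K[i, top] / mass
        else:
            S[i, i] = 1.0
    return S


def weight_matrix(K: np.ndarray, k: int) -> np.ndarray:
    """Mutual-neighborhood weights on the fused kernel.

    w(i, j) = 1 if i and j are in each other's top-k neighborhoods, 0 if
    neither direction holds, 0.5 otherwise.
    """
    n = K.shape[0]
    member = np.zeros((n, n), dtype=bool)
    for i, top in enumerate(neighbor_sets(K, k)):
        member[i, top] = True
    return (member.astype(float) + member.T.astype(float)) / 2.0


def _as_matrices(kernels) -> tuple[list[np.ndarray], list[str] | None]:
    mats, ids = [], None
    for k in kernels:
        if isinstance(k, SimilarityKernel):
            if ids is None:
                ids = k.ids
            elif k.ids != ids:
                raise ValueError("kernels are not aligned on the same identifier order")
            mats.append(k.K)
        else:
            mats.append(_check_square_nonneg(k))
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("kernels have mismatched shapes")
    return mats, ids


class SimilarityKernelFusion(BaseEstimator, TransformerMixin):
    """Fuse a list of similarity kernels into one (scikit-learn style).

    Parameters
    ----------
    alpha : float, default 0.1
        Diffusion share of the SKF update; (1 - alpha) anchors to the initial
        normalized kernels.
    neighbors : int, default 36
        kNN neighborhood size k (clamped to n when n < k at fit time only if
        ``clamp_neighbors`` is set).
    iterations : int, default 10
        Number of fusion iterations T.
    method : {"skf", "snf", "avg"}, default "skf"
    clamp_neighbors : bool, default False
        Clamp k to the kernel size instead of raising.
    allow_two : bool, default False
        Permit fusing two kernels with the SKF update (the pairwise mean over
        the r != l kernels then degenerates to the single remaining kernel).

    Attributes
    ----------
    fused_kernel_ : ndarray
        The integrated kernel K* (weighted and symmetrized for SKF).
    state_ : FusionState
        Normalized/sparse kernels, neighborhoods, weights, convergence trace.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        neighbors: int = 36,
        iterations: int = 10,
        method: str = "skf",
        clamp_neighbors: bool = False,
        allow_two: bool = False,
    ):
        self.alpha = alpha
        self.neighbors = neighbors
        self.iterations = iterations
        self.method = method
        self.clamp_neighbors = clamp_neighbors
        self.allow_two = allow_two

    def fit(self, X, y=None):
        """Fuse the kernels in X (list of SimilarityKernel or square arrays)."""
        mats, ids = _as_matrices(X)
        n = mats[0].shape[0]
        k = min(self.neighbors, n) if self.clamp_neighbors else self.neighbors
        config = FusionConfig(
            alpha=self.alpha if self.method == "skf" else 0.5,
            neighbors=k,
            iterations=self.iterations,
            method=self.method,
        )
        if self.method == "avg":
            fused = avg_fuse(mats)
            self.state_ = FusionState(
                normalized=[], sparse=[], neighbor_sets=[], weights=None,
                fused_pre_weight=fused, fused=fused,
            )
        elif self.method == "snf":
            fused, self.state_ = _snf(mats, config)
        else:
            if self.method == "skf":
                config.alpha = self.alpha
            fused, self.state_ = _skf(mats, config, allow_two=self.allow_two)
        self.ids_ = ids
        self.fused_kernel_ = fused
        return self

    def transform(self, X=None):
        """Return the fused kernel (the fusion is transductive)."""
        return self.fused_kernel_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def _cross_mean(mats: list[np.ndarray], exclude: int) -> np.ndarray:
    others = [m for r, m in enumerate(mats) if r != exclude]
    return sum(others) / len(others)


def _skf(mats: list[np.ndarray], config: FusionConfig, allow_two: bool = False):
    L = len(mats)
    if L != 3 and not allow_two:
        raise ValueError("SKF fuses exactly three kernels (set allow_two to generalize)")
    if L < 2:
        raise ValueError("SKF needs at least two kernels")
    P0 = [normalize_kernel(K) for K in mats]
    S = [sparsify_kernel(K, config.neighbors) for K in mats]
    P = [p.copy() for p in P0]
    anchors = [(1.0 - config.alpha) * _cross_mean(P0, l) for l in range(L)]
    trace = np.zeros((config.iterations, L))
    for t in range(config.iterations):
        new = []
        for l in range(L):
            cross = _cross_mean(P, l)
            new.append(config.alpha * (S[l] @ cross @ S[l].T) + anchors[l])
        for l in range(L):
            denom = np.linalg.norm(P[l])
            trace[t, l] = np.linalg.norm(new[l] - P[l]) / denom if denom > 0 else np.inf
        P = new
    K = sum(P) / L
    w = weight_matrix(K, config.neighbors)
    K_star = w * K
    K_star = (K_star + K_star.T) / 2.0
    state = FusionState(
        normalized=P0,
        sparse=S,
        neighbor_sets=neighbor_sets(K, config.neighbors),
        weights=w,
        fused_pre_weight=K,
        fused=K_star,
        convergence=trace,
    )
    return K_star, state


def snf_normalize(K: np.ndarray) -> np.ndarray:
    """Diagonal-reinforced row normalization used by similarity network fusion.

    Off-diagonal entries are scaled so each row's off-diagonal mass is 1/2 and
    the diagonal is set to 1/2, keeping self-similarity dominant so repeated
    cross-diffusion does not wash the network out to a rank-one consensus.
    Rows with no off-diagonal mass become unit rows.
    """
    K = _check_square_nonneg(K)
    n = K.shape[0]
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    row_mass = off.sum(axis=1)
    P = np.zeros_like(K)
    ok = row_mass > 0
    P[ok] = off[ok] / (2.0 * row_mass[ok, None])
    np.fill_diagonal(P, np.where(ok, 0.5, 1.0))
    return (P + P.T) / 2.0


def _snf(mats: list[np.ndarray], config: FusionConfig):
    L = len(mats)
    if L < 2:
        raise ValueError("SNF needs at least two kernels")
    P = [snf_normalize(K) for K in mats]
    P0 = [p.copy() for p in P]
    S = [sparsify_kernel(K, config.neighbors) for K in mats]
    trace = np.zeros((config.iterations, L))
    for t in range(config.iterations):
        new = []
        for l in range(L):
            cross = _cross_mean(P, l)
            new.append(snf_normalize(S[l] @ cross @ S[l].T))
        for l in range(L):
            denom = np.linalg.norm(P[l])
            trace[t, l] = np.linalg.norm(new[l] - P[l]) / denom if denom > 0 else np.inf
        P = new
    K = sum(P) / L
    K_star = (K + K.T) / 2.0
    state = FusionState(
        normalized=P0,
        sparse=S,
        neighbor_sets=neighbor_sets(K, config.neighbors),
        weights=None,
        fused_pre_weight=K,
        fused=K_star,
        convergence=trace,
    )
    return K_star, state


def skf_fuse(kernels, config: FusionConfig | None = None, allow_two: bool = False):
    """Functional wrapper: fuse three kernels with SKF.

    Returns (K*, FusionState).
    """
    config = config or FusionConfig()
    mats, _ = _as_matrices(kernels)
    return _skf(mats, config, allow_two=allow_two)


def snf_fuse(kernels, config: FusionConfig | None = None) -> np.ndarray:
    """Similarity network fusion comparator (cross-diffusion with
    per-iteration renormalization)."""
    config = config or FusionConfig(method="snf")
    mats, _ = _as_matrices(kernels)
    fused, _state = _snf(mats, config)
    return fused


def avg_fuse(kernels) -> np.ndarray:
    """Element-wise mean of the input kernels."""
    mats, _ = _as_matrices(kernels)
    return sum(mats) / len(mats)
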