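"""Laplacian regularized least squares (LapRLS) on fused similarity kernels.

The closed form in each subspace is

    F = K (K + beta L K)^{-1} Y

with L the symmetric normalized graph Laplacian of the fused kernel,
L = D^{-1/2} (D - K) D^{-1/2}, D the diagonal of row sums.  Predictions from
the miRNA subspace (F_m, p x q) and the disease subspace (F_d, q x p, fit
against Y^T) are averaged element-wise: F* = (F_m + F_d^T) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .fusion import SimilarityKernelFusion
from .io import AssociationMatrix

__all__ = [
    "LapRLSConfig",
    "PredictionResult",
    "LapRLS",
    "MDASKF",
    "normalized_laplacian",
    "laprls_solve",
    "combine_predictions",
    "predict",
]

DEFAULT_BETA = 2.0 ** -5  # 5-fold / global leave-one-out setting
LOCAL_BETA = 2.0 ** -1  # local leave-one-out setting
DEFAULT_NEIGHBORS = 36
LOCAL_NEIGHBORS = 192


@dataclass
class LapRLSConfig:
    """Regularization coefficients for the two subspaces (kept equal by default)."""

    beta_m: float = DEFAULT_BETA
    beta_d: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.beta_m < 0 or self.beta_d < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class PredictionResult:
    """Subspace score matrices and their combination."""

    F_m: np.ndarray  # p x q
    F_d: np.ndarray  # q x p
    F_star: np.ndarray  # p x q

    def __post_init__(self) -> None:
        for M in (self.F_m, self.F_d, self.F_star):
            if not np.isfinite(M).all():
                raise ValueError("prediction matrices must be finite")


def normalized_laplacian(K: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian D^{-1/2} (D - K) D^{-1/2}.

    Rows with zero degree get zero Laplacian rows/columns (isolated nodes).
    """
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    if np.max(np.abs(K - K.T)) > 1e-9:
        raise ValueError("Laplacian requires a symmetric kernel")
    deg = K.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    pos = deg > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(deg[pos])
    L = (np.diag(deg) - K) * np.outer(inv_sqrt, inv_sqrt)
    return L


def laprls_solve(K: np.ndarray, L: np.ndarray, Y: np.ndarray, beta: float) -> np.ndarray:
    """Closed-form LapRLS solution F = K (K + beta L K)^{-1} Y via linear solve.

    A singular system gets 1e-12 ridge jitter with a warning.
    """
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    A = K + beta * (L @ K)
    try:
        Z = np.linalg.solve(A, Y)
    except np.linalg.LinAlgError:
        warnings.warn("singular LapRLS system; adding 1e-12 ridge jitter", stacklevel=2)
        Z = np.linalg.solve(A + 1e-12 * np.eye(A.shape[0]), Y)
    F = K @ Z
    if not np.isfinite(F).all():
        raise FloatingPointError("LapRLS produced non-finite predictions")
    return F


def combine_predictions(F_m: np.ndarray, F_d: np.ndarray) -> np.ndarray:
    """Element-wise mean of the miRNA-subspace scores and the transposed
    disease-subspace scores."""
    F_m = np.asarray(F_m, dtype=float)
    F_d = np.asarray(F_d, dtype=float)
    if F_m.shape != F_d.T.shape:
        raise ValueError(f"shapes {F_m.shape} and {F_d.shape} are not transpose-conformable")
    return (F_m + F_d.T) / 2.0


class LapRLS(BaseEstimator):
    """Laplacian regularized least squares on a fixed similarity kernel.

    Parameters
    ----------
    beta : float, default 2**-5
        Graph-smoothness regularization coefficient.

    Attributes
    ----------
    F_ : ndarray of shape (n, n_targets)
        Predicted score matrix for the training kernel's entities.
    laplacian_ : ndarray
        Normalized Laplacian of the kernel used in the fit.
    """

    def __init__(self, beta: float = DEFAULT_BETA):
        self.beta = beta

    def fit(self, K: np.ndarray, Y: np.ndarray):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        self.laplacian_ = normalized_laplacian(K)
        self.F_ = laprls_solve(K, self.laplacian_, Y, self.beta)
        return self

    def predict(self) -> np.ndarray:
        """Return the fitted score matrix (the model is transductive)."""
        return self.F_


class MDASKF(BaseEstimator):
    """End-to-end association predictor: kernel fusion + two-subspace LapRLS.

    Takes the three miRNA kernels and three disease kernels (keys Km1..Km3,
    Kd1..Kd3), fuses each triple, solves LapRLS with Y in the miRNA subspace
    and Y^T in the disease subspace, and averages the two score matrices.

    Parameters
    ----------
    alpha : float, default 0.1
        SKF diffusion share.
    neighbors : int, default 36
        kNN neighborhood size for fusion (clamped to the axis size).
    iterations : int, default 10
        Fusion iterations.
    beta : float, default 2**-5
        LapRLS regularization, used for both subspaces.
    fusion : {"skf", "snf", "avg"}, default "skf"

    Attributes
    ----------
    F_star_ : ndarray of shape (p, q)
        Combined association scores.
    result_ : PredictionResult
    fused_mirna_kernel_, fused_disease_kernel_ : ndarray
    mirna_fusion_, disease_fusion_ : SimilarityKernelFusion
        Fitted fusion transformers (convergence traces under ``state_``).
    """

    def __init__(
        self,
        alpha: float = 0.1,
        neighbors: int = DEFAULT_NEIGHBORS,
        iterations: int = 10,
        beta: float = DEFAULT_BETA,
        fusion: str = "skf",
    ):
        self.alpha = alpha
        self.neighbors = neighbors
        self.iterations = iterations
        self.beta = beta
        self.fusion = fusion

    def fit(self, kernels: dict, Y: np.ndarray | AssociationMatrix):
        if isinstance(Y, AssociationMatrix):
            Y = Y.Y
        Y = np.asarray(Y, dtype=float)
        mirna_triple = [kernels["Km1"], kernels["Km2"], kernels["Km3"]]
        disease_triple = [kernels["Kd1"], kernels["Kd2"], kernels["Kd3"]]
        self.mirna_fusion_ = SimilarityKernelFusion(
            alpha=self.alpha, neighbors=self.neighbors, iterations=self.iterations,
            method=self.fusion, clamp_neighbors=True,
        ).fit(mirna_triple)
        self.disease_fusion_ = SimilarityKernelFusion(
            alpha=self.alpha, neighbors=self.neighbors, iterations=self.iterations,
            method=self.fusion, clamp_neighbors=True,
        ).fit(disease_triple)
        Km = self.fused_mirna_kernel_ = self.mirna_fusion_.fused_kernel_
        Kd = self.fused_disease_kernel_ = self.disease_fusion_.fused_kernel_
        if Km.shape[0] != Y.shape[0] or Kd.shape[0] != Y.shape[1]:
            raise ValueError("kernel sizes do not match the association matrix")
        F_m = LapRLS(beta=self.beta).fit(Km, Y).predict()
        F_d = LapRLS(beta=self.beta).fit(Kd, Y.T).predict()
        self.result_ = PredictionResult(F_m=F_m, F_d=F_d, F_star=combine_predictions(F_m, F_d))
        self.F_star_ = self.result_.F_star
        return self

    def predict(self) -> np.ndarray:
        """Return the combined p x q association score matrix."""
        return self.F_star_


def predict(
    assoc: AssociationMatrix,
    kernels: dict,
    alpha: float = 0.1,
    neighbors: int = DEFAULT_NEIGHBORS,
    iterations: int = 10,
    beta: float = DEFAULT_BETA,
    fusion: str = "skf",
) -> PredictionResult:
    """Functional wrapper around :class:`MDASKF`."""
    model = MDASKF(alpha=alpha, neighbors=neighbors, iterations=iterations,
                   beta=beta, fusion=fusion).fit(kernels, assoc)
    return model.result_
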