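"""Cross-validation protocols and ranking metrics for association prediction.

Three protocols are provided:

* global leave-one-out: each known association is masked in turn and ranked
  against all pairs unknown in the masked matrix;
* local leave-one-out: all associations of one disease are masked at once
  and the disease's miRNAs are ranked (per-disease AUC, averaged);
* k-fold: the known associations are randomly partitioned; each fold is
  masked in turn and the held-out positives are ranked against all
  never-known pairs.

Inside every fold the association-derived kernels (Hamming on both axes and
the MISIM miRNA functional kernel) are rebuilt from the masked matrix by
default, so no held-out label can leak into the similarity structure; a
``fast`` mode rebuilds only the cheap Hamming kernels.

Pooled metrics concatenate each fold's held-out positive scores with that
fold's negative (unknown-pair) scores and evaluate one ranking; per-fold and
per-disease values are also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import AssociationMatrix, Dataset
from .kernels import (
    SimilarityKernel,
    disease_functional_kernel,
    disease_semantic_kernel,
    hamming_profile_kernel,
    misim_kernel,
    sequence_kernel,
)
from .laprls import DEFAULT_BETA, DEFAULT_NEIGHBORS, LOCAL_BETA, LOCAL_NEIGHBORS, MDASKF

__all__ = [
    "CVSpec",
    "CVResult",
    "compute_auc",
    "compute_aupr",
    "run_global_loocv",
    "run_local_loocv",
    "run_kfold_cv",
    "top_candidates",
    "EvaluationContext",
]


@dataclass
class CVSpec:
    """Cross-validation protocol description."""

    scheme: str = "kfold"  # global-loocv | local-loocv | kfold
    folds: int = 5
    seed: int = 0
    recompute_y_kernels: frozenset = frozenset({"hamming", "misim"})

    def __post_init__(self) -> None:
        if self.scheme not in ("global-loocv", "local-loocv", "kfold"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.folds < 2:
            raise ValueError("k-fold CV needs folds >= 2")
        self.recompute_y_kernels = frozenset(self.recompute_y_kernels)


@dataclass
class CVResult:
    """Per-fold (or per-disease) and pooled AUC / AUPR plus positive ranks."""

    scheme: str
    pooled_auc: float
    pooled_aupr: float
    per_fold_auc: list[float] = field(default_factory=list)
    per_fold_aupr: list[float] = field(default_factory=list)
    per_unit: dict = field(default_factory=dict)  # local LOOCV: disease -> AUC
    ranks: list[int] = field(default_factory=list)
    n_positives: int = 0


def compute_auc(scores_pos, scores_neg) -> float:
    """ROC AUC (Mann-Whitney statistic; ties count one half)."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("AUC is undefined with an empty class")
    y = np.concatenate([np.ones(scores_pos.size), np.zeros(scores_neg.size)])
    return float(roc_auc_score(y, np.concatenate([scores_pos, scores_neg])))


def compute_aupr(scores_pos, scores_neg) -> float:
    """Area under the precision-recall curve as step-wise average precision."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("AUPR is undefined with an empty class")
    y = np.concatenate([np.ones(scores_pos.size), np.zeros(scores_neg.size)])
    return float(average_precision_score(y, np.concatenate([scores_pos, scores_neg])))


class EvaluationContext:
    """Precomputes the Y-independent kernels and refits per masked matrix.

    The disease semantic and functional kernels and the miRNA sequence kernel
    do not depend on the association matrix and are built once; the Hamming
    kernels and the MISIM kernel are rebuilt from each masked matrix
    according to ``recompute`` ({"hamming", "misim"} by default).
    """

    def __init__(
        self,
        dataset: Dataset,
        alpha: float = 0.1,
        neighbors: int = DEFAULT_NEIGHBORS,
        iterations: int = 10,
        beta: float = DEFAULT_BETA,
        fusion: str = "skf",
        recompute=frozenset({"hamming", "misim"}),
        delta: float = 0.5,
    ):
        self.dataset = dataset
        self.assoc = dataset.assoc
        self.alpha = alpha
        self.neighbors = neighbors
        self.iterations = iterations
        self.beta = beta
        self.fusion = fusion
        self.recompute = frozenset(recompute)
        self.kd1 = disease_semantic_kernel(dataset.ontology, self.assoc.disease_ids, delta)
        self.kd2 = disease_functional_kernel(dataset.gene_net, dataset.disease_genes,
                                             self.assoc.disease_ids)
        self.km2 = sequence_kernel(dataset.sequences, self.assoc.mirna_ids)
        full = self.assoc
        self._full_km1 = misim_kernel(full, self.kd1)
        self._full_kd3 = hamming_profile_kernel(full, "disease")
        self._full_km3 = hamming_profile_kernel(full, "miRNA")

    def kernels_for(self, Y_masked: np.ndarray) -> dict[str, SimilarityKernel]:
        assoc_m = AssociationMatrix(self.assoc.mirna_ids, self.assoc.disease_ids, Y_masked)
        if "hamming" in self.recompute:
            kd3 = hamming_profile_kernel(assoc_m, "disease")
            km3 = hamming_profile_kernel(assoc_m, "miRNA")
        else:
            kd3, km3 = self._full_kd3, self._full_km3
        km1 = misim_kernel(assoc_m, self.kd1) if "misim" in self.recompute else self._full_km1
        return {"Kd1": self.kd1, "Kd2": self.kd2, "Kd3": kd3,
                "Km1": km1, "Km2": self.km2, "Km3": km3}

    def score_matrix(self, Y_masked: np.ndarray) -> np.ndarray:
        """Rebuild kernels from the masked matrix, refit, return F*."""
        kernels = self.kernels_for(Y_masked)
        model = MDASKF(alpha=self.alpha, neighbors=self.neighbors,
                       iterations=self.iterations, beta=self.beta,
                       fusion=self.fusion).fit(kernels, Y_masked)
        return model.F_star_


def _pooled(pos_chunks: list[np.ndarray], neg_chunks: list[np.ndarray]) -> tuple[float, float]:
    pos = np.concatenate(pos_chunks)
    neg = np.concatenate(neg_chunks)
    return compute_auc(pos, neg), compute_aupr(pos, neg)


def _make_context(dataset, fast: bool, **kwargs) -> EvaluationContext:
    if fast:
        kwargs.setdefault("recompute", frozenset({"hamming"}))
    return EvaluationContext(dataset, **kwargs)


def run_global_loocv(dataset: Dataset, fast: bool = False, **kwargs) -> CVResult:
    """Leave each known association out in turn and rank it among unknowns.

    Candidate negatives for a fold are all pairs unknown in the masked
    matrix.  The input dataset is never mutated.
    """
    ctx = dataset if isinstance(dataset, EvaluationContext) else _make_context(dataset, fast, **kwargs)
    Y = ctx.assoc.Y
    pos = np.argwhere(Y == 1)
    if len(pos) < 2:
        raise ValueError("global LOOCV needs at least two known associations")
    per_fold_auc, ranks = [], []
    pos_scores, neg_chunks = [], []
    for i, j in pos:
        Ym = Y.copy()
        Ym[i, j] = 0.0
        F = ctx.score_matrix(Ym)
        neg_mask = Ym == 0
        neg_mask[i, j] = False
        neg = F[neg_mask]
        s = F[i, j]
        per_fold_auc.append(float((np.sum(neg < s) + 0.5 * np.sum(neg == s)) / neg.size))
        ranks.append(int(1 + np.sum(neg > s)))
        pos_scores.append(np.array([s]))
        neg_chunks.append(neg)
    pooled_auc, pooled_aupr = _pooled(pos_scores, neg_chunks)
    return CVResult(scheme="global-loocv", pooled_auc=pooled_auc, pooled_aupr=pooled_aupr,
                    per_fold_auc=per_fold_auc, ranks=ranks, n_positives=len(pos))


def run_local_loocv(dataset: Dataset, fast: bool = False, **kwargs) -> CVResult:
    """Mask each disease's whole association column and rank its miRNAs.

    AUC/AUPR are computed per disease (its true miRNAs against the rest) and
    averaged; diseases with no positive, or with every miRNA positive, are
    skipped.  Defaults follow the local setting (larger neighborhoods,
    beta = 1/2).
    """
    kwargs.setdefault("neighbors", LOCAL_NEIGHBORS)
    kwargs.setdefault("beta", LOCAL_BETA)
    ctx = dataset if isinstance(dataset, EvaluationContext) else _make_context(dataset, fast, **kwargs)
    Y = ctx.assoc.Y
    p, q = Y.shape
    per_disease: dict[str, float] = {}
    per_fold_auc, per_fold_aupr, ranks = [], [], []
    for j in range(q):
        n_pos = int(Y[:, j].sum())
        if n_pos == 0:
            continue
        if n_pos == p:
            warnings.warn(
                f"disease {ctx.assoc.disease_ids[j]!r} is associated with every miRNA; skipped",
                stacklevel=2,
            )
            continue
        Ym = Y.copy()
        Ym[:, j] = 0.0
        F = ctx.score_matrix(Ym)
        col = F[:, j]
        labels = Y[:, j]
        auc = compute_auc(col[labels == 1], col[labels == 0])
        aupr = compute_aupr(col[labels == 1], col[labels == 0])
        per_disease[ctx.assoc.disease_ids[j]] = auc
        per_fold_auc.append(auc)
        per_fold_aupr.append(aupr)
        neg = col[labels == 0]
        ranks.extend(int(1 + np.sum(neg > s)) for s in col[labels == 1])
    if not per_fold_auc:
        raise ValueError("no evaluable disease for local LOOCV")
    return CVResult(scheme="local-loocv",
                    pooled_auc=float(np.mean(per_fold_auc)),
                    pooled_aupr=float(np.mean(per_fold_aupr)),
                    per_fold_auc=per_fold_auc, per_fold_aupr=per_fold_aupr,
                    per_unit=per_disease, ranks=ranks,
                    n_positives=int(Y.sum()))


def run_kfold_cv(dataset: Dataset, folds: int = 5, seed: int = 0,
                 fast: bool = False, **kwargs) -> CVResult:
    """Random k-fold partition of the known associations.

    Each fold is masked in turn; held-out positives are scored against all
    pairs that were never known.  Pooled metrics concatenate the folds.
    """
    ctx = dataset if isinstance(dataset, EvaluationContext) else _make_context(dataset, fast, **kwargs)
    Y = ctx.assoc.Y
    pos = np.argwhere(Y == 1)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(pos) < folds:
        raise ValueError("fewer positives than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    chunks = np.array_split(order, folds)
    never_known = Y == 0
    per_fold_auc, per_fold_aupr = [], []
    pos_chunks, neg_chunks, ranks = [], [], []
    for chunk in chunks:
        Ym = Y.copy()
        idx = pos[chunk]
        Ym[idx[:, 0], idx[:, 1]] = 0.0
        F = ctx.score_matrix(Ym)
        s_pos = F[idx[:, 0], idx[:, 1]]
        s_neg = F[never_known]
        per_fold_auc.append(compute_auc(s_pos, s_neg))
        per_fold_aupr.append(compute_aupr(s_pos, s_neg))
        pos_chunks.append(s_pos)
        neg_chunks.append(s_neg)
        ranks.extend(int(1 + np.sum(s_neg > s)) for s in s_pos)
    pooled_auc, pooled_aupr = _pooled(pos_chunks, neg_chunks)
    return CVResult(scheme="kfold", pooled_auc=pooled_auc, pooled_aupr=pooled_aupr,
                    per_fold_auc=per_fold_auc, per_fold_aupr=per_fold_aupr,
                    ranks=ranks, n_positives=len(pos))


def top_candidates(F_star: np.ndarray, assoc: AssociationMatrix, disease: str,
                   n: int = 50) -> list[tuple[str, float]]:
    """The n highest-scoring miRNAs unknown in Y for one disease.

    Sorted by descending score, ties broken by miRNA identifier.  If fewer
    than n unknown pairs exist the list is truncated with a warning.
    """
    if disease not in assoc.disease_ids:
        raise KeyError(f"unknown disease {disease!r}")
    j = assoc.disease_ids.index(disease)
    unknown = np.nonzero(assoc.Y[:, j] == 0)[0]
    cands = sorted(((assoc.mirna_ids[i], float(F_star[i, j])) for i in unknown),
                   key=lambda t: (-t[1], t[0]))
    if len(cands) < n:
        warnings.warn(
            f"only {len(cands)} unknown pairs available for {disease!r} (requested {n})",
            stacklevel=2,
        )
    return cands[:n]
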