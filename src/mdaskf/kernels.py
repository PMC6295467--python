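"""The three miRNA and three disease similarity kernels.

Disease side:
  * semantic similarity from the disease ontology DAG (contribution factor
    delta decaying along parent links),
  * functional similarity from a gene functional-linkage network with
    min-max-normalized log-likelihood scores,
  * Hamming profile similarity from the association matrix columns.

miRNA side:
  * functional similarity (MISIM-style best-match average of the semantic
    similarities of the disease sets each miRNA is associated with),
  * sequence similarity from global Needleman-Wunsch alignment scores,
  * Hamming profile similarity from the association matrix rows.

Entities with missing auxiliary data (no ontology term, empty gene set,
empty disease set, no sequence) get fallback rows: 0 off-diagonal, 1 on the
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import (
    AssociationMatrix,
    DiseaseGeneMap,
    DiseaseOntology,
    GeneFunctionalNetwork,
    SequenceSet,
)

__all__ = [
    "SimilarityKernel",
    "SemanticProfile",
    "semantic_profile",
    "disease_semantic_kernel",
    "disease_functional_kernel",
    "misim_kernel",
    "sequence_kernel",
    "hamming_profile_kernel",
    "build_all_kernels",
]


@dataclass
class SimilarityKernel:
    """A labeled square non-negative similarity matrix over one entity axis."""

    axis: str  # "miRNA" or "disease"
    ids: list[str]
    K: np.ndarray
    name: str = "kernel"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.ids)
        if self.K.shape != (n, n):
            raise ValueError("kernel matrix shape does not match identifier list")
        if (self.K < 0).any():
            raise ValueError("kernel entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class SemanticProfile:
    """Per-ancestor semantic contributions D_d(t) and their sum DV(d)."""

    disease: str
    scores: dict[str, float]
    dv: float


class NoOntologyNode(KeyError):
    """Disease has no node in the ontology; caller substitutes the fallback."""


def semantic_profile(ontology: DiseaseOntology, disease: str, delta: float = 0.5) -> SemanticProfile:
    """Semantic contribution of every ancestor term of ``disease``.

    The disease's own term(s) contribute 1; every other ancestor t gets
    ``max(delta * D(t'))`` over its children t' inside the ancestor closure,
    so a term's contribution is ``delta ** (shortest upward distance)``.
    """
    seeds = ontology.terms_for(disease)
    if not seeds:
        raise NoOntologyNode(disease)
    closure: set[str] = set()
    for t in seeds:
        closure |= ontology.ancestor_closure(t)
    scores = {t: 1.0 for t in seeds}
    # relax upward until fixpoint; DAG depth bounds the number of sweeps
    changed = True
    while changed:
        changed = False
        for child in closure:
            if child not in scores:
                continue
            for parent in ontology.parents(child):
                if parent not in closure:
                    continue
                cand = delta * scores[child]
                if parent not in seeds and cand > scores.get(parent, 0.0) + 1e-15:
                    scores[parent] = cand
                    changed = True
    dv = float(sum(scores.values()))
    return SemanticProfile(disease=disease, scores=scores, dv=dv)


def disease_semantic_kernel(
    ontology: DiseaseOntology, disease_ids: list[str], delta: float = 0.5
) -> SimilarityKernel:
    """Pairwise semantic similarity over shared ontology ancestors.

    K(i, j) = sum over shared ancestors t of (D_i(t) + D_j(t)) divided by
    DV(i) + DV(j).  Diseases without ontology terms get the fallback row.
    """
    q = len(disease_ids)
    profiles: dict[int, SemanticProfile] = {}
    for j, d in enumerate(disease_ids):
        try:
            profiles[j] = semantic_profile(ontology, d, delta)
        except NoOntologyNode:
            pass
    K = np.eye(q)
    items = sorted(profiles.items())
    for a, (i, pi) in enumerate(items):
        for j, pj in (items[b] for b in range(a + 1, len(items))):
            shared = pi.scores.keys() & pj.scores.keys()
            if shared:
                num = sum(pi.scores[t] + pj.scores[t] for t in shared)
                K[i, j] = K[j, i] = num / (pi.dv + pj.dv)
    return SimilarityKernel(axis="disease", ids=list(disease_ids), K=K, name="semantic")


def normalized_lls(gene_net: GeneFunctionalNetwork) -> dict[frozenset, float]:
    """Min-max normalization of raw LLS edge weights over the whole network."""
    if gene_net.lls_max == gene_net.lls_min:
        raise ValueError("degenerate LLS normalization: all edge scores identical")
    span = gene_net.lls_max - gene_net.lls_min
    return {e: (s - gene_net.lls_min) / span for e, s in gene_net.edges.items()}


def disease_functional_kernel(
    gene_net: GeneFunctionalNetwork,
    disease_gene_map: DiseaseGeneMap,
    disease_ids: list[str],
) -> SimilarityKernel:
    """Pairwise disease similarity through their gene sets.

    Gene-gene similarity FS is 1 on identical genes, the normalized LLS on
    network edges, 0 otherwise.  A gene's similarity to a set is the best
    match, and the disease pair score averages those best matches in both
    directions.  Diseases with empty gene sets get the fallback row.
    """
    lls_star = normalized_lls(gene_net)
    genes = sorted({g for e in lls_star for g in e} | {g for d in disease_ids for g in disease_gene_map.genes_for(d)})
    gi = {g: k for k, g in enumerate(genes)}
    n_genes = len(genes)
    FS = np.zeros((n_genes, n_genes))
    np.fill_diagonal(FS, 1.0)
    for edge, val in lls_star.items():
        a, b = tuple(edge)
        FS[gi[a], gi[b]] = FS[gi[b], gi[a]] = val

    q = len(disease_ids)
    gene_sets = [sorted(disease_gene_map.genes_for(d)) for d in disease_ids]
    idx_sets = [np.array([gi[g] for g in gs], dtype=int) for gs in gene_sets]
    # best-match similarity of every gene to each disease's gene set
    FG = np.zeros((q, n_genes))
    for j, idx in enumerate(idx_sets):
        if idx.size:
            FG[j] = FS[idx].max(axis=0)

    K = np.eye(q)
    for i in range(q):
        if not idx_sets[i].size:
            continue
        for j in range(i + 1, q):
            if not idx_sets[j].size:
                continue
            num = FG[i, idx_sets[j]].sum() + FG[j, idx_sets[i]].sum()
            K[i, j] = K[j, i] = num / (idx_sets[i].size + idx_sets[j].size)
    return SimilarityKernel(axis="disease", ids=list(disease_ids), K=K, name="functional")


def misim_kernel(assoc: AssociationMatrix, disease_semantic: SimilarityKernel) -> SimilarityKernel:
    """miRNA functional similarity from the disease sets each miRNA targets.

    Best-match average of disease semantic similarities between the two
    miRNAs' associated disease sets, in both directions.  miRNAs with empty
    disease sets (possible after cross-validation masking) get the fallback
    row.
    """
    if disease_semantic.axis != "disease" or disease_semantic.ids != assoc.disease_ids:
        raise ValueError("disease semantic kernel does not match the association disease axis")
    Y = assoc.Y
    sim = disease_semantic.K
    sizes = Y.sum(axis=1)
    # V[i, d] = best semantic similarity between disease d and miRNA i's set
    masked = np.where(Y[:, None, :] > 0, sim.T[None, :, :], -np.inf)
    V = masked.max(axis=2)
    V[sizes == 0, :] = 0.0
    # cross terms: T[i, j] = sum over d in D_i of V[j, d]
    T = Y @ V.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (T.T + T) / denom
    K[~np.isfinite(K)] = 0.0
    empty = sizes == 0
    K[empty, :] = 0.0
    K[:, empty] = 0.0
    np.fill_diagonal(K, 1.0)
    K = np.clip(K, 0.0, 1.0)
    return SimilarityKernel(axis="miRNA", ids=list(assoc.mirna_ids), K=K, name="misim")


def _nw_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def sequence_kernel(
    sequences: SequenceSet,
    mirna_ids: list[str] | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> SimilarityKernel:
    """Needleman-Wunsch global-alignment similarity.

    K(i, j) = max(0, NW(i, j) / max(NW(i, i), NW(j, j))) with linear gap
    penalties, giving a symmetric kernel in [0, 1] with unit diagonal.
    miRNAs without a sequence get the fallback row.
    """
    if mirna_ids is None:
        mirna_ids = sorted(sequences.sequences)
    aligner = _nw_aligner(match, mismatch, gap)
    p = len(mirna_ids)
    seqs = [sequences.sequences.get(m) for m in mirna_ids]
    self_scores = [match * len(s) if s is not None else 0.0 for s in seqs]
    K = np.eye(p)
    for i in range(p):
        if seqs[i] is None:
            continue
        for j in range(i + 1, p):
            if seqs[j] is None:
                continue
            nw = aligner.score(seqs[i], seqs[j])
            K[i, j] = K[j, i] = max(0.0, nw / max(self_scores[i], self_scores[j]))
    return SimilarityKernel(axis="miRNA", ids=list(mirna_ids), K=K, name="sequence")


def hamming_profile_kernel(assoc: AssociationMatrix, axis: str) -> SimilarityKernel:
    """1 minus the normalized Hamming distance between interaction profiles.

    For diseases the profiles are the columns of Y (length p); for miRNAs the
    rows (length q).
    """
    Y = assoc.Y
    if axis == "disease":
        profiles, ids = Y.T, assoc.disease_ids
    elif axis == "miRNA":
        profiles, ids = Y, assoc.mirna_ids
    else:
        raise ValueError(f"axis must be 'miRNA' or 'disease', got {axis!r}")
    length = profiles.shape[1]
    # pairwise mismatch counts for binary profiles via two rank-1 products
    mism = profiles @ (1.0 - profiles).T
    mism = mism + mism.T
    K = 1.0 - mism / length
    return SimilarityKernel(axis=axis, ids=list(ids), K=K, name="hamming")


def build_all_kernels(dataset, delta: float = 0.5) -> dict[str, SimilarityKernel]:
    """Build the six base kernels from an aligned dataset.

    Returns a dict with keys Kd1 (semantic), Kd2 (functional), Kd3 (disease
    Hamming), Km1 (MISIM), Km2 (sequence), Km3 (miRNA Hamming).
    """
    assoc = dataset.assoc
    kd1 = disease_semantic_kernel(dataset.ontology, assoc.disease_ids, delta)
    kd2 = disease_functional_kernel(dataset.gene_net, dataset.disease_genes, assoc.disease_ids)
    kd3 = hamming_profile_kernel(assoc, "disease")
    km1 = misim_kernel(assoc, kd1)
    km2 = sequence_kernel(dataset.sequences, assoc.mirna_ids)
    km3 = hamming_profile_kernel(assoc, "miRNA")
    return {"Kd1": kd1, "Kd2": kd2, "Kd3": kd3, "Km1": km1, "Km2": km2, "Km3": km3}
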