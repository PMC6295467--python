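"""Readers and writers for the five input formats and labeled kernel matrices.

The association list defines the canonical universe of miRNA and disease
identifiers (sorted lexicographically).  Auxiliary sources (disease ontology,
gene functional network, disease-gene map, miRNA sequences) are aligned to
that universe; entities missing from an auxiliary source are retained and
flagged so the kernel builders can apply their fallback (off-diagonal 0,
diagonal 1).

Formats
-------
* Association list: 2-column TSV ``mirna_id<TAB>disease_id``; lines starting
  with ``#`` are comments.
* Disease ontology: either MeSH-style tree numbers
  (``disease_id<TAB>tree_number`` with parents derived by truncating the last
  dotted component) or explicit sections ``[edges]`` (``term<TAB>parent``)
  and ``[mapping]`` (``disease_id<TAB>term_id``).
* Gene network: TSV ``gene_a<TAB>gene_b<TAB>lls_score``.
* Disease-gene map: TSV ``disease_id<TAB>gene_id``.
* Sequences: FASTA (``T`` mapped to ``U``, case folded to upper).
* Kernel / prediction matrices: TSV with identifier row and column labels.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "DiseaseOntology",
    "GeneFunctionalNetwork",
    "DiseaseGeneMap",
    "SequenceSet",
    "Dataset",
    "FormatError",
    "load_dataset",
    "parse_association_file",
    "parse_ontology_file",
    "parse_gene_network_file",
    "parse_disease_gene_file",
    "parse_fasta_file",
    "write_association_file",
    "read_kernel",
    "write_kernel",
    "read_matrix",
    "write_matrix",
]


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass
class AssociationMatrix:
    """Binary bipartite association matrix Y (p miRNAs x q diseases).

    Row i of ``Y`` is the interaction profile IP(m_i) of miRNA i; column j is
    the interaction profile IP(d_j) of disease j.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("matrix shape does not match identifier lists")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def p(self) -> int:
        return len(self.mirna_ids)

    @property
    def q(self) -> int:
        return len(self.disease_ids)

    def mirna_profile(self, i: int) -> np.ndarray:
        """IP(m_i): row i of Y."""
        return self.Y[i, :]

    def disease_profile(self, j: int) -> np.ndarray:
        """IP(d_j): column j of Y."""
        return self.Y[:, j]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids), self.Y.copy())


@dataclass
class DiseaseOntology:
    """A DAG of ontology terms plus a disease -> term(s) mapping."""

    nodes: set[str]
    parent_links: dict[str, set[str]]  # child -> parents
    disease_to_terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, parents in self.parent_links.items():
            for parent in parents:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("ontology parent links contain a cycle")
        self._graph = g

    def ancestor_closure(self, term: str) -> set[str]:
        """All ancestors of ``term`` including itself (T_d for a single node)."""
        return {term} | nx.descendants(self._graph, term)

    def parents(self, term: str) -> set[str]:
        return self.parent_links.get(term, set())

    def terms_for(self, disease: str) -> set[str]:
        return self.disease_to_terms.get(disease, set())


@dataclass
class GeneFunctionalNetwork:
    """Undirected gene-gene functional linkage edges with raw LLS weights."""

    gene_ids: set[str]
    edges: dict[frozenset, float]
    lls_min: float = field(init=False)
    lls_max: float = field(init=False)

    def __post_init__(self) -> None:
        for pair in self.edges:
            if len(pair) != 2:
                raise ValueError("self-loop edge in gene network")
        scores = list(self.edges.values())
        self.lls_min = min(scores) if scores else float("nan")
        self.lls_max = max(scores) if scores else float("nan")

    def score(self, a: str, b: str) -> float | None:
        return self.edges.get(frozenset((a, b)))


@dataclass
class DiseaseGeneMap:
    """Disease identifier -> set of associated genes."""

    mapping: dict[str, set[str]]

    def genes_for(self, disease: str) -> set[str]:
        return self.mapping.get(disease, set())


@dataclass
class SequenceSet:
    """miRNA identifier -> RNA sequence over {A, C, G, U}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for {name!r}")
            bad = set(seq) - set("ACGU")
            if bad:
                raise FormatError(f"non-RNA characters {sorted(bad)} in sequence {name!r}")


@dataclass
class Dataset:
    """The five aligned inputs plus an identifier-matching report."""

    assoc: AssociationMatrix
    ontology: DiseaseOntology
    gene_net: GeneFunctionalNetwork
    disease_genes: DiseaseGeneMap
    sequences: SequenceSet
    report: dict


def _records(path, n_cols: int, name: str):
    """Yield (line_number, fields) for non-comment, non-blank lines."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise FormatError(
                    f"{name} {path}, line {lineno}: expected {n_cols} "
                    f"tab-separated fields, got {len(fields)}"
                )
            yield lineno, [f.strip() for f in fields]


def parse_association_file(path) -> AssociationMatrix:
    """Parse a 2-column miRNA-disease pair list into an AssociationMatrix.

    Identifiers are ordered lexicographically; duplicate pairs are removed
    with a warning; an empty file is an error.
    """
    pairs: set[tuple[str, str]] = set()
    n_dup = 0
    for lineno, (mirna, disease) in _records(path, 2, "association file"):
        if not mirna or not disease:
            raise FormatError(f"association file {path}, line {lineno}: empty identifier")
        if (mirna, disease) in pairs:
            n_dup += 1
        pairs.add((mirna, disease))
    if not pairs:
        raise FormatError(f"association file {path}: no records")
    if n_dup:
        warnings.warn(f"{n_dup} duplicate association pair(s) removed", stacklevel=2)
    mirna_ids = sorted({m for m, _ in pairs})
    disease_ids = sorted({d for _, d in pairs})
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    Y = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in pairs:
        Y[mi[m], di[d]] = 1.0
    return AssociationMatrix(mirna_ids, disease_ids, Y)


def write_association_file(assoc: AssociationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#mirna_id\tdisease_id\n")
        rows, cols = np.nonzero(assoc.Y)
        for i, j in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")


_TREE_NUMBER = re.compile(r"^[A-Za-z]*\d+(\.\d+)*$")


def _tree_number_parent(tn: str) -> str | None:
    if "." not in tn:
        return None
    return tn.rsplit(".", 1)[0]


def parse_ontology_file(path) -> DiseaseOntology:
    """Parse a disease DAG file.

    Two dialects are accepted.  With section headers ``[edges]`` and
    ``[mapping]`` the file lists explicit ``term<TAB>parent`` links followed
    by ``disease<TAB>term`` assignments.  Without section headers every line
    is read as ``disease_id<TAB>tree_number`` and parent links are derived by
    truncating the last dotted component of each tree number (MeSH style).
    """
    path = Path(path)
    lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            lines.append((lineno, stripped))
    if not lines:
        raise FormatError(f"ontology file {path}: no records")

    nodes: set[str] = set()
    parent_links: dict[str, set[str]] = {}
    disease_to_terms: dict[str, set[str]] = {}

    def add_link(child: str, parent: str) -> None:
        nodes.update((child, parent))
        parent_links.setdefault(child, set()).add(parent)

    if any(line in ("[edges]", "[mapping]") for _, line in lines):
        section = None
        for lineno, line in lines:
            if line in ("[edges]", "[mapping]"):
                section = line
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"ontology file {path}, line {lineno}: expected 2 fields")
            a, b = (f.strip() for f in fields)
            if section == "[edges]":
                add_link(a, b)
            elif section == "[mapping]":
                nodes.add(b)
                disease_to_terms.setdefault(a, set()).add(b)
            else:
                raise FormatError(f"ontology file {path}, line {lineno}: record before section header")
    else:
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"ontology file {path}, line {lineno}: expected 2 fields")
            disease, tn = (f.strip() for f in fields)
            if not _TREE_NUMBER.match(tn):
                raise FormatError(
                    f"ontology file {path}, line {lineno}: {tn!r} is not a tree number"
                )
            nodes.add(tn)
            disease_to_terms.setdefault(disease, set()).add(tn)
            cur = tn
            while (parent := _tree_number_parent(cur)) is not None:
                add_link(cur, parent)
                cur = parent
    return DiseaseOntology(nodes=nodes, parent_links=parent_links, disease_to_terms=disease_to_terms)


def parse_gene_network_file(path) -> GeneFunctionalNetwork:
    genes: set[str] = set()
    edges: dict[frozenset, float] = {}
    for lineno, (a, b, score) in _records(path, 3, "gene network file"):
        if a == b:
            raise FormatError(f"gene network file {path}, line {lineno}: self-loop {a!r}")
        try:
            lls = float(score)
        except ValueError as exc:
            raise FormatError(
                f"gene network file {path}, line {lineno}: bad LLS score {score!r}"
            ) from exc
        genes.update((a, b))
        edges[frozenset((a, b))] = lls
    if not edges:
        raise FormatError(f"gene network file {path}: no edges")
    return GeneFunctionalNetwork(gene_ids=genes, edges=edges)


def parse_disease_gene_file(path) -> DiseaseGeneMap:
    mapping: dict[str, set[str]] = {}
    for _lineno, (disease, gene) in _records(path, 2, "disease-gene file"):
        mapping.setdefault(disease, set()).add(gene)
    return DiseaseGeneMap(mapping=mapping)


def parse_fasta_file(path) -> SequenceSet:
    """Parse miRNA sequences; DNA-style T is mapped to U, case upper-folded."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            raise FormatError(f"FASTA {path}: empty sequence for {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"FASTA {path}: no sequences")
    return SequenceSet(sequences=sequences)


def load_dataset(assoc_path, ontology_path, gene_net_path, disease_gene_path, fasta_path) -> Dataset:
    """Load and align all five inputs on the association file's universe.

    The association file defines the canonical (sorted) miRNA and disease
    orderings.  Entities missing from an auxiliary source are kept and listed
    in the returned report; downstream kernel builders substitute their
    fallback rows for them.
    """
    assoc = parse_association_file(assoc_path)
    ontology = parse_ontology_file(ontology_path)
    gene_net = parse_gene_network_file(gene_net_path)
    disease_genes = parse_disease_gene_file(disease_gene_path)
    sequences = parse_fasta_file(fasta_path)

    report = {
        "n_mirnas": assoc.p,
        "n_diseases": assoc.q,
        "n_associations": int(assoc.Y.sum()),
        "diseases_without_ontology": sorted(
            d for d in assoc.disease_ids if not ontology.terms_for(d)
        ),
        "diseases_without_genes": sorted(
            d for d in assoc.disease_ids if not disease_genes.genes_for(d)
        ),
        "mirnas_without_sequence": sorted(
            m for m in assoc.mirna_ids if m not in sequences.sequences
        ),
    }
    logger.info(
        "loaded dataset: %d miRNAs, %d diseases, %d associations; "
        "%d disease(s) lack ontology terms, %d lack gene sets, "
        "%d miRNA(s) lack sequences",
        report["n_mirnas"],
        report["n_diseases"],
        report["n_associations"],
        len(report["diseases_without_ontology"]),
        len(report["diseases_without_genes"]),
        len(report["mirnas_without_sequence"]),
    )
    return Dataset(assoc, ontology, gene_net, disease_genes, sequences, report)


def write_matrix(ids_rows: list[str], ids_cols: list[str], M: np.ndarray, path) -> None:
    """Write a labeled matrix as TSV (full float precision)."""
    df = pd.DataFrame(M, index=ids_rows, columns=ids_cols)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path) -> tuple[list[str], list[str], np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot read labeled matrix from {path}: {exc}") from exc
    if df.empty and df.shape[1] == 0:
        raise FormatError(f"matrix file {path} is empty")
    return [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_kernel(kernel, path) -> None:
    """Write a SimilarityKernel as labeled TSV (see :func:`read_kernel`)."""
    write_matrix(kernel.ids, kernel.ids, kernel.K, path)


def read_kernel(path, axis: str = "miRNA", name: str = "kernel"):
    """Read a labeled square similarity matrix written by :func:`write_kernel`."""
    from .kernels import SimilarityKernel

    rows, cols, M = read_matrix(path)
    if rows != cols or M.shape[0] != M.shape[1]:
        raise FormatError(f"kernel file {path}: matrix is not square with matching labels")
    return SimilarityKernel(axis=axis, ids=rows, K=M, name=name)
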