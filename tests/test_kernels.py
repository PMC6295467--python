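import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdaskf.io import (
    AssociationMatrix,
    DiseaseGeneMap,
    DiseaseOntology,
    GeneFunctionalNetwork,
    SequenceSet,
)
from mdaskf.kernels import (
    SimilarityKernel,
    build_all_kernels,
    disease_functional_kernel,
    disease_semantic_kernel,
    hamming_profile_kernel,
    misim_kernel,
    normalized_lls,
    semantic_profile,
    sequence_kernel,
)


def nw_oracle(a: str, b: str, match=1.0, mismatch=-1.0, gap=-1.0) -> float:
    """Independent quadratic-space global-alignment DP."""
    m, n = len(a), len(b)
    D = np.zeros((m + 1, n + 1))
    D[:, 0] = gap * np.arange(m + 1)
    D[0, :] = gap * np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = D[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            D[i, j] = max(diag, D[i - 1, j] + gap, D[i, j - 1] + gap)
    return D[m, n]


class TestSemanticProfile:
    def test_chain_scores_decay_by_delta(self, chain_ontology):
        prof = semantic_profile(chain_ontology, "D")
        assert prof.scores == {"d": 1.0, "a": 0.5, "root": 0.25}
        assert prof.dv == pytest.approx(1.75)

    def test_isolated_node_has_dv_one(self):
        onto = DiseaseOntology(nodes={"t"}, parent_links={}, disease_to_terms={"D": {"t"}})
        prof = semantic_profile(onto, "D")
        assert prof.scores == {"t": 1.0}
        assert prof.dv == 1.0

    def test_diamond_takes_best_path(self):
        # two upward paths from d to root, lengths 2 and 3
        onto = DiseaseOntology(
            nodes={"root", "x", "y", "z", "d"},
            parent_links={"d": {"x", "y"}, "x": {"root"}, "y": {"z"}, "z": {"root"}},
            disease_to_terms={"D": {"d"}},
        )
        prof = semantic_profile(onto, "D")
        assert prof.scores["root"] == pytest.approx(max(0.25, 0.125))

    def test_missing_disease_raises(self, chain_ontology):
        with pytest.raises(KeyError):
            semantic_profile(chain_ontology, "nope")

    def test_each_ancestor_is_delta_times_its_best_child(self, synthetic):
        onto = synthetic.ontology
        for d in synthetic.assoc.disease_ids[:10]:
            prof = semantic_profile(onto, d)
            seeds = onto.terms_for(d)
            children: dict[str, list[str]] = {}
            for child in prof.scores:
                for parent in onto.parents(child):
                    if parent in prof.scores:
                        children.setdefault(parent, []).append(child)
            for term, score in prof.scores.items():
                if term in seeds:
                    assert score == 1.0
                else:
                    best = max(prof.scores[c] for c in children[term])
                    assert score == pytest.approx(0.5 * best, abs=1e-12)


class TestDiseaseSemanticKernel:
    def test_self_similarity_is_one(self, sibling_ontology):
        k = disease_semantic_kernel(sibling_ontology, ["D1", "D2"])
        assert np.allclose(np.diag(k.K), 1.0)

    def test_siblings_share_one_third(self, sibling_ontology):
        k = disease_semantic_kernel(sibling_ontology, ["D1", "D2"])
        assert k.K[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_nested_chain_value(self, chain_ontology):
        k = disease_semantic_kernel(chain_ontology, ["D", "A"])
        assert k.K[0, 1] == pytest.approx(9.0 / 13.0, abs=1e-12)

    def test_disjoint_components_share_nothing(self):
        onto = DiseaseOntology(
            nodes={"t1", "t2"}, parent_links={},
            disease_to_terms={"D1": {"t1"}, "D2": {"t2"}},
        )
        k = disease_semantic_kernel(onto, ["D1", "D2"])
        assert k.K[0, 1] == 0.0

    def test_missing_disease_gets_fallback_row(self, sibling_ontology):
        k = disease_semantic_kernel(sibling_ontology, ["D1", "D2", "D3"])
        assert k.K[2, 2] == 1.0
        assert k.K[2, 0] == k.K[2, 1] == 0.0


@pytest.fixture
def small_gene_net():
    # min raw score 1, max 5; (g1, g2) normalizes to (4-1)/(5-1) = 0.75
    return GeneFunctionalNetwork(
        gene_ids={"g1", "g2", "g3", "g4"},
        edges={
            frozenset(("g1", "g2")): 4.0,
            frozenset(("g3", "g4")): 1.0,
            frozenset(("g2", "g3")): 5.0,
        },
    )


class TestDiseaseFunctionalKernel:
    def test_lls_min_max_normalization(self):
        net = GeneFunctionalNetwork(
            gene_ids={"a", "b", "c", "d"},
            edges={frozenset(("a", "b")): 2.0, frozenset(("b", "c")): 1.0,
                   frozenset(("c", "d")): 3.0},
        )
        assert normalized_lls(net)[frozenset(("a", "b"))] == pytest.approx(0.5)

    def test_identical_singleton_sets_score_one(self, small_gene_net):
        dgm = DiseaseGeneMap({"D1": {"g1"}, "D2": {"g1"}})
        k = disease_functional_kernel(small_gene_net, dgm, ["D1", "D2"])
        assert k.K[0, 1] == pytest.approx(1.0)

    def test_single_edge_pair_scores_normalized_lls(self, small_gene_net):
        dgm = DiseaseGeneMap({"D1": {"g1"}, "D2": {"g2"}})
        k = disease_functional_kernel(small_gene_net, dgm, ["D1", "D2"])
        assert k.K[0, 1] == pytest.approx(0.75, abs=1e-12)

    def test_unconnected_gene_sets_score_zero(self, small_gene_net):
        dgm = DiseaseGeneMap({"D1": {"g1"}, "D2": {"g4"}})
        k = disease_functional_kernel(small_gene_net, dgm, ["D1", "D2"])
        assert k.K[0, 1] == 0.0

    def test_empty_gene_set_gets_fallback(self, small_gene_net):
        dgm = DiseaseGeneMap({"D1": {"g1"}})
        k = disease_functional_kernel(small_gene_net, dgm, ["D1", "D2"])
        assert k.K[1, 1] == 1.0 and k.K[0, 1] == 0.0

    def test_degenerate_normalization_is_an_error(self):
        net = GeneFunctionalNetwork(gene_ids={"a", "b"}, edges={frozenset(("a", "b")): 2.0})
        with pytest.raises(ValueError, match="degenerate"):
            disease_functional_kernel(net, DiseaseGeneMap({"D": {"a"}}), ["D"])


class TestMisimKernel:
    def _kd(self, sim01):
        return SimilarityKernel("disease", ["d1", "d2"],
                                np.array([[1.0, sim01], [sim01, 1.0]]), "semantic")

    def test_identical_disease_sets_score_one(self):
        am = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [1, 0]]))
        k = misim_kernel(am, self._kd(0.4))
        assert k.K[0, 1] == pytest.approx(1.0)

    def test_singleton_cross_sets_average_best_match(self):
        am = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [0, 1]]))
        k = misim_kernel(am, self._kd(0.4))
        assert k.K[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_zero_semantic_overlap_scores_zero(self):
        am = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [0, 1]]))
        k = misim_kernel(am, self._kd(0.0))
        assert k.K[0, 1] == 0.0

    def test_empty_disease_set_gets_fallback(self):
        # m2 loses all its diseases (as can happen under CV masking)
        am = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.array([[1, 1], [0, 0]]))
        k = misim_kernel(am, self._kd(0.4))
        assert k.K[1, 1] == 1.0
        assert k.K[0, 1] == 0.0

    def test_axis_mismatch_is_an_error(self):
        am = AssociationMatrix(["m1"], ["d1", "d2"], np.array([[1, 0]]))
        bad = SimilarityKernel("disease", ["d2", "d1"], np.eye(2), "semantic")
        with pytest.raises(ValueError, match="axis"):
            misim_kernel(am, bad)


class TestSequenceKernel:
    def test_identical_sequences_score_one(self):
        seqs = SequenceSet({"m1": "ACGUACGU", "m2": "ACGUACGU"})
        k = sequence_kernel(seqs)
        assert k.K[0, 1] == pytest.approx(1.0)

    def test_single_mismatch_hand_value(self):
        # NW("ACGU","ACGA") = 3 matches - 1 mismatch = 2; self-scores 4
        seqs = SequenceSet({"m1": "ACGU", "m2": "ACGA"})
        k = sequence_kernel(seqs)
        assert k.K[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_negative_alignment_clipped_to_zero(self):
        seqs = SequenceSet({"m1": "AAAAAA", "m2": "CCCCCC"})
        k = sequence_kernel(seqs)
        assert k.K[0, 1] == 0.0

    def test_agrees_with_dp_oracle_on_random_pairs(self, rng):
        alphabet = np.array(list("ACGU"))
        names, seqs = [], {}
        for i in range(8):
            L = int(rng.integers(3, 13))
            names.append(f"m{i}")
            seqs[f"m{i}"] = "".join(rng.choice(alphabet, size=L))
        k = sequence_kernel(SequenceSet(seqs), names)
        for i in range(8):
            for j in range(i + 1, 8):
                nw = nw_oracle(seqs[names[i]], seqs[names[j]])
                expect = max(0.0, nw / max(len(seqs[names[i]]), len(seqs[names[j]])))
                assert k.K[i, j] == pytest.approx(expect, abs=1e-12), (i, j)

    def test_missing_sequence_gets_fallback(self):
        seqs = SequenceSet({"m1": "ACGU"})
        k = sequence_kernel(seqs, ["m1", "m2"])
        assert k.K[1, 1] == 1.0 and k.K[0, 1] == 0.0


class TestHammingProfileKernel:
    def test_hand_counted_column_pair(self):
        Y = np.array([[1, 1], [0, 1], [1, 0], [0, 0]], dtype=float)
        k = hamming_profile_kernel(AssociationMatrix(list("abcd"), ["d1", "d2"], Y), "disease")
        assert k.K[0, 1] == pytest.approx(0.5)

    def test_identical_profiles_score_one(self):
        Y = np.array([[1, 1], [0, 0]], dtype=float)
        k = hamming_profile_kernel(AssociationMatrix(["m1", "m2"], ["d1", "d2"], Y), "disease")
        assert k.K[0, 1] == 1.0

    def test_complementary_profiles_score_zero(self):
        Y = np.array([[1, 0], [0, 1]], dtype=float)
        k = hamming_profile_kernel(AssociationMatrix(["m1", "m2"], ["d1", "d2"], Y), "disease")
        assert k.K[0, 1] == 0.0

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, deadline=None)
    def test_matches_elementwise_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        p, q = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        Y = (rng.random((p, q)) < 0.5).astype(float)
        am = AssociationMatrix([f"m{i}" for i in range(p)], [f"d{j}" for j in range(q)], Y)
        for axis, profiles in (("miRNA", Y), ("disease", Y.T)):
            k = hamming_profile_kernel(am, axis)
            n, L = profiles.shape
            for i in range(n):
                for j in range(n):
                    expect = 1.0 - np.sum(profiles[i] != profiles[j]) / L
                    assert k.K[i, j] == pytest.approx(expect, abs=1e-12)


class TestKernelInvariants:
    def test_all_base_kernels_symmetric_unit_diag_bounded(self, dataset):
        for name, k in build_all_kernels(dataset).items():
            np.testing.assert_allclose(k.K, k.K.T, atol=1e-12, err_msg=name)
            np.testing.assert_allclose(np.diag(k.K), 1.0, atol=1e-12, err_msg=name)
            assert k.K.min() >= 0.0 and k.K.max() <= 1.0 + 1e-12, name
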