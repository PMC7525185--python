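import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circlink.errors import (
    BandwidthUndefinedError,
    ConfigurationError,
    UnknownTermError,
    ZeroVarianceError,
)
from circlink.io_net import DiseaseDAG
from circlink.kernels import (
    AlignmentParams,
    SemanticDecay,
    alignment_score,
    assemble_kernel_stacks,
    expression_similarity,
    gip_kernel,
    regulatory_similarity,
    semantic_kernel,
    semantic_similarity,
    semantic_value,
    sequence_similarity,
)
from oracles import enumerate_global_alignments

import networkx as nx


def make_dag(edges, term_of=None):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return DiseaseDAG(graph=g, term_of=term_of or {t: t for t in g.nodes})


class TestRegulatorySimilarity:
    def test_identical_sets_score_one(self):
        s = {"m1", "m2", "m3"}
        assert regulatory_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_sets_score_zero(self):
        assert regulatory_similarity({"m1"}, {"m2", "m3"}) == 0.0

    def test_partial_overlap_hand_value(self):
        # |{m1}| / sqrt(2 * 3) = 1/sqrt(6)
        got = regulatory_similarity({"m1", "m2"}, {"m1", "m3", "m4"})
        assert got == pytest.approx(1.0 / math.sqrt(6.0), abs=1e-12)

    def test_empty_set_scores_zero(self):
        assert regulatory_similarity(set(), {"m1"}) == 0.0

    def test_literal_product_form(self):
        got = regulatory_similarity({"m1", "m2"}, {"m1", "m3", "m4"}, form="product")
        assert got == pytest.approx(1.0 / 6.0)


class TestExpressionSimilarity:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0])
        assert expression_similarity(x, x) == pytest.approx(1.0)

    def test_anticorrelation_clipped_to_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert expression_similarity(x, -x) == 0.0

    def test_hand_pearson_value(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        # brute-force Pearson from its definition
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert expression_similarity(x, y) == pytest.approx(r)
        assert expression_similarity(x, y) == pytest.approx(0.98198, abs=1e-5)

    def test_constant_vector_raises(self):
        with pytest.raises(ZeroVarianceError):
            expression_similarity(np.ones(3), np.array([1.0, 2.0, 3.0]))


class TestGipKernel:
    def test_orthonormal_profiles_hand_value(self):
        # gamma = 2 / (1 + 1) = 1; ||p1 - p2||^2 = 2
        k = gip_kernel(np.array([[1, 0], [0, 1]]), ids=("a", "b"))
        assert k.matrix[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_identical_rows_score_one(self, rng):
        profiles = rng.integers(0, 2, size=(4, 10))
        profiles[2] = profiles[0]
        k = gip_kernel(profiles, ids=tuple("abcd"))
        assert k.matrix[0, 2] == pytest.approx(1.0)

    def test_diagonal_exactly_one(self, rng):
        k = gip_kernel(rng.integers(0, 2, size=(6, 12)), ids=tuple("abcdef"))
        np.testing.assert_array_equal(np.diag(k.matrix), 1.0)

    def test_similarity_decreases_with_hamming_distance(self):
        base = np.zeros((4, 8), dtype=int)
        base[0, :4] = 1
        base[1, :4] = 1          # distance 0
        base[2, :4] = [1, 1, 1, 0]  # distance 1
        base[3, :4] = [1, 1, 0, 0]  # distance 2
        k = gip_kernel(base, ids=tuple("abcd")).matrix
        assert k[0, 1] > k[0, 2] > k[0, 3]

    def test_all_zero_profiles_have_undefined_bandwidth(self):
        with pytest.raises(BandwidthUndefinedError):
            gip_kernel(np.zeros((3, 5)), ids=tuple("abc"))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_kernel_invariants_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(0, 2, size=(5, 9))
        if p.sum() == 0:
            p[0, 0] = 1
        k = gip_kernel(p, ids=tuple("abcde")).matrix
        assert np.isfinite(k).all()
        assert (k >= 0).all() and (k <= 1).all()
        np.testing.assert_allclose(k, k.T, atol=1e-8)


class TestSemanticSimilarity:
    def test_leaf_with_single_parent(self):
        dag = make_dag([("r", "d")])
        contrib, dv = semantic_value(dag, "d")
        assert contrib == {"d": 1.0, "r": 0.5}
        assert dv == pytest.approx(1.5)

    def test_root_alone_has_value_one(self):
        dag = make_dag([("r", "d")])
        _, dv = semantic_value(dag, "r")
        assert dv == pytest.approx(1.0)

    def test_chain_decays_geometrically(self):
        dag = make_dag([("root", "a"), ("a", "d")])
        _, dv = semantic_value(dag, "d")
        assert dv == pytest.approx(1.0 + 0.5 + 0.25)

    def test_self_similarity_is_one(self):
        dag = make_dag([("r", "a"), ("a", "d")])
        assert semantic_similarity(dag, "d", "d") == pytest.approx(1.0)

    def test_siblings_share_only_the_root(self):
        dag = make_dag([("r", "d1"), ("r", "d2")])
        assert semantic_similarity(dag, "d1", "d2") == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_disconnected_components_score_zero(self):
        dag = make_dag([("r1", "d1"), ("r2", "d2")])
        assert semantic_similarity(dag, "d1", "d2") == 0.0

    def test_adding_a_shared_ancestor_never_decreases_the_score(self):
        shallow = make_dag([("r", "d1"), ("r", "d2")])
        # same siblings, plus a shared grandparent above the old root
        deep = make_dag([("g", "r"), ("r", "d1"), ("r", "d2")])
        assert semantic_similarity(deep, "d1", "d2") >= semantic_similarity(
            shallow, "d1", "d2"
        )

    def test_unknown_term_raises(self):
        dag = make_dag([("r", "d")])
        with pytest.raises(UnknownTermError):
            semantic_value(dag, "nope")

    def test_max_over_children_not_sum(self):
        # diamond: t has two children on paths to d; contribution is the max
        dag = make_dag([("t", "a"), ("t", "b"), ("a", "d"), ("b", "d")])
        contrib, _ = semantic_value(dag, "d", SemanticDecay(0.5))
        assert contrib["t"] == pytest.approx(0.25)  # 0.5 * max(0.5, 0.5)

    def test_kernel_diagonal_and_symmetry(self):
        dag = make_dag([("r", "d1"), ("r", "d2"), ("d2", "d3")])
        k = semantic_kernel(dag, ("d1", "d2", "d3")).matrix
        np.testing.assert_array_equal(np.diag(k), 1.0)
        np.testing.assert_allclose(k, k.T)


class TestSequenceSimilarity:
    def test_self_alignment_scores_one(self):
        assert sequence_similarity("ACGTACGT", "ACGTACGT") == pytest.approx(1.0)

    def test_reversed_sequence_oracle_value(self):
        best, sims = enumerate_global_alignments("ACGT", "TGCA")
        assert alignment_score("ACGT", "TGCA") == pytest.approx(best)
        assert any(
            math.isclose(sequence_similarity("ACGT", "TGCA"), s) for s in sims
        )

    def test_prefix_alignment_between_zero_and_one(self):
        best, sims = enumerate_global_alignments("AAAA", "AAAATTTT")
        got = sequence_similarity("AAAA", "AAAATTTT")
        assert alignment_score("AAAA", "AAAATTTT") == pytest.approx(best)
        assert any(math.isclose(got, s) for s in sims)
        assert 0.0 < got < 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sequence_similarity("", "ACGT")

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            sequence_similarity("ACGU", "ACGT")

    def test_matches_exhaustive_oracle_on_short_pairs(self, rng):
        # every pair up to length 3, then a seeded sample of longer pairs
        short = ["".join(p) for L in (1, 2, 3) for p in itertools.product("ACGT", repeat=L)]
        pairs = list(itertools.combinations(short[::3], 2))
        letters = np.array(list("ACGTN"))
        for _ in range(40):
            a = "".join(rng.choice(letters, rng.integers(4, 7)))
            b = "".join(rng.choice(letters[:4], rng.integers(4, 7)))
            pairs.append((a, b))
        for a, b in pairs:
            best, sims = enumerate_global_alignments(a, b)
            assert alignment_score(a, b) == pytest.approx(best), (a, b)
            got = sequence_similarity(a, b)
            assert any(math.isclose(got, s, abs_tol=1e-12) for s in sims), (a, b)


class TestAssembleKernelStacks:
    def test_full_study_yields_four_and_seven(self, kernel_stacks):
        circ_k, dis_k = kernel_stacks
        assert [k.name for k in circ_k] == ["SC_Seq", "SC_RG", "SC_EP", "SC_GIP"]
        assert len(dis_k) == 7 and dis_k[:2][0].name == "SD_Dss"

    def test_every_kernel_satisfies_invariants(self, kernel_stacks):
        for k in itertools.chain(*kernel_stacks):
            m = k.matrix
            assert np.isfinite(m).all(), k.name
            assert m.min() >= 0 and m.max() <= 1, k.name
            np.testing.assert_allclose(m, m.T, atol=1e-8, err_msg=k.name)

    def test_missing_expression_degrades_to_three_kernels(self, study):
        circ_k, _ = assemble_kernel_stacks(
            study.network,
            sequences=study.sequences,
            dag=study.dag,
            precomputed=study.precomputed,
        )
        assert [k.name for k in circ_k] == ["SC_Seq", "SC_RG", "SC_GIP"]

    def test_fewer_than_two_disease_kernels_is_an_error(self, study):
        with pytest.raises(ConfigurationError):
            assemble_kernel_stacks(study.network, sequences=study.sequences)
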