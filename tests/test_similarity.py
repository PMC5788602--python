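import math

import numpy as np
import pytest

from sscmda.datamodel import AssociationMatrix, DiseaseDAGSet, SimilarityMatrix
from sscmda.similarity import (
    GIPParams,
    SemanticParams,
    gip_similarity,
    integrate_disease,
    integrate_mirna,
    semantic_contribution_m1,
    semantic_similarity_m1,
    semantic_similarity_m2,
)

from conftest import random_dag_set


def exhaustive_contribution(dags, disease, delta):
    """Oracle: enumerate every directed path from the disease up to each term."""
    members = dags.ancestors(disease)
    best = {}

    def walk(term, depth):
        best[term] = max(best.get(term, 0.0), delta**depth)
        for parent in dags.parents(term):
            if parent in members:
                walk(parent, depth + 1)

    walk(disease, 0)
    return best


class TestContributionModel1:
    def test_chain(self, chain_dags):
        contrib, dv1 = semantic_contribution_m1(chain_dags, "D", SemanticParams(delta=0.5))
        assert contrib == {"D": 1.0, "p": 0.5, "g": 0.25}
        assert dv1 == pytest.approx(1.75)

    def test_isolated_disease(self):
        dags = DiseaseDAGSet([], {"D"})
        contrib, dv1 = semantic_contribution_m1(dags, "D")
        assert contrib == {"D": 1.0}
        assert dv1 == 1.0

    def test_diamond_takes_max_path(self):
        dags = DiseaseDAGSet([("D", "a"), ("D", "b"), ("a", "r"), ("b", "r")], set())
        contrib, dv1 = semantic_contribution_m1(dags, "D", SemanticParams(delta=0.5))
        assert contrib["r"] == 0.25
        assert dv1 == pytest.approx(2.25)

    def test_unknown_disease_errors(self, chain_dags):
        with pytest.raises(KeyError):
            semantic_contribution_m1(chain_dags, "nope")

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            dags = random_dag_set(rng)
            delta = 0.5
            for d in list(dags.vocabulary)[:4]:
                contrib, _ = semantic_contribution_m1(dags, d, SemanticParams(delta=delta))
                assert contrib == pytest.approx(exhaustive_contribution(dags, d, delta))


class TestSemanticSimilarityM1:
    def test_shared_parent(self):
        dags = DiseaseDAGSet([("d1", "a"), ("d2", "a")], set())
        sim = semantic_similarity_m1(dags, SemanticParams(delta=0.5), diseases=["d1", "d2"])
        assert sim.values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_disjoint_dags_zero(self):
        dags = DiseaseDAGSet([("d1", "a"), ("d2", "b")], set())
        sim = semantic_similarity_m1(dags, diseases=["d1", "d2"])
        assert sim.values[0, 1] == 0.0

    def test_self_similarity_one(self, chain_dags):
        sim = semantic_similarity_m1(chain_dags)
        assert np.diag(sim.values) == pytest.approx(np.ones(sim.n))

    def test_delta_one_counts_shared_terms(self):
        # with no decay the score reduces to 2|T_i & T_j| / (|T_i| + |T_j|)
        rng = np.random.default_rng(3)
        dags = random_dag_set(rng)
        sim = semantic_similarity_m1(dags, SemanticParams(delta=1.0))
        for i, di in enumerate(sim.names):
            for j, dj in enumerate(sim.names):
                ti, tj = dags.ancestors(di), dags.ancestors(dj)
                expected = 2 * len(ti & tj) / (len(ti) + len(tj))
                assert sim.values[i, j] == pytest.approx(expected)

    def test_bounds_and_symmetry_on_random_forests(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            dags = random_dag_set(rng)
            sim = semantic_similarity_m1(dags)
            assert (sim.values >= 0).all() and (sim.values <= 1 + 1e-12).all()
            np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-12)

    def test_added_shared_ancestor_never_lowers_numerator(self):
        base = DiseaseDAGSet([("d1", "a"), ("d2", "a")], set())
        extended = DiseaseDAGSet([("d1", "a"), ("d2", "a"), ("a", "r")], set())
        p = SemanticParams(delta=0.5)
        c1b, _ = semantic_contribution_m1(base, "d1", p)
        c1e, _ = semantic_contribution_m1(extended, "d1", p)
        shared_b = sum(2 * c1b[t] for t in {"a"})
        shared_e = sum(2 * c1e[t] for t in {"a", "r"})
        assert shared_e >= shared_b


class TestSemanticSimilarityM2:
    def _four_disease_set(self):
        return DiseaseDAGSet([("d1", "a"), ("d2", "a")], {"d1", "d2", "a", "b"})

    def test_worked_example(self):
        dags = self._four_disease_set()
        sim = semantic_similarity_m2(dags)
        names = sim.names
        i, j = names.index("d1"), names.index("d2")
        d2_a = -math.log(3 / 4)
        d2_d1 = -math.log(1 / 4)
        dv2_d1 = d2_a + d2_d1
        expected = 2 * d2_a / (2 * dv2_d1)
        assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)
        assert sim.values[i, j] == pytest.approx(0.17185, abs=1e-4)

    def test_ubiquitous_term_contributes_nothing(self):
        # with the disease set restricted to {d1, d2}, term r sits in every
        # DAG and has information content -log(1) = 0
        dags = DiseaseDAGSet([("d1", "r"), ("d2", "r")], set(), diseases=["d1", "d2"])
        sim = semantic_similarity_m2(dags)
        # shared ancestry is exactly {r} with zero contribution -> similarity 0
        i, j = sim.names.index("d1"), sim.names.index("d2")
        assert sim.values[i, j] == 0.0

    def test_self_similarity_one(self):
        sim = semantic_similarity_m2(self._four_disease_set())
        assert np.diag(sim.values) == pytest.approx(np.ones(sim.n))

    def test_invariant_to_log_base(self):
        dags = self._four_disease_set()
        nat = semantic_similarity_m2(dags, SemanticParams(log_base=None))
        b10 = semantic_similarity_m2(dags, SemanticParams(log_base=10))
        np.testing.assert_allclose(nat.values, b10.values, atol=1e-12)


class TestGIP:
    def test_identical_profiles_similarity_one(self):
        A = AssociationMatrix(np.array([[1, 0], [1, 0]]), ["d1", "d2"], ["m1", "m2"])
        gd = gip_similarity(A, "disease")
        assert gd.values[0, 1] == pytest.approx(1.0)

    def test_identity_matrix_hand_value(self):
        A = AssociationMatrix(np.eye(2, dtype=int), ["d1", "d2"], ["m1", "m2"])
        gd = gip_similarity(A, "disease", GIPParams(beta_prime_d=1.0))
        # mean squared profile norm 1 -> beta 1 -> exp(-2)
        assert gd.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)

    def test_doubling_bandwidth_squares_entries(self):
        rng = np.random.default_rng(5)
        A = AssociationMatrix((rng.random((6, 8)) < 0.4).astype(int),
                              [f"d{i}" for i in range(6)], [f"m{j}" for j in range(8)])
        if A.values.sum() == 0:
            pytest.skip("degenerate draw")
        g1 = gip_similarity(A, "disease", GIPParams(beta_prime_d=1.0)).values
        g2 = gip_similarity(A, "disease", GIPParams(beta_prime_d=2.0)).values
        np.testing.assert_allclose(g2, g1**2, atol=1e-12)

    def test_all_zero_matrix_errors(self):
        A = AssociationMatrix(np.zeros((2, 2), dtype=int), ["d1", "d2"], ["m1", "m2"])
        with pytest.raises(ValueError, match="bandwidth undefined"):
            gip_similarity(A, "disease")

    def test_kernel_is_positive_semidefinite(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            A = AssociationMatrix(
                (rng.random((7, 9)) < 0.3).astype(int),
                [f"d{i}" for i in range(7)],
                [f"m{j}" for j in range(9)],
            )
            if A.values.sum() == 0:
                continue
            for axis in ("disease", "mirna"):
                g = gip_similarity(A, axis)
                assert np.linalg.eigvalsh(g.values).min() >= -1e-10


class TestIntegration:
    def test_semantic_branch_averages(self):
        ss1 = SimilarityMatrix(np.array([[1, 0.4], [0.4, 1]]), ["d1", "d2"], "semantic1")
        ss2 = SimilarityMatrix(np.array([[1, 0.2], [0.2, 1]]), ["d1", "d2"], "semantic2")
        gd = SimilarityMatrix(np.array([[1, 0.7], [0.7, 1]]), ["d1", "d2"], "gip")
        sd = integrate_disease(ss1, ss2, gd)
        assert sd.values[0, 1] == pytest.approx(0.3)

    def test_gip_fallback_without_annotation(self):
        ss1 = SimilarityMatrix(np.eye(1), ["d1"], "semantic1")
        ss2 = SimilarityMatrix(np.eye(1), ["d1"], "semantic2")
        gd = SimilarityMatrix(np.array([[1, 0.7], [0.7, 1]]), ["d1", "d2"], "gip")
        sd = integrate_disease(ss1, ss2, gd)
        assert sd.values[0, 1] == pytest.approx(0.7)

    def test_zero_semantic_overlap_falls_back(self):
        ss1 = SimilarityMatrix(np.eye(2), ["d1", "d2"], "semantic1")
        ss2 = SimilarityMatrix(np.eye(2), ["d1", "d2"], "semantic2")
        gd = SimilarityMatrix(np.array([[1, 0.7], [0.7, 1]]), ["d1", "d2"], "gip")
        sd = integrate_disease(ss1, ss2, gd)
        assert sd.values[0, 1] == pytest.approx(0.7)

    def test_mirna_functional_preferred(self):
        ms = SimilarityMatrix(np.array([[1, 0.6], [0.6, 1]]), ["m1", "m2"], "functional")
        gr = SimilarityMatrix(np.array([[1, 0.25], [0.25, 1]]), ["m1", "m2"], "gip")
        sr = integrate_mirna(ms, gr)
        assert sr.values[0, 1] == pytest.approx(0.6)

    def test_mirna_absent_from_functional_falls_back(self):
        ms = SimilarityMatrix(np.eye(1), ["m1"], "functional")
        gr = SimilarityMatrix(np.array([[1, 0.25], [0.25, 1]]), ["m1", "m2"], "gip")
        sr = integrate_mirna(ms, gr)
        assert sr.values[0, 1] == pytest.approx(0.25)

    def test_zero_functional_entry_falls_back(self):
        ms = SimilarityMatrix(np.array([[1, 0.0], [0.0, 1]]), ["m1", "m2"], "functional")
        gr = SimilarityMatrix(np.array([[1, 0.25], [0.25, 1]]), ["m1", "m2"], "gip")
        sr = integrate_mirna(ms, gr)
        assert sr.values[0, 1] == pytest.approx(0.25)

    def test_integrated_diagonal_is_one(self, bench_sims):
        SD, SR = bench_sims
        assert np.diag(SD.values) == pytest.approx(np.ones(SD.n))
        assert np.diag(SR.values) == pytest.approx(np.ones(SR.n))
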