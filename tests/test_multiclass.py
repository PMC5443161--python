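"""Binary decompositions: problem building, coupling, routing."""

import itertools

import numpy as np
import pytest

from rpbci.multiclass import (ALL_REST, MOVEMENT, DecompositionScheme,
                              PairwiseProbabilities, build_binary_problems,
                              classify, pairwise_couple, required_problems)

from conftest import make_epochset


def oracle_node_probs(true_label, scheme, certainty=1.0):
    """Perfect binary oracles: each node assigns ``certainty`` to the
    side containing the true label."""
    probs = {}
    for pid in required_problems(scheme):
        a, b = pid.split("-") if pid != "RIL" else ("", "")
        if pid == "RIL":
            probs[pid] = {c: (certainty if c == true_label else
                              (1 - certainty) / 2) for c in "RIL"}
            continue
        if b == ALL_REST:
            hit = true_label == a
        elif b == MOVEMENT:
            hit = (true_label == "I") if a == "I" else None
            # a is always "I" for the DBT root
            hit = true_label == "I"
        else:
            if true_label not in (a, b):
                # non-competent node: anything; use 0.5/0.5
                probs[pid] = {a: 0.5, b: 0.5}
                continue
            hit = true_label == a
        probs[pid] = {a: certainty if hit else 1 - certainty,
                      b: 1 - certainty if hit else certainty}
    return probs


class TestBuildBinaryProblems:
    @pytest.fixture()
    def unbalanced(self):
        rng = np.random.default_rng(0)
        return make_epochset(rng, {"L": 90, "R": 90, "I": 180}, n_channels=3,
                             n_samples=10)

    def test_oao_pairs_balanced(self, unbalanced):
        probs = build_binary_problems(DecompositionScheme("oao"), unbalanced,
                                      seed=1)
        assert [p.problem_id for p in probs] == ["R-I", "R-L", "I-L"]
        for p in probs:
            counts = {c: int(np.sum(p.y == c)) for c in set(p.y)}
            assert set(counts.values()) == {90}

    def test_oaa_all_pool_balanced_proportionally(self, unbalanced):
        probs = build_binary_problems(DecompositionScheme("oaa"), unbalanced,
                                      seed=1)
        assert [p.problem_id for p in probs] == ["R-A", "I-A", "L-A"]
        ra = probs[0]
        assert int(np.sum(ra.y == "R")) == 90
        assert int(np.sum(ra.y == ALL_REST)) == 90
        # proportional: the 90:180 L:I pool maps to 30:60
        orig = ra.epochs.labels[ra.y == ALL_REST]
        assert int(np.sum(orig == "L")) == 30
        assert int(np.sum(orig == "I")) == 60

    def test_dbt_root_needs_no_subsampling_at_2to1(self, unbalanced):
        probs = build_binary_problems(DecompositionScheme("dbt"), unbalanced,
                                      seed=1)
        root = probs[0]
        assert root.problem_id == "I-M"
        assert int(np.sum(root.y == "I")) == 180
        assert int(np.sum(root.y == MOVEMENT)) == 180
        assert len(root.epochs) == 360

    def test_exact_balance_invariant_all_schemes(self, unbalanced):
        for kind in ("oao", "oaa", "dbt", "ddag", "mcs"):
            for p in build_binary_problems(DecompositionScheme(kind),
                                           unbalanced, seed=2):
                counts = [int(np.sum(p.y == c)) for c in set(p.y)]
                assert max(counts) - min(counts) == 0

    def test_seeded_and_reproducible(self, unbalanced):
        a = build_binary_problems(DecompositionScheme("oao"), unbalanced, seed=3)
        b = build_binary_problems(DecompositionScheme("oao"), unbalanced, seed=3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.epochs.trial_indices,
                                          pb.epochs.trial_indices)

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(1)
        es = make_epochset(rng, {"L": 5, "I": 5})
        with pytest.raises(ValueError, match="zero epochs"):
            build_binary_problems(DecompositionScheme("oao"), es)


class TestPairwiseCoupling:
    def test_symmetric_input_gives_uniform(self):
        r = np.full((3, 3), 0.5)
        p = pairwise_couple(PairwiseProbabilities(r))
        np.testing.assert_allclose(p, 1 / 3, atol=1e-10)

    def test_recovers_consistent_target(self):
        p_star = np.array([0.5, 0.3, 0.2])
        r = np.zeros((3, 3))
        for i, j in itertools.permutations(range(3), 2):
            r[i, j] = p_star[i] / (p_star[i] + p_star[j])
        p = pairwise_couple(PairwiseProbabilities(r))
        np.testing.assert_allclose(p, p_star, atol=1e-8)

    def test_binary_reduction(self):
        r = np.array([[0.0, 0.9], [0.1, 0.0]])
        p = pairwise_couple(PairwiseProbabilities(r, ["R", "I"]))
        np.testing.assert_allclose(p, [0.9, 0.1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p_star = rng.dirichlet(np.ones(3))
        r = np.zeros((3, 3))
        for i, j in itertools.permutations(range(3), 2):
            r[i, j] = p_star[i] / (p_star[i] + p_star[j])
        p = pairwise_couple(PairwiseProbabilities(r))
        perm = np.array([2, 0, 1])
        r_p = r[np.ix_(perm, perm)]
        p_p = pairwise_couple(PairwiseProbabilities(r_p))
        np.testing.assert_allclose(p_p, p[perm], atol=1e-8)

    def test_inconsistent_input_still_on_simplex(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.05, 0.95, size=(3, 3))
        r = np.triu(r, 1)
        r = r + (1 - r.T) * (np.tril(np.ones((3, 3)), -1))
        np.fill_diagonal(r, 0)
        p = pairwise_couple(PairwiseProbabilities(r))
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)

    def test_rij_sum_constraint_enforced(self):
        r = np.array([[0, 0.9, 0.5], [0.3, 0, 0.5], [0.5, 0.5, 0]])
        with pytest.raises(ValueError, match="equal 1"):
            PairwiseProbabilities(r)


class TestClassifyRouting:
    ALL_SCHEMES = [DecompositionScheme("mcs"), DecompositionScheme("oao"),
                   DecompositionScheme("oaa"), DecompositionScheme("dbt"),
                   DecompositionScheme("ddag", "RIL"),
                   DecompositionScheme("ddag", "ILR"),
                   DecompositionScheme("ddag", "RLI")]

    @pytest.mark.parametrize("scheme", ALL_SCHEMES,
                             ids=lambda s: f"{s.kind}-{s.ddag_order}")
    @pytest.mark.parametrize("truth", ["R", "I", "L"])
    def test_perfect_oracles_return_true_label(self, scheme, truth):
        probs = oracle_node_probs(truth, scheme, certainty=0.98)
        label, diag = classify(scheme, probs)
        assert label == truth

    @pytest.mark.parametrize("scheme", ALL_SCHEMES,
                             ids=lambda s: f"{s.kind}-{s.ddag_order}")
    def test_always_returns_exactly_one_class(self, scheme):
        rng = np.random.default_rng(4)
        for _ in range(25):
            probs = {}
            for pid in required_problems(scheme):
                if pid == "RIL":
                    v = rng.dirichlet(np.ones(3))
                    probs[pid] = dict(zip("RIL", v))
                else:
                    a, b = pid.split("-")
                    q = rng.uniform()
                    probs[pid] = {a: q, b: 1 - q}
            label, _ = classify(scheme, probs)
            assert label in ("R", "I", "L")

    def test_ddag_ril_routing_example(self):
        # root R-vs-L says L; node I-vs-L says I -> label I
        scheme = DecompositionScheme("ddag", "RIL")
        probs = {"R-L": {"R": 0.2, "L": 0.8},
                 "I-L": {"I": 0.7, "L": 0.3},
                 "R-I": {"R": 0.9, "I": 0.1}}
        label, diag = classify(scheme, probs)
        assert label == "I"
        assert diag["route"] == ["R-L", "I-L"]

    def test_oaa_tie_breaks_canonically(self):
        scheme = DecompositionScheme("oaa")
        probs = {"R-A": {"R": 0.6, "A": 0.4},
                 "I-A": {"I": 0.6, "A": 0.4},
                 "L-A": {"L": 0.2, "A": 0.8}}
        label, _ = classify(scheme, probs)
        assert label == "R"  # R precedes I in canonical order

    def test_missing_node_raises(self):
        scheme = DecompositionScheme("dbt")
        with pytest.raises(KeyError, match="I-M"):
            classify(scheme, {"R-L": {"R": 0.5, "L": 0.5}})
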