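"""Unit and property tests for the MUPP-2PL measurement model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import multivariate_normal

from fcassembly import (
    Item, ItemPool, Block, Questionnaire, QuadratureGrid,
    item_endorse_prob, block_prob, block_info,
    build_quadrature, objective_reliability, ReliabilityObjective,
    count_assemblies, ipsativity_bound,
)
from fcassembly import test_info as total_info  # avoid pytest collection
from conftest import enumerate_matchings


def _random_block(rng, D=5):
    d1, d2 = rng.choice(D, size=2, replace=False) + 1
    it1 = Item(id=1, dim=int(d1), a=float(rng.normal(1.5, 0.5)),
               b=float(rng.uniform(-2, 2)))
    it2 = Item(id=2, dim=int(d2), a=float(rng.normal(1.5, 0.5)),
               b=float(rng.uniform(-2, 2)))
    return it1, it2, Block.from_items(it1, it2, D)


class TestItemEndorseProb:
    @pytest.mark.parametrize("a,b,theta,expected", [
        (1.5, 0.0, 0.0, 0.5),                       # logistic at its center
        (2.0, -0.5, 1.0, math.exp(3) / (1 + math.exp(3))),  # c = 1, a*t+c = 3
        (1.5, 0.0, 500.0, 1.0),                     # saturation, no overflow
        (1.5, 0.0, -500.0, 0.0),
    ])
    def test_values(self, a, b, theta, expected):
        item = Item(id=1, dim=1, a=a, b=b)
        assert item_endorse_prob(item, theta) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_intercept_is_minus_ab(self):
        item = Item(id=1, dim=2, a=1.7, b=-0.3)
        assert item.c == pytest.approx(-1.7 * -0.3, abs=1e-15)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            Item(id=1, dim=1, a=float("nan"), b=0.0)
        item = Item(id=1, dim=1, a=1.0, b=0.0)
        with pytest.raises(ValueError):
            item_endorse_prob(item, float("inf"))


class TestBlockProb:
    def test_symmetric_block_is_even_odds(self):
        it = Item(id=1, dim=1, a=1.5, b=0.7)
        it2 = Item(id=2, dim=2, a=1.5, b=0.7)
        b = Block.from_items(it, it2, D=2)
        assert block_prob(b, np.array([0.7, 0.7])) == pytest.approx(0.5)

    def test_hand_value(self):
        # a1 = a2 = 1.5, b1 = -1, b2 = +1: c_j = 1.5 - (-1.5) = 3
        it1 = Item(id=1, dim=1, a=1.5, b=-1.0)
        it2 = Item(id=2, dim=2, a=1.5, b=1.0)
        b = Block.from_items(it1, it2, D=2)
        assert block_prob(b, np.zeros(2)) == pytest.approx(
            math.exp(3) / (1 + math.exp(3)), abs=1e-12)

    def test_matches_pairwise_preference_composition(self):
        """The compensatory-logistic form equals the two-statement
        preference composition p1 q2 / (p1 q2 + q1 p2) to 1e-12."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            it1, it2, blk = _random_block(rng)
            theta = rng.normal(0, 1, size=5)
            p1 = item_endorse_prob(it1, theta[it1.dim - 1])
            p2 = item_endorse_prob(it2, theta[it2.dim - 1])
            composed = p1 * (1 - p2) / (p1 * (1 - p2) + (1 - p1) * p2)
            assert block_prob(blk, theta) == pytest.approx(composed,
                                                           abs=1e-12)

    def test_complement_sums_to_one(self, rng):
        _, _, blk = _random_block(rng)
        theta = rng.normal(size=5)
        p = block_prob(blk, theta)
        swapped = Block(first=blk.second, second=blk.first, s=-blk.s,
                        c_j=-blk.c_j)
        assert p + block_prob(swapped, theta) == pytest.approx(1.0, abs=1e-15)

    def test_dimension_mismatch(self):
        _, _, blk = _random_block(np.random.default_rng(0))
        with pytest.raises(ValueError):
            block_prob(blk, np.zeros(3))

    @settings(derandomize=True, max_examples=100)
    @given(a1=st.floats(0.2, 3.0), a2=st.floats(0.2, 3.0),
           b1=st.floats(-2.0, 2.0), b2=st.floats(-2.0, 2.0),
           t1=st.floats(-4.0, 4.0), t2=st.floats(-4.0, 4.0))
    def test_composition_property(self, a1, a2, b1, b2, t1, t2):
        """Across the parameter space, the block response function equals
        the independent-evaluation composition of the two statements."""
        it1 = Item(id=1, dim=1, a=a1, b=b1)
        it2 = Item(id=2, dim=2, a=a2, b=b2)
        blk = Block.from_items(it1, it2, 2)
        p1 = item_endorse_prob(it1, t1)
        p2 = item_endorse_prob(it2, t2)
        composed = p1 * (1 - p2) / (p1 * (1 - p2) + (1 - p1) * p2)
        assert block_prob(blk, np.array([t1, t2])) == pytest.approx(
            composed, abs=1e-12)


class TestBlockInfo:
    def test_hand_value(self):
        # s = (1.5, -1.2), P = Q = 0.5 -> s s' / 4
        blk = Block(first=1, second=2, s=np.array([1.5, -1.2, 0, 0, 0]),
                    c_j=0.0)
        info = block_info(blk, np.zeros(5))
        expected = np.outer(blk.s, blk.s) * 0.25
        np.testing.assert_allclose(info, expected, atol=1e-12)
        assert info[0, 0] == pytest.approx(0.5625)
        assert info[0, 1] == pytest.approx(-0.45)
        assert info[1, 1] == pytest.approx(0.36)

    def test_vanishes_at_certainty(self):
        _, _, blk = _random_block(np.random.default_rng(3))
        theta = np.full(5, 200.0)
        np.testing.assert_allclose(block_info(blk, theta), 0.0, atol=1e-12)

    def test_rank_one_psd(self, rng):
        _, _, blk = _random_block(rng)
        info = block_info(blk, rng.normal(size=5))
        assert np.linalg.matrix_rank(info, tol=1e-10) <= 1
        assert np.all(np.linalg.eigvalsh(info) >= -1e-10)

    def test_equals_expected_negative_hessian(self, rng):
        """I_j is the negative expected second derivative of the Bernoulli
        log-likelihood (central finite differences)."""
        _, _, blk = _random_block(rng)
        theta = rng.normal(size=5)
        h = 1e-5

        def loglik(t, y):
            p = block_prob(blk, t)
            return math.log(p) if y == 1 else math.log(1 - p)

        D = 5
        H = np.zeros((D, D))
        p_true = block_prob(blk, theta)
        for y, w in ((1, p_true), (2, 1 - p_true)):
            for i in range(D):
                for j in range(D):
                    e_i = np.eye(D)[i] * h
                    e_j = np.eye(D)[j] * h
                    d2 = (loglik(theta + e_i + e_j, y)
                          - loglik(theta + e_i - e_j, y)
                          - loglik(theta - e_i + e_j, y)
                          + loglik(theta - e_i - e_j, y)) / (4 * h * h)
                    H[i, j] += w * d2
        np.testing.assert_allclose(block_info(blk, theta), -H, atol=1e-5)


class TestTestInfo:
    def test_empty_is_zero(self):
        q = Questionnaire(blocks=[])
        np.testing.assert_array_equal(total_info(q, np.zeros(5)), np.zeros((5, 5)))

    def test_additive_over_blocks(self, rng):
        blocks = []
        for k in range(4):
            it1 = Item(id=2 * k + 1, dim=1 + k % 5, a=1.2, b=0.1 * k)
            it2 = Item(id=2 * k + 2, dim=1 + (k + 1) % 5, a=1.6, b=-0.2 * k)
            blocks.append(Block.from_items(it1, it2, 5))
        theta = rng.normal(size=5)
        q12 = Questionnaire(blocks=blocks)
        q1 = Questionnaire(blocks=blocks[:2])
        q2 = Questionnaire(blocks=blocks[2:])
        np.testing.assert_allclose(
            total_info(q12, theta),
            total_info(q1, theta) + total_info(q2, theta), atol=1e-14)
        single = Questionnaire(blocks=blocks[:1])
        np.testing.assert_allclose(total_info(single, theta),
                                   block_info(blocks[0], theta), atol=1e-15)

    def test_symmetric_psd(self, pool_n60_d5, rng):
        from fcassembly import GAConfig, build_constraints
        from fcassembly.bruteforce import random_feasible_assembly
        from fcassembly.ga import decode_phenotype

        C = build_constraints(pool_n60_d5)
        delta = random_feasible_assembly(C, pool_n60_d5, GAConfig(J=30), rng)
        q = decode_phenotype(delta, pool_n60_d5)
        info = total_info(q, rng.normal(size=5))
        np.testing.assert_allclose(info, info.T, atol=1e-12)
        assert np.linalg.eigvalsh(info).min() >= -1e-10


class TestQuadrature:
    def test_full_factorial_size(self):
        grid = build_quadrature(5, [-2.0, 0.0, 2.0], np.eye(5))
        assert grid.L == 243
        assert grid.points.shape == (243, 5)
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (grid.weights > 0).all()

    def test_single_point(self):
        grid = build_quadrature(1, [0.0], np.eye(1))
        assert grid.L == 1
        assert grid.weights[0] == pytest.approx(1.0)

    def test_identity_weights_factorize(self):
        pts = np.array([-2.0, 0.0, 2.0])
        grid = build_quadrature(3, pts, np.eye(3))
        from scipy.stats import norm
        w1 = norm.pdf(pts)
        w1 /= w1.sum()
        expected = np.array([w1[i] * w1[j] * w1[k]
                             for i, j, k in itertools.product(range(3),
                                                              repeat=3)])
        np.testing.assert_allclose(grid.weights, expected, atol=1e-12)


def _oracle_reliability(q, Phi, D):
    """Independent straight-line evaluation of the reliability objective:
    explicit loop over every grid point with plain matrix inverses."""
    pts = [-2.0, 0.0, 2.0]
    Phi_inv = np.linalg.inv(Phi)
    dens, variances = [], []
    for theta in itertools.product(pts, repeat=D):
        theta = np.array(theta, dtype=float)
        info = np.zeros((D, D))
        for b in q.blocks:
            p = expit(float(b.s @ theta) + b.c_j)
            info += np.outer(b.s, b.s) * p * (1 - p)
        M = info + Phi_inv
        variances.append(np.diag(np.linalg.inv(M)))
        dens.append(multivariate_normal(np.zeros(D), Phi).pdf(theta))
    dens = np.array(dens)
    w = dens / dens.sum()
    var_bar = w @ np.array(variances)
    return 1.0 - var_bar


class TestObjectiveReliability:
    def test_empty_questionnaire_identity_prior(self):
        rho2, mean = objective_reliability(Questionnaire([]), np.eye(5))
        np.testing.assert_allclose(rho2, 0.0, atol=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_one_block_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        _, _, blk = _random_block(rng)
        q = Questionnaire([blk])
        rho2, mean = objective_reliability(q, np.eye(5))
        np.testing.assert_allclose(rho2, _oracle_reliability(q, np.eye(5), 5),
                                   atol=1e-10)
        assert 0 < mean < 1

    def test_random_questionnaires_match_oracle(self, pool_n60_d5, rng):
        from fcassembly import GAConfig, build_constraints, neo_phi
        from fcassembly.bruteforce import random_feasible_assembly
        from fcassembly.ga import decode_phenotype

        C = build_constraints(pool_n60_d5)
        for Phi in (np.eye(5), neo_phi()):
            delta = random_feasible_assembly(C, pool_n60_d5, GAConfig(J=30),
                                             rng)
            q = decode_phenotype(delta, pool_n60_d5)
            rho2, _ = objective_reliability(q, Phi)
            np.testing.assert_allclose(rho2, _oracle_reliability(q, Phi, 5),
                                       atol=1e-10)

    def test_evaluator_matches_functional_form(self, pool_n60_d5, rng):
        from fcassembly import GAConfig, build_constraints
        from fcassembly.bruteforce import random_feasible_assembly
        from fcassembly.ga import decode_phenotype, _pairs_array

        C = build_constraints(pool_n60_d5)
        cfg = GAConfig(J=30)
        deltas = np.stack([random_feasible_assembly(C, pool_n60_d5, cfg, rng)
                           for _ in range(4)])
        obj = ReliabilityObjective(pool_n60_d5, np.eye(5))
        batch = obj.evaluate_pairs(_pairs_array(deltas, 30))
        for k in range(4):
            q = decode_phenotype(deltas[k], pool_n60_d5)
            _, mean = objective_reliability(q, np.eye(5))
            assert batch[k] == pytest.approx(mean, abs=1e-10)

    def test_appending_a_block_never_hurts(self, rng):
        """Adding rank-one information decreases every posterior variance,
        so each trait reliability weakly increases."""
        blocks = []
        prev = -np.inf
        for k in range(6):
            it1 = Item(id=2 * k + 1, dim=1 + k % 5, a=1.4, b=0.3 * k - 1)
            it2 = Item(id=2 * k + 2, dim=1 + (k + 2) % 5, a=1.1, b=1 - 0.2 * k)
            blocks.append(Block.from_items(it1, it2, 5))
            _, mean = objective_reliability(Questionnaire(list(blocks)),
                                            np.eye(5))
            assert mean >= prev - 1e-12
            prev = mean


class TestCountAssemblies:
    def test_paper_scale_count(self):
        n = count_assemblies(60, 30, 2)
        assert f"{n:.2e}" == "2.92e+40"

    @pytest.mark.parametrize("N,J,expected", [(2, 1, 1), (4, 2, 3)])
    def test_tiny_values(self, N, J, expected):
        assert count_assemblies(N, J, 2) == expected

    def test_matches_exhaustive_enumeration(self):
        for N in range(2, 9):
            C = ~np.eye(N, dtype=bool)  # any two distinct items may pair
            for J in range(1, N // 2 + 1):
                n_enum = sum(1 for _ in enumerate_matchings(C, J))
                assert count_assemblies(N, J, 2) == n_enum, (N, J)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            count_assemblies(3, 2, 2)


def test_ipsativity_bound():
    assert ipsativity_bound(5) == pytest.approx(-0.25)
    assert ipsativity_bound(2) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        ipsativity_bound(1)


class TestPoolValidation:
    def test_duplicate_ids_rejected(self):
        items = [Item(id=1, dim=1, a=1, b=0), Item(id=1, dim=2, a=1, b=0)]
        with pytest.raises(ValueError, match="duplicate"):
            ItemPool(items, D=2)

    def test_missing_dim_rejected(self):
        items = [Item(id=1, dim=1, a=1, b=0), Item(id=2, dim=3, a=1, b=0)]
        with pytest.raises(ValueError):
            ItemPool(items, D=3)

    def test_questionnaire_rejects_shared_items(self):
        it = [Item(id=k, dim=1 + k % 2, a=1.0, b=0.0) for k in range(1, 4)]
        b1 = Block.from_items(it[0], it[1], 2)
        b2 = Block.from_items(it[1], it[2], 2)
        with pytest.raises(ValueError, match="more than one block"):
            Questionnaire(blocks=[b1, b2])
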