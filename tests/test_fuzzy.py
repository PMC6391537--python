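from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fimseq.fuzzy import (
    LambdaSolveError,
    MeasureError,
    densities,
    evidence,
    fuzzy_distance,
    fuzzy_similarity,
    measure_chain,
    solve_lambda,
    sort_order,
    subset_measure,
    sugeno_integral,
)

def delta(i, m=20):
    v = np.zeros(m)
    v[i] = 1.0
    return v


def level_set_oracle(rho, mu, lam):
    """Independent Sugeno integral: max over levels alpha of
    min(alpha, mu({i: rho_i >= alpha})), mu from the closed form."""
    best = 0.0
    for alpha in rho:
        s = [i for i in range(len(rho)) if rho[i] >= alpha - 1e-15]
        best = max(best, min(alpha, subset_measure(mu, lam, s)))
    return best


def chain_by_insertion(mu, lam, order):
    """Build prefix measures one element at a time via the union rule."""
    acc = 0.0
    out = []
    for j in order:
        acc = acc + mu[j] + lam * acc * mu[j]
        out.append(acc)
    return np.array(out)


class TestEvidenceAndDensities:
    def test_identical_vectors(self, simplex_pair):
        v, _ = simplex_pair()
        np.testing.assert_allclose(evidence(v, v), 1.0)
        np.testing.assert_allclose(densities(v, v), v)

    def test_disjoint_deltas(self):
        v, t = delta(0), delta(1)
        rho = evidence(v, t)
        assert rho[0] == rho[1] == 0.0
        assert (rho[2:] == 1.0).all()
        mu = densities(v, t)
        assert mu[0] == mu[1] == 1.0 and not mu[2:].any()

    def test_scalar_example(self):
        v, t = delta(0).copy(), delta(0).copy()
        v[0], v[1] = 0.3, 0.7
        t[0], t[1] = 0.5, 0.5
        assert evidence(v, t)[0] == pytest.approx(0.8)

    def test_density_sum_at_least_one(self, simplex_pair):
        # sum max(v, t) >= 1, equality iff v = t
        for _ in range(200):
            v, t = simplex_pair()
            assert densities(v, t).sum() >= 1.0 - 1e-12
        v, _ = simplex_pair()
        assert densities(v, v).sum() == pytest.approx(1.0)


class TestSolveLambda:
    def test_additive_case(self):
        assert solve_lambda(np.full(20, 0.05)) == 0.0

    def test_three_half_densities_analytic_root(self):
        # (1+l/2)^3 = 1+l  =>  l = (-0.75 + sqrt(0.3125)) / 0.25
        expected = (-0.75 + np.sqrt(0.3125)) / 0.25
        lam = solve_lambda(np.array([0.5, 0.5, 0.5]))
        assert lam == pytest.approx(expected, abs=1e-12)

    def test_degenerate_unit_densities(self):
        mu = np.zeros(20)
        mu[:2] = 1.0
        assert solve_lambda(mu) == 0.0

    def test_residual_and_sign_on_random_pairs(self, simplex_pair):
        for _ in range(200):
            v, t = simplex_pair()
            mu = densities(v, t)
            lam = solve_lambda(mu)
            assert -1.0 < lam <= 0.0
            assert abs(np.prod(1 + lam * mu) - (1 + lam)) < 1e-10

    def test_subadditive_densities_positive_root(self):
        mu = np.array([0.2, 0.2, 0.2])
        lam = solve_lambda(mu)
        assert lam > 0
        assert abs(np.prod(1 + lam * mu) - (1 + lam)) < 1e-10

    def test_single_small_density_has_no_root(self):
        with pytest.raises(LambdaSolveError):
            solve_lambda(np.array([0.3, 0.0, 0.0]))


class TestMeasureChain:
    def test_additive_chain_is_partial_sums(self, rng):
        mu = rng.dirichlet(np.ones(20))
        ch = measure_chain(mu, 0.0, np.arange(20))
        np.testing.assert_allclose(ch.chain, np.cumsum(mu), atol=1e-9)

    def test_hand_computed_chain(self):
        mu = np.array([0.5, 0.5, 0.5])
        lam = solve_lambda(mu)
        ch = measure_chain(mu, lam, np.array([0, 1, 2]))
        np.testing.assert_allclose(
            ch.chain, [0.5, 0.8090169943749475, 1.0], atol=1e-9
        )

    def test_monotone_and_normalised(self, simplex_pair):
        for _ in range(100):
            v, t = simplex_pair()
            mu = densities(v, t)
            lam = solve_lambda(mu)
            ch = measure_chain(mu, lam, sort_order(evidence(v, t)))
            assert (np.diff(ch.chain) >= -1e-12).all()
            assert ch.chain[-1] == 1.0

    def test_inconsistent_lambda_raises(self, rng):
        mu = rng.dirichlet(np.ones(20)) * 1.5  # sum = 1.5
        with pytest.raises(MeasureError, match="inconsistent"):
            measure_chain(np.clip(mu, 0, 1), 0.0, np.arange(20))

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_every_insertion_order_matches_closed_form(self, m, rng):
        # union rule is order-independent and agrees with the product form
        mu = rng.dirichlet(np.ones(m)) * 1.4
        mu = np.clip(mu, 0.0, 0.99)
        lam = solve_lambda(mu) if abs(mu.sum() - 1) > 1e-9 else 0.0
        for subset_size in range(1, m + 1):
            for subset in combinations(range(m), subset_size):
                ref = subset_measure(mu, lam, subset)
                for order in permutations(subset):
                    got = chain_by_insertion(mu, lam, order)[-1]
                    assert got == pytest.approx(ref, abs=1e-9)


class TestSugenoIntegral:
    def test_full_evidence_gives_one(self, simplex_pair):
        v, _ = simplex_pair()
        mu = densities(v, v)
        ch = measure_chain(mu, 0.0, sort_order(np.ones(20)))
        assert sugeno_integral(np.ones(20), ch) == 1.0

    def test_hand_example(self):
        mu = np.array([0.5, 0.5, 0.5])
        lam = solve_lambda(mu)
        rho = np.array([0.8, 0.6, 0.4])
        ch = measure_chain(mu, lam, sort_order(rho))
        assert sugeno_integral(rho, ch) == pytest.approx(0.6, abs=1e-9)

    def test_matches_level_set_oracle(self, rng):
        for _ in range(300):
            m = int(rng.integers(3, 9))
            v = rng.dirichlet(np.ones(m))
            t = rng.dirichlet(np.ones(m))
            rho = evidence(v, t)
            mu = densities(v, t)
            lam = solve_lambda(mu)
            ch = measure_chain(mu, lam, sort_order(rho))
            got = sugeno_integral(rho, ch)
            assert got == pytest.approx(level_set_oracle(rho, mu, lam),
                                        abs=1e-9)

    @pytest.mark.parametrize("m", [3, 4, 5, 6])
    def test_tie_invariance(self, m, rng):
        # permuting equal-evidence elements cannot change the integral
        rho = np.full(m, 0.6)
        rho[0] = 0.9
        mu = np.clip(rng.dirichlet(np.ones(m)) * 1.3, 0, 0.99)
        lam = solve_lambda(mu)
        vals = set()
        for perm in permutations(range(1, m)):
            order = np.array([0, *perm])
            ch = measure_chain(mu, lam, order)
            vals.add(round(sugeno_integral(rho, ch), 12))
        assert len(vals) == 1

    def test_unsorted_order_rejected(self):
        mu = np.array([0.5, 0.5, 0.5])
        lam = solve_lambda(mu)
        rho = np.array([0.2, 0.9, 0.5])
        ch = measure_chain(mu, lam, np.arange(3))
        with pytest.raises(ValueError, match="descending"):
            sugeno_integral(rho, ch)


class TestFuzzyDistance:
    def test_self_distance_zero(self, simplex_pair):
        v, _ = simplex_pair()
        assert fuzzy_distance(v, v) == 0.0

    def test_disjoint_deltas_distance_one(self):
        assert fuzzy_distance(delta(0), delta(1)) == 1.0

    def test_symmetry_and_range(self, simplex_pair):
        for _ in range(200):
            v, t = simplex_pair()
            d = fuzzy_distance(v, t)
            assert 0.0 <= d <= 1.0
            assert d == fuzzy_distance(t, v)

    @given(st.integers(0, 2**31 - 1))
    def test_distance_properties_hypothesis(self, seed):
        r = np.random.default_rng(seed)
        v, t = r.dirichlet(np.ones(20)), r.dirichlet(np.ones(20))
        d = fuzzy_distance(v, t)
        assert 0.0 <= d <= 1.0
        assert d == fuzzy_distance(t, v)
        assert fuzzy_similarity(v, t) == pytest.approx(1 - d, abs=1e-12)
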