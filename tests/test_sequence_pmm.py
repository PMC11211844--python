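import numpy as np
import pytest
from scipy.linalg import expm

from sdtrace import (
    PMMParams,
    SiteAlphabet,
    brute_force_site_loglik,
    dropout_emission,
    parse_newick,
    sequence_loglik,
    site_loglik,
    transition_matrix,
)
from sdtrace.sequence_pmm import CharacterMatrix, generator
from sdtrace.trees import MISSING, SILENT

from conftest import random_tree


@pytest.fixture
def site2():
    return SiteAlphabet(n_states=2)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, site2):
        P = transition_matrix(site2, PMMParams(lam=0.4, nu=0.2), 0.0)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-15)

    def test_zero_rates_identity(self, site2):
        P = transition_matrix(site2, PMMParams(lam=0.0, nu=0.0), 3.0)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-15)

    def test_closed_forms_single_edit_state(self):
        site = SiteAlphabet(n_states=1)
        lam, nu, d = 0.3, 0.1, 0.7
        P = transition_matrix(site, PMMParams(lam=lam, nu=nu), d)
        assert P[0, 0] == pytest.approx(np.exp(-(lam + nu) * d))
        assert P[0, 1] == pytest.approx(
            np.exp(-nu * d) * (1 - np.exp(-lam * d)))
        assert P[1, 2] == pytest.approx(1 - np.exp(-nu * d))
        # nu = 0 limit
        P0 = transition_matrix(site, PMMParams(lam=lam, nu=0.0), d)
        assert P0[0, 1] == pytest.approx(1 - np.exp(-lam * d))

    @pytest.mark.parametrize("m,lam,nu,d", [
        (1, 0.3, 0.1, 0.7), (2, 0.05, 0.4, 2.5), (3, 1.2, 0.0, 0.3),
    ])
    def test_matches_matrix_exponential(self, m, lam, nu, d):
        site = SiteAlphabet(n_states=m,
                            priors=np.arange(1, m + 1) / (m * (m + 1) / 2))
        params = PMMParams(lam=lam, nu=nu)
        P = transition_matrix(site, params, d)
        np.testing.assert_allclose(P, expm(generator(site, params) * d),
                                   atol=1e-12)

    def test_rows_sum_to_one_and_chapman_kolmogorov(self, site2):
        params = PMMParams(lam=0.7, nu=0.25)
        rng = np.random.default_rng(0)
        for _ in range(5):
            d1, d2 = rng.uniform(0, 3, 2)
            P1 = transition_matrix(site2, params, d1)
            P2 = transition_matrix(site2, params, d2)
            P12 = transition_matrix(site2, params, d1 + d2)
            np.testing.assert_allclose(P1.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(P1 @ P2, P12, atol=1e-12)

    def test_irreversibility(self, site2):
        P = transition_matrix(site2, PMMParams(lam=0.5, nu=0.2), 5.0)
        assert P[1, 0] == 0.0 and P[2, 0] == 0.0   # no reversion
        assert P[1, 2] == 0.0 and P[2, 1] == 0.0   # no edit switching
        assert P[3, 3] == 1.0                      # silent absorbing

    def test_negative_time_rejected(self, site2):
        with pytest.raises(ValueError):
            transition_matrix(site2, PMMParams(lam=0.1), -1.0)


class TestDropoutEmission:
    def test_no_dropout(self, site2):
        assert dropout_emission(site2, 0.0, 1, 1) == 1.0
        assert dropout_emission(site2, 0.0, 1, MISSING) == 0.0

    def test_silent_always_missing(self, site2):
        for phi in (0.0, 0.3, 0.9):
            assert dropout_emission(site2, phi, SILENT, MISSING) == 1.0

    def test_dropout_table(self, site2):
        assert dropout_emission(site2, 0.1, 2, MISSING) == pytest.approx(0.1)
        assert dropout_emission(site2, 0.1, 2, 2) == pytest.approx(0.9)
        assert dropout_emission(site2, 0.1, 2, 1) == 0.0

    def test_rows_sum_to_one_over_observables(self, site2):
        phi = 0.35
        for hidden in (0, 1, 2, SILENT):
            total = sum(
                dropout_emission(site2, phi, hidden, o)
                for o in (MISSING, 0, 1, 2))
            assert total == pytest.approx(1.0)

    def test_invalid_symbol(self, site2):
        with pytest.raises(ValueError):
            dropout_emission(site2, 0.1, 5, 0)


class TestSiteLoglik:
    def test_single_leaf_closed_form(self, single_leaf, site2):
        # P(observe 0 | root 0) with phi=0 is exp(-(lam+nu) * delta)
        params = PMMParams(lam=0.3, nu=0.1, phi=0.0)
        ll = site_loglik(single_leaf, np.array([0]), site2, params)
        assert ll == pytest.approx(-(0.3 + 0.1) * 1.0)

    def test_all_missing_column(self, cherry, site2):
        # with phi=0 and nu=0 an all-"?" column is impossible: -inf, not
        # an exception
        ll = site_loglik(cherry, np.array([MISSING, MISSING]), site2,
                         PMMParams(lam=0.3, nu=0.0, phi=0.0))
        assert ll == -np.inf
        # with nu>0 it is the probability that both lineages silenced
        ll2 = site_loglik(cherry, np.array([MISSING, MISSING]), site2,
                          PMMParams(lam=0.3, nu=0.1, phi=0.0))
        assert np.isfinite(ll2) and ll2 < 0

    def test_zero_length_no_events(self, site2):
        t = parse_newick("((A:1e-12,B:1e-12)u:1e-12)r;")
        ll = site_loglik(t, np.array([0, 0]), site2,
                         PMMParams(lam=0.5, nu=0.2, phi=0.0))
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_observed_silent_treated_as_missing(self, cherry, site2):
        params = PMMParams(lam=0.3, nu=0.1, phi=0.05)
        a = site_loglik(cherry, np.array([SILENT, 0]), site2, params)
        b = site_loglik(cherry, np.array([MISSING, 0]), site2, params)
        assert a == b
        with pytest.raises(ValueError, match="silent"):
            site_loglik(cherry, np.array([SILENT, 0]), site2, params,
                        strict_silent=True)

    def test_monotone_in_rates_for_unmutated_column(self, five_leaf, site2):
        col = np.zeros(5, dtype=int)
        lls = [site_loglik(five_leaf, col, site2,
                           PMMParams(lam=lam, nu=0.01, phi=0.0))
               for lam in (0.0, 0.1, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(lls, lls[1:]))


class TestPruningVsEnumeration:
    def test_randomized_small_trees(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            t, tau = random_tree(rng, n_leaves=int(rng.integers(2, 7)))
            m = int(rng.integers(1, 4))
            site = SiteAlphabet(n_states=m)
            params = PMMParams(
                lam=float(rng.uniform(0.01, 2.0) / tau * 5),
                nu=float(rng.uniform(0, 1.0) / tau * 5),
                phi=float(rng.uniform(0, 0.5)),
            )
            n = t.n_leaves
            col = rng.choice(
                [MISSING] + list(range(m + 1)), size=n,
                p=[0.2] + [0.8 / (m + 1)] * (m + 1))
            a = site_loglik(t, col, site, params)
            b = brute_force_site_loglik(t, col, site, params)
            if np.isinf(a) or np.isinf(b):
                assert a == b
            else:
                assert a == pytest.approx(b, rel=1e-10, abs=1e-12)

    def test_brute_force_refuses_large_trees(self):
        rng = np.random.default_rng(1)
        t, _ = random_tree(rng, n_leaves=12)
        with pytest.raises(ValueError, match="internal"):
            brute_force_site_loglik(
                t, np.zeros(12, dtype=int), SiteAlphabet(1),
                PMMParams(lam=0.1))


class TestSequenceLoglik:
    def test_single_site_equals_site_loglik(self, cherry, site2):
        params = PMMParams(lam=0.2, nu=0.05, phi=0.1)
        mat = CharacterMatrix(cells=["A", "B"],
                              data=np.array([[1], [0]]),
                              alphabets=[site2])
        assert sequence_loglik(cherry, mat, params) == pytest.approx(
            site_loglik(cherry, np.array([1, 0]), site2, params))

    def test_duplicated_column_doubles_contribution(self, cherry, site2):
        params = PMMParams(lam=0.2, nu=0.05, phi=0.1)
        one = CharacterMatrix(cells=["A", "B"], data=np.array([[2], [0]]),
                              alphabets=[site2])
        two = CharacterMatrix(cells=["A", "B"],
                              data=np.array([[2, 2], [0, 0]]),
                              alphabets=[site2, site2])
        assert sequence_loglik(cherry, two, params) == pytest.approx(
            2 * sequence_loglik(cherry, one, params))

    def test_additivity_over_sites(self, five_leaf):
        rng = np.random.default_rng(4)
        K = 6
        site = SiteAlphabet(n_states=2)
        data = rng.choice([MISSING, 0, 1, 2], size=(5, K))
        mat = CharacterMatrix(
            cells=sorted(five_leaf.leaf_name.values()), data=data,
            alphabets=[site] * K)
        params = PMMParams(lam=0.15, nu=0.02, phi=0.05)
        total = sequence_loglik(five_leaf, mat, params)
        parts = sum(
            site_loglik(five_leaf, data[:, k], site, params)
            for k in range(K))
        assert total == pytest.approx(parts, rel=1e-12)
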