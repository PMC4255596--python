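"""Quasi-species error-class dynamics and error-threshold location."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replicore.quasispecies import (
    ReplicationKernel,
    SinglePeakLandscape,
    ThresholdResult,
    class_transition_matrix,
    find_error_threshold,
    iterate,
    master_frequency_closed_form,
    solve_stationary,
    threshold_phase_table,
)


class TestTransitionMatrix:
    def test_perfect_copying_gives_identity(self):
        M = class_transition_matrix(2, ReplicationKernel(mu=0.0))
        np.testing.assert_allclose(M, np.eye(3))

    def test_single_site_symmetry(self):
        M = class_transition_matrix(1, ReplicationKernel(mu=0.1))
        np.testing.assert_allclose(M, [[0.9, 0.1], [0.1, 0.9]])

    def test_faithful_copy_probability_closed_form(self):
        M = class_transition_matrix(20, ReplicationKernel(mu=0.05))
        assert M[0, 0] == pytest.approx(0.95**20, rel=1e-12)

    def test_error_free_channel_adds_to_diagonal(self):
        base = class_transition_matrix(10, ReplicationKernel(mu=0.1, p=0.0))
        mixed = class_transition_matrix(10, ReplicationKernel(mu=0.1, p=0.4))
        np.testing.assert_allclose(mixed, 0.4 * np.eye(11) + 0.6 * base)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            ReplicationKernel(mu=1.5)

    @settings(deadline=None, max_examples=25)
    @given(
        L=st.integers(1, 40),
        mu=st.floats(0, 0.9),
        p=st.floats(0, 1),
    )
    def test_column_stochastic(self, L, mu, p):
        M = class_transition_matrix(L, ReplicationKernel(mu=mu, p=p))
        assert np.all(M >= 0)
        np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-10)


class TestIterate:
    def test_master_is_fixed_point_without_errors(self):
        lsc = SinglePeakLandscape(L=10, sigma=2)
        M = class_transition_matrix(10, ReplicationKernel(mu=0.0))
        x = np.zeros(11)
        x[0] = 1.0
        np.testing.assert_allclose(iterate(x, lsc, M), x)

    def test_selection_only_enriches_master(self):
        lsc = SinglePeakLandscape(L=10, sigma=2)
        M = class_transition_matrix(10, ReplicationKernel(mu=0.0))
        x = np.full(11, 1 / 11)
        for _ in range(5):
            x_next = iterate(x, lsc, M)
            assert x_next[0] > x[0]
            x = x_next

    @settings(deadline=None, max_examples=25)
    @given(
        mu=st.floats(0, 0.5),
        sigma=st.floats(1.1, 20),
        raw=st.lists(st.floats(0.01, 1), min_size=11, max_size=11),
    )
    def test_output_normalized(self, mu, sigma, raw):
        lsc = SinglePeakLandscape(L=10, sigma=sigma)
        M = class_transition_matrix(10, ReplicationKernel(mu=mu))
        x = np.array(raw) / np.sum(raw)
        assert iterate(x, lsc, M).sum() == pytest.approx(1.0, abs=1e-12)


class TestStationary:
    def test_no_errors_pure_master(self):
        x = solve_stationary(SinglePeakLandscape(L=20, sigma=2), ReplicationKernel(mu=0.0))
        assert x[0] == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_no_backmutation_oracle(self):
        x = solve_stationary(SinglePeakLandscape(L=20, sigma=2), ReplicationKernel(mu=0.005))
        assert x[0] == pytest.approx(master_frequency_closed_form(2, 20, 0.005), abs=0.02)

    def test_mixture_lower_bound(self):
        """With an error-free channel p, the master cannot fall below the
        closed-form floor (sigma*p - 1)/(sigma - 1)."""
        x = solve_stationary(
            SinglePeakLandscape(L=50, sigma=4), ReplicationKernel(mu=0.2, p=0.5)
        )
        assert x[0] >= (4 * 0.5 - 1) / (4 - 1) - 0.02

    def test_is_fixed_point_of_iterate(self):
        lsc = SinglePeakLandscape(L=30, sigma=3)
        kern = ReplicationKernel(mu=0.02, p=0.1)
        M = class_transition_matrix(30, kern)
        x = solve_stationary(lsc, kern)
        assert np.max(np.abs(iterate(x, lsc, M) - x)) < 1e-10

    def test_master_monotone_in_mu_and_p(self):
        lsc = SinglePeakLandscape(L=50, sigma=2)
        masters_mu = [
            solve_stationary(lsc, ReplicationKernel(mu=mu))[0]
            for mu in (0.0, 0.005, 0.01, 0.02, 0.05)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(masters_mu, masters_mu[1:]))
        masters_p = [
            solve_stationary(lsc, ReplicationKernel(mu=0.05, p=p))[0]
            for p in (0.0, 0.25, 0.5, 0.75)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(masters_p, masters_p[1:]))


class TestThreshold:
    def test_classic_threshold_matches_survival_of_the_flattest_form(self):
        """p=0: the threshold solves sigma*(1-mu)^L = 1, i.e. mu_c = 1 - sigma^(-1/L)."""
        res = find_error_threshold(SinglePeakLandscape(L=50, sigma=2), p=0.0)
        assert res.exists
        assert res.mu_critical == pytest.approx(1 - 2 ** (-1 / 50), rel=0.05)

    def test_genome_wide_threshold_near_one_mutation_per_replication(self):
        """sigma = e makes ln(sigma) = 1: about one mutation per genome per
        replication at the threshold."""
        res = find_error_threshold(SinglePeakLandscape(L=100, sigma=math.e), p=0.0)
        assert res.exists
        assert res.genome_wide_rate == pytest.approx(1.0, rel=0.10)

    def test_threshold_disappears_when_sigma_p_exceeds_one(self):
        res = find_error_threshold(SinglePeakLandscape(L=100, sigma=10), p=0.2)
        assert isinstance(res, ThresholdResult)
        assert res.exists is False
        assert res.mu_critical is None

    def test_unbracketed_range_rejected(self):
        lsc = SinglePeakLandscape(L=100, sigma=2)
        with pytest.raises(ValueError, match="bracket"):
            find_error_threshold(lsc, p=0.0, mu_range=(0.3, 0.5))


@pytest.fixture(scope="module")
def table():
    return threshold_phase_table(
        sigma_grid=[2.0, 10.0], p_grid=[0.0, 0.2, 0.4, 0.6], L=50, tol=1e-4
    )


class TestPhaseTable:

    def test_p0_column_reproduces_direct_search(self, table):
        direct = find_error_threshold(SinglePeakLandscape(L=50, sigma=2), p=0.0, tol=1e-4)
        row = table[(table.sigma == 2.0) & (table.p == 0.0)].iloc[0]
        assert row.mu_critical == pytest.approx(direct.mu_critical, abs=1e-3)

    def test_threshold_disappears_beyond_reciprocal_sigma(self, table):
        """Threshold exists while p < 1/sigma and is gone once sigma*p > 1."""
        s2 = table[table.sigma == 2.0].set_index("p")
        assert bool(s2.loc[0.0, "exists"]) and bool(s2.loc[0.4, "exists"])
        assert not bool(s2.loc[0.6, "exists"])

    def test_threshold_nondecreasing_in_p(self, table):
        for sigma in (2.0, 10.0):
            mu_c = table[table.sigma == sigma].sort_values("p")["mu_critical"].dropna()
            assert (mu_c.diff().dropna() >= -1e-6).all()


def test_landscape_validation():
    with pytest.raises(ValueError, match="sigma"):
        SinglePeakLandscape(L=10, sigma=1.0)
    with pytest.raises(ValueError, match="L"):
        SinglePeakLandscape(L=0, sigma=2.0)
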