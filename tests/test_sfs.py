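import numpy as np
import pytest

from traitarch.demography import constant_demography, preset
from traitarch.sfs import (
    ConditionalSFS,
    FrequencyGrid,
    build_cache,
    compute_k,
    equilibrium_cell_masses,
    equilibrium_sfs,
    expected_delta_q,
    present_day_sfs,
    seg_moment,
    stationary_sfs,
)
from traitarch.trait import DiracSelectionDensity, SelectionDensity

from _oracles import wf_stationary_masses, quantiles_from_masses

MU = 1.25e-8


class TestExpectedDeltaQ:
    @pytest.mark.parametrize("s,q,expected", [
        (0.01, 0.1, -3.6e-4),
        (0.05, 0.5, 0.0),
        (0.01, 0.9, +3.6e-4),
    ])
    def test_point_values(self, s, q, expected):
        assert expected_delta_q(s, q) == pytest.approx(expected, abs=1e-12)

    def test_minor_allele_symmetry(self):
        q = np.linspace(0.01, 0.99, 50)
        d = expected_delta_q(0.003, q)
        assert np.allclose(d, -d[::-1])

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_delta_q(-0.1, 0.5)
        with pytest.raises(ValueError):
            expected_delta_q(0.1, 1.5)


class TestFrequencyGrid:
    def test_weights_sum_to_one(self):
        g = FrequencyGrid.logit(512, 1e-5)
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_about_half(self):
        g = FrequencyGrid.logit(256, 1e-4)
        assert np.allclose(g.q + g.q[::-1], 1.0, atol=1e-12)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            FrequencyGrid.logit(101)  # odd
        with pytest.raises(ValueError):
            FrequencyGrid.logit(256, 0.7)


class TestEquilibrium:
    def test_neutral_one_over_q_shape(self):
        g = FrequencyGrid.logit()
        lam = equilibrium_sfs(0.0, 10_000, MU, g.q)
        mid = (g.q > 1e-4) & (g.q < 0.999)
        assert np.allclose(lam[mid] * g.q[mid], 4 * 10_000 * MU, rtol=1e-3)

    def test_mutation_selection_balance(self):
        # strong selection: E[2q(1-q)] ~ 4 mu / s
        g = FrequencyGrid.logit()
        for s in (1e-2, 1e-1):
            lam = equilibrium_sfs(s, 10_000, MU, g.q)
            e2pq = float((lam * 2 * g.q * (1 - g.q) * g.weights).sum())
            assert e2pq == pytest.approx(4 * MU / s, rel=0.2)

    def test_large_4ns_finite(self):
        g = FrequencyGrid.logit()
        lam = equilibrium_sfs(0.1, 500_000, MU, g.q)
        assert np.all(np.isfinite(lam)) and np.all(lam >= 0)

    def test_high_frequency_mass_suppressed(self):
        g = FrequencyGrid.logit()
        lam = equilibrium_sfs(1e-2, 10_000, MU, g.q)
        m = lam * g.weights
        assert m[g.q > 0.99].sum() < 1e-6 * m[g.q < 0.01].sum()


class TestTransientSolver:
    @pytest.mark.parametrize("s", [0.0, 1e-4, 1e-3, 1e-2])
    def test_constant_n_matches_closed_form(self, s):
        g = FrequencyGrid.logit()
        lam = present_day_sfs(s, constant_demography(10_000), MU, g)
        exact = equilibrium_cell_masses(s, 10_000, MU, g)
        rel_l1 = np.abs(lam * g.weights - exact).sum() / exact.sum()
        assert rel_l1 <= 1e-3

    def test_weaker_selection_commoner_variants(self, ukb_cache):
        # mirrors the effectively-neutral / moderate / strong ordering
        g = ukb_cache.grid
        maf = np.minimum(g.q, 1 - g.q)

        def mean_maf(s):
            lam = present_day_sfs(s, preset("ukb-default"), MU, g)
            m = lam * g.weights
            return (m * maf).sum() / m.sum()

        assert mean_maf(10**-4.5) > mean_maf(1e-3) > mean_maf(1e-2)

    def test_influx_linearity(self):
        g = FrequencyGrid.logit(256)
        dem = preset("ukb-default")
        lam1 = present_day_sfs(1e-3, dem, MU, g)
        lam2 = present_day_sfs(1e-3, dem, 2 * MU, g)
        assert np.allclose(lam2, 2 * lam1, rtol=1e-9)

    def test_total_mass_non_increasing_in_s(self, ukb_cache):
        assert np.all(np.diff(ukb_cache.seg_prob) <= 1e-12)

    def test_wright_fisher_matrix_oracle(self):
        # Brute-force WF matrix at N=500 vs the diffusion solver at the same
        # N, comparing quantiles of the distribution conditional on
        # q >= 0.05 (tens of copies): near the one-copy boundary the two
        # processes genuinely differ at O(1/copies), which is not solver
        # error.
        n_pop = 500
        g = FrequencyGrid.logit(1024, 1e-4)
        probs = np.linspace(0.1, 0.9, 9)
        cut = 0.05
        for s in (0.0, 0.008):  # 2Ns = 0 and 8
            masses_wf = wf_stationary_masses(n_pop, s, MU)
            edges_wf = (np.arange(1, 2 * n_pop) + 0.5) / (2 * n_pop)
            kw = np.arange(1, 2 * n_pop) / (2 * n_pop) >= cut
            lam = stationary_sfs(s, n_pop, MU, g)
            kd = g.q >= cut
            quant_wf = quantiles_from_masses(edges_wf[kw], masses_wf[kw], probs)
            quant_d = quantiles_from_masses(g.edges[1:][kd],
                                            (lam * g.weights)[kd], probs)
            assert np.all(np.abs(quant_d - quant_wf) / quant_wf < 0.02)


class TestSegMoment:
    def test_indicator_gives_seg_prob(self, const_cache):
        dem = constant_demography(10_000)
        total = seg_moment(1e-3, dem, MU, lambda q: np.ones_like(q))
        lam = present_day_sfs(1e-3, dem, MU, FrequencyGrid.logit())
        g = FrequencyGrid.logit()
        assert total == pytest.approx(float((lam * g.weights).sum()), rel=1e-9)

    def test_zero_function(self):
        assert seg_moment(1e-3, constant_demography(1000), MU,
                          lambda q: np.zeros_like(q)) == 0.0

    def test_grid_refinement_convergence(self):
        dem = constant_demography(10_000)
        vals = []
        for n_q in (512, 1024):
            g = FrequencyGrid.logit(n_q)
            lam = present_day_sfs(1e-3, dem, MU, g)
            vals.append(float((lam * 2 * g.q * (1 - g.q) * g.weights).sum()))
        assert abs(vals[1] - vals[0]) / vals[0] < 1e-3


class TestCache:
    def test_neutral_reference_column(self, ukb_cache):
        assert ukb_cache.lam0.shape == (ukb_cache.grid.n,)
        assert np.all(ukb_cache.lam0 >= 0)

    def test_densities_nonnegative(self, ukb_cache):
        assert np.all(ukb_cache.lam >= 0)

    def test_folding_consistency(self, ukb_cache):
        c = ukb_cache
        i = 40
        n2 = c.grid.n // 2
        manual = c.lam[i, :n2] + c.lam[i, :n2 - 1 - c.grid.n:-1]
        assert np.allclose(c.lam_maf[i], manual)

    def test_save_load_round_trip(self, ukb_cache, tmp_path):
        p = tmp_path / "cache.npz"
        ukb_cache.save(p)
        back = ConditionalSFS.load(p)
        assert np.allclose(back.lam, ukb_cache.lam)
        assert back.mu == ukb_cache.mu
        assert back.demography_digest == ukb_cache.demography_digest


class TestComputeK:
    def test_strong_point_mass_near_one(self, const_cache):
        k = compute_k(DiracSelectionDensity(-2.0), const_cache)
        assert 0.8 <= k <= 1.25

    def test_neutral_mass_inflates_k(self, const_cache):
        with pytest.warns(UserWarning):
            k_weak = compute_k(SelectionDensity.preset("weak"), const_cache)
        k_strong = compute_k(SelectionDensity.preset("strong"), const_cache)
        assert k_weak > 3 * k_strong

    def test_mu_invariance_in_strong_limit(self):
        fs = DiracSelectionDensity(-2.0)
        k1 = compute_k(fs, build_cache(constant_demography(10_000), MU))
        k2 = compute_k(fs, build_cache(constant_demography(10_000), 2 * MU))
        assert k1 == pytest.approx(k2, rel=0.02)
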