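import numpy as np
import pandas as pd
import pytest

from traitarch.inference import (
    FitConfig,
    bootstrap,
    fit_ssd,
    fit_tsd,
    nll,
    penalty,
)
from traitarch.simulate import TraitScenario, simulate_trait
from traitarch.trait import HitTable, SelectionDensity, TraitParams

TRUE_H2L = 3e-8
TRUE_L = 8.3e6


class TestNll:
    def test_duplicating_hits_doubles(self, canonical_hits, ukb_cache,
                                      canonical_scenario):
        params = canonical_scenario.params()
        v1 = nll(canonical_hits, params, ukb_cache)
        doubled = HitTable(
            data=pd.concat([canonical_hits.data, canonical_hits.data],
                           ignore_index=True),
            label="2x")
        assert nll(doubled, params, ukb_cache) == pytest.approx(2 * v1, rel=1e-9)

    def test_row_order_invariant(self, canonical_hits, ukb_cache,
                                 canonical_scenario):
        params = canonical_scenario.params()
        shuffled = HitTable(
            data=canonical_hits.data.sample(frac=1, random_state=0)
            .reset_index(drop=True), label="shuf")
        assert nll(shuffled, params, ukb_cache) == pytest.approx(
            nll(canonical_hits, params, ukb_cache), rel=1e-9)

    def test_true_params_beat_decade_shifted_fs(self, ukb_cache):
        wins = 0
        for rep in range(6):
            _, hits = simulate_trait(
                TraitScenario("t", h2_over_L=TRUE_H2L, L=TRUE_L, n=3e5,
                              seed=400 + rep),
                cache=ukb_cache, keep_architecture=False)
            true_p = TraitParams(fs=SelectionDensity.preset("ssd-like"),
                                 h2_over_L=TRUE_H2L, L=TRUE_L, n=3e5)
            shifted = true_p.with_(
                fs=SelectionDensity.preset("ssd-like").shifted(1.0))
            if nll(hits, true_p, ukb_cache) < nll(hits, shifted, ukb_cache):
                wins += 1
        assert wins >= 5

    def test_empty_table_rejected(self, ukb_cache, canonical_scenario):
        empty = HitTable(data=pd.DataFrame(
            columns=["snp", "maf", "abs_z", "n_eff"]))
        with pytest.raises(ValueError):
            nll(empty, canonical_scenario.params(), ukb_cache)


class TestPenalty:
    def test_flat_density_zero(self):
        assert penalty(SelectionDensity.preset("flat"), 1.0) == 0.0

    def test_zero_weight(self, ssd_fs):
        assert penalty(ssd_fs, 0.0) == 0.0

    def test_linear_in_weight(self):
        fs = SelectionDensity([0.0, -1.0, -2.0, -3.0])  # declining: left
        # slope positive (declining toward -7 going left is fine), right
        # slope negative; growth beyond either end is what gets penalised
        rising = SelectionDensity([-3.0, -2.0, -1.0, 0.0])
        assert penalty(rising, 2.0) == pytest.approx(2 * penalty(rising, 1.0))

    def test_only_outward_growth_penalised(self):
        declining_right = SelectionDensity([0.0, 0.5, -0.5, -2.0])
        sl, sr = declining_right.terminal_slopes()
        expected = (max(-sl, 0) ** 2 + max(sr, 0) ** 2)
        assert penalty(declining_right, 1.0) == pytest.approx(expected)


class TestFitTsd:
    def test_recovery_and_invariants(self, canonical_fit, canonical_hits,
                                     ukb_cache):
        fit = canonical_fit
        # single-replicate sanity: recovery within a factor 2 (the factor-1.5
        # in >=90%-of-replicates claim is exercised in the acceptance suite)
        assert TRUE_H2L / 2 <= fit.params.h2_over_L <= TRUE_H2L * 2
        assert TRUE_L / 2 <= fit.params.L <= TRUE_L * 2
        assert fit.converged and np.isfinite(fit.nll)
        # L matching: expected hit count equals the observed count
        from traitarch.trait import TraitModel

        model = TraitModel(fit.params, ukb_cache)
        assert model.expected_hits() == pytest.approx(len(canonical_hits),
                                                      abs=0.5)

    def test_refit_from_optimum_is_stable(self, canonical_fit, canonical_hits,
                                          ukb_cache):
        from traitarch.inference import _Workspace, _fit_from_workspace

        cfg = FitConfig(n_starts=1, seed=0)
        ws = _Workspace(canonical_hits, ukb_cache, cfg)
        x_opt = np.concatenate([
            canonical_fit.params.fs.knot_logdens[1:]
            - canonical_fit.params.fs.knot_logdens[0],
            [np.log10(canonical_fit.params.h2_over_L)],
        ])
        refit = _fit_from_workspace(ws, canonical_hits, ukb_cache.mu, 3e5,
                                    cfg, starts=[x_opt])
        assert canonical_fit.penalised_nll - refit.penalised_nll < 1e-4

    def test_small_table_warns_but_fits(self, ukb_cache, canonical_hits):
        small = HitTable(data=canonical_hits.data.iloc[:50].reset_index(drop=True),
                         label="small")
        fit = fit_tsd(small, ukb_cache, FitConfig(n_starts=2, seed=1))
        assert any("50 hits" in w for w in fit.warnings)

    def test_monotone_ascertainment_ladder(self, ukb_cache):
        # fitted h2/L strictly increases with the generating h2/L
        from scipy.stats import spearmanr

        truths = [1e-8, 2e-8, 4e-8, 8e-8, 1.6e-7]
        fits = []
        for i, h in enumerate(truths):
            # constant implied h2 = 0.225 so every rung has a few hundred hits
            _, hits = simulate_trait(
                TraitScenario("lad", h2_over_L=h, L=7.5e6 * 3e-8 / h,
                              n=3e5, seed=900 + i),
                cache=ukb_cache, keep_architecture=False)
            fit = fit_tsd(hits, ukb_cache, FitConfig(n_starts=2, seed=i))
            fits.append(fit.params.h2_over_L)
        rho, _ = spearmanr(truths, fits)
        assert rho == pytest.approx(1.0, abs=1e-9)


class TestFitSsd:
    def test_shared_fit_recovers_scales(self, ukb_cache):
        tables = []
        truths = [2e-8, 3e-8, 5e-8]
        for i, h in enumerate(truths):
            _, hits = simulate_trait(
                TraitScenario(f"s{i}", h2_over_L=h, L=6e6, n=3e5, seed=70 + i),
                cache=ukb_cache, keep_architecture=False)
            tables.append(hits)
        ssd = fit_ssd(tables, ukb_cache, FitConfig(n_starts=2, seed=0))
        for (label, fit), h in zip(ssd.trait_fits.items(), truths):
            assert h / 1.5 <= fit.params.h2_over_L <= h * 1.5

    def test_single_trait_matches_tsd(self, canonical_hits, ukb_cache,
                                      canonical_fit):
        ssd = fit_ssd([canonical_hits], ukb_cache, FitConfig(n_starts=2, seed=0))
        (fit,) = ssd.trait_fits.values()
        # same optimum within tolerance (different optimisers)
        assert fit.nll == pytest.approx(canonical_fit.nll, abs=1.0)
        assert np.log10(fit.params.h2_over_L) == pytest.approx(
            np.log10(canonical_fit.params.h2_over_L), abs=0.15)

    def test_tsd_nests_inside_ssd(self, ukb_cache):
        # genuinely different f(s): the constrained SSD cannot beat per-trait fits
        tables = []
        for i, fs in enumerate(["weak", "strong"]):
            _, hits = simulate_trait(
                TraitScenario(f"d{i}", fs=fs, h2_over_L=3e-8, L=6e6, n=3e5,
                              seed=80 + i),
                cache=ukb_cache, keep_architecture=False)
            tables.append(hits)
        ssd = fit_ssd(tables, ukb_cache, FitConfig(n_starts=2, seed=0))
        tsd_sum = sum(
            fit_tsd(t, ukb_cache, FitConfig(n_starts=2, seed=i)).nll
            for i, t in enumerate(tables))
        assert tsd_sum < ssd.joint_nll + 0.5


class TestBootstrap:
    def test_determinism(self, canonical_hits, ukb_cache, canonical_fit):
        cfg = FitConfig(n_starts=1, seed=0)
        e1 = bootstrap(canonical_hits, ukb_cache, b=20, seed=5, config=cfg,
                       point_fit=canonical_fit)
        e2 = bootstrap(canonical_hits, ukb_cache, b=20, seed=5, config=cfg,
                       point_fit=canonical_fit)
        assert np.array_equal(e1.cdf_lo, e2.cdf_lo)
        assert e1.h2_over_l_ci == e2.h2_over_l_ci

    def test_small_b_rejected(self, canonical_hits, ukb_cache, canonical_fit):
        with pytest.raises(ValueError):
            bootstrap(canonical_hits, ukb_cache, b=10, seed=0,
                      point_fit=canonical_fit)

    def test_envelope_contains_point_estimate(self, canonical_hits, ukb_cache,
                                              canonical_fit):
        env = bootstrap(canonical_hits, ukb_cache, b=24, seed=9,
                        config=FitConfig(n_starts=1, seed=0),
                        point_fit=canonical_fit)
        assert np.all(env.cdf_lo <= env.cdf_hi + 1e-12)
        cdf = canonical_fit.params.fs.cdf(env.u_grid)
        inside = (cdf >= env.cdf_lo - 1e-9) & (cdf <= env.cdf_hi + 1e-9)
        assert inside.mean() >= 0.9
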