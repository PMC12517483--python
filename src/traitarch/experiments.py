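"""Self-contained validation experiments for the whole pipeline.

Each function simulates data from the generative model under fixed study
conditions, runs the corresponding part of the inference or prediction
machinery, and returns summary metrics.  They power both the test suite and
``scripts/acceptance.py``.  Problem sizes (replicate counts, target sizes,
trajectory counts, the scaled-down age-study population size) are the
package's defaults for a desk-scale validation run; all randomness flows
from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from traitarch.demography import constant_demography, preset
from traitarch.sfs import (
    FrequencyGrid,
    build_cache,
    compute_k,
    equilibrium_cell_masses,
    present_day_sfs,
)
from traitarch.trait import (
    DiracSelectionDensity,
    SelectionDensity,
    genome_wide_z_threshold,
)
from traitarch.inference import FitConfig, bootstrap, fit_tsd
from traitarch.gof import crossval_residuals, fit_alpha_model, flag_outliers
from traitarch.simulate import TraitScenario, simulate_trait, spike_outlier
from traitarch.scaling import common_threshold_compare, rescale
from traitarch.ages import (
    build_age_pools,
    matched_neutral_ages,
    predicted_hit_ages,
    simulate_ages,
)

__all__ = [
    "sfs_equilibrium_check",
    "k_point_mass_check",
    "recovery_experiment",
    "residual_calibration_experiment",
    "alpha_rejection_experiment",
    "collapse_experiment",
    "age_experiment",
    "RECOVERY_SCENARIO",
]

#: Canonical single-trait study conditions: the shared-like f(s), a
#: heritability per site of 3e-8 (the height / platelet-crit scale), a
#: target size giving ~500 expected hits, and a UK-Biobank-scale sample.
RECOVERY_SCENARIO = dict(fs="ssd-like", h2_over_L=3e-8, L=8.3e6, n=3e5,
                         demography="ukb-default")


def _fit_config(seed: int, n_starts: int = 4) -> FitConfig:
    return FitConfig(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# solver-level checks
# ---------------------------------------------------------------------------


def significance_threshold() -> float:
    return genome_wide_z_threshold(5e-8)


def sfs_equilibrium_check(n_pop: int = 10_000, mu: float = 1.25e-8):
    """Transient solver vs closed-form equilibrium under constant N.

    Returns the relative L1 error for each s, the neutral-shape maximum
    relative error against 4 N mu / q, and the strong-selection
    ``E[2q(1-q)] / (4 mu / s)`` ratio at s = 1e-2.
    """
    grid = FrequencyGrid.logit()
    dem = constant_demography(n_pop)
    out = {"rel_l1": {}, "neutral_shape_max_rel_err": None,
           "e2pq_over_4mu_s": None}
    for s in (0.0, 1e-4, 1e-3, 1e-2):
        lam = present_day_sfs(s, dem, mu, grid)
        exact = equilibrium_cell_masses(s, n_pop, mu, grid)
        num = lam * grid.weights
        out["rel_l1"][s] = float(np.abs(num - exact).sum() / exact.sum())
        if s == 0.0:
            mid = (grid.q > 1e-3) & (grid.q < 0.99)
            shape = lam[mid] * grid.q[mid] / (4.0 * n_pop * mu)
            out["neutral_shape_max_rel_err"] = float(np.abs(shape - 1.0).max())
        if s == 1e-2:
            e2pq = float((lam * 2 * grid.q * (1 - grid.q) * grid.weights).sum())
            out["e2pq_over_4mu_s"] = e2pq / (4.0 * mu / s)
    return out


def k_point_mass_check(log10_s: float = -2.0, n_pop: int = 10_000,
                       mu: float = 1.25e-8) -> float:
    """k for a strong-selection point mass under constant N (about 1)."""
    cache = build_cache(constant_demography(n_pop), mu)
    return compute_k(DiracSelectionDensity(log10_s), cache)


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def recovery_experiment(n_reps: int = 20, seed: int = 0, bootstrap_b: int = 35):
    """Simulate-and-refit study at the canonical conditions.

    Metrics: fractions of replicates with h2/L and L recovered within a
    factor 1.5, and the fraction in which the true f(s) CDF lies inside the
    90% bootstrap envelope at >= 3 of the 4 knot positions.
    """
    cache = build_cache(preset("ukb-default"))
    true_fs = SelectionDensity.preset(RECOVERY_SCENARIO["fs"])
    true_h2l = RECOVERY_SCENARIO["h2_over_L"]
    true_l = RECOVERY_SCENARIO["L"]
    knots = np.asarray(true_fs.knot_positions)
    rng = np.random.default_rng(seed)
    h2l_ok, l_ok, env_ok = [], [], []
    h2l_ratio, l_ratio = [], []
    for rep in range(n_reps):
        sim_seed = int(rng.integers(2**31))
        _, hits = simulate_trait(
            TraitScenario("rec", seed=sim_seed, **RECOVERY_SCENARIO),
            cache=cache, keep_architecture=False)
        cfg = _fit_config(seed=rep)
        fit = fit_tsd(hits, cache, cfg)
        rh = fit.params.h2_over_L / true_h2l
        rl = fit.params.L / true_l
        h2l_ratio.append(rh)
        l_ratio.append(rl)
        h2l_ok.append(1 / 1.5 <= rh <= 1.5)
        l_ok.append(1 / 1.5 <= rl <= 1.5)
        env = bootstrap(hits, cache, b=bootstrap_b,
                        seed=int(rng.integers(2**31)), config=cfg,
                        point_fit=fit)
        env_ok.append(int(env.cdf_covers(true_fs, knots).sum()) >= 3)
    return {
        "h2l_within_factor_1p5": float(np.mean(h2l_ok)),
        "l_within_factor_1p5": float(np.mean(l_ok)),
        "envelope_covers_3_of_4_knots": float(np.mean(env_ok)),
        "h2l_ratios": h2l_ratio,
        "l_ratios": l_ratio,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# residual calibration and outlier flagging
# ---------------------------------------------------------------------------


def residual_calibration_experiment(n_reps: int = 20, seed: int = 0,
                                    spike_factors=(2.0, 5.0)):
    """Cross-validated residual uniformity plus spiked-outlier detection.

    For each replicate: simulate at the canonical conditions, compute 10-fold
    block cross-validated residual p-values (KS uniformity), then re-run the
    analysis with one common hit's z multiplied by each spike factor and
    check whether the spiked snp is Bonferroni-flagged.
    """
    cache = build_cache(preset("ukb-default"))
    rng = np.random.default_rng(seed)
    ks_pass, flagged = [], {f: [] for f in spike_factors}
    ks_pvalues = []
    for rep in range(n_reps):
        sim_seed = int(rng.integers(2**31))
        _, hits = simulate_trait(
            TraitScenario("cal", seed=sim_seed, **RECOVERY_SCENARIO),
            cache=cache, keep_architecture=False)
        cfg = _fit_config(seed=rep, n_starts=2)
        report = crossval_residuals(hits, cache, cfg,
                                    seed=int(rng.integers(2**31)))
        ks_pvalues.append(report.ks_p)
        ks_pass.append(report.ks_p > 0.01)
        for factor in spike_factors:
            spiked, snp = spike_outlier(hits, factor,
                                        seed=int(rng.integers(2**31)))
            rep_sp = crossval_residuals(spiked, cache, cfg,
                                        seed=int(rng.integers(2**31)))
            out = flag_outliers(rep_sp)
            flagged[factor].append(snp in set(out["snp"]))
    return {
        "ks_uniform_pass_fraction": float(np.mean(ks_pass)),
        "ks_pvalues": ks_pvalues,
        "spike_flag_rate": {f: float(np.mean(v)) for f, v in flagged.items()},
        "n_reps": n_reps,
    }


def alpha_rejection_experiment(n_reps: int = 20, seed: int = 0):
    """How often alpha-model residuals fail KS uniformity on model data."""
    from traitarch.gof import ks_uniform

    cache = build_cache(preset("ukb-default"))
    rng = np.random.default_rng(seed)
    rejected = []
    for rep in range(n_reps):
        sim_seed = int(rng.integers(2**31))
        _, hits = simulate_trait(
            TraitScenario("alpha", seed=sim_seed, **RECOVERY_SCENARIO),
            cache=cache, keep_architecture=False)
        am = fit_alpha_model(hits)
        _, p = ks_uniform(am.residual_pvalues(hits))
        rejected.append(p < 0.05)
    return {"alpha_reject_fraction": float(np.mean(rejected)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# scaling collapse
# ---------------------------------------------------------------------------


def collapse_experiment(seed: int = 0, n_pairs: int = 5):
    """Scaling-law collapse for replicate pairs of traits sharing f(s).

    Each pair: trait A (height-like, h2/L = 3e-8) vs trait B (FEV1-like, 6x
    lower), equal sample sizes.  A is pooled over four replicate genomes so
    that >= 300 hits survive B's more stringent scaled threshold (a single
    genome is capped by h2 < 1).  The negative control shifts A's f(s) one
    decade stronger, which should break the MAF collapse.

    Because a *perfect* collapse still fails one of three simultaneous KS
    tests at the 5% level ~14% of the time, the experiment runs ``n_pairs``
    independent pairs and summarises with medians across pairs; per-pair
    results are returned as well.
    """
    from scipy import stats
    import pandas as pd
    from traitarch.trait import HitTable

    cache = build_cache(preset("ukb-default"))
    rng = np.random.default_rng(seed)
    h_hi, h_lo, n = 3e-8, 5e-9, 4.6e5

    def pooled(label, fs, h2l, l_each, n_genomes):
        frames = []
        for g in range(n_genomes):
            _, h = simulate_trait(
                TraitScenario(f"{label}{g}", fs=fs, h2_over_L=h2l, L=l_each,
                              n=n, seed=int(rng.integers(2**31))),
                cache=cache, keep_architecture=False)
            frames.append(h.data)
        df = pd.concat(frames, ignore_index=True)
        return HitTable(data=df, label=label)

    pairs = []
    for _ in range(n_pairs):
        a = pooled("height-like", "ssd-like", h_hi, 2.0e7, 4)
        b = pooled("fev1-like", "ssd-like", h_lo, 1.3e8, 1)
        pre = stats.ks_2samp(a.abs_z, b.abs_z)
        sa, sb = rescale(a, h_hi), rescale(b, h_lo)
        report = common_threshold_compare(sa, sb)
        neg = pooled("shifted",
                     SelectionDensity.preset("ssd-like").shifted(1.0),
                     h_lo, 1.3e8, 1)
        neg_report = common_threshold_compare(sa, rescale(neg, h_lo))
        pairs.append({
            "pre_scaling_z_ks_p": float(pre.pvalue),
            "post_ks_p": {m: report.pvalue(m) for m in report.ks.index},
            "post_min_ks_p": report.min_pvalue(),
            "n_survivors": (report.n_a, report.n_b),
            "negative_control_maf_ks_p": neg_report.pvalue("maf"),
            "n_hits": (len(a), len(b)),
        })
    return {
        "pairs": pairs,
        "n_pairs": n_pairs,
        "median_pre_scaling_z_ks_p": float(np.median(
            [p["pre_scaling_z_ks_p"] for p in pairs])),
        "median_post_min_ks_p": float(np.median(
            [p["post_min_ks_p"] for p in pairs])),
        "median_negative_control_maf_ks_p": float(np.median(
            [p["negative_control_maf_ks_p"] for p in pairs])),
        "min_survivors": int(min(min(p["n_survivors"]) for p in pairs)),
    }


# ---------------------------------------------------------------------------
# allele ages
# ---------------------------------------------------------------------------


def age_experiment(seed: int = 0, n_pop: int = 5_000, reps: int = 1_200_000,
                   oracle_n: int = 150, oracle_reps: int = 400_000):
    """Hit-age prediction vs frequency-matched neutral ages (scaled down).

    The age study runs under a constant population of ``n_pop`` diploids (a
    scaled-down stand-in for the full history, which only sharpens with
    size): hits are simulated and fitted at the canonical trait conditions,
    ages are drawn from trajectory pools, and the predicted hit-age CDF is
    compared with the neutral frequency-matched CDF.  Separately the neutral
    simulator's mean age of common alleles is checked against a small-N
    Wright-Fisher matrix oracle (returned as simulator mean + oracle inputs;
    the oracle itself lives in the caller/tests to stay independent).
    """
    dem = constant_demography(n_pop)
    cache = build_cache(dem)
    rng = np.random.default_rng(seed)
    _, hits = simulate_trait(
        TraitScenario("ages", fs="ssd-like", h2_over_L=3e-8, L=8.3e6, n=3e5,
                      demography=dem, seed=int(rng.integers(2**31))),
        cache=cache, keep_architecture=False)
    fit = fit_tsd(hits, cache, _fit_config(seed=1, n_starts=2))
    pools = build_age_pools(
        dem, cache.mu, reps, int(rng.integers(2**30)),
        s_values=(0.0, 1e-4, 10**-3.5, 1e-3, 10**-2.5, 1e-2))
    predicted = predicted_hit_ages(fit.params, hits, cache, pools,
                                   int(rng.integers(2**30)),
                                   condition_on_z=True)
    neutral = matched_neutral_ages(hits, pools[0.0], int(rng.integers(2**30)))
    # CDF dominance of predicted (younger) over neutral on a quantile grid
    grid = np.quantile(neutral, np.linspace(0.1, 0.9, 17))
    f_pred = np.array([np.mean(predicted <= g) for g in grid])
    f_neut = np.array([np.mean(neutral <= g) for g in grid])
    # the independent sampling unit is the hit, not the (20x clustered)
    # age draw: two binomial CDFs at ~n_hits effective samples each
    mc_err = 2.0 * np.sqrt(0.5 / len(hits))
    # neutral simulator sample for the oracle comparison at small N
    small = simulate_ages(0.0, constant_demography(oracle_n), cache.mu,
                          oracle_reps, int(rng.integers(2**30)))
    common = small.in_maf_bin(0.1, 0.5)
    return {
        "median_hit_age": float(np.median(predicted)),
        "median_neutral_age": float(np.median(neutral)),
        "median_age_ratio": float(np.median(predicted) / np.median(neutral)),
        "cdf_dominance_ok": bool(np.all(f_pred >= f_neut - mc_err)),
        "min_cdf_gap": float((f_pred - f_neut).min()),
        "mc_err": float(mc_err),
        "neutral_mean_common_age_small_n": float(common.mean()),
        "oracle_n": oracle_n,
        "oracle_t_max": int(small.t_max),
        "n_hits": len(hits),
    }
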