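"""Model criticism: residual p-values, cross-validation, baselines.

The central diagnostic is the *residual p-value* of a hit,

    Pr(|z| > z_i | |z| > threshold, maf_i, model),

a probability-integral transform that is Uniform(0,1) when the model's
conditional z-score distribution is correct: skew toward 1 means observed
z-scores are too small, skew toward 0 too large.  To avoid scoring hits with
a model fitted to them, residuals are computed block-wise out of sample:
genome blocks are split into folds, the model is refitted on 90% of blocks
and the held-out 10% are scored.

Two heuristic baselines are fitted under identical ascertainment for
comparison: a *normal-effects* model (effect variance independent of
frequency) and the *alpha-model* (effect variance proportional to
``[2q(1-q)]^alpha``).  Both are conditional-on-frequency Gaussian models,
so their residual p-values use the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from traitarch.sfs import ConditionalSFS
from traitarch.trait import HitTable, TraitModel, _q_tail
from traitarch.inference import FitConfig, TraitFit, fit_tsd, _Workspace, _fit_from_workspace

__all__ = [
    "ResidualReport",
    "AlphaModelFit",
    "residual_pvalue",
    "crossval_residuals",
    "ks_uniform",
    "bh_fdr",
    "flag_outliers",
    "fit_alpha_model",
    "fit_normal_model",
    "model_conditional_nll",
]


@dataclass
class ResidualReport:
    """Per-hit residual p-values with fold assignment and GOF summaries."""

    table: pd.DataFrame  # snp, maf, abs_z, fold, residual_p
    ks_stat: float
    ks_p: float
    label: str = ""

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["residual_p"].to_numpy(float)

    def qq_data(self) -> pd.DataFrame:
        """Expected vs observed quantiles of the residual p-values."""
        p = np.sort(self.pvalues)
        n = p.size
        return pd.DataFrame({
            "expected": (np.arange(1, n + 1) - 0.5) / n,
            "observed": p,
        })


def residual_pvalue(z, q, model: TraitModel, n=None):
    """Residual p-value(s) of observed |z| at MAF q under a trait model."""
    return model.conditional_z_tail_given_q(z, q, n)


def ks_uniform(pvals) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against Uniform(0,1)."""
    pvals = np.asarray(pvals, dtype=float)
    res = stats.kstest(pvals, "uniform")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals, level: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask at the given FDR."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    rejected, _, _, _ = multipletests(pvals, alpha=level, method="fdr_bh")
    return rejected


def flag_outliers(report: ResidualReport, n_tests: int | None = None,
                  level: float = 0.05) -> pd.DataFrame:
    """Hits whose residual p-value survives Bonferroni correction."""
    if len(report.table) == 0:
        return report.table.copy()
    n_tests = n_tests if n_tests is not None else len(report.table)
    cut = level / n_tests
    return report.table[report.table["residual_p"] < cut].copy()


# ---------------------------------------------------------------------------
# cross-validated residuals
# ---------------------------------------------------------------------------


def crossval_residuals(
    hits: HitTable,
    cache: ConditionalSFS,
    config: FitConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    warm_fit: TraitFit | None = None,
) -> ResidualReport:
    """Block-wise out-of-sample residual p-values.

    Blocks are randomly partitioned into ``n_folds`` folds; for each fold
    the model is refitted on the complement (warm-started at the full-data
    optimum) and the held-out hits are scored.  Every hit is scored exactly
    once.
    """
    config = config or FitConfig()
    blocks = hits.block
    if blocks is None:
        raise ValueError("cross-validation requires a block column")
    uniq = np.unique(blocks)
    if uniq.size < n_folds:
        raise ValueError(f"need at least {n_folds} blocks, got {uniq.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    fold_of_block = {b: i % n_folds for i, b in enumerate(perm)}
    fold = np.array([fold_of_block[b] for b in blocks])

    if warm_fit is None:
        warm_fit = fit_tsd(hits, cache, config)
    x_warm = np.concatenate([
        warm_fit.params.fs.knot_logdens[1:] - warm_fit.params.fs.knot_logdens[0],
        [np.log10(warm_fit.params.h2_over_L)],
    ])
    warm_config = FitConfig(**{**config.__dict__, "n_starts": 1,
                               "maxiter": max(200, config.maxiter // 2)})

    rows = []
    for f in range(n_folds):
        held = fold == f
        train_df = hits.data.loc[~held].reset_index(drop=True)
        train = HitTable(data=train_df, label=hits.label)
        ws = _Workspace(train, cache, warm_config)
        fit = _fit_from_workspace(ws, train, cache.mu,
                                  float(np.median(train.n_eff)), warm_config,
                                  starts=[x_warm.copy()])
        model = TraitModel(fit.params, cache)
        held_df = hits.data.loc[held]
        pvals = model.conditional_z_tail_given_q(
            held_df["abs_z"].to_numpy(float), held_df["maf"].to_numpy(float),
            held_df["n_eff"].to_numpy(float),
        )
        for (_, r), p in zip(held_df.iterrows(), np.atleast_1d(pvals)):
            rows.append((r["snp"], r["maf"], r["abs_z"], f, float(p)))
    table = pd.DataFrame(rows, columns=["snp", "maf", "abs_z", "fold", "residual_p"])
    d, p = ks_uniform(table["residual_p"])
    return ResidualReport(table=table, ks_stat=d, ks_p=p, label=hits.label)


def insample_residuals(hits: HitTable, model: TraitModel) -> ResidualReport:
    """Residual p-values of all hits under a fixed (already fitted) model."""
    pvals = model.conditional_z_tail_given_q(hits.abs_z, hits.maf, hits.n_eff)
    table = pd.DataFrame({
        "snp": hits.data["snp"], "maf": hits.maf, "abs_z": hits.abs_z,
        "fold": -1, "residual_p": np.atleast_1d(pvals),
    })
    d, p = ks_uniform(table["residual_p"])
    return ResidualReport(table=table, ks_stat=d, ks_p=p, label=hits.label)


# ---------------------------------------------------------------------------
# heuristic baselines
# ---------------------------------------------------------------------------


@dataclass
class AlphaModelFit:
    """Frequency-power-law Gaussian effects: beta|q ~ N(0, sigma2 [2q(1-q)]^alpha)."""

    alpha: float
    sigma2: float
    nll: float
    converged: bool

    def z_sd(self, maf: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
        twopq = 2.0 * np.asarray(maf) * (1.0 - np.asarray(maf))
        var_beta = self.sigma2 * twopq**self.alpha
        return np.sqrt(1.0 + var_beta * twopq * np.asarray(n_eff))

    def residual_pvalues(self, hits: HitTable, z_thresh: float = 5.45) -> np.ndarray:
        sd = self.z_sd(hits.maf, hits.n_eff)
        return _q_tail(hits.abs_z / sd) / _q_tail(z_thresh / sd)

    def report(self, hits: HitTable) -> ResidualReport:
        p = self.residual_pvalues(hits)
        table = pd.DataFrame({
            "snp": hits.data["snp"], "maf": hits.maf, "abs_z": hits.abs_z,
            "fold": -1, "residual_p": p,
        })
        d, pv = ks_uniform(p)
        return ResidualReport(table=table, ks_stat=d, ks_p=pv, label=hits.label)


def _conditional_gaussian_nll(log_sigma2: float, alpha: float,
                              hits: HitTable, z_thresh: float) -> float:
    sigma2 = np.exp(log_sigma2)
    twopq = 2.0 * hits.maf * (1.0 - hits.maf)
    sd = np.sqrt(1.0 + sigma2 * twopq**alpha * twopq * hits.n_eff)
    zz = hits.abs_z / sd
    # density of |z| given ascertainment |z| > threshold at fixed maf:
    # 2 phi(z/sd)/sd / (2 Q(thresh/sd)); constants kept so the value is
    # directly comparable with model_conditional_nll
    log_dens = (-0.5 * zz**2 - 0.5 * np.log(2.0 * np.pi) - np.log(sd)
                - np.log(_q_tail(z_thresh / sd)))
    return float(-np.sum(log_dens))


def fit_alpha_model(hits: HitTable, z_thresh: float = 5.45,
                    fixed_alpha: float | None = None) -> AlphaModelFit:
    """ML fit of the alpha-model conditional on observed frequencies.

    The likelihood conditions on each hit's MAF and on ascertainment
    ``|z| > threshold``, matching how residual p-values are computed.
    """
    z2 = np.maximum(hits.abs_z**2 - 1.0, 1.0)
    twopq = 2.0 * hits.maf * (1.0 - hits.maf)
    sig0 = float(np.log(np.median(z2 / (twopq * hits.n_eff))))
    if fixed_alpha is not None:
        res = minimize(
            lambda x: _conditional_gaussian_nll(x[0], fixed_alpha, hits, z_thresh),
            [sig0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("alpha-model fit failed to converge")
        return AlphaModelFit(alpha=float(fixed_alpha), sigma2=float(np.exp(res.x[0])),
                             nll=float(res.fun), converged=bool(res.success))
    best = None
    for a0 in (-0.8, -0.4, 0.0):
        res = minimize(
            lambda x: _conditional_gaussian_nll(x[0], x[1], hits, z_thresh),
            [sig0 - a0 * float(np.mean(np.log(twopq))), a0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 800},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("alpha-model fit failed to converge")
    return AlphaModelFit(alpha=float(best.x[1]), sigma2=float(np.exp(best.x[0])),
                         nll=float(best.fun), converged=bool(best.success))


def fit_normal_model(hits: HitTable, z_thresh: float = 5.45) -> AlphaModelFit:
    """Normal-effects baseline: the alpha-model with alpha fixed at 0."""
    return fit_alpha_model(hits, z_thresh, fixed_alpha=0.0)


def model_conditional_nll(hits: HitTable, model: TraitModel) -> float:
    """Conditional-on-frequency nll of the main model (baseline-comparable).

    ``-sum_i log p(z_i | maf_i, |z| > threshold)``, the same conditioning the
    alpha and normal baselines use, so the three values are directly
    comparable.
    """
    p = model.params
    lam = model.cache.lam_maf_at(hits.maf)  # (n_s, n_hits)
    v = model.beta_variance(model.s)
    sd = np.sqrt(1.0 + v[:, None] * (2.0 * hits.maf * (1.0 - hits.maf)
                                     * hits.n_eff)[None, :])
    w = model.wu[:, None] * model.rho[:, None] * lam
    zz = hits.abs_z[None, :] / sd
    # num/den is the proper conditional density (phi carries its 1/sqrt(2 pi))
    num = np.sum(w * np.exp(-0.5 * zz**2) / (np.sqrt(2.0 * np.pi) * sd), axis=0)
    den = np.sum(w * _q_tail(p.z_thresh / sd), axis=0)
    if np.any(num <= 0) or np.any(den <= 0):
        return np.inf
    return float(-np.sum(np.log(num) - np.log(den)))
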