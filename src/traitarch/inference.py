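"""Ascertainment-corrected maximum-likelihood fitting.

The likelihood of a trait's hit table conditions on ascertainment: each hit
contributes ``log[ density(maf_i, |z|_i) / Pr(hit) ]``, where the joint
density and the per-site hit probability both integrate the (s, q, beta, z)
hierarchy over the cached conditional SFS.  The mutational target size L
never enters this conditional likelihood; it is estimated afterwards by
matching the expected number of hits to the observed count.

Fitted quantities per trait: the four spline knot values of f(s) (identified
up to an additive constant, so three free shape parameters), the
heritability per site h2/L, and L.  Regularisation keeps f(s) sensible at
the extremes of the selection range, where GWAS hits carry almost no
information: (i) log-density growth beyond the terminal knots toward either
extreme is penalised (flat or declining tails are free), and (ii) the
heritability-decomposition constant k is softly capped, since k far above 1
signals that the fit is loading heritability onto effectively-neutral sites
-- a direction the ascertained likelihood cannot distinguish from the
truth.  The shared-distribution (SSD) fit ties one f(s) across traits,
leaving one shape-relevant free parameter per trait (h2/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from traitarch.sfs import ConditionalSFS, _trapezoid_weights
from traitarch.trait import (
    DEFAULT_KNOTS,
    HitTable,
    SelectionDensity,
    TraitParams,
    _phi,
    _q_tail,
)

__all__ = [
    "FitConfig",
    "TraitFit",
    "SSDFit",
    "BootstrapEnvelope",
    "nll",
    "penalty",
    "fit_tsd",
    "fit_ssd",
    "bootstrap",
]


@dataclass
class FitConfig:
    """Optimiser and regularisation settings for the maximum-likelihood fits."""

    penalty_weight: float = 1.0
    k_penalty_weight: float = 50.0
    k_reference: float | None = None  # None: k of the reference shape
    knot_positions: tuple[float, ...] = DEFAULT_KNOTS
    n_starts: int = 8
    seed: int = 0
    maxiter: int = 600
    tol: float = 1e-6
    log10_h2l_bounds: tuple[float, float] = (-10.5, -5.0)
    ssd_tol: float = 1e-3
    ssd_max_rounds: int = 60


@dataclass
class TraitFit:
    """A fitted trait: parameters, objective value and provenance."""

    params: TraitParams
    nll: float
    penalised_nll: float
    converged: bool
    n_hits_used: int
    penalty_weight: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class SSDFit:
    """Joint fit with a single shared f(s) and per-trait (h2/L, L)."""

    fs: SelectionDensity
    trait_fits: dict[str, TraitFit]
    joint_nll: float
    converged: bool


@dataclass
class BootstrapEnvelope:
    """Percentile envelopes over bootstrap refits."""

    u_grid: np.ndarray
    cdf_lo: np.ndarray  # 5% pointwise quantile of the f(s) CDF
    cdf_hi: np.ndarray  # 95%
    h2_over_l_ci: tuple[float, float]
    l_ci: tuple[float, float]
    replicates: list[TraitFit]

    def cdf_covers(self, fs: SelectionDensity, at_u: np.ndarray) -> np.ndarray:
        """Whether a reference CDF lies inside the envelope at given log10 s."""
        ref = np.interp(at_u, self.u_grid, fs.cdf(self.u_grid))
        lo = np.interp(at_u, self.u_grid, self.cdf_lo)
        hi = np.interp(at_u, self.u_grid, self.cdf_hi)
        return (ref >= lo - 1e-12) & (ref <= hi + 1e-12)


# ---------------------------------------------------------------------------
# likelihood workspace
# ---------------------------------------------------------------------------


class _Workspace:
    """Precomputed per-dataset quadrature tables for fast objective evaluation."""

    def __init__(self, hits: HitTable, cache: ConditionalSFS, config: FitConfig,
                 maf_min: float = 0.01, z_thresh: float = 5.45):
        self.cache = cache
        self.config = config
        self.maf_min = maf_min
        self.z_thresh = z_thresh
        self.u = cache.log10_s
        self.wu = _trapezoid_weights(self.u)
        self.s = cache.s
        self.e2pq = cache.e2pq
        asc = cache.maf >= maf_min
        self.maf_grid = cache.maf[asc]
        self.maf_w = cache.maf_weights[asc]
        self.lam_grid = cache.lam_maf[:, asc]  # (n_s, n_m)
        self.twopq_grid = 2.0 * self.maf_grid * (1.0 - self.maf_grid)
        self.maf_i = hits.maf
        self.z_i = hits.abs_z
        self.n_i = hits.n_eff
        self.lam_i = cache.lam_maf_at(self.maf_i)  # (n_s, n_hits)
        self.twopq_i = 2.0 * self.maf_i * (1.0 - self.maf_i)
        # group hits by effective sample size so Pr(hit) is computed per group
        self.n_values, self.n_group = np.unique(self.n_i, return_inverse=True)
        self.n_counts = np.bincount(self.n_group)
        self.n_hits = len(hits)
        # reference value of the heritability constant toward which fits are
        # shrunk (h2/L and k are only jointly identified from ascertained
        # hits; see `regularisation`)
        if config.k_reference is not None:
            self.k_ref = float(config.k_reference)
        else:
            self.k_ref = self.k_of(self.make_fs(_BASE_SHAPE).density_log10(self.u))

    # un-penalised negative log-likelihood for given shape/scale ------------
    def nll_theta(self, shape: np.ndarray, log10_h2l: float) -> float:
        fs = self.make_fs(shape)
        rho = fs.density_log10(self.u)
        return self._nll_rho(rho, log10_h2l)

    def _nll_rho(self, rho: np.ndarray, log10_h2l: float) -> float:
        w_s = self.wu * rho
        denom_k = float(np.sum(w_s * self.s * self.e2pq))
        if denom_k <= 0 or not np.isfinite(denom_k):
            return np.inf
        # Var(beta|s) = (h2/L) k s/(4 mu) with k = 4 mu / denom_k
        v = 10.0**log10_h2l * self.s / denom_k
        # per-hit joint density
        sd_i = np.sqrt(1.0 + v[:, None] * self.twopq_i[None, :] * self.n_i[None, :])
        dens = np.sum(
            (w_s[:, None] * self.lam_i) * _phi(self.z_i[None, :] / sd_i) * 2.0 / sd_i,
            axis=0,
        )
        if np.any(dens <= 0):
            return np.inf
        # per-group ascertainment probability
        log_psig = np.empty(self.n_values.size)
        for g, n in enumerate(self.n_values):
            sd = np.sqrt(1.0 + v[:, None] * self.twopq_grid[None, :] * n)
            tail = 2.0 * _q_tail(self.z_thresh / sd)
            psig = float(np.sum(w_s * ((self.lam_grid * tail) @ self.maf_w)))
            if psig <= 0:
                return np.inf
            log_psig[g] = np.log(psig)
        return float(-np.sum(np.log(dens)) + np.sum(self.n_counts * log_psig))

    def prob_significant(self, fs: SelectionDensity, log10_h2l: float) -> float:
        """Hit-count-weighted ascertainment probability across n_eff groups."""
        rho = fs.density_log10(self.u)
        w_s = self.wu * rho
        denom_k = float(np.sum(w_s * self.s * self.e2pq))
        v = 10.0**log10_h2l * self.s / denom_k
        total = 0.0
        for g, n in enumerate(self.n_values):
            sd = np.sqrt(1.0 + v[:, None] * self.twopq_grid[None, :] * n)
            tail = 2.0 * _q_tail(self.z_thresh / sd)
            psig = float(np.sum(w_s * ((self.lam_grid * tail) @ self.maf_w)))
            total += self.n_counts[g] * psig
        return total / self.n_counts.sum()

    def make_fs(self, shape: np.ndarray) -> SelectionDensity:
        """Shape parameters are knot log-densities with the first pinned at 0."""
        knots = np.concatenate([[0.0], np.asarray(shape, dtype=float)])
        return SelectionDensity(knots, self.config.knot_positions)

    def k_of(self, rho: np.ndarray) -> float:
        denom = float(np.sum(self.wu * rho * self.s * self.e2pq))
        return 4.0 * self.cache.mu / denom if denom > 0 else np.inf

    def regularisation(self, fs: SelectionDensity, rho: np.ndarray) -> float:
        """Tail-growth penalty plus shrinkage of k toward the reference.

        The ascertained likelihood identifies the product (h2/L)*k but is
        nearly flat along k itself (mass of effectively-neutral mutations
        trades off against the effect-size scale).  Shrinking log10 k toward
        the reference shape's value pins that direction; the spline stays
        data-driven along every identified direction.
        """
        cfg = self.config
        pen = penalty(fs, cfg.penalty_weight)
        k = self.k_of(rho)
        if np.isfinite(k):
            pen += cfg.k_penalty_weight * np.log10(k / self.k_ref) ** 2
        return pen

    def objective(self, x: np.ndarray) -> float:
        shape, log10_h2l = x[:-1], x[-1]
        lo, hi = self.config.log10_h2l_bounds
        if not (lo <= log10_h2l <= hi) or np.any(np.abs(shape) > 12):
            return np.inf
        fs = self.make_fs(shape)
        rho = fs.density_log10(self.u)
        return self._nll_rho(rho, log10_h2l) + self.regularisation(fs, rho)


# ---------------------------------------------------------------------------
# public objective pieces
# ---------------------------------------------------------------------------


def nll(hits: HitTable, params: TraitParams, cache: ConditionalSFS,
        config: FitConfig | None = None) -> float:
    """Conditional negative log-likelihood of a hit table under ``params``.

    ``-sum_i log[density(maf_i, z_i) / Pr(hit)]``; L does not enter.
    """
    if len(hits) == 0:
        raise ValueError("empty hit table")
    config = config or FitConfig()
    ws = _Workspace(hits, cache, config, params.maf_min, params.z_thresh)
    rho = params.fs.density_log10(ws.u)
    return ws._nll_rho(rho, np.log10(params.h2_over_L))


def penalty(fs: SelectionDensity, weight: float) -> float:
    """Tail regularisation: squared log-density growth toward the extremes.

    Only outward *growth* is penalised -- a left (neutral-end) extrapolation
    slope below zero or a right (strong-end) slope above zero; flat tails
    incur no penalty, and the penalty is linear in ``weight``.
    """
    sl, sr = fs.terminal_slopes()
    return weight * (max(-sl, 0.0) ** 2 + max(sr, 0.0) ** 2)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_BASE_SHAPE = np.array(SelectionDensity.preset("ssd-like").knot_logdens)
_BASE_SHAPE = _BASE_SHAPE[1:] - _BASE_SHAPE[0]


def _initial_points(ws: _Workspace, rng: np.random.Generator,
                    n_starts: int) -> list[np.ndarray]:
    """Moment-matched initialisation plus seeded jitter.

    The h2/L scale is located by a coarse scan of the profile likelihood at
    the broad default shape; subsequent starts jitter both shape and scale
    to step off the known ridge between the f(s) scale and h2/L.
    """
    scan = np.arange(ws.config.log10_h2l_bounds[0] + 0.5,
                     ws.config.log10_h2l_bounds[1] - 0.4, 0.5)
    nlls = [ws.nll_theta(_BASE_SHAPE, g) for g in scan]
    g0 = float(scan[int(np.argmin(nlls))])
    points = [np.concatenate([_BASE_SHAPE, [g0]])]
    for _ in range(n_starts - 1):
        jitter = np.concatenate(
            [rng.normal(0.0, 0.6, size=_BASE_SHAPE.size), rng.normal(0.0, 0.4, 1)]
        )
        points.append(points[0] + jitter)
    return points


def _polish(ws: _Workspace, x0: np.ndarray, maxiter: int):
    res = minimize(
        ws.objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7},
    )
    return res


def _fit_from_workspace(ws: _Workspace, hits: HitTable, mu: float, n_trait: float,
                        config: FitConfig, *, starts: list[np.ndarray] | None = None
                        ) -> TraitFit:
    rng = np.random.default_rng(config.seed)
    warnings_list: list[str] = []
    if len(hits) < 100:
        warnings_list.append(
            f"only {len(hits)} hits; estimates are noisy below ~100 hits"
        )
    if starts is None:
        starts = _initial_points(ws, rng, config.n_starts)
    best = None
    any_converged = False
    for x0 in starts:
        res = _polish(ws, x0, config.maxiter)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimiser starts failed to converge; trace: "
                           f"{best}")
    shape, log10_h2l = best.x[:-1], best.x[-1]
    fs = ws.make_fs(shape)
    psig = ws.prob_significant(fs, log10_h2l)
    l_hat = len(hits) / psig
    if l_hat * 10.0**log10_h2l >= 1.0:
        warnings_list.append(
            f"hit-count-matched L = {l_hat:.3g} implies h2 >= 1; "
            "capped at the h2 < 1 boundary"
        )
        l_hat = 0.999 / 10.0**log10_h2l
    params = TraitParams(
        fs=fs, h2_over_L=10.0**log10_h2l, L=l_hat, mu=mu, n=float(n_trait),
        maf_min=ws.maf_min, z_thresh=ws.z_thresh,
    )
    data_nll = ws.nll_theta(shape, log10_h2l)
    return TraitFit(
        params=params,
        nll=float(data_nll),
        penalised_nll=float(best.fun),
        converged=any_converged,
        n_hits_used=len(hits),
        penalty_weight=config.penalty_weight,
        warnings=warnings_list,
    )


def fit_tsd(hits: HitTable, cache: ConditionalSFS,
            config: FitConfig | None = None) -> TraitFit:
    """Trait-specific fit: f(s) shape, h2/L by ML; L by hit-count matching."""
    if len(hits) == 0:
        raise ValueError("empty hit table")
    config = config or FitConfig()
    ws = _Workspace(hits, cache, config)
    n_trait = float(np.median(hits.n_eff))
    return _fit_from_workspace(ws, hits, cache.mu, n_trait, config)


def fit_ssd(hit_tables: Sequence[HitTable], cache: ConditionalSFS,
            config: FitConfig | None = None) -> SSDFit:
    """Joint fit with one shared f(s): block-coordinate over shape and h2/L."""
    if len(hit_tables) < 1:
        raise ValueError("need at least one hit table")
    config = config or FitConfig()
    workspaces = [_Workspace(h, cache, config) for h in hit_tables]
    rng = np.random.default_rng(config.seed)
    shape = _BASE_SHAPE.copy()
    # initial per-trait scales from a coarse profile scan at the base shape
    scales = []
    for ws in workspaces:
        scan = np.arange(config.log10_h2l_bounds[0] + 0.5,
                         config.log10_h2l_bounds[1] - 0.4, 0.5)
        scales.append(float(scan[int(np.argmin([ws.nll_theta(shape, g)
                                                for g in scan]))]))
    scales = np.array(scales)

    def joint(shape_x: np.ndarray) -> float:
        if np.any(np.abs(shape_x) > 12):
            return np.inf
        fs = workspaces[0].make_fs(shape_x)
        rho = fs.density_log10(workspaces[0].u)
        pen = workspaces[0].regularisation(fs, rho)
        return sum(ws._nll_rho(rho, g) for ws, g in zip(workspaces, scales)) + pen

    prev = joint(shape)
    converged = False
    for _ in range(config.ssd_max_rounds):
        # per-trait scale refinement (1-D, smooth)
        for i, ws in enumerate(workspaces):
            res = minimize_scalar(
                lambda g, _ws=ws: _ws.nll_theta(shape, g),
                bounds=config.log10_h2l_bounds, method="bounded",
                options={"xatol": 1e-4},
            )
            scales[i] = res.x
        # shared shape refinement
        res = minimize(joint, shape, method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-7})
        shape = res.x
        cur = res.fun
        if abs(prev - cur) < config.ssd_tol:
            converged = True
            prev = cur
            break
        prev = cur

    fs = workspaces[0].make_fs(shape)
    trait_fits: dict[str, TraitFit] = {}
    joint_nll = 0.0
    for ws, g, hits in zip(workspaces, scales, hit_tables):
        psig = ws.prob_significant(fs, g)
        l_hat = len(hits) / psig
        params = TraitParams(fs=fs, h2_over_L=10.0**g, L=l_hat, mu=cache.mu,
                             n=float(np.median(hits.n_eff)))
        data_nll = ws.nll_theta(shape, g)
        joint_nll += data_nll
        label = hits.label or f"trait{len(trait_fits)}"
        trait_fits[label] = TraitFit(
            params=params, nll=float(data_nll),
            penalised_nll=float(data_nll + penalty(fs, config.penalty_weight)),
            converged=converged, n_hits_used=len(hits),
            penalty_weight=config.penalty_weight,
        )
    return SSDFit(fs=fs, trait_fits=trait_fits, joint_nll=float(joint_nll),
                  converged=converged)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap(hits: HitTable, cache: ConditionalSFS, b: int, seed: int,
              config: FitConfig | None = None,
              point_fit: TraitFit | None = None) -> BootstrapEnvelope:
    """Percentile bootstrap over hits (block-wise when block ids exist).

    Each resample is refitted from a warm start at the point estimate; the
    envelope is the pointwise 5/95% band of the f(s) CDF plus percentile CIs
    for h2/L and L.
    """
    if b < 20:
        raise ValueError("need at least 20 bootstrap replicates for a 90% envelope")
    config = config or FitConfig()
    if point_fit is None:
        point_fit = fit_tsd(hits, cache, config)
    x_point = np.concatenate([
        point_fit.params.fs.knot_logdens[1:] - point_fit.params.fs.knot_logdens[0],
        [np.log10(point_fit.params.h2_over_L)],
    ])
    rng = np.random.default_rng(seed)
    blocks = hits.block
    fits: list[TraitFit] = []
    warm_config = FitConfig(**{**config.__dict__, "n_starts": 1,
                               "maxiter": max(200, config.maxiter // 2)})
    for _ in range(b):
        if blocks is not None:
            uniq = np.unique(blocks)
            chosen = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([np.flatnonzero(blocks == c) for c in chosen])
        else:
            idx = rng.integers(0, len(hits), size=len(hits))
        df = hits.data.iloc[idx].reset_index(drop=True)
        resampled = HitTable(data=df, label=hits.label)
        ws = _Workspace(resampled, cache, warm_config)
        fit = _fit_from_workspace(ws, resampled, cache.mu,
                                  float(np.median(resampled.n_eff)),
                                  warm_config, starts=[x_point.copy()])
        fits.append(fit)
    u = cache.log10_s
    cdfs = np.array([f.params.fs.cdf(u) for f in fits])
    h2ls = np.array([f.params.h2_over_L for f in fits])
    ls = np.array([f.params.L for f in fits])
    return BootstrapEnvelope(
        u_grid=u,
        cdf_lo=np.quantile(cdfs, 0.05, axis=0),
        cdf_hi=np.quantile(cdfs, 0.95, axis=0),
        h2_over_l_ci=(float(np.quantile(h2ls, 0.05)), float(np.quantile(h2ls, 0.95))),
        l_ci=(float(np.quantile(ls, 0.05)), float(np.quantile(ls, 0.95))),
        replicates=fits,
    )
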