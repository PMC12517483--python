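"""The generative model of a trait's architecture.

A trait-affecting site draws a selection coefficient ``s ~ f(s)``; its
present-day derived frequency follows the conditional SFS ``lambda(q|s)``;
its effect on the focal trait (in trait standard deviations) is

    beta | s ~ Normal(0, (h2/L) * k * s / (4 mu)),

where ``k`` is the self-consistency constant of the heritability
decomposition (approximately 1 under strong selection); and the observed
GWAS z-score is ``z | beta, q ~ Normal(beta * sqrt(2 q (1-q) n), 1)``.
GWAS hits are the sites with minor allele frequency >= 1% and |z| above the
genome-wide threshold 5.45 (the two-sided normal quantile of p = 5e-8).

The module owns the spline-parameterised selection-coefficient density
``SelectionDensity``, the per-trait parameter bundle ``TraitParams``, the
ascertained hit table, and the quadrature machinery (``TraitModel``) for the
joint hit density, the significance probability and the conditional
distributions that underlie both inference and the scaling laws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.special import ndtr, ndtri

from traitarch.sfs import (
    ConditionalSFS,
    DEFAULT_MU,
    LOG10_S_MAX,
    LOG10_S_MIN,
    compute_k,
    _trapezoid_weights,
)

__all__ = [
    "genome_wide_z_threshold",
    "Z_THRESHOLD",
    "MAF_MIN",
    "SelectionDensity",
    "DiracSelectionDensity",
    "TraitParams",
    "TraitModel",
    "HitTable",
    "DEFAULT_KNOTS",
]


def genome_wide_z_threshold(p: float = 5e-8) -> float:
    """Two-sided standard-normal |z| quantile for a genome-wide p-value."""
    return float(-ndtri(p / 2.0))


#: Conventional genome-wide threshold, |z| > 5.45 for p < 5e-8.
Z_THRESHOLD = 5.45
#: Imputation-driven minor-allele-frequency cutoff.
MAF_MIN = 0.01

DEFAULT_KNOTS = (-6.0, -4.5, -3.0, -1.5)


# ---------------------------------------------------------------------------
# selection-coefficient densities
# ---------------------------------------------------------------------------


class SelectionDensity:
    """Spline density of selection coefficients on the log10 s axis.

    ``log10 density`` is a natural cubic interpolation of four knot values at
    fixed knot positions, extrapolated linearly beyond the terminal knots
    (using the end-knot derivatives) and truncated to
    ``s in [1e-7, 1e-1]``.  The density is defined up to an additive
    constant in the knot values; normalisation is by quadrature.
    """

    def __init__(
        self,
        knot_logdens: Sequence[float],
        knot_positions: Sequence[float] = DEFAULT_KNOTS,
    ):
        self.knot_positions = np.asarray(knot_positions, dtype=float)
        self.knot_logdens = np.asarray(knot_logdens, dtype=float)
        if self.knot_positions.size != self.knot_logdens.size:
            raise ValueError("knot positions and values must have equal length")
        if self.knot_positions.size < 3:
            raise ValueError("need at least 3 knots")
        if np.any(np.diff(self.knot_positions) <= 0):
            raise ValueError("knot positions must be strictly increasing")
        self._spline = CubicSpline(
            self.knot_positions, self.knot_logdens, bc_type="natural"
        )
        d = self._spline.derivative()
        self._slopes = (float(d(self.knot_positions[0])), float(d(self.knot_positions[-1])))

    # -- shape -----------------------------------------------------------
    def log10_unnormalised(self, u) -> np.ndarray:
        """log10 of the (un-normalised) density over u = log10 s."""
        u = np.asarray(u, dtype=float)
        lo, hi = self.knot_positions[0], self.knot_positions[-1]
        g = self._spline(np.clip(u, lo, hi))
        g = g + np.where(u < lo, (u - lo) * self._slopes[0], 0.0)
        g = g + np.where(u > hi, (u - hi) * self._slopes[1], 0.0)
        return g

    def terminal_slopes(self) -> tuple[float, float]:
        """d(log10 f)/d(log10 s) used for linear extrapolation at both ends."""
        return self._slopes

    def density_log10(self, u: np.ndarray) -> np.ndarray:
        """Normalised density over u = log10 s on the support [-7, -1].

        ``sum(w_u * density_log10(u))`` is 1 on the quadrature grid ``u``.
        """
        u = np.asarray(u, dtype=float)
        g = self.log10_unnormalised(u)
        rho = np.where((u >= LOG10_S_MIN - 1e-12) & (u <= LOG10_S_MAX + 1e-12),
                       10.0 ** (g - g.max()), 0.0)
        z = float(np.sum(_trapezoid_weights(u) * rho))
        if z <= 0:
            raise ValueError("selection density vanishes on its support")
        return rho / z

    def expect(self, u: np.ndarray, values: np.ndarray) -> float:
        """Quadrature expectation of ``values`` tabulated on the u grid."""
        rho = self.density_log10(u)
        return float(np.sum(_trapezoid_weights(u) * rho * values))

    def cdf(self, u: np.ndarray) -> np.ndarray:
        """CDF of log10 s evaluated on the grid ``u`` (for envelopes/plots)."""
        rho = self.density_log10(u)
        w = _trapezoid_weights(u)
        c = np.cumsum(rho * w)
        return c / c[-1]

    # -- presets ---------------------------------------------------------
    @classmethod
    def preset(cls, name: str) -> "SelectionDensity":
        """Named shapes used by the synthetic-data generator.

        ``ssd-like`` peaks near s ~ 1e-4.5 with a substantial strong-selection
        tail (the shape inferred jointly across many traits); ``weak`` and
        ``strong`` shift the mass by roughly a decade either way; ``flat`` is
        uniform on log10 s.
        """
        shapes = {
            "ssd-like": (-0.6, 0.45, -0.25, -1.3),
            "weak": (0.4, 0.35, -1.2, -2.6),
            "strong": (-1.8, -0.4, 0.45, -0.6),
            "flat": (0.0, 0.0, 0.0, 0.0),
        }
        try:
            return cls(shapes[name])
        except KeyError:
            raise ValueError(
                f"unknown f(s) preset {name!r}; available: {sorted(shapes)}"
            ) from None

    def shifted(self, decades: float) -> "SelectionDensity":
        """Same shape with knot values translated along log10 s by ``decades``.

        Implemented by re-interpolating the extrapolated log-density at the
        original knot positions, so the support stays [1e-7, 1e-1].
        """
        g = self.log10_unnormalised(self.knot_positions - decades)
        return SelectionDensity(g, self.knot_positions)

    def __repr__(self) -> str:  # pragma: no cover
        pairs = ", ".join(
            f"{p:g}:{v:.3g}" for p, v in zip(self.knot_positions, self.knot_logdens)
        )
        return f"SelectionDensity({pairs})"


class DiracSelectionDensity:
    """Point mass at a single selection coefficient (oracle/test helper)."""

    def __init__(self, log10_s: float):
        if not LOG10_S_MIN <= log10_s <= LOG10_S_MAX:
            raise ValueError("point mass must lie within the supported s range")
        self.log10_s = float(log10_s)

    def density_log10(self, u: np.ndarray) -> np.ndarray:
        """Delta represented on the quadrature grid (unit mass in one node)."""
        u = np.asarray(u, dtype=float)
        rho = np.zeros_like(u)
        i = int(np.argmin(np.abs(u - self.log10_s)))
        rho[i] = 1.0 / _trapezoid_weights(u)[i]
        return rho

    def expect(self, u: np.ndarray, values: np.ndarray) -> float:
        return float(np.interp(self.log10_s, u, values))

    def cdf(self, u: np.ndarray) -> np.ndarray:
        return (np.asarray(u) >= self.log10_s).astype(float)


# ---------------------------------------------------------------------------
# parameters and hit tables
# ---------------------------------------------------------------------------


@dataclass
class TraitParams:
    """Per-trait parameters of the generative model.

    h2_over_L is the heritability per site (trait-variance units, per site);
    L the mutational target size in sites; n the effective GWAS sample size.
    """

    fs: SelectionDensity | DiracSelectionDensity
    h2_over_L: float
    L: float
    mu: float = DEFAULT_MU
    n: float = 3e5
    z_thresh: float = Z_THRESHOLD
    maf_min: float = MAF_MIN

    def __post_init__(self) -> None:
        if self.h2_over_L <= 0:
            raise ValueError("h2_over_L must be positive")
        if self.L < 0:
            raise ValueError("L must be non-negative")
        if self.mu <= 0 or self.n <= 0:
            raise ValueError("mu and n must be positive")
        h2 = self.h2_over_L * self.L
        if h2 >= 1:
            raise ValueError(f"implied h2 = L*h2/L = {h2:.3g} must be < 1")

    @property
    def h2(self) -> float:
        return self.h2_over_L * self.L

    def with_(self, **kwargs) -> "TraitParams":
        return replace(self, **kwargs)


class HitTableError(ValueError):
    pass


_HIT_COLUMNS = ("snp", "maf", "abs_z", "n_eff")


@dataclass
class HitTable:
    """Ascertained GWAS hits of one trait: (snp, maf, |z|, n_eff[, block])."""

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _HIT_COLUMNS if c not in df.columns]
        if missing:
            raise HitTableError(f"hit table missing columns {missing}")
        bad = df.index[(df["maf"] < MAF_MIN) | (df["maf"] > 0.5)]
        if len(bad):
            raise HitTableError(
                f"row {bad[0] + 1}: maf outside [{MAF_MIN}, 0.5]"
            )
        bad = df.index[df["abs_z"] < Z_THRESHOLD]
        if len(bad):
            raise HitTableError(f"row {bad[0] + 1}: |z| below threshold {Z_THRESHOLD}")
        bad = df.index[df["n_eff"] <= 0]
        if len(bad):
            raise HitTableError(f"row {bad[0] + 1}: non-positive n_eff")

    # array views --------------------------------------------------------
    @property
    def maf(self) -> np.ndarray:
        return self.data["maf"].to_numpy(float)

    @property
    def abs_z(self) -> np.ndarray:
        return self.data["abs_z"].to_numpy(float)

    @property
    def n_eff(self) -> np.ndarray:
        return self.data["n_eff"].to_numpy(float)

    @property
    def block(self) -> np.ndarray | None:
        if "block" in self.data.columns:
            return self.data["block"].to_numpy()
        return None

    @property
    def n_hits(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    # IO -----------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path, label: str | None = None) -> "HitTable":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise HitTableError(f"{path}: cannot parse TSV ({exc})") from exc
        for col in _HIT_COLUMNS:
            if col not in df.columns:
                raise HitTableError(f"{path}: missing required column {col!r}")
            if col != "snp" and not np.issubdtype(df[col].dtype, np.number):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                line = int(bad[0]) + 2 if len(bad) else "?"
                raise HitTableError(f"{path}: line {line}: non-numeric {col!r}")
        df = df.reset_index(drop=True)
        return cls(data=df, label=label or path.stem)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# quadrature model
# ---------------------------------------------------------------------------


class TraitModel:
    """Quadrature implementation of the (q, beta, z) hierarchy for one trait.

    Binds a parameter set to a conditional-SFS cache; precomputes the
    normalised f(s) on the cache's s grid, the constant ``k`` and the folded
    frequency densities, then exposes the joint hit density, ascertainment
    probability and conditional distributions.
    """

    #: Gauss-Hermite order for expectations over beta
    GH_POINTS = 40

    def __init__(self, params: TraitParams, cache: ConditionalSFS):
        if abs(cache.mu - params.mu) > 1e-20 + 1e-9 * params.mu:
            raise ValueError("cache was built with a different mutation rate")
        self.params = params
        self.cache = cache
        self.u = cache.log10_s
        self.wu = _trapezoid_weights(self.u)
        self.rho = params.fs.density_log10(self.u)
        self.k = compute_k(params.fs, cache)
        self.s = cache.s
        # folded density restricted to the ascertainment MAF range
        self.maf = cache.maf
        self.maf_w = cache.maf_weights
        self.lam_maf = cache.lam_maf  # (n_s, n_maf)
        self._asc = self.maf >= params.maf_min

    # -- elementary pieces ----------------------------------------------
    def beta_variance(self, s) -> np.ndarray | float:
        """Var(beta | s) = (h2/L) k s / (4 mu); zero in the neutral limit."""
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("selection coefficient must be >= 0")
        v = self.params.h2_over_L * self.k * s / (4.0 * self.params.mu)
        return float(v) if v.ndim == 0 else v

    def _z_sd(self, maf, n=None) -> np.ndarray:
        """Marginal z-score sd given (s, maf): sqrt(1 + Var(beta|s) 2m(1-m) n).

        Returns an (n_s, n_maf) array broadcast over the cache's s grid.
        """
        n = self.params.n if n is None else n
        m = np.asarray(maf, dtype=float)
        v = self.beta_variance(self.s)[:, None]
        return np.sqrt(1.0 + v * (2.0 * m * (1.0 - m) * n)[None, :])

    def heritability(self) -> float:
        """h2 = L * int E[2 beta^2 q(1-q) | s] f(s) ds (numerical check).

        Equals ``L * h2_over_L`` by construction of ``k``; a value >= 1 is
        rejected as an inconsistent parameter set.
        """
        e_contrib = self.beta_variance(self.s) * self.cache.e2pq
        h2 = self.params.L * float(np.sum(self.wu * self.rho * e_contrib))
        if h2 >= 1:
            raise ValueError(f"heritability {h2:.3g} >= 1: inconsistent parameters")
        return h2

    # -- joint hit density ----------------------------------------------
    def hit_density(self, maf, z, n=None) -> np.ndarray:
        """Un-normalised per-site joint density of (MAF, |z|), paired inputs.

        Marginalises the s -> (q, beta, z) hierarchy: folded frequency
        density times the |z| density of N(0, sigma^2(s, m)) reflected to
        the half line.
        """
        m = np.atleast_1d(np.asarray(maf, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        m, z = np.broadcast_arrays(m, z)
        lam = self.cache.lam_maf_at(m.ravel())  # (n_s, n_pts)
        sd = self._z_sd(m.ravel(), n)
        zz = z.ravel()[None, :] / sd
        dens = lam * (2.0 / sd) * _phi(zz)
        out = np.sum(self.wu[:, None] * self.rho[:, None] * dens, axis=0)
        return out.reshape(m.shape)

    def prob_significant(self, n=None) -> float:
        """Per-site probability of being a hit (MAF >= 1%, |z| > threshold)."""
        sd = self._z_sd(self.maf, n)
        tail = 2.0 * _q_tail(self.params.z_thresh / sd)
        inner = np.sum((self.lam_maf * tail)[:, self._asc] * self.maf_w[self._asc],
                       axis=1)
        return float(np.sum(self.wu * self.rho * inner))

    def expected_hits(self) -> float:
        return self.params.L * self.prob_significant()

    # -- conditionals ----------------------------------------------------
    def conditional_z_tail_given_q(self, z0, q, n=None) -> np.ndarray | float:
        """Pr(|z| > z0 | |z| > threshold, MAF = q), the residual p-value."""
        z0 = np.atleast_1d(np.asarray(z0, dtype=float))
        q = np.atleast_1d(np.asarray(q, dtype=float))
        z0, q = np.broadcast_arrays(z0, q)
        if np.any(z0 < self.params.z_thresh - 1e-9):
            raise ValueError("z0 must be at or above the significance threshold")
        lam = self.cache.lam_maf_at(q.ravel())
        sd = self._z_sd(q.ravel(), n)
        w = self.wu[:, None] * self.rho[:, None] * lam
        num = np.sum(w * _q_tail(z0.ravel()[None, :] / sd), axis=0)
        den = np.sum(w * _q_tail(self.params.z_thresh / sd), axis=0)
        out = num / den
        out = out.reshape(z0.shape)
        return float(out) if out.ndim == 0 else out

    def conditional_s_given_q(self, q: float) -> np.ndarray:
        """Posterior density of log10 s at a causal variant with MAF q.

        Normalised on the cache's s grid: proportional to
        ``lambda_maf(q|s) f(s)``.
        """
        lam = self.cache.lam_maf_at(np.atleast_1d(float(q)))[:, 0]
        post = self.rho * lam
        z = float(np.sum(self.wu * post))
        if z <= 0:
            raise ValueError(f"zero frequency density at maf={q}")
        return post / z

    def conditional_beta2_given_q(self, q: float, beta2_scaled: np.ndarray) -> np.ndarray:
        """Density of beta^2 / (h2/L) at MAF q (invariant to h2/L).

        A mixture over the s posterior of scaled chi-square(1) densities with
        scale ``k s / (4 mu)``.
        """
        x = np.asarray(beta2_scaled, dtype=float)
        post = self.conditional_s_given_q(q)
        scale = self.k * self.s / (4.0 * self.params.mu)  # beta^2/(h2/L) scale
        xx = x[None, :] / scale[:, None]
        dens = np.exp(-xx / 2.0) / np.sqrt(2.0 * np.pi * xx) / scale[:, None]
        return np.sum((self.wu * post)[:, None] * dens, axis=0)

    def prop_h2_explained_by_hits(self) -> float:
        """Fraction of h2 carried by sites inside the ascertainment region."""
        p = self.params
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(self.GH_POINTS)
        m = self.maf[self._asc]
        a = np.sqrt(2.0 * m * (1.0 - m) * p.n)  # (n_m,)
        v = self.beta_variance(self.s)  # (n_s,)
        sd_b = np.sqrt(v)
        beta = sd_b[:, None, None] * gh_x[None, None, :]  # (n_s, 1, gh)
        arg_p = p.z_thresh - a[None, :, None] * beta
        arg_m = p.z_thresh + a[None, :, None] * beta
        p_sig = _q_tail(arg_p) + _q_tail(arg_m)  # (n_s, n_m, gh)
        e_b2 = np.sum(gh_w[None, None, :] * beta**2 * p_sig, axis=2) / np.sqrt(2 * np.pi)
        twopq = 2.0 * m * (1.0 - m)
        lam = self.lam_maf[:, self._asc]
        per_s = np.sum(lam * twopq[None, :] * e_b2 * self.maf_w[None, self._asc], axis=1)
        num = p.L * float(np.sum(self.wu * self.rho * per_s))
        return num / self.heritability()


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _q_tail(x: np.ndarray) -> np.ndarray:
    """Upper-tail standard normal probability Q(x) = 1 - Phi(x)."""
    return ndtr(-np.asarray(x, dtype=float))
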