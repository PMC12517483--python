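"""Allele-frequency distributions under underdominant selection.

For a site under stabilizing selection with coefficient ``s`` the expected
per-generation change of the derived-allele frequency ``q`` is

    E[dq] = -s q (1 - q) (1/2 - q),

i.e. selection pushes the minor allele toward loss regardless of the sign of
the underlying trait effect.  Together with binomial drift of variance
``q(1-q)/(2N)`` and an influx of new mutations at rate ``mu`` per site per
gamete, this defines a diffusion whose present-day density of segregating
derived alleles, ``lambda(q | s)``, is computed here:

* ``equilibrium_sfs`` -- the closed-form stationary influx solution for
  constant ``N`` (Wright's formula for the underdominant drift term);
* ``present_day_sfs`` -- a transient finite-volume solver for arbitrary
  piecewise-constant demographies, initialised at the ancient stationary
  state (exponentially-fitted fluxes, so the constant-``N`` case reproduces
  the closed form);
* ``ConditionalSFS`` -- a cache of ``lambda(q | s)`` over a log-spaced grid
  of selection coefficients, which every downstream fit reuses;
* ``compute_k`` -- the self-consistency constant relating effect-size
  variance to ``s`` (approximately 1 when selection is strong).

Densities are per site and un-normalised: ``integral lambda(q|s) dq`` is the
expected number of segregating derived alleles per site (the segregating
probability).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from scipy.linalg import solve_banded

from traitarch.demography import DemographicModel

__all__ = [
    "FrequencyGrid",
    "ConditionalSFS",
    "expected_delta_q",
    "equilibrium_sfs",
    "present_day_sfs",
    "seg_moment",
    "build_cache",
    "compute_k",
    "default_s_grid",
]

LOG10_S_MIN = -7.0
LOG10_S_MAX = -1.0
DEFAULT_MU = 1.25e-8


def expected_delta_q(s: float, q) -> np.ndarray | float:
    """Expected one-generation change of the derived-allele frequency.

    ``-s q (1-q) (1/2 - q)``: zero at the q=1/2 fixed point, negative for
    minor derived alleles, positive (toward fixation) above 1/2.
    """
    q = np.asarray(q, dtype=float)
    if s < 0:
        raise ValueError("selection coefficient must be >= 0")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequency must lie in [0, 1]")
    out = -s * q * (1.0 - q) * (0.5 - q)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# frequency grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyGrid:
    """Logit-uniform nodes on (0, 1) with cell-integration weights.

    Nodes are symmetric about 1/2 (``q`` on the grid iff ``1-q`` is), and the
    terminal cells extend to the absorbing boundaries 0 and 1, so the weights
    sum to exactly 1.
    """

    q: np.ndarray
    edges: np.ndarray  # len(q) + 1 cell edges, edges[0] = 0, edges[-1] = 1

    @classmethod
    def logit(cls, n: int = 512, q_min: float = 1e-5) -> "FrequencyGrid":
        if n < 8 or n % 2:
            raise ValueError("grid size must be an even integer >= 8")
        if not 0 < q_min < 0.5:
            raise ValueError("q_min must lie in (0, 0.5)")
        u_max = np.log(q_min / (1 - q_min))
        u = np.linspace(u_max, -u_max, n)
        q = 1.0 / (1.0 + np.exp(-u))
        q = 0.5 * (q + (1.0 - q[::-1]))  # enforce exact symmetry
        edges = np.empty(n + 1)
        edges[1:-1] = 0.5 * (q[:-1] + q[1:])
        edges[0], edges[-1] = 0.0, 1.0
        return cls(q=q, edges=edges)

    @property
    def weights(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def n(self) -> int:
        return self.q.size

    def fold_index(self) -> np.ndarray:
        """Index of the node at ``1 - q`` for each node (symmetry partner)."""
        return np.arange(self.n)[::-1]


# ---------------------------------------------------------------------------
# closed-form stationary solution (constant N)
# ---------------------------------------------------------------------------


def _scale_ratio_tables(n_pop: float, s: float, n_dense: int = 20001):
    """Dense tables of the scale-function ratio S(x)/S(1) for psi = exp(2Ns x(1-x))."""
    y = np.linspace(0.0, 1.0, n_dense)
    phi = 2.0 * n_pop * s * y * (1.0 - y)
    c = phi.max()
    psi = np.exp(phi - c)
    s_cum = np.concatenate([[0.0], np.cumsum(0.5 * (psi[1:] + psi[:-1]) * np.diff(y))])
    return y, s_cum / s_cum[-1]


def equilibrium_sfs(
    s: float,
    n_pop: int,
    mu: float,
    q,
    *,
    p0: float | None = None,
) -> np.ndarray:
    """Stationary influx density ``lambda(q|s)`` for constant diploid size N.

    Wright's constant-flux solution with injection of new mutations at
    frequency ``p0`` (default ``1/(2N)``) at rate ``2 N mu`` per site per
    generation; absorbing boundaries at 0 and 1.  Evaluated in log space so
    arbitrarily large ``2 N s`` is safe.  The neutral case reduces to
    ``4 N mu / q``.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("evaluate the density strictly inside (0, 1)")
    if p0 is None:
        p0 = 1.0 / (2.0 * n_pop)
    y, sr = _scale_ratio_tables(n_pop, s)
    s_ratio = np.interp(q, y, sr)
    s_ratio_p0 = float(np.interp(p0, y, sr))
    phi_q = 2.0 * n_pop * s * q * (1.0 - q)
    # Constant-flux solution with injection at p0 (Phi(p0) ~ s is small, so
    # S near the boundary is computed by direct quadrature, no overflow).
    # q >= p0:  lambda = 8 N^2 mu S(p0) (1 - S(q)/S(1)) / (q(1-q) psi(q))
    s_p0 = _scale_integral_small(p0, n_pop, s)
    lam_hi = (
        8.0 * n_pop**2 * mu * s_p0 * (1.0 - s_ratio)
        * np.exp(-phi_q) / (q * (1.0 - q))
    )
    # q < p0:   lambda = 8 N^2 mu S(q) (1 - S(p0)/S(1)) / (q(1-q) psi(q))
    s_q = _scale_integral_small(np.minimum(q, p0), n_pop, s)
    lam_lo = (
        8.0 * n_pop**2 * mu * s_q * (1.0 - s_ratio_p0)
        * np.exp(-phi_q) / (q * (1.0 - q))
    )
    lam = np.where(q >= p0, lam_hi, lam_lo)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite equilibrium density after rescaling")
    return lam


def _scale_integral_small(x, n_pop: float, s: float):
    """S(x) = int_0^x exp(2Ns y(1-y)) dy for x near 0 (Gauss-Legendre)."""
    x = np.asarray(x, dtype=float)
    gl_x, gl_w = np.polynomial.legendre.leggauss(32)
    half = 0.5 * x
    nodes = half[..., None] * (gl_x + 1.0)
    vals = np.exp(2.0 * n_pop * s * nodes * (1.0 - nodes))
    out = (vals * gl_w).sum(axis=-1) * half
    return out if out.ndim else float(out)


def equilibrium_cell_masses(
    s: float, n_pop: int, mu: float, grid: FrequencyGrid, points: int = 7
) -> np.ndarray:
    """Integral of the closed-form density over each grid cell (Gauss-Legendre)."""
    gl_x, gl_w = np.polynomial.legendre.leggauss(points)
    lo, hi = grid.edges[:-1].copy(), grid.edges[1:].copy()
    lo[0] = min(grid.edges[1] * 1e-6, 1e-12) + 0.0  # open at 0
    lo[0] = max(lo[0], 1e-14)
    hi[-1] = 1.0 - (1.0 - grid.edges[-2]) * 1e-6
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = mid[:, None] + half[:, None] * gl_x[None, :]
    vals = equilibrium_sfs(s, n_pop, mu, nodes.ravel()).reshape(nodes.shape)
    return (vals * gl_w[None, :]).sum(axis=1) * half


# ---------------------------------------------------------------------------
# transient finite-volume solver
# ---------------------------------------------------------------------------


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (e^x - 1), the exponential-fitting weight (B(0) = 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - 0.5 * x[small]
    xs = np.clip(x[~small], -700.0, 700.0)
    out[~small] = xs / np.expm1(xs)
    return out


def _operator(n_pop: float, s: float, mu: float, grid: FrequencyGrid):
    """Tridiagonal generator A (dl, d, du) and influx vector b for d lambda/dt = A lambda + b.

    Scharfetter-Gummel (exponentially fitted) fluxes for
    F = v w - D w' with w = V lambda, V = q(1-q)/(2N), v = M/V = -Ns(1-2q),
    D = 1/2; absorbing boundaries; mutational influx 2 N mu into the cell
    containing 1/(2N).
    """
    q, edges, cw = grid.q, grid.edges, grid.weights
    n = grid.n
    v_node = q * (1.0 - q) / (2.0 * n_pop)  # diffusion variance V(q)
    # faces between nodes (n+1 of them); spacing = distance between the
    # states entering the flux (terminal faces use node-to-boundary distance)
    hface = np.empty(n + 1)
    hface[1:-1] = np.diff(q)
    hface[0] = q[0]
    hface[-1] = 1.0 - q[-1]
    vface = -n_pop * s * (1.0 - 2.0 * edges)  # advection v = M/V at faces
    d_coef = 0.5
    pe = vface * hface / d_coef
    b_minus = _bernoulli(-pe)  # weight of the left (upwind for v>0) state
    b_plus = _bernoulli(pe)  # weight of the right state
    g = d_coef / hface
    # flux at face i: F_i = g_i (b_minus_i w_{i-1} - b_plus_i w_i); w_{-1}=w_n=0
    # and d lambda_j / dt = (F_j - F_{j+1}) / cw_j
    lower = np.zeros(n)
    upper = np.zeros(n)
    lower[1:] = g[1:-1] * b_minus[1:-1] * v_node[:-1]
    diag = -(g[:-1] * b_plus[:-1] + g[1:] * b_minus[1:]) * v_node
    upper[:-1] = g[1:-1] * b_plus[1:-1] * v_node[1:]
    a_lower = lower / cw
    a_diag = diag / cw
    a_upper = upper / cw
    # Influx of 2 N mu new copies per site per generation at p0 = 1/(2N).
    # The stationary density downstream of the source scales with the scale
    # function S(p0) ~ p0, so the injection position matters: split the
    # source between the bracketing nodes (linear in q), or, when p0 falls
    # below the grid, inject into the first node scaled by p0/q_0.
    b = np.zeros(n)
    p0 = 1.0 / (2.0 * n_pop)
    rate = 2.0 * n_pop * mu
    if p0 <= q[0]:
        b[0] = rate * (p0 / q[0]) / cw[0]
    elif p0 >= q[-1]:  # pathological (tiny N); keep mass on the grid
        b[-1] = rate / cw[-1]
    else:
        j = int(np.searchsorted(q, p0)) - 1
        alpha = (q[j + 1] - p0) / (q[j + 1] - q[j])
        b[j] = rate * alpha / cw[j]
        b[j + 1] = rate * (1.0 - alpha) / cw[j + 1]
    return a_lower, a_diag, a_upper, b


def _solve_tridiag(a_lower, a_diag, a_upper, rhs):
    n = a_diag.size
    ab = np.zeros((3, n))
    ab[0, 1:] = a_upper[:-1]
    ab[1] = a_diag
    ab[2, :-1] = a_lower[1:]
    return solve_banded((1, 1), ab, rhs)


def stationary_sfs(s: float, n_pop: int, mu: float, grid: FrequencyGrid) -> np.ndarray:
    """Discrete stationary density: solve A lambda = -b."""
    al, ad, au, b = _operator(n_pop, s, mu, grid)
    lam = _solve_tridiag(-al, -ad, -au, b)
    return np.maximum(lam, 0.0)


def present_day_sfs(
    s: float,
    demography: DemographicModel,
    mu: float,
    grid: FrequencyGrid,
    *,
    max_step: float = 50.0,
) -> np.ndarray:
    """Transient density at present under a piecewise-constant demography.

    Initialised at the stationary state of the oldest epoch (long-term
    mutation-selection-drift balance), then evolved through each younger
    epoch by implicit-Euler steps of the exponentially fitted operator.
    A constant-``N`` history returns the discrete stationary solution.
    """
    epochs = list(demography.epochs)  # (start, N), increasing start
    lam = stationary_sfs(s, epochs[-1][1], mu, grid)
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError(
            f"ancient stationary state non-finite (s={s}, N={epochs[-1][1]})"
        )
    # evolve from oldest boundary toward the present
    for k in range(len(epochs) - 2, -1, -1):
        start, n_pop = epochs[k]
        duration = epochs[k + 1][0] - start
        al, ad, au, b = _operator(n_pop, s, mu, grid)
        steps = max(int(np.ceil(duration / min(max_step, max(n_pop / 20.0, 1.0)))), 4)
        dt = duration / steps
        # (I - dt A) lam' = lam + dt b
        il = -dt * al
        idg = 1.0 - dt * ad
        iu = -dt * au
        for _ in range(steps):
            lam = _solve_tridiag(il, idg, iu, lam + dt * b)
        lam = np.maximum(lam, 0.0)
    return lam


def seg_moment(
    s: float,
    demography: DemographicModel,
    mu: float,
    g,
    grid: FrequencyGrid | None = None,
) -> float:
    """Per-site expectation ``integral g(q) lambda(q|s) dq`` (un-normalised)."""
    grid = grid or FrequencyGrid.logit()
    lam = present_day_sfs(s, demography, mu, grid)
    return float(np.sum(np.asarray(g(grid.q), dtype=float) * lam * grid.weights))


# ---------------------------------------------------------------------------
# cached conditional SFS over a grid of selection coefficients
# ---------------------------------------------------------------------------


def default_s_grid(n: int = 121) -> np.ndarray:
    """Log10-uniform grid of selection coefficients on [1e-7, 1e-1]."""
    return np.linspace(LOG10_S_MIN, LOG10_S_MAX, n)


@dataclass
class ConditionalSFS:
    """Present-day density ``lambda(q|s)`` tabulated on (s, q) grids.

    ``lam[i, j]`` is the density at ``q[j]`` for ``s = 10**log10_s[i]``;
    ``lam0`` is the neutral (s = 0) reference column.
    """

    log10_s: np.ndarray
    grid: FrequencyGrid
    lam: np.ndarray
    lam0: np.ndarray
    mu: float
    demography_digest: str
    demography_label: str = ""

    @property
    def s(self) -> np.ndarray:
        return 10.0**self.log10_s

    @property
    def seg_prob(self) -> np.ndarray:
        return self.lam @ self.grid.weights

    @property
    def e2pq(self) -> np.ndarray:
        """E[2 q (1-q) | s] per site (un-normalised second moment)."""
        q = self.grid.q
        return self.lam @ (2.0 * q * (1.0 - q) * self.grid.weights)

    # folded (minor-allele) view -----------------------------------------
    @property
    def maf(self) -> np.ndarray:
        n2 = self.grid.n // 2
        return self.grid.q[:n2]

    @property
    def maf_weights(self) -> np.ndarray:
        n2 = self.grid.n // 2
        return self.grid.weights[:n2]

    @property
    def lam_maf(self) -> np.ndarray:
        """Folded density over minor allele frequency, lambda(m) + lambda(1-m)."""
        n2 = self.grid.n // 2
        return self.lam[:, :n2] + self.lam[:, : n2 - 1 - self.grid.n : -1]

    @property
    def lam0_maf(self) -> np.ndarray:
        n2 = self.grid.n // 2
        return self.lam0[:n2] + self.lam0[: n2 - 1 - self.grid.n : -1]

    def lam_maf_at(self, maf: np.ndarray) -> np.ndarray:
        """Folded density interpolated at arbitrary MAFs: (n_s, len(maf))."""
        maf = np.asarray(maf, dtype=float)
        out = np.empty((self.log10_s.size, maf.size))
        for i in range(self.log10_s.size):
            out[i] = np.interp(maf, self.maf, self.lam_maf[i])
        return out

    # persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "mu": self.mu,
            "demography_digest": self.demography_digest,
            "demography_label": self.demography_label,
        }
        np.savez_compressed(
            path,
            log10_s=self.log10_s,
            q=self.grid.q,
            edges=self.grid.edges,
            lam=self.lam,
            lam0=self.lam0,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConditionalSFS":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            grid = FrequencyGrid(q=z["q"], edges=z["edges"])
            return cls(
                log10_s=z["log10_s"],
                grid=grid,
                lam=z["lam"],
                lam0=z["lam0"],
                mu=float(meta["mu"]),
                demography_digest=meta["demography_digest"],
                demography_label=meta.get("demography_label", ""),
            )


_CACHE: dict[tuple, ConditionalSFS] = {}


def build_cache(
    demography: DemographicModel,
    mu: float = DEFAULT_MU,
    *,
    n_s: int = 121,
    n_q: int = 512,
    q_min: float = 1e-5,
    memoize: bool = True,
) -> ConditionalSFS:
    """Tabulate ``lambda(q|s)`` for the demography; memoised per process."""
    key = (demography.digest(), mu, n_s, n_q, q_min)
    if memoize and key in _CACHE:
        return _CACHE[key]
    grid = FrequencyGrid.logit(n_q, q_min)
    log10_s = default_s_grid(n_s)
    lam = np.empty((n_s, grid.n))
    for i, u in enumerate(log10_s):
        lam[i] = present_day_sfs(10.0**u, demography, mu, grid)
    lam0 = present_day_sfs(0.0, demography, mu, grid)
    cache = ConditionalSFS(
        log10_s=log10_s,
        grid=grid,
        lam=lam,
        lam0=lam0,
        mu=mu,
        demography_digest=demography.digest(),
        demography_label=demography.label,
    )
    if memoize:
        _CACHE[key] = cache
    return cache


def compute_k(fs, cache: ConditionalSFS) -> float:
    """Self-consistency constant k = 4 mu / integral s E[2q(1-q)|s] f(s) ds.

    With Var(beta|s) = (h2/L) k s / (4 mu) this makes the heritability
    decomposition h2 = L int E[2 beta^2 q(1-q)|s] f(s) ds hold exactly.
    For f(s) concentrated at strong selection E[2q(1-q)|s] -> 4 mu / s and
    k -> 1; for effectively neutral mass k grows well above 1.
    """
    import warnings

    u = cache.log10_s
    rho = fs.density_log10(u)  # normalised density on the log10 s axis
    wu = _trapezoid_weights(u)
    denom = float(np.sum(wu * rho * cache.s * cache.e2pq))
    if denom <= 0:
        raise ValueError("degenerate f(s): zero selection-weighted variance flux")
    k = 4.0 * cache.mu / denom
    if k > 5.0:
        warnings.warn(
            f"k = {k:.3g} far above 1: f(s) is concentrated at effectively "
            "neutral selection coefficients",
            stacklevel=2,
        )
    return k


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += 0.5 * dx
    w[1:] += 0.5 * dx
    return w
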