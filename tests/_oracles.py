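"""Independent brute-force oracles used only by the tests.

A discrete Wright-Fisher transition matrix at small population size provides
reference values for the diffusion solver (stationary allele-frequency
distribution under mutational influx) and for neutral allele ages under a
truncated origin horizon.  These deliberately share no code with the
package's solvers.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def wf_transition_matrix(n_pop: int, s: float) -> np.ndarray:
    """Row-stochastic WF matrix over copy counts 0..2N with underdominance."""
    two_n = 2 * n_pop
    j = np.arange(two_n + 1)
    q = j / two_n
    q_next = q - s * q * (1.0 - q) * (0.5 - q)
    q_next = np.clip(q_next, 0.0, 1.0)
    return binom.pmf(j[None, :], two_n, q_next[:, None])


def wf_stationary_masses(n_pop: int, s: float, mu: float) -> np.ndarray:
    """Expected segregating-site mass per copy class (1..2N-1) at influx 2Nmu.

    Solves lambda = lambda T + 2 N mu e_1 over the transient states.
    """
    two_n = 2 * n_pop
    p = wf_transition_matrix(n_pop, s)
    t = p[1:two_n, 1:two_n]
    rhs = np.zeros(two_n - 1)
    rhs[0] = 2.0 * n_pop * mu
    lam = np.linalg.solve(np.eye(two_n - 1) - t.T, rhs)
    return lam


def wf_neutral_age_moments(n_pop: int, t_max: int):
    """Per-state (mass, mean age) for neutral alleles, origins within t_max.

    Mirrors the trajectory simulator's bookkeeping: a mutation born t
    generations ago has undergone t binomial transitions from one copy.
    Returns (masses, mean_ages) over copy classes 1..2N-1.
    """
    two_n = 2 * n_pop
    p = wf_transition_matrix(n_pop, 0.0)
    v = np.zeros(two_n + 1)
    v[1] = 1.0
    mass = np.zeros(two_n + 1)
    aged = np.zeros(two_n + 1)
    for t in range(1, t_max + 1):
        v = v @ p
        v[0] = 0.0
        v[two_n] = 0.0
        mass += v
        aged += t * v
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_age = np.where(mass > 0, aged / mass, np.nan)
    return mass[1:two_n], mean_age[1:two_n]


def quantiles_from_masses(right_edges: np.ndarray, masses: np.ndarray,
                          probs) -> np.ndarray:
    """Quantiles of a binned mass function by linear CDF interpolation.

    ``masses[i]`` is the mass of the cell whose right edge is
    ``right_edges[i]``; the CDF is exact at the edges, so no half-cell bias.
    """
    cdf = np.cumsum(masses)
    cdf = cdf / cdf[-1]
    return np.interp(np.asarray(probs), cdf, right_edges)
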