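"""Allele-age prediction by forward trajectory simulation.

The age of a segregating variant is the number of generations since its
originating mutation, conditional on segregating at present.  Conditional on
present frequency, selected alleles are younger than neutral ones — selection
keeps old alleles from persisting at appreciable frequency — and the fitted
selection-coefficient distribution quantifies how much younger the GWAS hits
of a trait should be than frequency-matched neutral variants.

``simulate_ages`` runs origin-time-stamped Wright-Fisher trajectories under
the underdominant drift term and binomial sampling at the epoch's population
size; origins are spread over the past ``4 N_ancestral`` generations with
influx weight proportional to N(t), and trajectories segregating at present
are retained with their ages.  ``predicted_hit_ages`` mixes those conditional
age pools over each hit's posterior of s given its MAF (optionally sharpened
by its z-score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traitarch.demography import DemographicModel
from traitarch.sfs import ConditionalSFS, expected_delta_q, _trapezoid_weights
from traitarch.trait import HitTable, TraitModel

__all__ = [
    "AgeSample",
    "simulate_ages",
    "predicted_hit_ages",
    "matched_neutral_ages",
    "to_years",
    "YEARS_PER_GENERATION",
    "DEFAULT_MAF_BINS",
]

YEARS_PER_GENERATION = 28.0
DEFAULT_MAF_BINS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5)


def to_years(generations, years_per_generation: float = YEARS_PER_GENERATION):
    """Convert generations to years (28 years per generation by default)."""
    return np.asarray(generations, dtype=float) * years_per_generation


@dataclass
class AgeSample:
    """Draws of (s, present derived frequency, age in generations)."""

    s: np.ndarray
    q: np.ndarray
    age: np.ndarray
    seed: int
    reps: int
    t_max: int

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.q, 1.0 - self.q)

    def __len__(self) -> int:
        return self.age.size

    def in_maf_bin(self, lo: float, hi: float) -> np.ndarray:
        m = self.maf
        return self.age[(m >= lo) & (m < hi)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "q": self.q, "maf": self.maf,
                             "age_generations": self.age})

    def summary(self) -> pd.DataFrame:
        """Median and quartile ages (generations and years) per MAF bin."""
        rows = []
        edges = DEFAULT_MAF_BINS
        for lo, hi in zip(edges[:-1], edges[1:]):
            a = self.in_maf_bin(lo, hi)
            if a.size == 0:
                continue
            qs = np.percentile(a, [25, 50, 75])
            rows.append((lo, hi, a.size, *qs, *to_years(qs)))
        return pd.DataFrame(rows, columns=[
            "maf_lo", "maf_hi", "n", "age_q25", "age_median", "age_q75",
            "years_q25", "years_median", "years_q75",
        ])


def simulate_ages(
    s: float,
    demography: DemographicModel,
    mu: float,
    reps: int,
    seed: int,
    t_max: int | None = None,
) -> AgeSample:
    """Forward-simulate ``reps`` mutation trajectories; keep present-day segregants.

    Each trajectory starts at one copy at its origin generation and evolves
    by the deterministic underdominant pressure plus binomial resampling at
    the current epoch's diploid size.  Origin times are drawn over
    ``(0, t_max]`` with probability proportional to N(t) (mutational influx
    is ``2 N(t) mu``, and ``mu`` is constant).  Ages are conditional on
    origin within the horizon, which defaults to 4x the ancestral size.
    """
    if reps < 1000:
        raise ValueError("use at least 1e3 trajectories for a usable sample")
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = int(4 * demography.ancestral_size)
    # per-epoch origin counts proportional to N(t) summed over the epoch
    starts = list(demography.starts.astype(int)) + [t_max]
    sizes = demography.sizes.astype(float)
    spans = np.diff(starts)
    keep = spans > 0
    weights = sizes[: len(spans)] * spans
    weights = np.where(keep, weights, 0.0)
    weights /= weights.sum()
    per_epoch = rng.multinomial(reps, weights)
    birth = np.concatenate([
        rng.integers(lo + 1, hi + 1, size=c)
        for lo, hi, c in zip(starts[:-1], starts[1:], per_epoch)
    ]) if reps else np.empty(0, dtype=int)
    order = np.argsort(birth)[::-1]  # oldest first
    birth = birth[order]

    q_active = np.empty(0)
    born_active = np.empty(0, dtype=int)
    ptr = 0
    for t in range(t_max, 0, -1):
        n_pop = demography.size_at(t - 1)  # size during the step toward t-1
        # spawn trajectories whose origin is generation t
        n_new = 0
        while ptr + n_new < birth.size and birth[ptr + n_new] == t:
            n_new += 1
        if n_new:
            q_active = np.concatenate([
                q_active, np.full(n_new, 1.0 / (2.0 * n_pop))])
            born_active = np.concatenate([born_active, birth[ptr:ptr + n_new]])
            ptr += n_new
        if q_active.size == 0:
            continue
        q_next = q_active + expected_delta_q(s, q_active)
        q_next = np.clip(q_next, 0.0, 1.0)
        counts = rng.binomial(int(2 * n_pop), q_next)
        q_active = counts / (2.0 * n_pop)
        alive = (counts > 0) & (counts < int(2 * n_pop))
        q_active = q_active[alive]
        born_active = born_active[alive]
    if q_active.size == 0:
        raise RuntimeError(
            f"no segregating trajectories retained at s={s}; increase reps "
            f"(used {reps})"
        )
    return AgeSample(
        s=np.full(q_active.size, float(s)), q=q_active,
        age=born_active.astype(float), seed=seed, reps=reps, t_max=t_max,
    )


# ---------------------------------------------------------------------------
# hit-age prediction
# ---------------------------------------------------------------------------

#: Coarse selection values used when pooling trajectory simulations.
DEFAULT_S_POOL = (0.0, 1e-5, 10**-4.5, 1e-4, 10**-3.5, 1e-3, 10**-2.5, 1e-2)


def _bin_of(maf: np.ndarray, bins) -> np.ndarray:
    return np.clip(np.searchsorted(bins, maf, side="right") - 1, 0, len(bins) - 2)


def build_age_pools(
    demography: DemographicModel,
    mu: float,
    reps: int,
    seed: int,
    s_values=DEFAULT_S_POOL,
    t_max: int | None = None,
) -> dict[float, AgeSample]:
    """One trajectory sample per pooled selection coefficient."""
    pools = {}
    for i, s in enumerate(s_values):
        pools[float(s)] = simulate_ages(s, demography, mu, reps, seed + 7919 * i,
                                        t_max=t_max)
    return pools


def predicted_hit_ages(
    fit_params,
    hits: HitTable,
    cache: ConditionalSFS,
    pools: dict[float, AgeSample],
    seed: int,
    draws_per_hit: int = 20,
    maf_bins=DEFAULT_MAF_BINS,
    condition_on_z: bool = False,
) -> np.ndarray:
    """Model-predicted ages for a hit table (mixture over s posteriors).

    For each hit, the posterior over the pooled selection values is
    proportional to ``lambda_maf(maf_i|s) f(s)`` (times the z-likelihood when
    ``condition_on_z``); ages are then resampled from the matching
    (s, MAF-bin) trajectory pool.
    """
    rng = np.random.default_rng(seed)
    model = TraitModel(fit_params, cache)
    u = cache.log10_s
    wu = _trapezoid_weights(u)
    pos_pool = np.array(sorted(k for k in pools if k > 0))
    u_pos = np.log10(pos_pool)
    has_neutral = 0.0 in pools
    # map each fine-grid s to the nearest pooled s in log space; selection
    # half a decade below the weakest positive pool is effectively neutral
    # and uses the s = 0 pool when available
    edges = 0.5 * (u_pos[1:] + u_pos[:-1])
    assign = np.searchsorted(edges, u)
    if has_neutral:
        s_pool = np.concatenate([[0.0], pos_pool])
        assign = np.where(u < u_pos[0] - 0.5, 0, assign + 1)
    else:
        s_pool = pos_pool

    lam = cache.lam_maf_at(hits.maf)  # (n_s, n_hits)
    post_fine = wu[:, None] * model.rho[:, None] * lam
    if condition_on_z:
        sd = model._z_sd(hits.maf, hits.n_eff)
        zz = hits.abs_z[None, :] / sd
        post_fine = post_fine * np.exp(-0.5 * zz**2) / sd
    post = np.zeros((s_pool.size, len(hits)))
    for j in range(s_pool.size):
        post[j] = post_fine[assign == j].sum(axis=0)
    post /= post.sum(axis=0, keepdims=True)

    bins = np.asarray(maf_bins)
    hit_bin = _bin_of(hits.maf, bins)
    # pre-bin pool ages
    pool_ages: dict[tuple[float, int], np.ndarray] = {}
    for sv, sample in pools.items():
        b = _bin_of(sample.maf, bins)
        for j in range(bins.size - 1):
            pool_ages[(float(sv), j)] = sample.age[b == j]

    out = np.empty(len(hits) * draws_per_hit)
    pos = 0
    for i in range(len(hits)):
        s_idx = rng.choice(s_pool.size, size=draws_per_hit, p=post[:, i])
        for j in s_idx:
            ages = pool_ages[(float(s_pool[j]), int(hit_bin[i]))]
            jj = int(hit_bin[i])
            # fall back to the nearest populated MAF bin for sparse pools
            step = 1
            while ages.size == 0 and step < bins.size:
                for cand in (jj - step, jj + step):
                    if 0 <= cand < bins.size - 1:
                        ages = pool_ages[(float(s_pool[j]), cand)]
                        if ages.size:
                            break
                step += 1
            out[pos] = ages[rng.integers(ages.size)]
            pos += 1
    return out


def matched_neutral_ages(
    hits: HitTable,
    neutral_pool: AgeSample,
    seed: int,
    draws_per_hit: int = 20,
    maf_bins=DEFAULT_MAF_BINS,
) -> np.ndarray:
    """Neutral ages resampled to match the hits' MAF-bin distribution."""
    rng = np.random.default_rng(seed)
    bins = np.asarray(maf_bins)
    hit_bin = _bin_of(hits.maf, bins)
    pool_bin = _bin_of(neutral_pool.maf, bins)
    out = np.empty(len(hits) * draws_per_hit)
    pos = 0
    for i in range(len(hits)):
        ages = neutral_pool.age[pool_bin == hit_bin[i]]
        jj = int(hit_bin[i])
        step = 1
        while ages.size == 0 and step < bins.size:
            for cand in (jj - step, jj + step):
                if 0 <= cand < bins.size - 1:
                    ages = neutral_pool.age[pool_bin == cand]
                    if ages.size:
                        break
            step += 1
        idx = rng.integers(ages.size, size=draws_per_hit)
        out[pos:pos + draws_per_hit] = ages[idx]
        pos += draws_per_hit
    return out
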