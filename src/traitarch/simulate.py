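"""Synthetic multi-trait GWAS-hit generation.

Draws whole causal architectures from the generative model itself — per-site
selection coefficients from f(s), present-day frequencies from the cached
``lambda(q|s)``, effects from the beta|s normal and z-scores from the GWAS
noise model — then applies the ascertainment region to produce hit tables
with the exact statistical structure the inference assumes.  This is the
stand-in for biobank GWAS input and the engine of every recovery and
calibration experiment.

Segregating sites are sampled directly (Poisson counts per selection-grid
bin, inverse-CDF frequency draws), which keeps target sizes up to 1e8 cheap;
forward trajectory simulation is reserved for allele ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from traitarch.demography import DemographicModel, preset
from traitarch.sfs import ConditionalSFS, DEFAULT_MU, build_cache, _trapezoid_weights
from traitarch.trait import (
    MAF_MIN,
    SelectionDensity,
    TraitParams,
    HitTable,
    Z_THRESHOLD,
)

__all__ = [
    "TraitScenario",
    "simulate_trait",
    "simulate_panel",
    "fig_grid_scenarios",
    "ssd_panel_scenarios",
    "spike_outlier",
    "DEFAULT_N_BLOCKS",
]

#: Number of genome blocks used for block bootstrap / cross-validation,
#: mirroring the ~1,700 approximately independent LD blocks of a human genome.
DEFAULT_N_BLOCKS = 1700


@dataclass
class TraitScenario:
    """Ground-truth parameters for one synthetic trait."""

    label: str
    fs: SelectionDensity | str = "ssd-like"
    h2_over_L: float = 3e-8
    L: float = 1e7
    n: float = 3e5
    mu: float = DEFAULT_MU
    seed: int = 0
    demography: DemographicModel | str = "ukb-default"
    n_blocks: int = DEFAULT_N_BLOCKS

    def resolve(self) -> tuple[SelectionDensity, DemographicModel]:
        fs = SelectionDensity.preset(self.fs) if isinstance(self.fs, str) else self.fs
        dem = preset(self.demography) if isinstance(self.demography, str) else self.demography
        return fs, dem

    def params(self, cache: ConditionalSFS | None = None) -> TraitParams:
        fs, dem = self.resolve()
        return TraitParams(fs=fs, h2_over_L=self.h2_over_L, L=self.L,
                           mu=self.mu, n=self.n)


def simulate_trait(
    scenario: TraitScenario,
    cache: ConditionalSFS | None = None,
    rng: np.random.Generator | None = None,
    keep_architecture: bool = True,
) -> tuple[pd.DataFrame | None, HitTable]:
    """Draw one trait's causal architecture and its ascertained hit table.

    Returns ``(architecture, hits)``; the architecture table lists every
    segregating causal site (s, derived q, maf, beta, z, significance flag,
    block), and sums ``2 beta^2 q(1-q)`` to approximately ``h2``.
    """
    fs, dem = scenario.resolve()
    if scenario.h2_over_L * scenario.L >= 1:
        raise ValueError("implied h2 >= 1; refuse to simulate")
    if cache is None:
        cache = build_cache(dem, scenario.mu)
    rng = rng or np.random.default_rng(scenario.seed)

    u = cache.log10_s
    wu = _trapezoid_weights(u)
    rho = fs.density_log10(u)
    seg_p = cache.seg_prob
    # expected segregating causal sites per s-grid bin
    intensity = scenario.L * wu * rho * seg_p
    counts = rng.poisson(intensity)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no segregating sites drawn; increase L")

    # k matching the analytic model, so Var(beta|s) is consistent
    denom = float(np.sum(wu * rho * cache.s * cache.e2pq))
    var_scale = scenario.h2_over_L / denom  # = (h2/L) k / (4 mu)

    s_idx = np.repeat(np.arange(u.size), counts)
    # frequency: inverse-CDF draw from the cell masses of lambda(q|s),
    # uniform within the chosen cell
    masses = cache.lam * cache.grid.weights[None, :]
    cdf = np.cumsum(masses, axis=1)
    cdf /= cdf[:, -1:]
    r = rng.random(total)
    cells = np.empty(total, dtype=np.int64)
    for i in np.unique(s_idx):
        sel = s_idx == i
        cells[sel] = np.searchsorted(cdf[i], r[sel])
    lo = cache.grid.edges[cells]
    hi = cache.grid.edges[cells + 1]
    q = lo + (hi - lo) * rng.random(total)

    s_vals = cache.s[s_idx]
    beta = rng.normal(0.0, np.sqrt(var_scale * s_vals))
    z = beta * np.sqrt(2.0 * q * (1.0 - q) * scenario.n) + rng.normal(size=total)
    maf = np.minimum(q, 1.0 - q)
    significant = (maf >= MAF_MIN) & (np.abs(z) > Z_THRESHOLD)
    block = (np.arange(total) * scenario.n_blocks) // max(total, 1)

    arch = None
    if keep_architecture:
        arch = pd.DataFrame({
            "snp": [f"{scenario.label}_v{i}" for i in range(total)],
            "s": s_vals,
            "q": q,
            "maf": maf,
            "beta": beta,
            "z": z,
            "significant": significant,
            "block": block,
        })

    hit_df = pd.DataFrame({
        "snp": [f"{scenario.label}_v{i}" for i in np.flatnonzero(significant)],
        "maf": maf[significant],
        "abs_z": np.abs(z[significant]),
        "n_eff": np.full(int(significant.sum()), float(scenario.n)),
        "block": block[significant],
    })
    hits = HitTable(data=hit_df, label=scenario.label)
    return arch, hits


def simulate_panel(
    scenarios: list[TraitScenario],
    outdir: str | Path | None = None,
    keep_architecture: bool = False,
) -> dict[str, HitTable]:
    """Simulate a panel of traits; optionally write TSVs plus a manifest."""
    tables: dict[str, HitTable] = {}
    manifest = {}
    for sc in scenarios:
        arch, hits = simulate_trait(sc, keep_architecture=keep_architecture)
        tables[sc.label] = hits
        fs, dem = sc.resolve()
        manifest[sc.label] = {
            "fs_knots": list(np.asarray(fs.knot_logdens, dtype=float)),
            "knot_positions": list(np.asarray(fs.knot_positions, dtype=float)),
            "h2_over_L": sc.h2_over_L,
            "L": sc.L,
            "n": sc.n,
            "mu": sc.mu,
            "seed": sc.seed,
            "demography": dem.label,
            "n_hits": len(hits),
        }
        if outdir is not None:
            outdir_p = Path(outdir)
            outdir_p.mkdir(parents=True, exist_ok=True)
            hits.to_tsv(outdir_p / f"{sc.label}.hits.tsv")
            if keep_architecture and arch is not None:
                arch.to_csv(outdir_p / f"{sc.label}.architecture.tsv",
                            sep="\t", index=False, float_format="%.12g")
    if outdir is not None:
        with (Path(outdir) / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
    return tables


def fig_grid_scenarios(seed: int = 0, n: float = 3e5) -> list[TraitScenario]:
    """Three scenario pairs, each varying one model axis.

    (A) weak vs strong selection at fixed scaling parameters; (B) high vs low
    heritability per site; (C) small vs large mutational target size.
    """
    base = dict(n=n, demography="ukb-default")
    return [
        TraitScenario("A_weak", fs="weak", h2_over_L=3e-8, L=8e6, seed=seed, **base),
        TraitScenario("A_strong", fs="strong", h2_over_L=3e-8, L=8e6, seed=seed + 1, **base),
        TraitScenario("B_high_h2L", fs="ssd-like", h2_over_L=6e-8, L=6e6, seed=seed + 2, **base),
        TraitScenario("B_low_h2L", fs="ssd-like", h2_over_L=1e-8, L=6e6, seed=seed + 3, **base),
        TraitScenario("C_small_L", fs="ssd-like", h2_over_L=3e-8, L=5e6, seed=seed + 4, **base),
        TraitScenario("C_large_L", fs="ssd-like", h2_over_L=3e-8, L=1e7, seed=seed + 5, **base),
    ]


def ssd_panel_scenarios(
    n_traits: int = 95,
    seed: int = 0,
    hit_range: tuple[float, float] = (100.0, 1760.0),
    cache: ConditionalSFS | None = None,
) -> list[TraitScenario]:
    """A multi-trait panel sharing one f(s), shaped like a biobank dataset.

    Per-trait h2/L is log-uniform over a half-decade around 3e-8 and per-trait
    target hit counts are log-uniform between the requested bounds (geometric
    mean ~420, close to a biobank panel's mean of ~500); L is set so the
    expected hit count matches the target.  Effective sample sizes span
    2.5e5-4.6e5.
    """
    from traitarch.trait import TraitModel

    rng = np.random.default_rng(seed)
    fs = SelectionDensity.preset("ssd-like")
    if cache is None:
        cache = build_cache(preset("ukb-default"))
    lo, hi = np.log(hit_range[0]), np.log(hit_range[1])
    scenarios = []
    for i in range(n_traits):
        target_hits = float(np.exp(rng.uniform(lo, hi)))
        h2l = float(10.0 ** rng.uniform(-7.8, -7.2))
        n = float(rng.uniform(2.5e5, 4.6e5))
        params = TraitParams(fs=fs, h2_over_L=h2l, L=1.0, n=n, mu=cache.mu)
        psig = TraitModel(params, cache).prob_significant()
        l_val = target_hits / psig
        if l_val * h2l >= 0.9:  # keep implied h2 < 1
            l_val = 0.9 / h2l
        scenarios.append(TraitScenario(
            label=f"trait{i:03d}", fs=fs, h2_over_L=h2l, L=l_val, n=n,
            mu=cache.mu, seed=int(rng.integers(2**31)),
        ))
    return scenarios


def spike_outlier(
    hits: HitTable, factor: float, seed: int, maf_min: float = 0.3
) -> tuple[HitTable, str | None]:
    """Multiply one random common hit's |z| by ``factor``.

    Emulates a large-effect common variant that the stabilizing-selection
    model cannot accommodate (an FTO-style outlier); returns the modified
    table and the spiked snp id (None if factor == 1 leaves it unchanged).
    """
    rng = np.random.default_rng(seed)
    df = hits.data.copy()
    common = np.flatnonzero(df["maf"].to_numpy() >= maf_min)
    if common.size == 0:
        common = np.array([int(df["maf"].idxmax())])
    row = int(rng.choice(common))
    if factor != 1.0:
        df.loc[row, "abs_z"] = df.loc[row, "abs_z"] * factor
    return HitTable(data=df, label=hits.label), (
        str(df.loc[row, "snp"]) if factor != 1.0 else None
    )
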