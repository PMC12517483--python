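"""Scaling-law rescaling and architecture-collapse tests.

Under a shared selection-coefficient distribution, two traits' hit
architectures differ only through the heritability per site (h2/L), which
sets the natural units of effect sizes, and the target size L, which sets
the number of hits.  Dividing z-scores and effect sizes by sqrt(h2/L) and
imposing the more stringent *scaled* significance threshold should therefore
collapse the joint (MAF, z) hit distributions of any two such traits onto
each other.  This module performs the rescaling, the common-threshold
comparison for a pair, and the pooled collapse test for a panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from traitarch.trait import HitTable, Z_THRESHOLD

__all__ = [
    "ScaledHits",
    "ComparisonReport",
    "rescale",
    "common_threshold_compare",
    "panel_collapse",
]


@dataclass
class ScaledHits:
    """One trait's hits in scaled units (z and beta divided by sqrt(h2/L))."""

    label: str
    maf: np.ndarray
    scaled_z: np.ndarray
    scaled_beta: np.ndarray
    scaled_threshold: float
    h2_over_L: float

    @property
    def n_hits(self) -> int:
        return self.maf.size

    def above(self, threshold: float) -> "ScaledHits":
        keep = self.scaled_z > threshold
        return ScaledHits(
            label=self.label, maf=self.maf[keep], scaled_z=self.scaled_z[keep],
            scaled_beta=self.scaled_beta[keep],
            scaled_threshold=max(threshold, self.scaled_threshold),
            h2_over_L=self.h2_over_L,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "maf": self.maf, "scaled_z": self.scaled_z,
            "scaled_beta": self.scaled_beta,
        })


def rescale(hits: HitTable, h2_over_L: float, z_thresh: float = Z_THRESHOLD) -> ScaledHits:
    """Scale a hit table by its trait's heritability per site.

    ``scaled z = z / sqrt(h2/L)``; the implied per-allele effect
    ``|beta| = z / sqrt(2 m (1-m) n)`` is scaled the same way; the recorded
    scaled threshold is ``z_thresh / sqrt(h2/L)``.
    """
    if h2_over_L <= 0:
        raise ValueError("h2_over_L must be positive")
    root = np.sqrt(h2_over_L)
    beta = hits.abs_z / np.sqrt(2.0 * hits.maf * (1.0 - hits.maf) * hits.n_eff)
    return ScaledHits(
        label=hits.label,
        maf=hits.maf.copy(),
        scaled_z=hits.abs_z / root,
        scaled_beta=beta / root,
        scaled_threshold=z_thresh / root,
        h2_over_L=h2_over_L,
    )


@dataclass
class ComparisonReport:
    """Two-sample KS comparisons of scaled-hit marginals at a common threshold."""

    label_a: str
    label_b: str
    threshold: float
    n_a: int
    n_b: int
    ks: pd.DataFrame  # rows: marginal, columns: statistic, pvalue

    def pvalue(self, marginal: str) -> float:
        return float(self.ks.loc[marginal, "pvalue"])

    def min_pvalue(self) -> float:
        return float(self.ks["pvalue"].min())


def common_threshold_compare(a: ScaledHits, b: ScaledHits,
                             min_hits: int = 20) -> ComparisonReport:
    """Compare two scaled architectures above their joint stringent threshold."""
    thr = max(a.scaled_threshold, b.scaled_threshold)
    fa, fb = a.above(thr), b.above(thr)
    if fa.n_hits < min_hits or fb.n_hits < min_hits:
        raise ValueError(
            f"only {fa.n_hits}/{fb.n_hits} hits survive the common scaled "
            f"threshold; simulate larger target sizes"
        )
    rows = {}
    for name, xa, xb in (
        ("maf", fa.maf, fb.maf),
        ("scaled_z", fa.scaled_z, fb.scaled_z),
        ("scaled_beta", fa.scaled_beta, fb.scaled_beta),
    ):
        res = stats.ks_2samp(xa, xb)
        rows[name] = (float(res.statistic), float(res.pvalue))
    ks = pd.DataFrame(rows, index=["statistic", "pvalue"]).T
    return ComparisonReport(
        label_a=a.label, label_b=b.label, threshold=thr,
        n_a=fa.n_hits, n_b=fb.n_hits, ks=ks,
    )


def panel_collapse(panel: list[ScaledHits], min_hits: int = 20) -> pd.DataFrame:
    """Pairwise collapse tests for a panel at the global stringent threshold.

    All traits are filtered to the most stringent scaled threshold in the
    panel; returns one row per ordered pair with KS statistics and p-values
    for the MAF and scaled-z marginals, plus per-trait rejection counts via
    ``rejections_from``.
    """
    thr = max(s.scaled_threshold for s in panel)
    filtered = [s.above(thr) for s in panel]
    rows = []
    for i in range(len(filtered)):
        for j in range(i + 1, len(filtered)):
            fa, fb = filtered[i], filtered[j]
            if fa.n_hits < min_hits or fb.n_hits < min_hits:
                continue
            ks_m = stats.ks_2samp(fa.maf, fb.maf)
            ks_z = stats.ks_2samp(fa.scaled_z, fb.scaled_z)
            rows.append((fa.label, fb.label, fa.n_hits, fb.n_hits,
                         float(ks_m.statistic), float(ks_m.pvalue),
                         float(ks_z.statistic), float(ks_z.pvalue)))
    return pd.DataFrame(rows, columns=[
        "trait_a", "trait_b", "n_a", "n_b",
        "maf_D", "maf_p", "z_D", "z_p",
    ])


def rejections_from(pairwise: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-trait count of pairwise MAF-marginal rejections at level alpha."""
    rej = pairwise[pairwise["maf_p"] < alpha]
    counts = pd.concat([rej["trait_a"], rej["trait_b"]]).value_counts()
    all_traits = pd.concat([pairwise["trait_a"], pairwise["trait_b"]]).unique()
    return counts.reindex(all_traits, fill_value=0)
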