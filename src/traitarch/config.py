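"""Run configuration, seed substreams, and artifact round-tripping.

A run is fully described by a ``RunConfig`` (YAML on disk).  All randomness
flows from the single ``seed``, expanded into named substreams so that the
simulation, bootstrap, cross-validation and optimiser stages are independently
reproducible; the resolved configuration is written beside every run's
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from traitarch.demography import DemographicModel, load_demography, preset
from traitarch.inference import FitConfig
from traitarch.sfs import DEFAULT_MU

__all__ = ["RunConfig", "substream", "SUBSTREAMS"]

#: Named random substreams in fixed order; each expands the master seed.
SUBSTREAMS = ("simulation", "bootstrap", "cv", "optimizer", "ages")


def substream(seed: int, name: str) -> int:
    """A 31-bit child seed for a named stage, derived from the master seed."""
    try:
        idx = SUBSTREAMS.index(name)
    except ValueError:
        raise KeyError(f"unknown substream {name!r}; choose from {SUBSTREAMS}") from None
    child = np.random.SeedSequence(entropy=int(seed), spawn_key=(idx,))
    return int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    demography: str = "ukb-default"  # preset name or path to a history file
    mu: float = DEFAULT_MU
    n_s: int = 121
    n_q: int = 512
    q_min: float = 1e-5
    knot_positions: tuple[float, ...] = (-6.0, -4.5, -3.0, -1.5)
    penalty_weight: float = 1.0
    k_penalty_weight: float = 50.0
    k_reference: float | None = None
    n_starts: int = 8
    maxiter: int = 600
    bootstrap_b: int = 100
    cv_folds: int = 10
    seed: int = 0
    outdir: str = "runs/out"

    def fit_config(self) -> FitConfig:
        return FitConfig(
            penalty_weight=self.penalty_weight,
            k_penalty_weight=self.k_penalty_weight,
            k_reference=self.k_reference,
            knot_positions=tuple(self.knot_positions),
            n_starts=self.n_starts,
            seed=substream(self.seed, "optimizer"),
            maxiter=self.maxiter,
        )

    def demography_model(self) -> DemographicModel:
        p = Path(self.demography)
        if p.exists():
            return load_demography(p)
        return preset(self.demography)

    # -- IO --------------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "knot_positions" in raw:
            raw["knot_positions"] = tuple(raw["knot_positions"])
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        data = asdict(self)
        data["knot_positions"] = list(self.knot_positions)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
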