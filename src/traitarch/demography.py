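"""Piecewise-constant population-size histories.

Time is measured in generations before present; epoch ``(t_k, N_k)`` means the
diploid population size is ``N_k`` for all ``t`` with ``t_k <= t < t_{k+1}``,
and the oldest epoch extends to infinity.  A boundary time belongs to the
older epoch that starts at it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
import numpy as np

__all__ = [
    "DemographicModel",
    "load_demography",
    "write_demography",
    "constant_demography",
    "preset",
]


class DemographyError(ValueError):
    """Raised for malformed or inconsistent demographic histories."""


@dataclass(frozen=True)
class DemographicModel:
    """Ordered epochs of (start generation before present, diploid size N)."""

    epochs: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise DemographyError("demographic model needs at least one epoch")
        starts = [t for t, _ in self.epochs]
        sizes = [n for _, n in self.epochs]
        if starts[0] != 0:
            raise DemographyError("first epoch must start at generation 0 (present)")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise DemographyError("epoch start times must be strictly increasing")
        if any(t < 0 for t in starts):
            raise DemographyError("epoch start times must be >= 0")
        if any(n < 2 for n in sizes):
            raise DemographyError("diploid sizes must be >= 2")

    # -- queries ---------------------------------------------------------
    def size_at(self, t: float) -> int:
        """Diploid size of the epoch containing generation ``t`` before present."""
        t = float(t)
        if np.isnan(t) or t < 0:
            raise DemographyError(f"time before present must be >= 0, got {t}")
        n = self.epochs[0][1]
        for start, size in self.epochs:
            if t >= start:
                n = size
            else:
                break
        return n

    @property
    def starts(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs], dtype=float)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs], dtype=float)

    @property
    def ancestral_size(self) -> int:
        return self.epochs[-1][1]

    def digest(self) -> str:
        """Stable hash of the epochs, used to key SFS caches."""
        payload = ";".join(f"{t}:{n}" for t, n in self.epochs)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"(t>={t}: N={n})" for t, n in self.epochs)
        return f"DemographicModel[{self.label or 'unnamed'}: {body}]"


def constant_demography(n: int, label: str = "constant") -> DemographicModel:
    return DemographicModel(epochs=((0, int(n)),), label=label)


#: Built-in histories.  "ukb-default" is a four-epoch caricature of the
#: British history: ancestral size 14,000; a bottleneck to 3,000 around
#: 2,500 generations ago lasting ~100 generations; recovery to 10,000; and
#: recent explosive growth represented by a large final epoch.
_PRESETS: dict[str, DemographicModel] = {
    "constant": constant_demography(10_000),
    "ukb-default": DemographicModel(
        epochs=((0, 500_000), (150, 10_000), (2_400, 3_000), (2_500, 14_000)),
        label="ukb-default",
    ),
}


def preset(name: str) -> DemographicModel:
    """Return a built-in demographic history by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise DemographyError(
            f"unknown demography preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def load_demography(path: str | Path, label: str | None = None) -> DemographicModel:
    """Load a model from a two-column text file ``start_generation diploid_N``.

    Lines starting with '#' are comments; a non-numeric first line is
    treated as a header.  Later epochs are older (larger start times).
    """
    path = Path(path)
    epochs: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DemographyError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                t, n = float(parts[0]), float(parts[1])
            except ValueError:
                if not epochs:  # first non-comment line may be a header
                    continue
                raise DemographyError(
                    f"{path}:{lineno}: non-numeric entry {line!r}"
                ) from None
            if n <= 1:
                raise DemographyError(f"{path}:{lineno}: diploid size must be > 1")
            epochs.append((int(round(t)), int(round(n))))
    if not epochs:
        raise DemographyError(f"{path}: no epochs found")
    return DemographicModel(epochs=tuple(epochs), label=label or path.stem)


def write_demography(model: DemographicModel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# start_generation diploid_N\n")
        for t, n in model.epochs:
            fh.write(f"{t} {n}\n")
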