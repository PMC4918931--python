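"""Gower mixed-trait dissimilarities between species.

The functional facet of the analysis rests on a species-by-species distance
matrix in [0, 1] built from one quantitative trait (mean biomass, grams) and
one categorical trait (functional guild: roller / tunneler / dweller).
Gower's coefficient averages per-trait partial distances — the range-scaled
absolute difference for quantitative traits, a 0/1 mismatch indicator for
categorical ones — so traits of different types combine on a common scale.

Range normalisation always uses the full species pool of the table, never a
per-subset range: a pair's distance must be a fixed property of the pair for
the diversity partition to be coherent under pooling and subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import TraitTable, ValidationError

__all__ = ["DissimilarityMatrix", "gower_distance", "taxonomic_distance"]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise species distances with zero diagonal, in [0, 1]."""

    species_ids: list
    d: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")
        self.d = np.clip(d, 0.0, 1.0)
        self.species_ids = list(self.species_ids)

    def align(self, species_ids: Sequence) -> np.ndarray:
        """Return the sub-matrix reordered to ``species_ids``."""
        pos = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in species_ids if s not in pos]
        if missing:
            raise ValidationError(f"species missing from distance matrix: {missing}")
        idx = np.array([pos[s] for s in species_ids])
        return self.d[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.species_ids, columns=self.species_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="species")


def gower_distance(
    traits: TraitTable,
    weights: Mapping[str, float] | None = None,
    log_biomass: bool = False,
) -> DissimilarityMatrix:
    """Pairwise Gower distances from guild and biomass.

    Parameters
    ----------
    traits : TraitTable
        Complete trait table (guild, biomass_g) for the species pool.
    weights : mapping, optional
        Non-negative per-trait weights keyed by ``"guild"`` and
        ``"biomass"``; default is equal weights. All-zero weights error.
    log_biomass : bool
        Compare biomass on the natural-log scale before range scaling.
        Off by default: body mass enters untransformed.

    Notes
    -----
    If the biomass range over the pool is zero the quantitative trait is
    uninformative; it then contributes a partial distance of 0 and the fact
    is recorded in the result's ``meta['degenerate_traits']``.
    """
    df = traits.table
    n = df.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 species for Gower distances")
    w = {"guild": 1.0, "biomass": 1.0}
    if weights is not None:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ValidationError("trait weights must be non-negative")
    wsum = w["guild"] + w["biomass"]
    if wsum == 0:
        raise ValidationError("all trait weights are zero")

    guild = df["guild"].to_numpy()
    d_guild = (guild[:, None] != guild[None, :]).astype(float)

    x = df["biomass_g"].to_numpy(dtype=float)
    if log_biomass:
        x = np.log(x)
    rng = x.max() - x.min()
    degenerate = []
    if rng == 0:
        d_mass = np.zeros((n, n))
        degenerate.append("biomass")
    else:
        d_mass = np.abs(x[:, None] - x[None, :]) / rng

    d = (w["guild"] * d_guild + w["biomass"] * d_mass) / wsum
    meta = {
        "traits": ["guild", "biomass"],
        "weights": dict(w),
        "log_biomass": log_biomass,
        "degenerate_traits": degenerate,
    }
    return DissimilarityMatrix(list(df.index), d, meta=meta)


def taxonomic_distance(species_ids: Sequence) -> DissimilarityMatrix:
    """The taxonomic limiting case: every species pair maximally distinct.

    With d_ij = 1 for all i != j, Rao quadratic entropy reduces to the
    Simpson index, so this matrix turns the functional machinery into the
    taxonomic facet.
    """
    species_ids = list(species_ids)
    if not species_ids:
        raise ValidationError("need at least 1 species")
    n = len(species_ids)
    d = np.ones((n, n)) - np.eye(n)
    return DissimilarityMatrix(species_ids, d, meta={"traits": None, "kind": "taxonomic"})
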