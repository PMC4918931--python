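"""Multi-site beta diversity and its turnover / nestedness decomposition.

Total incidence-based (Sørensen family) multi-site dissimilarity splits into
a turnover (Simpson-type, replacement) component that ignores richness
differences and a nestedness-resultant component due to poorer sites being
subsets of richer ones.  With b_ij the number of entities present in site i
but not j, S_i site richness and S_T pooled richness:

    beta_SIM = sum_min / [(sum_i S_i - S_T) + sum_min]
    beta_SOR = (sum_min + sum_max) / [2 (sum_i S_i - S_T) + sum_min + sum_max]
    beta_SNE = beta_SOR - beta_SIM

where sum_min = sum over pairs of min(b_ij, b_ji) and likewise sum_max.

For the functional variant, species are first collapsed to functional units
(guild x biomass class); a unit is present at a site when any member species
is.  This incidence-level analysis is complementary to the Rao partition and
is not forced to reconcile with it numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CommunityMatrix, SpatialHierarchy, TraitTable, ValidationError

__all__ = [
    "BetaDecomposition",
    "multisite_sorensen_decompose",
    "functional_units",
    "incidence_by_group",
    "decompose_beta1",
    "decompose_beta2",
]


@dataclass
class BetaDecomposition:
    """Multi-site Sørensen dissimilarity with turnover and nestedness parts."""

    beta_total: float
    beta_turnover: float
    beta_nestedness: float
    n_sites: int
    meta: dict | None = None

    @property
    def prop_turnover(self) -> float:
        return self.beta_turnover / self.beta_total if self.beta_total > 0 else float("nan")

    @property
    def prop_nestedness(self) -> float:
        return self.beta_nestedness / self.beta_total if self.beta_total > 0 else float("nan")

    def to_dict(self) -> dict:
        # undefined proportions (zero total beta) serialize as null, not NaN
        return {
            "beta_total": self.beta_total,
            "beta_turnover": self.beta_turnover,
            "beta_nestedness": self.beta_nestedness,
            "prop_turnover": None if np.isnan(self.prop_turnover) else self.prop_turnover,
            "prop_nestedness": None if np.isnan(self.prop_nestedness) else self.prop_nestedness,
            "n_sites": self.n_sites,
            **({"meta": self.meta} if self.meta else {}),
        }


def _validate_incidence(inc: pd.DataFrame) -> np.ndarray:
    arr = (inc.to_numpy() > 0).astype(np.int64)
    if arr.shape[0] < 2:
        raise ValidationError("multi-site decomposition needs >= 2 sites")
    if np.any(arr.sum(axis=1) == 0):
        empty = inc.index[arr.sum(axis=1) == 0].tolist()
        raise ValidationError(f"site(s) with zero entities: {empty}")
    return arr


def multisite_sorensen_decompose(inc: pd.DataFrame, meta: dict | None = None) -> BetaDecomposition:
    """Decompose multi-site Sørensen beta over a sites x entities incidence table."""
    arr = _validate_incidence(inc)
    shared = arr @ arr.T
    s_i = arr.sum(axis=1)
    b = s_i[:, None] - shared  # b[i, j] = entities in i absent from j
    iu = np.triu_indices(arr.shape[0], k=1)
    sum_min = float(np.minimum(b[iu], b.T[iu]).sum())
    sum_max = float(np.maximum(b[iu], b.T[iu]).sum())
    s_t = int((arr.sum(axis=0) > 0).sum())
    core = float(s_i.sum() - s_t)

    turn_den = core + sum_min
    turnover = sum_min / turn_den if turn_den > 0 else 0.0
    tot_den = 2 * core + sum_min + sum_max
    total = (sum_min + sum_max) / tot_den if tot_den > 0 else 0.0
    return BetaDecomposition(
        beta_total=total,
        beta_turnover=turnover,
        beta_nestedness=total - turnover,
        n_sites=arr.shape[0],
        meta=meta,
    )


def functional_units(
    traits: TraitTable,
    matrix: CommunityMatrix,
    biomass_bins: int = 2,
) -> pd.DataFrame:
    """Site x functional-unit incidence, units = guild x biomass class.

    Biomass classes are quantile bins over the matrix's species pool
    (default 2 bins split at the pooled median).  A unit is present at a
    site when any of its member species is.  This mapping is an explicit
    modelling choice for incidence-level functional beta; its settings are
    recorded in the frame's ``attrs``.
    """
    traits.check_covers(matrix)
    if biomass_bins < 1:
        raise ValidationError("biomass_bins must be >= 1")
    sub = traits.table.loc[matrix.species_ids]
    if biomass_bins == 1:
        klass = pd.Series(0, index=sub.index)
    else:
        try:
            klass = pd.qcut(sub["biomass_g"], biomass_bins, labels=False, duplicates="drop")
        except ValueError as exc:  # pragma: no cover - unbinnable edge
            raise ValidationError(f"cannot bin biomass into {biomass_bins} classes: {exc}")
    unit = sub["guild"].astype(str) + "|m" + klass.astype(int).astype(str)
    inc = matrix.incidence()
    out = inc.T.groupby(unit.loc[inc.columns]).max().T
    out.attrs["functional_units"] = {"biomass_bins": biomass_bins, "rule": "guild x biomass quantile class"}
    return out


def incidence_by_group(inc: pd.DataFrame, hierarchy: SpatialHierarchy) -> pd.DataFrame:
    """Pool a site-level incidence table to one presence vector per group."""
    rows = {}
    for g in hierarchy.groups:
        sites = [s for s in hierarchy.sites_in(g) if s in inc.index]
        if not sites:
            raise ValidationError(f"group {g!r} has no sites in the incidence table")
        rows[g] = (inc.loc[sites].sum(axis=0) > 0).astype(np.int64)
    return pd.DataFrame(rows).T


def decompose_beta1(
    matrix: CommunityMatrix,
    hierarchy: SpatialHierarchy,
    traits: TraitTable | None = None,
    biomass_bins: int = 2,
) -> dict:
    """Per-group turnover/nestedness of the transects within each altitude."""
    inc = (
        functional_units(traits, matrix, biomass_bins)
        if traits is not None
        else matrix.incidence()
    )
    facet = "FD" if traits is not None else "TD"
    out = {}
    for g in hierarchy.groups:
        sites = [s for s in hierarchy.sites_in(g) if s in inc.index]
        if len(sites) < 2:
            continue
        out[g] = multisite_sorensen_decompose(
            inc.loc[sites], meta={"facet": facet, "level": "within-group", "group": str(g)}
        )
    return out


def decompose_beta2(
    matrix: CommunityMatrix,
    hierarchy: SpatialHierarchy,
    traits: TraitTable | None = None,
    biomass_bins: int = 2,
) -> BetaDecomposition:
    """Turnover/nestedness among altitude-pooled communities."""
    inc = (
        functional_units(traits, matrix, biomass_bins)
        if traits is not None
        else matrix.incidence()
    )
    pooled = incidence_by_group(inc, hierarchy)
    facet = "FD" if traits is not None else "TD"
    return multisite_sorensen_decompose(
        pooled, meta={"facet": facet, "level": "among-groups"}
    )
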