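"""Jost-corrected Rao/Simpson diversity and its additive spatial partition.

Rao quadratic entropy Q = sum_ij d_ij p_i p_j is the expected trait
dissimilarity between two randomly drawn individuals.  With d_ij = 1 for all
pairs it reduces to the Simpson index 1 - sum p_i^2, so one partition
machinery serves both the taxonomic (TD) and functional (FD) facets.

Raw entropies are converted to equivalent numbers via Jost's correction
1/(1 - Q): diversity in units of equally abundant, maximally distinct
species, which makes beta independent of alpha.  The partition follows the
two-level sampling hierarchy transect-within-altitude:

    alpha1  within-transect diversity (corrected mean of transect entropies)
    alpha2  within-altitude diversity (transects pooled per altitude)
    gamma   regional diversity (all transects pooled)
    beta1 = alpha2 - alpha1     among transects, within altitudes
    beta2 = gamma - alpha2      among altitudes

and each component is also expressed as a proportion of gamma so taxonomic
and functional partitions are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AbundanceVector, CommunityMatrix, SpatialHierarchy, ValidationError
from .gower import DissimilarityMatrix, taxonomic_distance

__all__ = [
    "DiversityPartition",
    "rao_entropy",
    "simpson_entropy",
    "jost_correct",
    "partition_two_level",
    "richness",
]


def rao_entropy(p: AbundanceVector, D: DissimilarityMatrix) -> float:
    """Raw Rao quadratic entropy sum_ij d_ij p_i p_j, in [0, 1]."""
    d = D.align(p.species_ids)
    return float(p.p @ d @ p.p)


def simpson_entropy(p: AbundanceVector) -> float:
    """Raw Simpson entropy 1 - sum p_i^2 (Rao under the all-ones distance)."""
    return float(1.0 - np.dot(p.p, p.p))


def jost_correct(raw: float) -> float:
    """Equivalent-numbers transform 1/(1 - raw) of a Simpson/Rao entropy.

    Maps a single-species community (raw = 0) to 1, the index floor, and a
    perfectly even community of S maximally distinct species to S.
    """
    if raw >= 1.0:
        raise ValidationError("raw entropy must be < 1 for a finite community")
    return 1.0 / (1.0 - raw)


@dataclass
class DiversityPartition:
    """Equivalent-number diversity components for one facet (TD or FD)."""

    facet: str
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    gamma: float
    prop_alpha1: float
    prop_beta1: float
    prop_beta2: float
    raw_transect: pd.Series = field(repr=False)
    raw_group: pd.Series = field(repr=False)
    raw_gamma: float = field(repr=False)
    # per-altitude beta1 contribution, (alpha2_g - alpha1_g)/alpha2_g in %
    beta1_contrib_pct: pd.Series = field(repr=False)
    convention: str = "mean-then-correct"

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: facet, component, equivalent number, proportion of gamma."""
        rows = [
            ("alpha1", self.alpha1, self.prop_alpha1),
            ("beta1", self.beta1, self.prop_beta1),
            ("alpha2", self.alpha2, self.prop_alpha1 + self.prop_beta1),
            ("beta2", self.beta2, self.prop_beta2),
            ("gamma", self.gamma, 1.0),
        ]
        return pd.DataFrame(
            [(self.facet, c, v, p) for c, v, p in rows],
            columns=["facet", "component", "equivalent_number", "proportion_of_gamma"],
        )

    def to_dict(self) -> dict:
        return {
            "facet": self.facet,
            "alpha1": self.alpha1,
            "beta1": self.beta1,
            "alpha2": self.alpha2,
            "beta2": self.beta2,
            "gamma": self.gamma,
            "prop_alpha1": self.prop_alpha1,
            "prop_beta1": self.prop_beta1,
            "prop_beta2": self.prop_beta2,
            "convention": self.convention,
            "beta1_contrib_pct": self.beta1_contrib_pct.to_dict(),
        }


def _corrected(raws: np.ndarray, convention: str) -> float:
    """Alpha in equivalent numbers from unit-level raw entropies."""
    if convention == "mean-then-correct":
        return jost_correct(float(np.mean(raws)))
    if convention == "correct-then-mean":
        return float(np.mean([jost_correct(r) for r in raws]))
    raise ValidationError(f"unknown averaging convention {convention!r}")


def partition_two_level(
    matrix: CommunityMatrix,
    hierarchy: SpatialHierarchy,
    D: DissimilarityMatrix | None = None,
    facet: str | None = None,
    convention: str = "mean-then-correct",
) -> DiversityPartition:
    """Additive alpha1/beta1/alpha2/beta2/gamma partition in equivalent numbers.

    Parameters
    ----------
    matrix : CommunityMatrix
        Transect-level counts.
    hierarchy : SpatialHierarchy
        Transect -> altitude-group assignment; must cover every site.
    D : DissimilarityMatrix, optional
        Species distances for the functional facet.  ``None`` uses the
        all-ones taxonomic distance (Rao = Simpson).
    convention : str
        ``"mean-then-correct"`` (default): average raw entropies across
        units, then apply Jost's correction — this keeps beta components
        non-negative because 1/(1-x) is convex and Rao entropy is concave
        under pooling.  ``"correct-then-mean"`` averages equivalent numbers
        instead and is provided for comparison only.

    Notes
    -----
    Pooling sums raw counts before normalising, so transects with more
    individuals weigh more in alpha2/gamma entropies; with equal transect
    totals this coincides with averaging relative-abundance vectors.
    """
    hierarchy.check_covers(matrix)
    if len(matrix.site_ids) < 2:
        raise ValidationError("partition needs at least 2 transects")
    taxonomic = D is None
    if taxonomic:
        facet = facet or "TD"
        d = None
    else:
        facet = facet or "FD"
        d = D.align(matrix.species_ids)

    counts = matrix.counts.to_numpy(dtype=float)

    def _raw(rows: np.ndarray) -> np.ndarray:
        """Rao entropy of each row of a count (or pooled-count) array."""
        tot = rows.sum(axis=1, keepdims=True)
        if np.any(tot == 0):
            raise ValidationError("a unit with zero individuals")
        P = rows / tot
        if taxonomic:
            return 1.0 - np.einsum("ij,ij->i", P, P)
        return np.einsum("ij,jk,ik->i", P, d, P)

    raw_t = pd.Series(_raw(counts), index=matrix.counts.index, name="raw_transect")
    groups = [g for g in hierarchy.groups if hierarchy.sites_in(g)]
    site_pos = {s: i for i, s in enumerate(matrix.counts.index)}
    group_sites = {}
    for g in groups:
        sites = [s for s in hierarchy.sites_in(g) if s in site_pos]
        if not sites:
            raise ValidationError(f"group {g!r} has no surviving transect")
        group_sites[g] = sites
    pooled = np.vstack(
        [counts[[site_pos[s] for s in group_sites[g]]].sum(axis=0) for g in groups]
    )
    raw_g = pd.Series(_raw(pooled), index=pd.Index(groups), name="raw_group")
    alpha1_within = {
        g: _corrected(raw_t.loc[group_sites[g]].to_numpy(), convention) for g in groups
    }
    raw_gamma = float(_raw(counts.sum(axis=0, keepdims=True))[0])

    alpha1 = _corrected(raw_t.to_numpy(), convention)
    alpha2 = _corrected(raw_g.to_numpy(), convention)
    gamma = jost_correct(raw_gamma)
    beta1 = alpha2 - alpha1
    beta2 = gamma - alpha2

    contrib = pd.Series(
        {
            g: 100.0 * (jost_correct(raw_g[g]) - alpha1_within[g]) / jost_correct(raw_g[g])
            for g in groups
        },
        name="beta1_contrib_pct",
    )

    return DiversityPartition(
        facet=facet,
        alpha1=alpha1,
        beta1=beta1,
        alpha2=alpha2,
        beta2=beta2,
        gamma=gamma,
        prop_alpha1=alpha1 / gamma,
        prop_beta1=beta1 / gamma,
        prop_beta2=beta2 / gamma,
        raw_transect=raw_t,
        raw_group=raw_g,
        raw_gamma=raw_gamma,
        beta1_contrib_pct=contrib,
        convention=convention,
    )


def richness(
    matrix: CommunityMatrix,
    hierarchy: SpatialHierarchy | None = None,
    level: str = "site",
):
    """Species counts with positive abundance at the requested level.

    ``level`` is ``"site"`` (per transect), ``"group"`` (per altitude,
    transects pooled; requires a hierarchy) or ``"total"``.
    """
    inc = matrix.incidence()
    if level == "site":
        return inc.sum(axis=1)
    if level == "group":
        if hierarchy is None:
            raise ValidationError("group-level richness needs a hierarchy")
        hierarchy.check_covers(matrix)
        out = {}
        for g in hierarchy.groups:
            sites = [s for s in hierarchy.sites_in(g) if s in matrix.counts.index]
            out[g] = int((matrix.counts.loc[sites].sum(axis=0) > 0).sum())
        return pd.Series(out)
    if level == "total":
        return int((matrix.counts.sum(axis=0) > 0).sum())
    raise ValidationError(f"unknown level {level!r}")
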