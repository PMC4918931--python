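"""Model/results front-end tying the partition, decomposition and null stages
together in the familiar build-then-fit idiom:

>>> model = DiversityModel(matrix, hierarchy, traits=traits)
>>> res = model.fit(n_null=199, seed=1)
>>> print(res.summary())

``fit`` computes the Jost-corrected Rao/Simpson partition for the taxonomic
facet (and the functional facet when traits are supplied), the multi-site
turnover/nestedness decomposition of beta1 (per altitude) and beta2, and —
unless ``n_null=0`` — null-model Z scores and empirical p-values for the
partition components, which play the role of the uncertainty statements a
regression table would carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beta import BetaDecomposition, decompose_beta1, decompose_beta2
from .data import (
    CommunityMatrix,
    SpatialHierarchy,
    TraitTable,
    read_community_matrix,
    read_hierarchy,
    read_trait_table,
)
from .gower import DissimilarityMatrix, gower_distance
from .nullmodels import (
    null_abundance_swap,
    null_binary_fixed_fixed,
    null_test,
    partition_statistic,
)
from .partition import DiversityPartition, partition_two_level, richness

__all__ = ["DiversityModel", "DiversityResults"]


class DiversityModel:
    """Diversity-partition analysis of one site-by-species matrix.

    Parameters
    ----------
    matrix : CommunityMatrix
        Transect-level counts.
    hierarchy : SpatialHierarchy
        Transect -> altitude-group map.
    traits : TraitTable, optional
        Guild + biomass per species; omitting it yields a taxonomic-only
        analysis.
    distance : DissimilarityMatrix, optional
        Pre-computed functional distances; by default Gower distances are
        built from ``traits``.
    convention : str
        Jost-correction averaging convention (see
        :func:`divrao.partition.partition_two_level`).
    """

    def __init__(
        self,
        matrix: CommunityMatrix,
        hierarchy: SpatialHierarchy,
        traits: TraitTable | None = None,
        distance: DissimilarityMatrix | None = None,
        convention: str = "mean-then-correct",
        biomass_bins: int = 2,
    ) -> None:
        hierarchy.check_covers(matrix)
        if traits is not None:
            traits.check_covers(matrix)
        self.matrix = matrix
        self.hierarchy = hierarchy
        self.traits = traits
        self.convention = convention
        self.biomass_bins = biomass_bins
        if distance is not None:
            self.distance = distance
        elif traits is not None:
            self.distance = gower_distance(traits)
        else:
            self.distance = None

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        hierarchy_path: str | Path,
        traits_path: str | Path | None = None,
        **kwargs,
    ) -> "DiversityModel":
        traits = read_trait_table(traits_path) if traits_path else None
        return cls(
            read_community_matrix(matrix_path),
            read_hierarchy(hierarchy_path),
            traits=traits,
            **kwargs,
        )

    def fit(
        self,
        n_null: int = 999,
        seed: int = 0,
        null_stats: tuple = ("alpha2", "beta2", "gamma"),
        null_models: tuple = ("binary", "abundance"),
    ) -> "DiversityResults":
        """Run all stages; ``n_null=0`` skips the permutation tests."""
        partitions = {
            "TD": partition_two_level(
                self.matrix, self.hierarchy, D=None, convention=self.convention
            )
        }
        beta1 = {"TD": decompose_beta1(self.matrix, self.hierarchy)}
        beta2 = {"TD": decompose_beta2(self.matrix, self.hierarchy)}
        if self.distance is not None:
            partitions["FD"] = partition_two_level(
                self.matrix, self.hierarchy, D=self.distance, facet="FD",
                convention=self.convention,
            )
            if self.traits is not None:
                beta1["FD"] = decompose_beta1(
                    self.matrix, self.hierarchy, self.traits, self.biomass_bins
                )
                beta2["FD"] = decompose_beta2(
                    self.matrix, self.hierarchy, self.traits, self.biomass_bins
                )

        null_results: dict = {}
        if n_null > 0:
            facets = list(partitions)
            for model_name in null_models:
                if model_name == "binary":
                    ens = null_binary_fixed_fixed(self.matrix, n_perm=n_null, seed=seed)
                    observed = self.matrix.binary()
                elif model_name == "abundance":
                    ens = null_abundance_swap(self.matrix, n_perm=n_null, seed=seed)
                    observed = self.matrix
                else:
                    raise ValueError(f"unknown null model {model_name!r}")
                for facet in facets:
                    D = None if facet == "TD" else self.distance
                    for comp in null_stats:
                        fn = partition_statistic(
                            comp, self.hierarchy, D=D, convention=self.convention
                        )
                        key = f"{model_name}:{facet}:{comp}"
                        null_results[key] = null_test(fn, observed, ens, name=key)

        return DiversityResults(
            model=self,
            partitions=partitions,
            beta1=beta1,
            beta2=beta2,
            null_results=null_results,
            n_null=n_null,
            seed=seed,
        )


@dataclass
class DiversityResults:
    """Fitted diversity analysis: partitions, decompositions, null tests."""

    model: DiversityModel
    partitions: dict  # facet -> DiversityPartition
    beta1: dict       # facet -> {group -> BetaDecomposition}
    beta2: dict       # facet -> BetaDecomposition
    null_results: dict
    n_null: int
    seed: int

    # -- tabular views ---------------------------------------------------------
    def partition_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.partitions.values()],
                         ignore_index=True)

    def beta_frame(self) -> pd.DataFrame:
        rows = []
        for facet, dec in self.beta2.items():
            rows.append({"facet": facet, "level": "among-groups", "group": "",
                         **{k: v for k, v in dec.to_dict().items() if k != "meta"}})
        for facet, per_group in self.beta1.items():
            for g, dec in per_group.items():
                rows.append({"facet": facet, "level": "within-group", "group": str(g),
                             **{k: v for k, v in dec.to_dict().items() if k != "meta"}})
        return pd.DataFrame(rows)

    def null_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.null_results.values()])

    def richness(self) -> pd.Series:
        return richness(self.model.matrix, self.model.hierarchy, level="group")

    # -- summary ---------------------------------------------------------------
    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "Diversity partition (Jost-corrected Rao/Simpson, equivalent numbers)",
            "=" * 72,
            f"sites: {len(m.site_ids)}   species: {len(m.species_ids)}   "
            f"individuals: {m.n_individuals}   groups: {len(self.model.hierarchy.groups)}",
            "",
        ]
        for facet, p in self.partitions.items():
            lines += [
                f"[{facet}]  alpha1={p.alpha1:.3f}  beta1={p.beta1:.3f}  "
                f"alpha2={p.alpha2:.3f}  beta2={p.beta2:.3f}  gamma={p.gamma:.3f}",
                f"      proportions of gamma: alpha1 {100 * p.prop_alpha1:.1f}%  "
                f"beta1 {100 * p.prop_beta1:.1f}%  beta2 {100 * p.prop_beta2:.1f}%",
            ]
        lines.append("")
        for facet, dec in self.beta2.items():
            lines.append(
                f"beta2-{facet} (multi-site Sorensen): total={dec.beta_total:.3f}  "
                f"turnover={dec.beta_turnover:.3f} ({100 * dec.prop_turnover:.1f}%)  "
                f"nestedness={dec.beta_nestedness:.3f} ({100 * dec.prop_nestedness:.1f}%)"
            )
        if self.null_results:
            lines += ["", f"null models ({self.n_null} permutations, seed {self.seed}):"]
            for key, r in self.null_results.items():
                z = "nan" if np.isnan(r.z) else f"{r.z:+.2f}"
                lines.append(
                    f"  {key:<24s} obs={r.observed:.3f}  null={r.null_mean:.3f}"
                    f"±{r.null_sd:.3f}  Z={z}  p={r.p_value:.4f}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "partitions": {f: p.to_dict() for f, p in self.partitions.items()},
            "beta2": {f: d.to_dict() for f, d in self.beta2.items()},
            "beta1": {
                f: {str(g): d.to_dict() for g, d in per.items()}
                for f, per in self.beta1.items()
            },
            "null_models": {k: r.to_dict() for k, r in self.null_results.items()},
            "n_null": self.n_null,
            "seed": self.seed,
        }

    # -- plotting --------------------------------------------------------------
    def plot_contributions(self, ax=None):
        """Stacked bars of alpha1/beta1/beta2 proportions of gamma per facet."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        facets = list(self.partitions)
        comps = ["prop_alpha1", "prop_beta1", "prop_beta2"]
        labels = ["alpha1", "beta1", "beta2"]
        bottom = np.zeros(len(facets))
        for comp, lab in zip(comps, labels):
            vals = np.array([getattr(self.partitions[f], comp) for f in facets])
            ax.bar(facets, 100 * vals, bottom=100 * bottom, label=lab)
            bottom = bottom + vals
        ax.set_ylabel("% of gamma diversity")
        ax.legend()
        return ax

    def plot_beta_components(self, ax=None):
        """Stacked bars of turnover vs nestedness shares of beta2 per facet."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        facets = list(self.beta2)
        turn = np.array([self.beta2[f].prop_turnover for f in facets])
        nest = np.array([self.beta2[f].prop_nestedness for f in facets])
        ax.bar(facets, 100 * turn, label="turnover")
        ax.bar(facets, 100 * nest, bottom=100 * turn, label="nestedness")
        ax.set_ylabel("% of beta2 (multi-site Sorensen)")
        ax.legend()
        return ax
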