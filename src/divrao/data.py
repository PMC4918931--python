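"""Core data containers and delimited-text I/O.

The universal input is a site-by-species abundance matrix of non-negative
integer counts (individuals per trap-period, pooled per transect), together
with a species trait table (functional guild and mean body mass) and a
spatial hierarchy assigning each transect to an altitude group.  Relative
abundances are always derived lazily from the counts and never stored on
disk, so there is no rounding drift between files and analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

GUILDS = ("roller", "tunneler", "dweller")

__all__ = [
    "GUILDS",
    "CommunityMatrix",
    "SpatialHierarchy",
    "TraitTable",
    "AbundanceVector",
    "read_community_matrix",
    "read_trait_table",
    "read_hierarchy",
    "read_species_summary",
    "pool_sites",
    "sum_matrices",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates a hard invariant."""


def _check_unique(labels: Sequence, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} label(s): {dup}")


@dataclass
class CommunityMatrix:
    """Sites x species abundance counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts, index = site labels (transects), columns = species.

    Sites whose row is entirely zero are dropped at construction and listed
    in ``validation_report['dropped_empty_sites']``.  Species columns that
    are all zero are *retained* (the species universe stays stable across
    subsets, and a zero relative abundance contributes nothing to Rao
    entropy) but are listed in ``validation_report['zero_species']``.
    """

    counts: pd.DataFrame
    validation_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "site")
        _check_unique(df.columns, "species")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise ValidationError(f"non-numeric counts in column(s) {list(bad)}")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at site {df.index[i]!r}, species {df.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at site {df.index[i]!r}, species {df.columns[j]!r}"
            )
        df = df.astype(np.int64)
        empty = df.index[df.sum(axis=1) == 0].tolist()
        if empty:
            df = df.drop(index=empty)
        if df.shape[0] == 0:
            raise ValidationError("matrix has no site with a positive count")
        zero_sp = df.columns[df.sum(axis=0) == 0].tolist()
        report = dict(self.validation_report)
        report.setdefault("dropped_empty_sites", empty)
        report.setdefault("zero_species", zero_sp)
        object.__setattr__(self, "counts", df)
        object.__setattr__(self, "validation_report", report)

    # -- convenience accessors -------------------------------------------------
    @property
    def site_ids(self) -> list:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_individuals(self) -> int:
        return int(self.counts.to_numpy().sum())

    def incidence(self) -> pd.DataFrame:
        """Presence/absence (0/1 int) projection."""
        return (self.counts > 0).astype(np.int64)

    def binary(self) -> "CommunityMatrix":
        return CommunityMatrix(self.incidence())

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.counts.to_csv(path, sep=sep)

    def write_validation_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.validation_report, indent=2))


@dataclass
class SpatialHierarchy:
    """Transect -> altitude-group assignment (the two nesting levels)."""

    mapping: dict

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValidationError("hierarchy is empty")
        self.mapping = dict(self.mapping)

    @property
    def groups(self) -> list:
        out = []
        for g in self.mapping.values():
            if g not in out:
                out.append(g)
        return out

    def sites_in(self, group) -> list:
        return [s for s, g in self.mapping.items() if g == group]

    def check_covers(self, matrix: CommunityMatrix) -> None:
        missing = [s for s in matrix.site_ids if s not in self.mapping]
        if missing:
            raise ValidationError(f"sites missing from hierarchy: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site": list(self.mapping), "group": list(self.mapping.values())}
        )


@dataclass
class TraitTable:
    """Species traits: functional guild (categorical) and mean biomass in grams.

    One row per species; guild must be one of ``GUILDS`` and biomass strictly
    positive.  Missing values are hard errors: the analysis assumes complete
    trait coverage of the species pool.
    """

    table: pd.DataFrame  # index = species, columns at least {guild, biomass_g}

    def __post_init__(self) -> None:
        df = self.table
        _check_unique(df.index, "species")
        for col in ("guild", "biomass_g"):
            if col not in df.columns:
                raise ValidationError(f"trait table lacks required column {col!r}")
        if df[["guild", "biomass_g"]].isna().any().any():
            raise ValidationError("trait table contains missing values")
        bad = sorted(set(df["guild"]) - set(GUILDS))
        if bad:
            raise ValidationError(f"unknown guild level(s) {bad}; expected {GUILDS}")
        if (df["biomass_g"] <= 0).any():
            sp = df.index[df["biomass_g"] <= 0][0]
            raise ValidationError(f"non-positive biomass for species {sp!r}")
        self.table = df

    @property
    def species_ids(self) -> list:
        return list(self.table.index)

    def check_covers(self, matrix: CommunityMatrix) -> None:
        missing = [s for s in matrix.species_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"species missing from trait table: {missing}")

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index_label="species")


@dataclass
class AbundanceVector:
    """Relative abundances p_i for one (possibly pooled) community."""

    species_ids: list
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0):
            raise ValidationError("relative abundances must be non-negative")
        s = p.sum()
        if not np.isclose(s, 1.0, atol=1e-12, rtol=0):
            raise ValidationError(f"relative abundances sum to {s}, not 1")
        self.p = p
        self.species_ids = list(self.species_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.p, index=self.species_ids)


# ---------------------------------------------------------------------------
# pooling


def pool_sites(matrix: CommunityMatrix, site_subset: Iterable | None = None) -> AbundanceVector:
    """Sum counts across a subset of sites and normalise to relative abundances.

    ``site_subset=None`` pools every site (the gamma-level community).
    Summation before normalisation mirrors pooling seasonal/trap replicates
    by adding individuals, so sites with more individuals weigh more in the
    pooled vector.
    """
    if site_subset is None:
        sub = matrix.counts
    else:
        site_subset = list(site_subset)
        if not site_subset:
            raise ValidationError("empty site subset")
        missing = [s for s in site_subset if s not in matrix.counts.index]
        if missing:
            raise ValidationError(f"unknown site(s) {missing}")
        sub = matrix.counts.loc[site_subset]
    tot = sub.to_numpy().sum(axis=0).astype(float)
    if tot.sum() == 0:
        raise ValidationError("pooled subset contains no individuals")
    return AbundanceVector(matrix.species_ids, tot / tot.sum())


def sum_matrices(matrices: Sequence[CommunityMatrix]) -> CommunityMatrix:
    """Element-wise sum of replicate matrices (e.g. seasonal samples).

    All matrices must share identical site and species universes; counts are
    added, mirroring the pooling of repeated trap periods by summation.
    """
    if not matrices:
        raise ValidationError("no matrices to sum")
    base = matrices[0].counts
    total = base.copy()
    for m in matrices[1:]:
        if list(m.counts.index) != list(base.index) or list(m.counts.columns) != list(
            base.columns
        ):
            raise ValidationError("matrices to sum must share sites and species")
        total = total + m.counts
    return CommunityMatrix(total)


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Comma- or tab-delimited UTF-8 table; '#'-prefixed comment lines skipped."""
    path = Path(path)
    first = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                first = line
                break
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def read_community_matrix(path: str | Path) -> CommunityMatrix:
    """Read a site-by-species count table.

    First column holds site labels, header row holds species labels.
    Negative, missing or non-numeric cells raise naming the offending cell.
    """
    df = _read_delimited(path)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"missing/non-numeric count at site {df.index[r]!r}, species {df.columns[c]!r}"
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[~df[col].astype(str).str.fullmatch(r"-?\d+(\.0*)?")]
            where = bad[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric count at site {where!r}, species {col!r}"
            )
    return CommunityMatrix(df)


def read_trait_table(path: str | Path) -> TraitTable:
    df = _read_delimited(path)
    df.index.name = "species"
    return TraitTable(df)


def read_hierarchy(path: str | Path) -> SpatialHierarchy:
    """Read a transect->group map from YAML (mapping) or two-column CSV/TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, Mapping):
            raise ValidationError("hierarchy YAML must be a mapping site -> group")
        return SpatialHierarchy(dict(data))
    df = _read_delimited(path, index_col=None)
    if df.shape[1] < 2:
        raise ValidationError("hierarchy CSV needs two columns: site, group")
    return SpatialHierarchy(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_species_summary(path: str | Path) -> pd.DataFrame:
    """Read a per-species summary table (species, guild, biomass, total count).

    This is the shape in which regional studies often deposit community data
    when transect-level matrices are withheld: one row per species with its
    guild, mean biomass and the total number of individuals collected.
    Returns the parsed table; use :func:`summarize_species_table` for the
    derived headline counts.
    """
    df = _read_delimited(path)
    df.index.name = "species"
    needed = {"guild", "total_individuals"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"species summary lacks column(s) {sorted(missing)}")
    bad = sorted(set(df["guild"]) - set(GUILDS))
    if bad:
        raise ValidationError(f"unknown guild level(s) {bad}")
    if (df["total_individuals"] < 0).any():
        raise ValidationError("negative total_individuals")
    return df


def summarize_species_table(df: pd.DataFrame) -> dict:
    """Headline counts from a per-species summary: totals and per-guild richness."""
    out = {
        "total_individuals": int(df["total_individuals"].sum()),
        "total_species": int(df.shape[0]),
    }
    for g in GUILDS:
        out[f"species_{g}"] = int((df["guild"] == g).sum())
    return out
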