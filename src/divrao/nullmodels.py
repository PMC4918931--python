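"""Constrained matrix randomizations and Z-score tests against null ensembles.

Two null families, matching the two questions a gradient study asks of its
diversity components:

* ``null_binary_fixed_fixed`` — randomize the presence/absence projection
  while holding both the number of species per transect (row sums) and the
  number of transects each species occupies (column sums).  Implemented as a
  Markov chain of checkerboard 2x2 swaps with burn-in and thinning, the
  standard fixed-fixed co-occurrence null.
* ``null_abundance_swap`` — randomize the count matrix.  The default variant
  first randomizes the incidence structure with fixed-fixed swaps and then
  redistributes each transect's individuals over its occupied cells by a
  multinomial draw, conserving row richness, column occupancy counts and row
  abundance totals (the "support capacity" of each transect).  The stricter
  ``quasiswap-count`` variant conserves row AND column abundance totals plus
  matrix fill.

Observed statistics are compared with the ensemble through a standardized
effect size Z = (obs - mean)/sd and a two-sided empirical p-value with
add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import CommunityMatrix, ValidationError

__all__ = [
    "NullEnsemble",
    "NullModelResult",
    "null_binary_fixed_fixed",
    "null_abundance_swap",
    "null_test",
]


@dataclass
class NullEnsemble:
    """A set of randomized matrices satisfying a declared constraint set."""

    members: list  # list of np.ndarray, all same shape as observed
    constraints: str
    n_perm: int
    seed: int
    site_ids: list
    species_ids: list
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def as_matrices(self):
        for m in self.members:
            yield CommunityMatrix(
                pd.DataFrame(m, index=self.site_ids, columns=self.species_ids)
            )


@dataclass
class NullModelResult:
    """Observed statistic against a null ensemble."""

    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # nan when sd == 0
    p_value: float
    n_perm: int
    null_values: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
        }


# ---------------------------------------------------------------------------
# fixed-fixed binary chain


def _count_checkerboards(B: np.ndarray) -> int:
    """Number of 2x2 checkerboard submatrix units (swappable degrees of freedom)."""
    n = B.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = int(np.sum((B[i] == 1) & (B[j] == 0)))
            b = int(np.sum((B[i] == 0) & (B[j] == 1)))
            total += a * b
    return total


def _swap_chain(B: np.ndarray, n_attempts: int, rng: np.random.Generator) -> int:
    """Attempt ``n_attempts`` random checkerboard swaps in place.

    An attempt picks two distinct rows and two distinct columns and swaps
    when the 2x2 submatrix is a checkerboard.  Returns the number of
    successful swaps.  Counting the schedule in attempted (not successful)
    swaps keeps the chain aperiodic even on tiny matrices whose swap space
    would otherwise be traversed in lockstep.
    """
    n, m = B.shape
    rows = rng.integers(0, n, size=(n_attempts, 2))
    cols = rng.integers(0, m, size=(n_attempts, 2))
    successes = 0
    for t in range(n_attempts):
        i, j = rows[t]
        k, l = cols[t]
        if i == j or k == l:  # degenerate draw: a failed attempt, not a redraw
            continue
        a, b2, c, d = B[i, k], B[i, l], B[j, k], B[j, l]
        if (a == 1 and d == 1 and b2 == 0 and c == 0) or (
            a == 0 and d == 0 and b2 == 1 and c == 1
        ):
            B[i, k] = 1 - a
            B[i, l] = 1 - b2
            B[j, k] = 1 - c
            B[j, l] = 1 - d
            successes += 1
    return successes


def null_binary_fixed_fixed(
    matrix: CommunityMatrix,
    n_perm: int = 999,
    seed: int = 0,
    burnin_factor: int = 10,
    thin_factor: int = 1,
) -> NullEnsemble:
    """Fixed-fixed randomization of the presence/absence projection.

    Every ensemble member has exactly the observed row sums and column sums.
    The chain burns in for ``burnin_factor x fill`` attempted swaps and
    saves a member every ``thin_factor x fill`` attempted swaps.  A matrix
    with no swappable checkerboard yields an ensemble of identical copies
    and ``diagnostics['no_swaps_possible'] = True``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    B = matrix.incidence().to_numpy().copy()
    fill = int(B.sum())
    rng = np.random.default_rng(seed)
    diagnostics = {"algorithm": "checkerboard-swap", "fill": fill,
                   "burnin_attempts": burnin_factor * fill,
                   "thin_attempts": thin_factor * fill,
                   "attempts": 0, "successes": 0,
                   "rng": "numpy PCG64", "seed": seed}
    if _count_checkerboards(B) == 0:
        diagnostics["no_swaps_possible"] = True
        members = [B.copy() for _ in range(n_perm)]
        return NullEnsemble(members, "binary fixed-fixed", n_perm, seed,
                            matrix.site_ids, matrix.species_ids, diagnostics)
    diagnostics["successes"] += _swap_chain(B, burnin_factor * fill, rng)
    diagnostics["attempts"] += burnin_factor * fill
    members = []
    for _ in range(n_perm):
        diagnostics["successes"] += _swap_chain(B, thin_factor * fill, rng)
        diagnostics["attempts"] += thin_factor * fill
        members.append(B.copy())
    return NullEnsemble(members, "binary fixed-fixed", n_perm, seed,
                        matrix.site_ids, matrix.species_ids, diagnostics)


# ---------------------------------------------------------------------------
# abundance nulls


def _redistribute_rows(binary: np.ndarray, row_totals: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Place each row's total individuals on its occupied cells: one individual
    per occupied cell, remainder multinomially at equal odds."""
    out = np.zeros_like(binary, dtype=np.int64)
    for i in range(binary.shape[0]):
        occ = np.flatnonzero(binary[i])
        k = occ.size
        extra = int(row_totals[i]) - k
        counts = np.ones(k, dtype=np.int64)
        if extra > 0:
            counts += rng.multinomial(extra, np.full(k, 1.0 / k))
        out[i, occ] = counts
    return out


def _r2dtable(row: np.ndarray, col: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random contingency table with the given margins (hypergeometric fill)."""
    remaining = col.astype(np.int64).copy()
    out = np.zeros((row.size, col.size), dtype=np.int64)
    for i in range(row.size - 1):
        out[i] = rng.multivariate_hypergeometric(remaining, int(row[i]))
        remaining -= out[i]
    out[-1] = remaining
    return out


def _quasiswap_to_fill(M: np.ndarray, target_fill: int, rng: np.random.Generator,
                       max_iter: int) -> bool:
    """Margin-preserving 2x2 transfers that walk the number of occupied cells
    down to ``target_fill`` without ever increasing it or overshooting.

    A move picks two rows and two columns and shifts ``t`` individuals along
    one diagonal of the 2x2 submatrix (draining a cell when ``t`` equals its
    stock), which preserves all row and column totals.  Moves are accepted
    when the resulting change in fill is <= 0 and stays at or above the
    target.  Returns True once fill equals the target.
    """
    n, m = M.shape
    fill = int(np.count_nonzero(M))
    if fill < target_fill:
        return False
    it = 0
    block = 8192
    while fill != target_fill and it < max_iter:
        rows = rng.integers(0, n - 1, size=(block, 2))
        cols = rng.integers(0, m - 1, size=(block, 2))
        rows[:, 1] += rows[:, 1] >= rows[:, 0]
        cols[:, 1] += cols[:, 1] >= cols[:, 0]
        for idx in range(block):
            it += 1
            i, j = rows[idx]
            k, l = cols[idx]
            a, b, c, d = M[i, k], M[i, l], M[j, k], M[j, l]
            if a > 0 and d > 0:
                t = min(a, d)
                delta = int(b == 0) + int(c == 0) - int(t == a) - int(t == d)
                if delta <= 0 and fill + delta >= target_fill:
                    M[i, k] -= t
                    M[i, l] += t
                    M[j, k] += t
                    M[j, l] -= t
                    fill += delta
            elif b > 0 and c > 0:
                t = min(b, c)
                delta = int(a == 0) + int(d == 0) - int(t == b) - int(t == c)
                if delta <= 0 and fill + delta >= target_fill:
                    M[i, l] -= t
                    M[j, k] -= t
                    M[i, k] += t
                    M[j, l] += t
                    fill += delta
            if fill == target_fill or it >= max_iter:
                break
    return fill == target_fill


def null_abundance_swap(
    matrix: CommunityMatrix,
    n_perm: int = 999,
    seed: int = 0,
    variant: str = "incidence-fixed-rowsum",
    burnin_factor: int = 10,
    thin_factor: int = 1,
) -> NullEnsemble:
    """Randomize the count matrix under abundance-aware constraints.

    ``incidence-fixed-rowsum`` (default): fixed-fixed swaps on the incidence
    followed by a multinomial redistribution of each row's individuals over
    its occupied cells — conserves row richness, column occupancy counts and
    row totals.  ``quasiswap-count``: random margin-true tables reduced to
    the observed fill — conserves row and column abundance totals and fill.
    """
    counts = matrix.counts.to_numpy()
    row_tot = counts.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValidationError("row with zero individuals")
    rng = np.random.default_rng(seed)
    if variant == "incidence-fixed-rowsum":
        binary_ens = null_binary_fixed_fixed(
            matrix, n_perm=n_perm, seed=seed + 1,
            burnin_factor=burnin_factor, thin_factor=thin_factor,
        )
        members = [_redistribute_rows(b, row_tot, rng) for b in binary_ens.members]
        diag = dict(binary_ens.diagnostics)
        diag["redistribution"] = "multinomial, equal odds over occupied cells"
        return NullEnsemble(members, "abundance incidence-fixed-rowsum", n_perm, seed,
                            matrix.site_ids, matrix.species_ids, diag)
    if variant == "quasiswap-count":
        col_tot = counts.sum(axis=0)
        target_fill = int(np.count_nonzero(counts))
        members = []
        failures = 0
        for _ in range(n_perm):
            for _try in range(20):
                M = _r2dtable(row_tot, col_tot, rng)
                if _quasiswap_to_fill(M, target_fill, rng, max_iter=200 * target_fill + 10000):
                    members.append(M)
                    break
            else:
                failures += 1
                members.append(counts.copy())
        diag = {"algorithm": "r2dtable + quasiswap", "fill": target_fill,
                "fill_failures": failures, "rng": "numpy PCG64", "seed": seed}
        return NullEnsemble(members, "abundance quasiswap-count", n_perm, seed,
                            matrix.site_ids, matrix.species_ids, diag)
    raise ValidationError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# comparison


def null_test(
    statistic_fn: Callable[[CommunityMatrix], float],
    observed: CommunityMatrix,
    ensemble: NullEnsemble,
    name: str = "statistic",
) -> NullModelResult:
    """Evaluate a statistic on the observed matrix and every ensemble member.

    Z uses the sample standard deviation of the null values; the two-sided
    empirical p counts null deviations from the null mean at least as large
    as the observed one, with add-one correction.  When the null ensemble is
    degenerate (sd = 0) Z is reported as nan and p as 1.
    """
    if len(ensemble) < 2:
        raise ValidationError("need at least 2 ensemble members")
    obs = float(statistic_fn(observed))
    nulls = np.array([statistic_fn(m) for m in ensemble.as_matrices()], dtype=float)
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0:
        z = float("nan")
        p = 1.0
    else:
        z = (obs - mean) / sd
        p = (1.0 + np.sum(np.abs(nulls - mean) >= abs(obs - mean))) / (len(nulls) + 1.0)
    return NullModelResult(name, obs, mean, sd, z, float(p), len(ensemble), nulls)


def partition_statistic(
    component: str,
    hierarchy,
    D=None,
    convention: str = "mean-then-correct",
) -> Callable[[CommunityMatrix], float]:
    """Build a statistic function returning one partition component
    (``alpha1``, ``beta1``, ``alpha2``, ``beta2``, ``gamma`` or a
    ``prop_*`` variant) for use with :func:`null_test`."""
    from .partition import partition_two_level

    def stat(cm: CommunityMatrix) -> float:
        part = partition_two_level(cm, hierarchy, D=D, convention=convention)
        return float(getattr(part, component))

    stat.__name__ = f"partition_{component}"
    return stat
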