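"""Step-1 classification of multi-locus genotype cells into high/low risk.

Two classification rules are provided:

* the Kaplan-Meier median rule — a cell is high-risk when its KM median
  survival time is strictly below the overall KM median;
* the martingale-residual rule — a cell is high-risk when the sum of
  martingale residuals of its members (from a reduced Cox model containing
  only the adjusting covariates, or no covariates at all) is strictly
  positive, i.e. the cell saw more events than the reduced model predicts.

Ties at the boundary (cell median equal to the overall median; residual sum
exactly zero), empty cells, and cells whose KM curve never reaches 1/2 are
all labeled low-risk: such cells carry no evidence of elevated hazard.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, LocusCombination, SurvivalData, ValidationError
from .nonparametric import _HALF, km_median

__all__ = ["CellPartition", "CellLabeling", "partition_cells", "classify_km", "classify_mr"]


def cell_codes(geno_cols: np.ndarray) -> np.ndarray:
    """Flatten k genotype columns in {0,1,2} to a single cell index in [0, 3^k)."""
    k = geno_cols.shape[1]
    weights = 3 ** np.arange(k - 1, -1, -1)
    return geno_cols @ weights


def code_to_tuple(code: int, k: int) -> tuple[int, ...]:
    out = []
    for _ in range(k):
        out.append(code % 3)
        code //= 3
    return tuple(reversed(out))


@dataclass
class CellPartition:
    """Partition of individuals into the 3^k genotype cells of a combination."""

    combo: LocusCombination
    codes: np.ndarray  # per-individual cell index in [0, 3^k)

    @property
    def k(self) -> int:
        return self.combo.k

    @property
    def n_cells(self) -> int:
        return 3 ** self.k

    @property
    def cells(self) -> dict[tuple[int, ...], np.ndarray]:
        """Mapping genotype tuple -> member indices (all 3^k cells, possibly empty)."""
        return {
            tuple(t): np.flatnonzero(self.codes == cell_codes(np.array([t])))
            for t in product((0, 1, 2), repeat=self.k)
        }

    def counts(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_cells)


@dataclass
class CellLabeling:
    """High/low labels per genotype cell plus the per-individual indicator S."""

    combo: LocusCombination
    high: np.ndarray  # bool per cell index
    S: np.ndarray  # 1 for members of a high-risk cell
    cell_statistic: np.ndarray  # per-cell median (KM rule) or residual sum (MR rule)
    cell_counts: np.ndarray
    rule: str

    @property
    def cell_labels(self) -> dict[tuple[int, ...], str]:
        k = self.combo.k
        return {
            code_to_tuple(c, k): ("H" if self.high[c] else "L")
            for c in range(3 ** k)
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per genotype cell: tuple, member count, statistic, label."""
        k = self.combo.k
        return pd.DataFrame(
            {
                "cell": ["/".join(map(str, code_to_tuple(c, k))) for c in range(3 ** k)],
                "n": self.cell_counts,
                "statistic": self.cell_statistic,
                "label": np.where(self.high, "H", "L"),
            }
        )


def partition_cells(G: GenotypeMatrix, combo: LocusCombination) -> CellPartition:
    """Assign every individual to its multi-locus genotype cell."""
    combo.validate_for(G)
    return CellPartition(combo, cell_codes(G.values[:, combo.indices]))


def _km_cell_medians_sorted(
    codes_s: np.ndarray, time_s: np.ndarray, status_s: np.ndarray, n_cells: int
) -> np.ndarray:
    """KM median per genotype cell, vectorized across cells.

    Inputs are in time-ascending order; the product-limit curve of every cell
    is built in one segmented pass after a stable re-sort by cell index.
    """
    ord2 = np.argsort(codes_s, kind="stable")  # time order preserved within cell
    c2 = codes_s[ord2]
    t2 = time_s[ord2]
    d2 = status_s[ord2]
    m = c2.size
    new_cell = np.empty(m, dtype=bool)
    new_cell[0] = True
    new_cell[1:] = c2[1:] != c2[:-1]
    new_grp = new_cell.copy()
    new_grp[1:] |= t2[1:] != t2[:-1]
    gid = np.cumsum(new_grp) - 1
    g_start = np.flatnonzero(new_grp)
    g_events = np.bincount(gid, weights=d2)
    g_cell = c2[g_start]
    cell_start = np.flatnonzero(new_cell)
    cell_sizes = np.diff(np.append(cell_start, m))
    groups_per_cell = np.add.reduceat(new_grp, cell_start)
    # end position (exclusive) of the cell each group belongs to
    cell_end_of_grp = np.repeat(cell_start + cell_sizes, groups_per_cell)
    at_risk = (cell_end_of_grp - g_start).astype(float)
    with np.errstate(divide="ignore"):
        logfrac = np.log1p(-g_events / at_risk)
    # a group where everyone at risk dies gives log(0); keep it finite so the
    # segmented cumulative sum stays exact for the cells that follow
    logfrac[np.isneginf(logfrac)] = -1e3
    cs = np.cumsum(logfrac)
    cell_first_grp = gid[cell_start]
    offset = np.repeat(np.concatenate([[0.0], cs])[cell_first_grp], groups_per_cell)
    surv = np.exp(cs - offset)
    hit = (surv <= _HALF) & (g_events > 0)
    medians = np.full(n_cells, math.inf)
    idx = np.flatnonzero(hit)
    if idx.size:
        cells_hit, first = np.unique(g_cell[idx], return_index=True)
        medians[cells_hit] = t2[g_start[idx[first]]]
    return medians


def _km_labels_sorted(
    codes_s: np.ndarray,
    time_s: np.ndarray,
    status_s: np.ndarray,
    n_cells: int,
    overall_median: float,
) -> tuple[np.ndarray, np.ndarray]:
    """High-risk flags and cell medians given time-sorted arrays."""
    medians = _km_cell_medians_sorted(codes_s, time_s, status_s, n_cells)
    return medians < overall_median, medians


def classify_km(partition: CellPartition, surv: SurvivalData) -> CellLabeling:
    """Kaplan-Meier median rule: cell H iff its KM median < overall KM median."""
    overall = km_median(surv)
    if math.isinf(overall):
        raise ValidationError(
            "overall Kaplan-Meier median is undefined (curve never reaches 1/2); "
            "the KM-median classifier cannot be applied to this sample"
        )
    order = np.argsort(surv.time, kind="stable")
    high, medians = _km_labels_sorted(
        partition.codes[order],
        surv.time[order],
        surv.status[order],
        partition.n_cells,
        overall,
    )
    return CellLabeling(
        partition.combo,
        high,
        high[partition.codes].astype(np.int8),
        medians,
        partition.counts(),
        rule="km_median",
    )


def _mr_labels(codes: np.ndarray, residuals: np.ndarray, n_cells: int):
    sums = np.bincount(codes, weights=residuals, minlength=n_cells)
    return sums > 0, sums


def classify_mr(partition: CellPartition, residuals: np.ndarray) -> CellLabeling:
    """Martingale-residual rule: cell H iff its members' residuals sum > 0."""
    residuals = np.asarray(residuals, float)
    if residuals.shape != partition.codes.shape:
        raise ValidationError("residual vector length does not match partition")
    high, sums = _mr_labels(partition.codes, residuals, partition.n_cells)
    return CellLabeling(
        partition.combo,
        high,
        high[partition.codes].astype(np.int8),
        sums,
        partition.counts(),
        rule="martingale_residual",
    )
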