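"""Core data containers for genotype, survival, and covariate data.

All containers are lightweight, validated wrappers around numpy arrays.
Genotypes use additive minor-allele coding {0, 1, 2}; the classifiers in
this package are invariant to which homozygote is coded 0 versus 2, so
either convention may be used at load time.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "SurvivalData",
    "CovariateMatrix",
    "LocusCombination",
    "ValidationError",
    "align",
]


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def _as_unique_ids(ids: Sequence, what: str, n: int) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise ValidationError(f"{what}: expected {n} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"{what}: duplicate identifiers {sorted(set(dups))!r}")
    return ids


@dataclass
class GenotypeMatrix:
    """n x p matrix of additively coded SNP genotypes.

    Parameters
    ----------
    values : array-like of int, shape (n, p)
        Entries must be 0, 1 or 2 (minor-allele dosage).
    snp_ids : sequence of str, optional
        Unique SNP identifiers; defaults to ``SNP1..SNPp``.
    sample_ids : sequence of str, optional
        Unique sample identifiers; defaults to ``S1..Sn``.
    """

    values: np.ndarray
    snp_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError(f"genotype matrix must be 2-D, got shape {v.shape}")
        n, p = v.shape
        if n < 1 or p < 2:
            raise ValidationError(f"need n >= 1 samples and p >= 2 SNPs, got n={n}, p={p}")
        with np.errstate(invalid="ignore"):
            bad = ~np.isin(v, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype entry {v[i, j]!r} at row {i}, column {j} is not in {{0, 1, 2}}"
            )
        self.values = v.astype(np.int8)
        self.snp_ids = _as_unique_ids(
            self.snp_ids if self.snp_ids is not None else [f"SNP{k + 1}" for k in range(p)],
            "snp_ids", p,
        )
        self.sample_ids = _as_unique_ids(
            self.sample_ids
            if self.sample_ids is not None
            else [f"S{k + 1}" for k in range(n)],
            "sample_ids", n,
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def reorder(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[index], self.snp_ids, [self.sample_ids[i] for i in index]
        )


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: observed time and event status.

    ``status`` is 1 for an observed event (death) and 0 for censoring.
    Tied times are permitted; downstream Cox fits use the Breslow tie
    approximation.
    """

    time: np.ndarray
    status: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.status)
        if t.ndim != 1 or d.ndim != 1 or len(t) != len(d):
            raise ValidationError("time and status must be 1-D arrays of equal length")
        if not np.all(np.isfinite(t)):
            raise ValidationError("survival times must be finite")
        if np.any(t <= 0):
            i = int(np.argmax(t <= 0))
            raise ValidationError(f"survival time {t[i]} at row {i} is not > 0")
        if not np.isin(d, (0, 1)).all():
            i = int(np.argmax(~np.isin(d, (0, 1))))
            raise ValidationError(f"status {d[i]!r} at row {i} is not in {{0, 1}}")
        self.time = t
        self.status = d.astype(np.int8)
        if self.sample_ids is not None:
            self.sample_ids = _as_unique_ids(self.sample_ids, "sample_ids", len(t))

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def reorder(self, index: np.ndarray) -> "SurvivalData":
        ids = None if self.sample_ids is None else [self.sample_ids[i] for i in index]
        return SurvivalData(self.time[index], self.status[index], ids)


@dataclass
class CovariateMatrix:
    """n x q real-valued matrix of adjusting covariates (q = 0 allowed)."""

    values: np.ndarray
    names: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValidationError(f"covariate matrix must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            i, j = np.argwhere(~np.isfinite(v))[0]
            raise ValidationError(f"non-finite covariate at row {i}, column {j}")
        self.values = v
        q = v.shape[1]
        self.names = _as_unique_ids(
            self.names if self.names is not None else [f"Z{k + 1}" for k in range(q)],
            "names", q,
        )
        if self.sample_ids is not None:
            self.sample_ids = _as_unique_ids(self.sample_ids, "sample_ids", v.shape[0])

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(np.empty((n, 0)), [])

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def reorder(self, index: np.ndarray) -> "CovariateMatrix":
        ids = None if self.sample_ids is None else [self.sample_ids[i] for i in index]
        return CovariateMatrix(self.values[index], self.names, ids)


@dataclass(frozen=True)
class LocusCombination:
    """An ordered tuple of k >= 2 distinct SNP column indices (a multi-locus model)."""

    indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) < 2:
            raise ValidationError("a locus combination needs k >= 2 SNPs")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(f"indices must be strictly increasing, got {idx}")
        if idx[0] < 0:
            raise ValidationError(f"negative SNP index in {idx}")
        object.__setattr__(self, "indices", idx)

    @property
    def k(self) -> int:
        return len(self.indices)

    def validate_for(self, G: GenotypeMatrix) -> None:
        if self.indices[-1] >= G.n_snps:
            raise ValidationError(
                f"SNP index {self.indices[-1]} out of range for p={G.n_snps}"
            )

    def labels(self, G: GenotypeMatrix) -> tuple[str, ...]:
        return tuple(G.snp_ids[i] for i in self.indices)


def align(
    G: GenotypeMatrix,
    surv: SurvivalData,
    Z: CovariateMatrix | None = None,
) -> tuple[GenotypeMatrix, SurvivalData, CovariateMatrix]:
    """Align genotype, survival and covariate tables to a shared sample order.

    When both the survival (and covariate) tables carry sample ids, rows are
    reordered to the genotype matrix's sample order; otherwise equal lengths
    are required and row correspondence is assumed (with a warning).
    """
    n = G.n_samples
    if Z is None:
        Z = CovariateMatrix.empty(n)

    def _match(obj, what):
        if obj.sample_ids is not None:
            pos = {s: i for i, s in enumerate(obj.sample_ids)}
            missing = [s for s in G.sample_ids if s not in pos]
            if missing:
                raise ValidationError(
                    f"{what}: sample ids {missing[:5]!r} missing (of {len(missing)})"
                )
            return obj.reorder(np.array([pos[s] for s in G.sample_ids]))
        m = len(obj.time) if isinstance(obj, SurvivalData) else obj.n_samples
        if m != n:
            raise ValidationError(f"{what} has {m} samples but genotypes have {n}")
        warnings.warn(
            f"{what}: no sample ids; assuming row correspondence with genotypes",
            stacklevel=2,
        )
        return obj

    return G, _match(surv, "survival"), _match(Z, "covariates")
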