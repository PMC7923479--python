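"""Unified-model MDR scan for survival phenotypes.

The two-step procedure tests, for every k-SNP combination, whether membership
in the data-driven high-risk genotype cells is associated with the hazard:

1. genotype cells are labeled high/low risk (KM-median rule or
   martingale-residual rule, see :mod:`ummdr.classify`), defining a binary
   indicator S;
2. a Cox model lambda0(t) exp(alpha*S [+ gamma'Z] [+ theta'SNPs]) is fitted
   and the Wald statistic W = alpha_hat^2 / Var(alpha_hat) computed.

Because S is chosen by looking at the outcome, W is stochastically larger
than a central chi-square(1) under the null. The scan therefore permutes the
trait a small number of times (B, default 10), uses the mean permuted W,
mu_hat, to estimate a non-centrality parameter q_hat = max(0, mu_hat - 1),
and refers W to a noncentral chi-square(1, q_hat) for its p-value. No
cross-validation and no full permutation test are needed.

Variants
--------
KM-UMMDR   step 1 KM-median rule;                      step 2 fits S + Z
Cox-UMMDR  step 1 residuals from a covariate-free fit; step 2 fits S + Z
Cox2-UMMDR step 1 residuals from a Z-adjusted fit;     step 2 fits S only
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import _km_labels_sorted, _mr_labels, cell_codes
from .coxph import SurvivalOrder, _martingale_sorted, _newton
from .datamodel import (
    CovariateMatrix,
    GenotypeMatrix,
    LocusCombination,
    SurvivalData,
    ValidationError,
    align,
)
from .nonparametric import _km_median_sorted

__all__ = [
    "MethodVariant",
    "VARIANTS",
    "WaldResult",
    "NCPEstimate",
    "UMMDRScan",
    "UMMDRScanResults",
    "wald_statistic",
    "permutation_null_W",
    "estimate_ncp",
    "corrected_pvalue",
    "scan",
]


@dataclass(frozen=True)
class MethodVariant:
    name: str
    step1_rule: str  # km_median | mr_unadjusted | mr_adjusted
    step2_covariates: str  # S_plus_Z | S_only


VARIANTS = {
    "km-ummdr": MethodVariant("KM-UMMDR", "km_median", "S_plus_Z"),
    "cox-ummdr": MethodVariant("Cox-UMMDR", "mr_unadjusted", "S_plus_Z"),
    "cox2-ummdr": MethodVariant("Cox2-UMMDR", "mr_adjusted", "S_only"),
}


def get_variant(variant) -> MethodVariant:
    if isinstance(variant, MethodVariant):
        return variant
    key = str(variant).lower().replace("_", "-")
    if key not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    return VARIANTS[key]


@dataclass
class WaldResult:
    """Wald test of the high-risk indicator's coefficient in the step-2 Cox model."""

    alpha_hat: float
    var_alpha: float
    W: float
    degenerate: bool = False


@dataclass
class NCPEstimate:
    """Non-centrality estimate from the permutation-null mean of W."""

    mu_hat: float
    q_hat: float
    n_perms: int
    pooled: bool


def corrected_pvalue(W: float, q_hat: float) -> float:
    """Upper tail of the noncentral chi-square(1, q_hat) at W; q_hat = 0
    reduces to the central chi-square(1) tail."""
    if W < 0 or q_hat < 0:
        raise ValueError("W and q_hat must be non-negative")
    if q_hat == 0:
        return float(stats.chi2.sf(W, df=1))
    return float(stats.ncx2.sf(W, df=1, nc=q_hat))


def estimate_ncp(null_Ws, pooled: bool = True):
    """Estimate q_hat = max(0, mean(null W) - 1).

    ``null_Ws`` is a list of per-combination lists of permuted W values.
    Pooled: one common estimate from all values; otherwise one per list.
    """
    lists = [np.asarray(x, float) for x in null_Ws]
    if any(x.size == 0 for x in lists):
        raise ValueError("each null-W list must be non-empty")
    if pooled:
        allw = np.concatenate(lists)
        mu = float(allw.mean())
        est = NCPEstimate(mu, max(0.0, mu - 1.0), allw.size, True)
        return [est] * len(lists)
    return [
        NCPEstimate(float(x.mean()), max(0.0, float(x.mean()) - 1.0), x.size, False)
        for x in lists
    ]


def _wald_sorted(X_s: np.ndarray, so: SurvivalOrder,
                 beta0: np.ndarray | None = None) -> WaldResult:
    """Fit the step-2 Cox model on pre-sorted design and return the Wald result
    for the first column (the indicator S)."""
    if np.ptp(X_s[:, 0]) == 0:
        return WaldResult(0.0, math.nan, 0.0, degenerate=True)
    beta, cov, _, converged, _ = _newton(X_s, so, beta0=beta0)
    if not converged or not np.isfinite(cov[0, 0]) or cov[0, 0] <= 0:
        return WaldResult(0.0, math.nan, 0.0, degenerate=True)
    return WaldResult(float(beta[0]), float(cov[0, 0]), float(beta[0] ** 2 / cov[0, 0]))


def wald_statistic(
    surv: SurvivalData,
    S,
    Z: CovariateMatrix | None = None,
    variant="cox-ummdr",
    adjust_main=None,
) -> WaldResult:
    """Wald statistic W = alpha_hat^2 / Var(alpha_hat) for the indicator S.

    ``adjust_main`` optionally supplies the additive codes of the scanned
    SNPs (n x k array) to be appended to the step-2 design. A constant S or a
    non-converging fit yields a degenerate result with W = 0 rather than an
    exception, so exhaustive scans never abort on sparse cells.
    """
    variant = get_variant(variant)
    S = np.asarray(S, float)
    if not np.isin(S, (0, 1)).all():
        raise ValidationError("S must be a binary indicator")
    cols = [S[:, None]]
    if variant.step2_covariates == "S_plus_Z" and Z is not None and Z.n_covariates:
        cols.append(Z.values)
    if adjust_main is not None:
        am = np.asarray(adjust_main, float)
        cols.append(am[:, None] if am.ndim == 1 else am)
    X = np.hstack(cols)
    so = SurvivalOrder(surv.time, surv.status)
    return _wald_sorted(so.sort(X), so)


class _ScanEngine:
    """Shared per-dataset state for the exhaustive scan.

    Everything that depends only on (time, status, Z) is computed once: the
    sort order, the overall KM median, and the reduced-model martingale
    residuals. Jointly permuting (time, status, Z) against the genotype rows
    is then implemented as a row permutation of the sorted genotype matrix,
    which is exactly equivalent and lets all precomputed pieces be reused.
    """

    def __init__(self, G: GenotypeMatrix, surv: SurvivalData, Z: CovariateMatrix,
                 variant: MethodVariant, adjust_main: bool):
        if surv.n_events < 1:
            raise ValidationError("scan requires at least one observed event")
        self.variant = variant
        self.adjust_main = adjust_main
        self.so = SurvivalOrder(surv.time, surv.status)
        self.G_s = self.so.sort(G.values)
        self.Z_s = self.so.sort(Z.values) if Z.n_covariates else np.empty((len(surv), 0))
        self.n = len(surv)
        if variant.step1_rule == "km_median":
            self.overall_median = _km_median_sorted(self.so.time_s, self.so.status_s)
            if math.isinf(self.overall_median):
                raise ValidationError(
                    "overall Kaplan-Meier median undefined; KM-UMMDR not applicable"
                )
            self.resid_s = None
        else:
            if variant.step1_rule == "mr_adjusted" and self.Z_s.shape[1]:
                beta, _, _, converged, it = _newton(self.Z_s, self.so)
                if not converged:
                    raise ValidationError(
                        f"reduced Cox model (step 1) did not converge in {it} iterations"
                    )
                eta = self.Z_s @ beta
            else:
                eta = np.zeros(self.n)
            self.resid_s = _martingale_sorted(eta, self.so)
            self.overall_median = None
        # warm start for the step-2 fits: the adjusting covariates' coefficients
        # barely move when S is added, and the trait-Z relationship is preserved
        # under the joint permutation scheme, so one reduced fit serves them all
        self.beta_Z = None
        if variant.step2_covariates == "S_plus_Z" and self.Z_s.shape[1]:
            beta, _, _, converged, _ = _newton(self.Z_s, self.so)
            self.beta_Z = beta if converged else np.zeros(self.Z_s.shape[1])

    def pass_W(self, combos, perm: np.ndarray | None = None):
        """Ws and degeneracy flags for all combos on one (possibly permuted) pass."""
        G = self.G_s if perm is None else self.G_s[perm]
        n_combos = len(combos)
        Ws = np.zeros(n_combos)
        degen = np.zeros(n_combos, dtype=bool)
        use_Z = self.variant.step2_covariates == "S_plus_Z" and self.Z_s.shape[1]
        for i, combo in enumerate(combos):
            cols = G[:, combo]
            codes = cell_codes(cols)
            n_cells = 3 ** len(combo)
            if self.variant.step1_rule == "km_median":
                high, _ = _km_labels_sorted(
                    codes, self.so.time_s, self.so.status_s, n_cells, self.overall_median
                )
            else:
                high, _ = _mr_labels(codes, self.resid_s, n_cells)
            S = high[codes].astype(float)
            parts = [S[:, None]]
            beta0 = [0.0]
            if use_Z:
                parts.append(self.Z_s)
                beta0.extend(self.beta_Z)
            if self.adjust_main:
                parts.append(cols.astype(float))
                beta0.extend([0.0] * cols.shape[1])
            res = _wald_sorted(np.hstack(parts), self.so, beta0=np.array(beta0))
            Ws[i], degen[i] = res.W, res.degenerate
        return Ws, degen


class UMMDRScan:
    """Exhaustive k-way UM-MDR interaction scan (model object).

    Parameters
    ----------
    genotypes : GenotypeMatrix or array-like (n, p) in {0,1,2}
    survival : SurvivalData
    covariates : CovariateMatrix or array-like, optional
        Adjusting covariates Z (age, sex, principal components, ...).
    variant : {"km-ummdr", "cox-ummdr", "cox2-ummdr"} or MethodVariant
    order : int
        Interaction order k (2 or 3).
    adjust_main : bool
        Append the scanned SNPs' additive codes to each step-2 model, so the
        test targets the interaction beyond the SNPs' marginal effects.

    Examples
    --------
    >>> scan = UMMDRScan(G, surv, Z, variant="cox-ummdr", order=2)
    >>> res = scan.fit(B=10, seed=1)
    >>> res.table.head()
    """

    def __init__(self, genotypes, survival, covariates=None, variant="cox-ummdr",
                 order: int = 2, adjust_main: bool = False):
        if not isinstance(genotypes, GenotypeMatrix):
            genotypes = GenotypeMatrix(np.asarray(genotypes))
        if not isinstance(survival, SurvivalData):
            raise TypeError("survival must be a SurvivalData instance")
        if covariates is None:
            covariates = CovariateMatrix.empty(genotypes.n_samples)
        elif not isinstance(covariates, CovariateMatrix):
            covariates = CovariateMatrix(np.asarray(covariates, float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.G, self.surv, self.Z = align(genotypes, survival, covariates)
        if order < 2 or order > self.G.n_snps:
            raise ValidationError(f"order {order} invalid for p={self.G.n_snps}")
        self.variant = get_variant(variant)
        self.order = int(order)
        self.adjust_main = bool(adjust_main)
        self.combos = [
            LocusCombination(c) for c in _combinations(range(self.G.n_snps), self.order)
        ]

    @classmethod
    def from_dataframes(cls, genotypes: pd.DataFrame, survival: pd.DataFrame,
                        covariates: pd.DataFrame | None = None,
                        time_col: str = "time", status_col: str = "status", **kwargs):
        G = GenotypeMatrix(
            genotypes.to_numpy(), list(genotypes.columns),
            [str(i) for i in genotypes.index],
        )
        surv = SurvivalData(
            survival[time_col].to_numpy(float), survival[status_col].to_numpy(),
            [str(i) for i in survival.index],
        )
        Z = None
        if covariates is not None:
            Z = CovariateMatrix(
                covariates.to_numpy(float), list(covariates.columns),
                [str(i) for i in covariates.index],
            )
        return cls(G, surv, Z, **kwargs)

    def fit(self, B: int = 10, pooled: bool = True, seed=None, alpha_level: float = 0.05,
            correction: str = "bonferroni") -> "UMMDRScanResults":
        """Run the scan: observed W per combination, B trait permutations for
        the non-centrality estimate, corrected p-values and ranking.

        The B permutations are shared across combinations (each permuted
        trait is scanned against every combination), which is what pooling
        the permuted statistics into one mu_hat presumes.
        """
        if B < 1:
            raise ValueError("B must be >= 1")
        if correction not in ("none", "bonferroni"):
            raise ValueError("correction must be 'none' or 'bonferroni'")
        engine = _ScanEngine(self.G, self.surv, self.Z, self.variant, self.adjust_main)
        combo_idx = [c.indices for c in self.combos]
        W_obs, degen = engine.pass_W(combo_idx)
        rng = np.random.default_rng(seed)
        null_W = np.empty((B, len(combo_idx)))
        for b in range(B):
            null_W[b], _ = engine.pass_W(combo_idx, perm=rng.permutation(engine.n))
        ncps = estimate_ncp(list(null_W.T), pooled=pooled)
        q_hats = np.array([e.q_hat for e in ncps])
        pvals = np.array([corrected_pvalue(w, q) for w, q in zip(W_obs, q_hats)])
        pvals[degen] = 1.0
        m = len(combo_idx)
        p_adj = np.minimum(1.0, pvals * m) if correction == "bonferroni" else pvals.copy()
        # rank by descending W; ties broken lexicographically on SNP indices
        # (combos are generated in lexicographic order, so a stable sort does it)
        rank_order = np.argsort(-W_obs, kind="stable")
        ranks = np.empty(m, dtype=int)
        ranks[rank_order] = np.arange(1, m + 1)
        return UMMDRScanResults(
            model=self,
            W=W_obs,
            q_hat=q_hats,
            mu_hat=np.array([e.mu_hat for e in ncps]),
            p_value=pvals,
            p_adjusted=p_adj,
            rank=ranks,
            degenerate=degen,
            null_W=null_W,
            B=B,
            pooled=pooled,
            seed=seed,
            alpha_level=alpha_level,
            correction=correction,
        )


class UMMDRScanResults:
    """Results of :meth:`UMMDRScan.fit`.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per SNP combination: combo, W, mu_hat, q_hat, p_value,
        p_adjusted, rank, degenerate, significant.
    """

    def __init__(self, model, W, q_hat, mu_hat, p_value, p_adjusted, rank,
                 degenerate, null_W, B, pooled, seed, alpha_level, correction):
        self.model = model
        self.W = W
        self.q_hat = q_hat
        self.mu_hat = mu_hat
        self.p_value = p_value
        self.p_adjusted = p_adjusted
        self.rank = rank
        self.degenerate = degenerate
        self.null_W = null_W
        self.B = B
        self.pooled = pooled
        self.seed = seed
        self.alpha_level = alpha_level
        self.correction = correction
        names = [":".join(c.labels(model.G)) for c in model.combos]
        self.table = pd.DataFrame(
            {
                "combo": names,
                "snp_indices": [",".join(map(str, c.indices)) for c in model.combos],
                "W": W,
                "mu_hat": mu_hat,
                "q_hat": q_hat,
                "p_value": p_value,
                "p_adjusted": p_adjusted,
                "rank": rank,
                "degenerate": degenerate,
                "significant": p_adjusted < alpha_level,
            }
        )

    @property
    def best_combo(self) -> LocusCombination:
        """Top-ranked combination (largest W; lexicographic tie-break)."""
        return self.model.combos[int(np.argmax(self.rank == 1))]

    @property
    def adjusted_for(self) -> dict:
        """What each step-2 model adjusted for besides the indicator S."""
        m = self.model
        return {
            "covariates": list(m.Z.names)
            if m.variant.step2_covariates == "S_plus_Z"
            else [],
            "scanned_snp_main_effects": m.adjust_main,
        }

    @property
    def n_significant(self) -> int:
        return int((self.p_adjusted < self.alpha_level).sum())

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("rank").head(n)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"UM-MDR scan: {m.variant.name}, order k={m.order}",
            f"n={m.G.n_samples} samples, p={m.G.n_snps} SNPs, "
            f"{len(m.combos)} combinations, {m.Z.n_covariates} adjusting covariates",
            f"adjust_main={m.adjust_main}, B={self.B} permutations, "
            f"pooled NCP={self.pooled} (q_hat={self.q_hat[0]:.4f})"
            if self.pooled
            else f"adjust_main={m.adjust_main}, B={self.B} permutations, per-combo NCP",
            f"{self.n_significant} combination(s) significant at "
            f"{self.alpha_level} ({self.correction})",
            "",
            self.top(10).to_string(index=False),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        """Write the per-combination table as TSV plus a JSON config sidecar."""
        import json

        self.table.to_csv(path, sep="\t", index=False)
        sidecar = {
            "variant": self.model.variant.name,
            "order": self.model.order,
            "adjust_main": self.model.adjust_main,
            "B": self.B,
            "pooled": self.pooled,
            "seed": self.seed,
            "alpha_level": self.alpha_level,
            "correction": self.correction,
            "n_samples": self.model.G.n_samples,
            "n_snps": self.model.G.n_snps,
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def permutation_null_W(surv, G, Z, combo, variant="cox-ummdr", B: int = 10,
                       rng_seed=None, adjust_main: bool = False) -> np.ndarray:
    """B permutation-null Wald statistics for a single combination.

    The trait — the (time, status, covariate-row) triple — is jointly
    permuted against the genotype rows; both scan steps are recomputed on
    each permuted dataset. Degenerate permutations contribute W = 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(G, GenotypeMatrix):
        G = GenotypeMatrix(np.asarray(G))
    if Z is None:
        Z = CovariateMatrix.empty(G.n_samples)
    combo = combo if isinstance(combo, LocusCombination) else LocusCombination(tuple(combo))
    combo.validate_for(G)
    engine = _ScanEngine(G, surv, Z, get_variant(variant), adjust_main)
    rng = np.random.default_rng(rng_seed)
    out = np.empty(B)
    for b in range(B):
        W, _ = engine.pass_W([combo.indices], perm=rng.permutation(engine.n))
        out[b] = W[0]
    return out


def scan(G, surv, Z=None, k: int = 2, variant="cox-ummdr", B: int = 10,
         pooled: bool = True, adjust_main: bool = False, alpha_level: float = 0.05,
         multiple_testing: str = "bonferroni", seed=None) -> UMMDRScanResults:
    """Functional one-call interface to :class:`UMMDRScan`."""
    return UMMDRScan(
        G, surv, Z, variant=variant, order=k, adjust_main=adjust_main
    ).fit(B=B, pooled=pooled, seed=seed, alpha_level=alpha_level,
          correction=multiple_testing)
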