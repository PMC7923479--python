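"""Cross-validation-based MDR comparators for survival: KM-MDR and Cox-MDR.

These follow the original MDR template: within each cross-validation fold,
genotype cells are labeled high/low risk on the training part (KM-median
rule for KM-MDR; martingale-residual rule from a covariate-adjusted reduced
Cox model for Cox-MDR), each combination is scored by the training-set
log-rank statistic between the high- and low-risk groups, the fold's winner
is the top-scoring combination, and the overall best combination is the
modal fold winner. Significance of the best combination is assessed with a
full permutation test on the mean test-fold log-rank statistic — the
computational burden the unified-model scan is designed to avoid.

KM-MDR is nonparametric and ignores covariates entirely; Cox-MDR adjusts
for them in its classification step.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np

from .classify import _km_labels_sorted, _mr_labels, cell_codes
from .coxph import SurvivalOrder, _martingale_sorted, _newton
from .datamodel import (
    CovariateMatrix,
    GenotypeMatrix,
    LocusCombination,
    align,
)
from .nonparametric import _km_median_sorted, _logrank_sorted

__all__ = ["ClassicMDRScan", "CVResult", "cv_scan", "permutation_test"]

_CLASSIFIERS = ("km_median", "mr_adjusted")


@dataclass
class CVResult:
    """Cross-validation outcome of a classic MDR scan."""

    best_combo: LocusCombination
    cv_consistency: int
    mean_test_statistic: float
    n_folds: int
    permutation_p: float | None = None
    n_permutations: int = 0
    fold_winners: list[tuple[int, ...]] | None = None

    def summary(self) -> str:
        lines = [
            f"classic MDR cross-validation: best combo {self.best_combo.indices}",
            f"CV consistency {self.cv_consistency}/{self.n_folds}, "
            f"mean test log-rank {self.mean_test_statistic:.4f}",
        ]
        if self.permutation_p is not None:
            lines.append(
                f"permutation p = {self.permutation_p:.4g} "
                f"({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


def _stratified_folds(status: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold assignment stratified by event status (round-robin after shuffling)."""
    fold = np.empty(len(status), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(status == value)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


class _CVEngine:
    """One cross-validated scan over all combinations for a fixed fold split."""

    def __init__(self, Gv, time, status, Zv, combos, classifier, fold):
        self.Gv, self.time, self.status, self.Zv = Gv, time, status, Zv
        self.combos, self.classifier, self.fold = combos, classifier, fold
        self.n_folds = int(fold.max()) + 1
        self._prepare_folds()

    def _prepare_folds(self):
        self.train = []
        for f in range(self.n_folds):
            tr = self.fold != f
            te = ~tr
            so = SurvivalOrder(self.time[tr], self.status[tr])
            te_order = np.argsort(self.time[te], kind="stable")
            entry = {
                "tr": tr, "te": te, "so": so,
                "G_tr_s": so.sort(self.Gv[tr]),
                "G_te_s": self.Gv[te][te_order],
                "t_te_s": self.time[te][te_order],
                "d_te_s": self.status[te][te_order],
                "no_events": self.status[tr].sum() == 0,
            }
            if entry["no_events"]:
                warnings.warn(f"fold {f}: training part has no events; statistics are 0")
            elif self.classifier == "km_median":
                entry["overall_median"] = _km_median_sorted(so.time_s, so.status_s)
                if math.isinf(entry["overall_median"]):
                    entry["no_events"] = True  # median undefined: treat as uninformative
            else:
                Z_tr_s = so.sort(self.Zv[tr]) if self.Zv.shape[1] else None
                if Z_tr_s is not None:
                    beta, _, _, converged, _ = _newton(Z_tr_s, so)
                    eta = Z_tr_s @ beta if converged else np.zeros(tr.sum())
                else:
                    eta = np.zeros(tr.sum())
                entry["resid_s"] = _martingale_sorted(eta, so)
            self.train.append(entry)

    def _labels(self, entry, combo):
        """High-risk flags per cell, learned on the training part of a fold."""
        codes = cell_codes(entry["G_tr_s"][:, combo])
        n_cells = 3 ** len(combo)
        if self.classifier == "km_median":
            high, _ = _km_labels_sorted(
                codes, entry["so"].time_s, entry["so"].status_s,
                n_cells, entry["overall_median"],
            )
        else:
            high, _ = _mr_labels(codes, entry["resid_s"], n_cells)
        return high, codes

    def run(self):
        n_combos = len(self.combos)
        train_stat = np.zeros((self.n_folds, n_combos))
        label_cache = {}
        for f, entry in enumerate(self.train):
            if entry["no_events"]:
                continue
            so = entry["so"]
            for i, combo in enumerate(self.combos):
                high, codes = self._labels(entry, combo)
                label_cache[(f, i)] = high
                S_tr = high[codes]
                train_stat[f, i] = _logrank_sorted(so.time_s, so.status_s, S_tr)
        winners = np.argmax(train_stat, axis=1)  # ties -> lexicographically first

        def mean_test_stat(i):
            vals = []
            for f, entry in enumerate(self.train):
                if entry["no_events"]:
                    vals.append(0.0)
                    continue
                high = label_cache.get((f, i))
                if high is None:
                    high, _ = self._labels(entry, self.combos[i])
                codes_te = cell_codes(entry["G_te_s"][:, self.combos[i]])
                S_te = high[codes_te]
                vals.append(_logrank_sorted(entry["t_te_s"], entry["d_te_s"], S_te))
            return float(np.mean(vals))

        counts = np.bincount(winners, minlength=n_combos)
        top = counts.max()
        candidates = np.flatnonzero(counts == top)
        if len(candidates) == 1:
            best = int(candidates[0])
            best_mts = mean_test_stat(best)
        else:
            mts = {int(i): mean_test_stat(int(i)) for i in candidates}
            best = max(sorted(mts), key=lambda i: mts[i])
            best_mts = mts[best]
        return best, int(counts[best]), best_mts, [self.combos[w] for w in winners]


class ClassicMDRScan:
    """Classic cross-validated MDR scan (model object).

    Parameters
    ----------
    genotypes, survival, covariates
        As in :class:`ummdr.scan.UMMDRScan`. Covariates are used only by the
        ``mr_adjusted`` classifier (Cox-MDR); KM-MDR ignores them.
    classifier : {"km_median", "mr_adjusted"}
    order : int
        Interaction order k.
    """

    def __init__(self, genotypes, survival, covariates=None,
                 classifier: str = "km_median", order: int = 2):
        if classifier not in _CLASSIFIERS:
            raise ValueError(f"classifier must be one of {_CLASSIFIERS}")
        if not isinstance(genotypes, GenotypeMatrix):
            genotypes = GenotypeMatrix(np.asarray(genotypes))
        if covariates is None:
            covariates = CovariateMatrix.empty(genotypes.n_samples)
        elif not isinstance(covariates, CovariateMatrix):
            covariates = CovariateMatrix(np.asarray(covariates, float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.G, self.surv, self.Z = align(genotypes, survival, covariates)
        self.classifier = classifier
        self.order = int(order)
        self.combos = [
            tuple(c) for c in _combinations(range(self.G.n_snps), self.order)
        ]

    def fit(self, n_folds: int = 10, n_permutations: int = 0, seed=None) -> CVResult:
        """Cross-validated selection of the best combination, optionally with
        a permutation test on the mean test-fold log-rank statistic.

        The permutation p-value uses the rank construction
        p = (1 + #{permuted >= observed}) / (M + 1).
        """
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        rng = np.random.default_rng(seed)
        Gv = self.G.values
        time, status, Zv = self.surv.time, self.surv.status, self.Z.values

        def one_run(Gmat, rng_local):
            fold = _stratified_folds(status, n_folds, rng_local)
            eng = _CVEngine(Gmat, time, status, Zv, self.combos, self.classifier, fold)
            return eng.run()

        best, consistency, mts, winners = one_run(Gv, rng)
        perm_p = None
        if n_permutations > 0:
            # permute the trait jointly against genotype rows == permute G rows
            exceed = 0
            for _ in range(n_permutations):
                Gp = Gv[rng.permutation(len(time))]
                _, _, mts_p, _ = one_run(Gp, rng)
                if mts_p >= mts:
                    exceed += 1
            perm_p = (1 + exceed) / (n_permutations + 1)
        return CVResult(
            LocusCombination(self.combos[best]),
            consistency,
            mts,
            n_folds,
            perm_p,
            n_permutations,
            fold_winners=winners,
        )


def cv_scan(G, surv, Z=None, k: int = 2, classifier: str = "km_median",
            n_folds: int = 10, rng_seed=None) -> CVResult:
    """Functional interface to :meth:`ClassicMDRScan.fit` without permutations."""
    return ClassicMDRScan(G, surv, Z, classifier=classifier, order=k).fit(
        n_folds=n_folds, seed=rng_seed
    )


def permutation_test(G, surv, Z=None, k: int = 2, classifier: str = "km_median",
                     n_folds: int = 10, M: int = 99, rng_seed=None) -> float:
    """Permutation p-value of the cross-validated best combination."""
    if M < 1:
        raise ValueError("M must be >= 1")
    res = ClassicMDRScan(G, surv, Z, classifier=classifier, order=k).fit(
        n_folds=n_folds, n_permutations=M, seed=rng_seed
    )
    return res.permutation_p
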