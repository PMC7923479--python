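"""Synthetic-data engine and simulation-study harness.

Data are generated the way the epistasis-detection literature does it:

* genotypes — unlinked diallelic loci in Hardy-Weinberg equilibrium, minor
  allele dosage ~ Binomial(2, MAF), loci independent (linkage equilibrium);
* a penetrance table f over the 3^k genotype cells of the causal loci gives
  P(high-risk | cell); each subject's latent risk indicator x is Bernoulli(f);
* survival times come from a Cox model with Weibull(shape 5, scale 2)
  baseline and linear predictor alpha*x + gamma*z + delta*SNP_main, with
  z ~ N(0,1) a single adjusting covariate;
* censoring times are U(0, c), with c calibrated numerically so the expected
  censoring fraction hits a target.

Penetrance tables for 2-way models are generated by constrained random
search: cell penetrances with (near-)equal marginal penetrances per SNP
("pure" epistasis, no marginal effects) rescaled to an exact target
heritability h^2 = sum_cells P(cell) (f_cell - fbar)^2 / (fbar (1 - fbar)).
A fixed 3-way table with six cells at penetrance 0.2 (the classic
checkerboard-style model of the MDR literature) is also provided.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .classic import ClassicMDRScan
from .classify import cell_codes
from .datamodel import CovariateMatrix, GenotypeMatrix, SurvivalData, ValidationError
from .scan import UMMDRScan, VARIANTS

__all__ = [
    "PenetranceModel",
    "SimulationConfig",
    "SimulatedDataset",
    "hwe_probs",
    "generate_genotypes",
    "heritability_of",
    "generate_penetrance",
    "build_ritchie_3way",
    "assign_risk",
    "generate_survival",
    "calibrate_censoring",
    "generate_dataset",
    "run_type1_study",
    "run_power_study",
]


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (dosage 0, 1, 2) at one locus."""
    if not 0 < maf <= 0.5:
        raise ValidationError(f"MAF must be in (0, 0.5], got {maf}")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])


@dataclass
class PenetranceModel:
    """3^k table of P(high risk | genotype cell) with its MAFs and heritability.

    ``table`` is flat in lexicographic cell order (first locus slowest), the
    same order as :func:`ummdr.classify.cell_codes` produces.
    """

    k: int
    table: np.ndarray
    mafs: tuple[float, ...]
    heritability: float = field(init=False)

    def __post_init__(self):
        t = np.asarray(self.table, float).ravel()
        if t.size != 3 ** self.k:
            raise ValidationError(f"table must have 3^{self.k} cells, got {t.size}")
        if np.any((t < 0) | (t > 1)):
            raise ValidationError("penetrances must lie in [0, 1]")
        if len(self.mafs) != self.k:
            raise ValidationError("need one MAF per locus")
        self.table = t
        self.mafs = tuple(float(m) for m in self.mafs)
        try:
            self.heritability = heritability_of(self)
        except ValidationError:
            # degenerate table (mean penetrance 0 or 1): usable for risk
            # assignment but carries no defined heritability
            self.heritability = math.nan

    @property
    def cell_probs(self) -> np.ndarray:
        """HWE probability of each genotype cell (sums to 1)."""
        probs = hwe_probs(self.mafs[0])
        for m in self.mafs[1:]:
            probs = np.multiply.outer(probs, hwe_probs(m)).ravel()
        return probs

    @property
    def mean_penetrance(self) -> float:
        return float(self.cell_probs @ self.table)

    def marginal_penetrances(self, locus: int) -> np.ndarray:
        """P(high risk | genotype of one locus): equal across genotypes for
        a pure-epistasis model."""
        shape = (3,) * self.k
        f = self.table.reshape(shape)
        p = self.cell_probs.reshape(shape)
        other = tuple(i for i in range(self.k) if i != locus)
        num = (f * p).sum(axis=other)
        den = p.sum(axis=other)
        return num / den


def heritability_of(model: PenetranceModel) -> float:
    """Penetrance-based heritability: Var(f) / (fbar (1 - fbar)) with cells
    weighted by their HWE probabilities."""
    p = model.cell_probs
    f = model.table
    fbar = float(p @ f)
    if fbar <= 0 or fbar >= 1:
        raise ValidationError(f"mean penetrance {fbar} leaves heritability undefined")
    return float(p @ (f - fbar) ** 2 / (fbar * (1 - fbar)))


def generate_genotypes(n: int, mafs, rng) -> GenotypeMatrix:
    """n individuals at len(mafs) unlinked HWE loci, additive coding."""
    mafs = np.atleast_1d(np.asarray(mafs, float))
    for m in mafs:
        if not 0 < m <= 0.5:
            raise ValidationError(f"MAF must be in (0, 0.5], got {m}")
    values = rng.binomial(2, mafs, size=(n, len(mafs)))
    return GenotypeMatrix(values)


def generate_penetrance(maf: float, target_h2: float, rng, k: int = 2,
                        max_iter: int = 500) -> PenetranceModel:
    """Random pure-epistasis penetrance table at an exact target heritability.

    Random tables are projected onto the equal-marginal-penetrance manifold
    (bounded least squares), then deviations from the mean penetrance are
    rescaled so the realized heritability equals ``target_h2`` to 1e-6.
    """
    if not 0 < target_h2 < 1:
        raise ValidationError("target heritability must be in (0, 1)")
    if k != 2:
        raise NotImplementedError("random table generation is implemented for k=2")
    p1 = hwe_probs(maf)
    p2 = hwe_probs(maf)
    cellp = np.multiply.outer(p1, p2).ravel()
    # deviations d with zero marginal penetrance per locus genotype: A d = 0,
    # where A stacks the HWE-weighted row and column sums of the 3x3 table.
    # Any f = fbar + c*d then has all marginal penetrances exactly fbar.
    A = np.zeros((6, 9))
    for i in range(3):
        for j in range(3):
            A[i, 3 * i + j] = p2[j]
            A[3 + j, 3 * i + j] = p1[i]
    basis = null_space(A)  # 4-dimensional for k=2
    fbar_grid = np.linspace(0.15, 0.85, 15)
    for _ in range(max_iter):
        d = basis @ rng.standard_normal(basis.shape[1])
        var_d = float(cellp @ d ** 2)  # E_p[d] = 0 by construction
        if var_d < 1e-10:
            continue
        for fbar in rng.permutation(fbar_grid):
            c = math.sqrt(target_h2 * fbar * (1 - fbar) / var_d)
            f = fbar + c * d
            if f.min() < 0 or f.max() > 1:
                continue
            model = PenetranceModel(k, f, (maf,) * k)
            if abs(model.heritability - target_h2) <= 1e-6:
                return model
    raise ValidationError(
        f"no penetrance table found for MAF={maf}, h2={target_h2} in "
        f"{max_iter} attempts; try a smaller heritability"
    )


# six cells at penetrance 0.2 (all cells with total minor-allele dosage 4),
# zero elsewhere: AAbbcc, AaBbcc, aaBBcc, aaBbCc, AabbCc, aabbCC
_RITCHIE_CELLS = [(0, 2, 2), (1, 1, 2), (2, 0, 2), (2, 1, 1), (1, 2, 1), (2, 2, 0)]


def build_ritchie_3way(mafs=(0.5, 0.5, 0.5)) -> PenetranceModel:
    """The classic three-locus epistasis model: penetrance 0.2 in six specific
    cells, 0 in the remaining 21 — no marginal effects at allele frequency 1/2."""
    table = np.zeros(27)
    for cell in _RITCHIE_CELLS:
        table[int(cell_codes(np.array([cell]))[0])] = 0.2
    return PenetranceModel(3, table, tuple(mafs))


def assign_risk(G: GenotypeMatrix, combo, model: PenetranceModel, rng) -> np.ndarray:
    """Latent high-risk indicator x_i ~ Bernoulli(f at i's genotype cell)."""
    combo = tuple(combo)
    if len(combo) != model.k:
        raise ValidationError(f"combo has {len(combo)} loci, model expects {model.k}")
    codes = cell_codes(G.values[:, combo])
    return rng.binomial(1, model.table[codes]).astype(np.int8)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated design cell.

    Defaults follow the standard simulation design for this method family:
    400 patients, 10 unlinked SNPs with the first two causal, effect of the
    latent risk indicator alpha = 0.8, covariate effect gamma = 0.8, optional
    SNP main effect delta (Scenario II), Weibull(5, 2) baseline hazard and
    uniform censoring calibrated to the target censoring fraction.
    """

    n: int = 400
    p: int = 10
    causal_combo: tuple[int, ...] = (0, 1)
    maf: float = 0.2
    heritability: float = 0.1
    alpha: float = 0.8
    gamma: float = 0.8
    delta: float = 0.0
    snp_main_index: int | None = None
    weibull_shape: float = 5.0
    weibull_scale: float = 2.0
    target_cf: float = 0.1
    censor_upper: float | None = None  # c of U(0, c); calibrated when None
    n_replicates: int = 100
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0 <= self.target_cf < 1:
            raise ValidationError("target_cf must be in [0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValidationError("Weibull parameters must be positive")
        self.causal_combo = tuple(self.causal_combo)


@dataclass
class SimulatedDataset:
    G: GenotypeMatrix
    surv: SurvivalData
    Z: CovariateMatrix
    x: np.ndarray
    config: SimulationConfig

    @property
    def censoring_fraction(self) -> float:
        return float(1 - self.surv.status.mean())


def generate_survival(x, z, snp_main, config: SimulationConfig, rng) -> SurvivalData:
    """Survival under lambda(t) = lambda0(t) exp(alpha x + gamma z + delta SNP),
    Weibull baseline Lambda0(t) = (t / scale)^shape, censoring U(0, c).

    With Lambda0 Weibull, inverse-transform sampling gives
    T = scale * (-log U * exp(-eta))^(1/shape).
    """
    x = np.asarray(x, float)
    n = len(x)
    eta = config.alpha * x
    if z is not None:
        eta = eta + config.gamma * np.asarray(z, float)
    if snp_main is not None:
        eta = eta + config.delta * np.asarray(snp_main, float)
    u = rng.uniform(size=n)
    T = config.weibull_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / config.weibull_shape)
    if config.target_cf == 0 or config.censor_upper is None:
        return SurvivalData(T, np.ones(n, dtype=np.int8))
    C = rng.uniform(0, config.censor_upper, size=n)
    time = np.minimum(T, C)
    status = (T <= C).astype(np.int8)
    return SurvivalData(time, status)


def _pilot_event_times(config: SimulationConfig, model: PenetranceModel | None,
                      rng, n_pilot: int) -> np.ndarray:
    """Uncensored event times from the config's generative model."""
    cfg = replace(config, target_cf=0.0, censor_upper=None)
    k = len(cfg.causal_combo)
    G = generate_genotypes(n_pilot, [cfg.maf] * cfg.p, rng)
    if model is not None and cfg.alpha != 0:
        x = assign_risk(G, cfg.causal_combo, model, rng)
    else:
        x = np.zeros(n_pilot)
    z = rng.standard_normal(n_pilot)
    snp = G.values[:, cfg.snp_main_index] if cfg.snp_main_index is not None else None
    return generate_survival(x, z, snp, cfg, rng).time


def calibrate_censoring(config: SimulationConfig, rng, n_pilot: int = 20000,
                        model: PenetranceModel | None = None) -> float:
    """Upper bound c of the U(0, c) censoring law hitting the target censoring
    fraction.

    With C ~ U(0, c), P(censored | T) = min(T, c)/c, so the expected censoring
    fraction is E[min(T, c)]/c — smooth and decreasing in c. It is estimated
    on a pilot sample of uncensored event times and solved by bisection.
    """
    if not 0 < config.target_cf < 1:
        raise ValidationError("calibration needs target_cf in (0, 1)")
    T = _pilot_event_times(config, model, rng, n_pilot)

    def cf(c):
        return float(np.minimum(T, c).mean() / c)

    lo, hi = 1e-9, float(T.max()) * 2
    for _ in range(200):
        if cf(hi) < config.target_cf:
            break
        hi *= 2
    else:
        raise ValidationError("censoring calibration failed to bracket the target")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if cf(mid) > config.target_cf:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: SimulationConfig, model: PenetranceModel | None,
                     rng) -> SimulatedDataset:
    """One full dataset: genotypes, latent risk, covariate, survival.

    ``model`` may be None for a null design (survival independent of G).
    ``config.censor_upper`` must already be calibrated when ``target_cf > 0``.
    """
    if config.target_cf > 0 and config.censor_upper is None:
        raise ValidationError("censor_upper not set; run calibrate_censoring first")
    G = generate_genotypes(config.n, [config.maf] * config.p, rng)
    if model is not None and config.alpha != 0:
        x = assign_risk(G, config.causal_combo, model, rng)
    else:
        x = np.zeros(config.n, dtype=np.int8)
    z = rng.standard_normal(config.n)
    snp = G.values[:, config.snp_main_index] if config.snp_main_index is not None else None
    surv = generate_survival(x, z, snp, config, rng)
    return SimulatedDataset(G, surv, CovariateMatrix(z[:, None], ["z"]), x, config)


def _method_hits(dataset: SimulatedDataset, method: str, causal: tuple[int, ...],
                 k: int, B: int, alpha_level: float, adjust_main: bool,
                 n_folds: int, n_permutations: int, seed) -> dict:
    """Per-dataset outcome of one method: which combo won and was it significant."""
    if method in VARIANTS:
        res = UMMDRScan(
            dataset.G, dataset.surv, dataset.Z, variant=method, order=k,
            adjust_main=adjust_main,
        ).fit(B=B, pooled=True, seed=seed, correction="none")
        best = res.best_combo.indices
        i = res.model.combos.index(res.best_combo)
        sig = bool(res.p_value[i] < alpha_level)
    elif method in ("km-mdr", "cox-mdr"):
        classifier = "km_median" if method == "km-mdr" else "mr_adjusted"
        res = ClassicMDRScan(
            dataset.G, dataset.surv, dataset.Z, classifier=classifier, order=k
        ).fit(n_folds=n_folds, n_permutations=n_permutations, seed=seed)
        best = res.best_combo.indices
        sig = True if res.permutation_p is None else res.permutation_p <= alpha_level
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"best": best, "selected": best == tuple(causal), "significant": sig}


def run_type1_study(maf: float, cf: float, methods=("cox2-ummdr", "km-ummdr"),
                    n_datasets: int = 200, n: int = 400, p: int = 8, k: int = 2,
                    B: int = 10, gamma: float = 0.8, alpha_level: float = 0.05,
                    seed=None) -> pd.DataFrame:
    """Per-pair Type I error of the scan under the global null (no genotype
    effect on survival; the covariate effect is retained).

    For each method, every combination's rate of being simultaneously
    top-ranked by W and significant at ``alpha_level`` (uncorrected) is
    recorded; the returned table reports, per method, the per-combination
    average of that top-and-significant rate together with the selection-only
    rate and its nominal value 1/C(p, k).
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    cfg = SimulationConfig(n=n, p=p, maf=maf, alpha=0.0, gamma=gamma, target_cf=cf)
    rng_cal = np.random.default_rng(ss.spawn(1)[0])
    if cf > 0:
        cfg.censor_upper = calibrate_censoring(cfg, rng_cal)
    from math import comb

    n_combos = comb(p, k)
    counts = {m: {"top": np.zeros(n_combos), "top_sig": np.zeros(n_combos),
                  "sig": np.zeros(n_combos)} for m in methods}
    child_seeds = ss.spawn(n_datasets)
    for d in range(n_datasets):
        rng = np.random.default_rng(child_seeds[d])
        data = generate_dataset(cfg, None, rng)
        scan_seed = int(rng.integers(2 ** 31))
        for m in methods:
            res = UMMDRScan(data.G, data.surv, data.Z, variant=m, order=k).fit(
                B=B, pooled=True, seed=scan_seed, correction="none"
            )
            top = int(np.argmax(res.rank == 1))
            sig = res.p_value < alpha_level
            counts[m]["top"][top] += 1
            counts[m]["sig"] += sig
            if sig[top]:
                counts[m]["top_sig"][top] += 1
    rows = []
    for m in methods:
        rows.append(
            {
                "method": VARIANTS[m].name if m in VARIANTS else m,
                "maf": maf,
                "cf": cf,
                "n_datasets": n_datasets,
                "n_combos": n_combos,
                "nominal_selection_rate": 1.0 / n_combos,
                "selection_rate": counts[m]["top"].mean() / n_datasets,
                "type1_top_sig": counts[m]["top_sig"].mean() / n_datasets,
                "significance_rate": counts[m]["sig"].mean() / n_datasets,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["per_pair"] = {m: {kk: v / n_datasets for kk, v in c.items()}
                            for m, c in counts.items()}
    return df


def run_power_study(maf: float = 0.2, heritability: float = 0.1, cf: float = 0.1,
                    methods=("km-ummdr", "cox-ummdr", "cox2-ummdr"),
                    scenario: str = "I", adjust_main: bool = False,
                    n_datasets: int = 100, n_models: int = 5, n: int = 400,
                    p: int = 10, k: int = 2, B: int = 10, alpha: float = 0.8,
                    gamma: float = 0.8, delta: float = 0.5,
                    alpha_level: float = 0.05, n_folds: int = 10,
                    n_permutations: int = 99, seed=None,
                    model: PenetranceModel | None = None) -> pd.DataFrame:
    """Power of the five methods under planted epistasis.

    Scenario I: survival depends on the latent risk x and the covariate z.
    Scenario II: an additional marginal main effect delta of a non-causal SNP
    (``SNP3`` for 2-way designs) enters the hazard; ``adjust_main`` controls
    whether each scanned combination's SNP dosages are appended to the step-2
    model (UM-MDR variants).

    Power is the fraction of datasets in which the causal combination is both
    top-ranked and significant at ``alpha_level`` (UM-MDR: corrected p,
    uncorrected across combos; classic comparators: permutation p). The
    selection-only fraction is reported alongside.
    """
    if scenario not in ("I", "II"):
        raise ValueError("scenario must be 'I' or 'II'")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    root_rng = np.random.default_rng(ss.spawn(1)[0])
    causal = tuple(range(k))
    snp_main = k if scenario == "II" else None  # first non-causal SNP
    cfg = SimulationConfig(
        n=n, p=p, causal_combo=causal, maf=maf, heritability=heritability,
        alpha=alpha, gamma=gamma, delta=delta if scenario == "II" else 0.0,
        snp_main_index=snp_main, target_cf=cf,
    )
    if model is not None:
        models = [model]
    else:
        models = [generate_penetrance(maf, heritability, root_rng, k=k)
                  for _ in range(n_models)]
    rows = []
    for mi, pen in enumerate(models):
        cfg_m = replace(cfg)
        if cf > 0:
            cfg_m.censor_upper = calibrate_censoring(cfg_m, root_rng, model=pen)
        hits = {m: {"selected": 0, "power": 0} for m in methods}
        child_seeds = ss.spawn(n_datasets)
        for d in range(n_datasets):
            rng = np.random.default_rng(child_seeds[d])
            data = generate_dataset(cfg_m, pen, rng)
            mseed = int(rng.integers(2 ** 31))
            for m in methods:
                out = _method_hits(
                    data, m, causal, k, B, alpha_level, adjust_main,
                    n_folds, n_permutations, mseed,
                )
                hits[m]["selected"] += out["selected"]
                hits[m]["power"] += out["selected"] and out["significant"]
        for m in methods:
            rows.append(
                {
                    "model": mi,
                    "maf": maf,
                    "heritability": pen.heritability,
                    "cf": cf,
                    "scenario": scenario,
                    "adjust_main": adjust_main,
                    "method": VARIANTS[m].name if m in VARIANTS else m.upper(),
                    "n_datasets": n_datasets,
                    "selection_rate": hits[m]["selected"] / n_datasets,
                    "power": hits[m]["power"] / n_datasets,
                }
            )
    return pd.DataFrame(rows)
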