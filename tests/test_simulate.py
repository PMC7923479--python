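import math

import numpy as np
import pytest

import ummdr
from ummdr import (
    PenetranceModel,
    SimulationConfig,
    ValidationError,
    assign_risk,
    build_ritchie_3way,
    calibrate_censoring,
    generate_dataset,
    generate_genotypes,
    generate_penetrance,
    generate_survival,
    heritability_of,
    hwe_probs,
)


class TestGenotypes:
    def test_hwe_frequencies_half(self):
        rng = np.random.default_rng(0)
        G = generate_genotypes(20000, [0.5, 0.5], rng)
        freq = np.bincount(G.values[:, 0], minlength=3) / 20000
        np.testing.assert_allclose(freq, [0.25, 0.5, 0.25], atol=0.02)

    def test_allele_frequency_within_3se(self):
        rng = np.random.default_rng(1)
        n = 100_000
        G = generate_genotypes(n, [0.2, 0.2], rng)
        p_hat = G.values[:, 0].mean() / 2
        se = math.sqrt(0.2 * 0.8 / (2 * n))
        assert abs(p_hat - 0.2) < 3 * se

    def test_deterministic(self):
        a = generate_genotypes(50, [0.3, 0.4], np.random.default_rng(5))
        b = generate_genotypes(50, [0.3, 0.4], np.random.default_rng(5))
        np.testing.assert_array_equal(a.values, b.values)


class TestHeritability:
    def test_constant_table_zero(self):
        m = PenetranceModel(2, np.full(9, 0.3), (0.2, 0.2))
        assert heritability_of(m) == pytest.approx(0.0)

    def test_deterministic_penetrance_is_one(self):
        # f in {0,1}: Var(f) = fbar(1-fbar) exactly
        table = np.zeros(9)
        table[[0, 4, 8]] = 1.0
        m = PenetranceModel(2, table, (0.5, 0.5))
        assert heritability_of(m) == pytest.approx(1.0)

    def test_hand_built_table_direct_summation(self):
        table = np.array([0.1, 0.2, 0.3, 0.2, 0.1, 0.0, 0.3, 0.3, 0.1])
        mafs = (0.3, 0.4)
        m = PenetranceModel(2, table, mafs)
        p = np.multiply.outer(hwe_probs(0.3), hwe_probs(0.4)).ravel()
        fbar = sum(pi * fi for pi, fi in zip(p, table))
        var = sum(pi * (fi - fbar) ** 2 for pi, fi in zip(p, table))
        assert heritability_of(m) == pytest.approx(var / (fbar * (1 - fbar)))


class TestGeneratePenetrance:
    @pytest.mark.parametrize("maf,h2", [(0.2, 0.1), (0.4, 0.1), (0.2, 0.4), (0.4, 0.01)])
    def test_hits_target_exactly(self, maf, h2):
        rng = np.random.default_rng(0)
        m = generate_penetrance(maf, h2, rng)
        assert abs(m.heritability - h2) <= 1e-6
        assert m.table.min() >= 0 and m.table.max() <= 1

    def test_marginal_penetrances_flat(self):
        rng = np.random.default_rng(1)
        m = generate_penetrance(0.2, 0.2, rng)
        for locus in (0, 1):
            marg = m.marginal_penetrances(locus)
            assert np.ptp(marg) <= 1e-6 * max(m.mean_penetrance, 1e-12) + 1e-7

    def test_distinct_models_same_conditions(self):
        m1 = generate_penetrance(0.2, 0.1, np.random.default_rng(2))
        m2 = generate_penetrance(0.2, 0.1, np.random.default_rng(3))
        assert not np.allclose(m1.table, m2.table)
        assert m1.heritability == pytest.approx(m2.heritability, abs=1e-6)


class TestRitchieModel:
    def test_six_listed_cells(self):
        m = build_ritchie_3way()
        table = m.table.reshape(3, 3, 3)
        assert table[0, 2, 2] == 0.2  # AAbbcc
        assert table[1, 1, 2] == 0.2  # AaBbcc
        assert table[2, 0, 2] == 0.2  # aaBBcc
        assert table[2, 1, 1] == 0.2  # aaBbCc
        assert table[1, 2, 1] == 0.2  # AabbCc
        assert table[2, 2, 0] == 0.2  # aabbCC
        assert table[0, 0, 0] == 0.0  # AABBCC
        assert (m.table > 0).sum() == 6

    def test_marginal_penetrances_hand_computed_at_half(self):
        # locus 1, allele frequency 1/2 (genotype probs 1/4, 1/2, 1/4):
        # genotype 0 -> only cell (0,2,2): 1/4*1/4*0.2 / 1 = 0.0125
        # genotype 1 -> cells (1,1,2),(1,2,1): (1/2*1/4 + 1/4*1/2)*0.2 = 0.05
        # genotype 2 -> cells (2,0,2),(2,1,1),(2,2,0):
        #               (1/4*1/4 + 1/2*1/2 + 1/4*1/4)*0.2 = 0.075
        m = build_ritchie_3way()
        np.testing.assert_allclose(
            m.marginal_penetrances(0), [0.0125, 0.05, 0.075], atol=1e-12
        )


class TestAssignRisk:
    def test_degenerate_tables(self):
        rng = np.random.default_rng(0)
        G = generate_genotypes(50, [0.3, 0.3], rng)
        zero = PenetranceModel(2, np.zeros(9), (0.3, 0.3))
        ones = PenetranceModel(2, np.ones(9), (0.3, 0.3))
        with pytest.raises(ValidationError):
            heritability_of(zero)  # fbar = 0 undefined
        assert assign_risk(G, (0, 1), zero, rng).sum() == 0
        assert assign_risk(G, (0, 1), ones, rng).sum() == 50

    def test_conditional_rates_match_table(self):
        rng = np.random.default_rng(4)
        m = build_ritchie_3way()
        G = generate_genotypes(60000, [0.5] * 3, rng)
        x = assign_risk(G, (0, 1, 2), m, rng)
        from ummdr.classify import cell_codes

        codes = cell_codes(G.values[:, :3])
        for cell in [13, 8]:  # (1,1,1) -> 0; (0,2,2) -> 0.2
            mask = codes == cell
            emp = x[mask].mean()
            f = m.table[cell]
            se = math.sqrt(max(f * (1 - f), 1e-4) / mask.sum())
            assert abs(emp - f) < 4 * se


class TestSurvivalGeneration:
    def test_weibull_median_closed_form(self):
        cfg = SimulationConfig(alpha=0.0, gamma=0.0, target_cf=0.0)
        rng = np.random.default_rng(0)
        surv = generate_survival(np.zeros(40000), None, None, cfg, rng)
        expected = 2.0 * math.log(2) ** (1 / 5)
        assert np.median(surv.time) == pytest.approx(expected, rel=0.01)
        assert surv.status.all()

    def test_hazard_monotone_in_risk(self):
        cfg = SimulationConfig(alpha=2.0, gamma=0.0, target_cf=0.0)
        rng = np.random.default_rng(1)
        x = np.repeat([0.0, 1.0], 5000)
        surv = generate_survival(x, None, None, cfg, rng)
        assert np.median(surv.time[x == 1]) < np.median(surv.time[x == 0])

    def test_parameter_recovery_with_true_indicator(self):
        """Fitting the step-2 Cox model with the true latent x recovers the
        generative log-hazard ratio."""
        rng = np.random.default_rng(7)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        z = rng.standard_normal(n)
        cfg = SimulationConfig(n=n, alpha=0.8, gamma=0.8, target_cf=0.0)
        surv = generate_survival(x, z, None, cfg, rng)
        fit = ummdr.fit_cox(surv, np.column_stack([x, z]))
        se = math.sqrt(fit.covariance[0, 0])
        assert abs(fit.coefficients[0] - 0.8) < 3 * se


class TestCensoringCalibration:
    def test_targets_reached(self):
        cfg = SimulationConfig(alpha=0.0, gamma=0.8, target_cf=0.1, p=4)
        rng = np.random.default_rng(0)
        c10 = calibrate_censoring(cfg, rng, n_pilot=20000)
        cfg50 = SimulationConfig(alpha=0.0, gamma=0.8, target_cf=0.5, p=4)
        c50 = calibrate_censoring(cfg50, rng, n_pilot=20000)
        assert c50 < c10  # more censoring -> tighter uniform
        # achieved CF on fresh replicates
        cfg.censor_upper = c10
        achieved = []
        for seed in range(50):
            d = generate_dataset(cfg, None, np.random.default_rng(seed))
            achieved.append(d.censoring_fraction)
        assert abs(np.mean(achieved) - 0.1) < 0.015

    def test_calibration_stable_across_seeds(self):
        cfg = SimulationConfig(alpha=0.0, gamma=0.8, target_cf=0.3, p=4)
        c1 = calibrate_censoring(cfg, np.random.default_rng(1), n_pilot=20000)
        c2 = calibrate_censoring(cfg, np.random.default_rng(2), n_pilot=20000)
        assert c1 == pytest.approx(c2, rel=0.03)

    def test_zero_cf_means_no_censoring(self):
        cfg = SimulationConfig(alpha=0.0, gamma=0.8, target_cf=0.0, p=4)
        d = generate_dataset(cfg, None, np.random.default_rng(0))
        assert d.surv.status.all()


class TestStudies:
    def test_type1_nominal_rates(self):
        from math import comb

        df = ummdr.run_type1_study(maf=0.3, cf=0.0, n_datasets=5, seed=0)
        assert df["nominal_selection_rate"].iloc[0] == pytest.approx(1 / comb(8, 2))
        assert ((df["type1_top_sig"] >= 0) & (df["type1_top_sig"] <= 1)).all()

    def test_power_null_reduces_to_type1(self):
        """With alpha = 0 the 'power' is just the per-pair false-positive rate."""
        df = ummdr.run_power_study(
            maf=0.2, heritability=0.1, cf=0.0, methods=("cox-ummdr",),
            alpha=0.0, gamma=0.8, n_datasets=8, n_models=1, p=5, seed=0,
        )
        assert df["power"].iloc[0] <= 0.4

    def test_power_table_schema(self):
        df = ummdr.run_power_study(
            maf=0.2, heritability=0.4, cf=0.0, methods=("cox-ummdr", "km-ummdr"),
            n_datasets=4, n_models=1, p=5, seed=1,
        )
        assert set(df["method"]) == {"Cox-UMMDR", "KM-UMMDR"}
        assert ((df["power"] >= 0) & (df["power"] <= 1)).all()
        assert (df["selection_rate"] >= df["power"] - 1e-12).all()
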