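import numpy as np
import pytest
from scipy import stats

from ummdr import (
    CovariateMatrix,
    GenotypeMatrix,
    SurvivalData,
    UMMDRScan,
    corrected_pvalue,
    estimate_ncp,
    permutation_null_W,
    wald_statistic,
)
from tests.test_coxph import partial_loglik_bruteforce


class TestWaldStatistic:
    def test_constant_S_degenerate(self, eight_subjects_split):
        surv, _ = eight_subjects_split
        res = wald_statistic(surv, np.zeros(8))
        assert res.degenerate and res.W == 0.0

    def test_matches_bruteforce_grid_and_hessian(self, eight_subjects_split):
        """W from the 1-parameter fit must match an independent grid-search
        maximization plus a finite-difference second derivative."""
        surv, S = eight_subjects_split
        res = wald_statistic(surv, S)
        grid = np.linspace(-6, 6, 120001)
        lls = np.array(
            [partial_loglik_bruteforce(b, surv.time, surv.status, S[:, None]) for b in grid]
        )
        i = int(np.argmax(lls))
        beta_hat = grid[i]
        h = grid[1] - grid[0]
        d2 = (lls[i + 1] - 2 * lls[i] + lls[i - 1]) / h**2
        W_oracle = beta_hat**2 * (-d2)
        assert res.alpha_hat == pytest.approx(beta_hat, abs=1e-3)
        assert res.W == pytest.approx(W_oracle, rel=1e-3)

    def test_covariate_added_keeps_W_finite(self, eight_subjects_split):
        surv, S = eight_subjects_split
        rng = np.random.default_rng(0)
        Z = CovariateMatrix(rng.standard_normal((8, 1)))
        res = wald_statistic(surv, S, Z, variant="cox-ummdr")
        assert np.isfinite(res.W) and res.W >= 0

    def test_W_invariant_to_HL_relabeling(self, eight_subjects_split):
        # swapping H and L flips the sign of alpha_hat but leaves W unchanged
        surv, S = eight_subjects_split
        a = wald_statistic(surv, S)
        b = wald_statistic(surv, 1 - S)
        assert a.W == pytest.approx(b.W, rel=1e-8)
        assert a.alpha_hat == pytest.approx(-b.alpha_hat, rel=1e-6)

    def test_s_only_variant_ignores_Z(self, eight_subjects_split):
        surv, S = eight_subjects_split
        rng = np.random.default_rng(0)
        Z = CovariateMatrix(rng.standard_normal((8, 1)))
        with_z = wald_statistic(surv, S, Z, variant="cox2-ummdr")
        without = wald_statistic(surv, S, None, variant="cox2-ummdr")
        assert with_z.W == without.W


class TestNCPAndPValue:
    def test_estimate_ncp_arithmetic(self):
        (e,) = estimate_ncp([[0.2, 0.4]], pooled=False)
        assert (e.mu_hat, e.q_hat) == (pytest.approx(0.3), 0.0)
        (e,) = estimate_ncp([[2.0, 4.0]], pooled=False)
        assert (e.mu_hat, e.q_hat) == (pytest.approx(3.0), pytest.approx(2.0))

    def test_pooling_shares_estimate(self):
        a, b = estimate_ncp([[2.0], [4.0]], pooled=True)
        assert a.q_hat == b.q_hat == pytest.approx(2.0)
        a, b = estimate_ncp([[2.0], [4.0]], pooled=False)
        assert (a.q_hat, b.q_hat) == (pytest.approx(1.0), pytest.approx(3.0))

    def test_corrected_pvalue_central_reduction(self):
        assert corrected_pvalue(0.0, 0.0) == 1.0
        assert corrected_pvalue(3.841, 0.0) == pytest.approx(
            stats.chi2.sf(3.841, 1), rel=1e-12
        )
        assert corrected_pvalue(3.841, 0.0) == pytest.approx(0.050, abs=5e-4)

    def test_pvalue_increasing_in_ncp(self):
        assert corrected_pvalue(5.0, 2.0) > corrected_pvalue(5.0, 0.0)
        qs = np.linspace(0, 4, 9)
        ps = [corrected_pvalue(5.0, q) for q in qs]
        assert all(a < b for a, b in zip(ps, ps[1:]))


def _null_data(seed, n=120, p=5):
    rng = np.random.default_rng(seed)
    G = GenotypeMatrix(rng.integers(0, 3, (n, p)))
    z = rng.standard_normal(n)
    t = rng.exponential(np.exp(-0.5 * z)) + 1e-6
    d = (rng.uniform(size=n) < 0.8).astype(int)
    return G, SurvivalData(t, d), CovariateMatrix(z[:, None])


class TestScan:
    @pytest.mark.parametrize("variant", ["km-ummdr", "cox-ummdr", "cox2-ummdr"])
    def test_record_count_and_rank_permutation(self, variant):
        G, surv, Z = _null_data(1, p=5)
        res = UMMDRScan(G, surv, Z, variant=variant).fit(B=3, seed=0)
        assert len(res.table) == 10  # C(5,2)
        assert sorted(res.rank) == list(range(1, 11))
        assert ((res.p_value >= 0) & (res.p_value <= 1)).all()

    def test_deterministic_given_seed(self):
        G, surv, Z = _null_data(2)
        r1 = UMMDRScan(G, surv, Z).fit(B=5, seed=42)
        r2 = UMMDRScan(G, surv, Z).fit(B=5, seed=42)
        np.testing.assert_array_equal(r1.null_W, r2.null_W)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)

    def test_planted_strong_pair_ranks_first(self):
        """A large-effect epistatic pair should dominate the ranking."""
        import ummdr

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = ummdr.generate_genotypes(400, [0.2] * 6, rng)
            model = ummdr.generate_penetrance(0.2, 0.4, rng)
            x = ummdr.assign_risk(G, (0, 1), model, rng)
            cfg = ummdr.SimulationConfig(n=400, p=6, alpha=1.2, gamma=0.0, target_cf=0.0)
            surv = ummdr.generate_survival(x, None, None, cfg, rng)
            res = UMMDRScan(G, surv, variant="cox-ummdr").fit(B=5, seed=seed)
            hits += res.best_combo.indices == (0, 1)
        assert hits >= 6  # majority of replicates

    def test_adjust_main_changes_W(self):
        G, surv, Z = _null_data(3)
        r0 = UMMDRScan(G, surv, Z, adjust_main=False).fit(B=2, seed=0)
        r1 = UMMDRScan(G, surv, Z, adjust_main=True).fit(B=2, seed=0)
        assert not np.allclose(r0.W, r1.W)

    def test_from_dataframes_roundtrip(self):
        import pandas as pd

        G, surv, Z = _null_data(4)
        gdf = pd.DataFrame(G.values, columns=G.snp_ids)
        sdf = pd.DataFrame({"time": surv.time, "status": surv.status})
        zdf = pd.DataFrame(Z.values, columns=Z.names)
        r1 = UMMDRScan.from_dataframes(gdf, sdf, zdf).fit(B=3, seed=9)
        r2 = UMMDRScan(G, surv, Z).fit(B=3, seed=9)
        np.testing.assert_allclose(r1.W, r2.W)

    def test_tsv_export(self, tmp_path):
        G, surv, Z = _null_data(5)
        res = UMMDRScan(G, surv, Z).fit(B=2, seed=0)
        out = str(tmp_path / "scan.tsv")
        res.to_tsv(out)
        import json

        import pandas as pd

        assert len(pd.read_csv(out, sep="\t")) == len(res.table)
        sidecar = json.load(open(out + ".json"))
        assert sidecar["seed"] == 0


class TestPermutationNull:
    def test_contract_and_determinism(self):
        G, surv, Z = _null_data(6)
        w1 = permutation_null_W(surv, G, Z, (0, 1), B=5, rng_seed=3)
        w2 = permutation_null_W(surv, G, Z, (0, 1), B=5, rng_seed=3)
        assert len(w1) == 5 and (w1 >= 0).all()
        np.testing.assert_array_equal(w1, w2)

    def test_null_mean_matches_independent_null_datasets(self):
        """Permutation-null W and W from fresh null datasets estimate the
        same distribution; their means must agree within Monte-Carlo error."""
        import ummdr

        rng = np.random.default_rng(0)
        n, B = 150, 150
        G, surv, Z = _null_data(7, n=n)
        perm_W = permutation_null_W(surv, G, Z, (0, 1), variant="km-ummdr",
                                    B=B, rng_seed=1)
        fresh = []
        for seed in range(B):
            Gf, survf, Zf = _null_data(1000 + seed, n=n)
            res = ummdr.wald_statistic(
                survf,
                ummdr.classify_km(
                    ummdr.partition_cells(Gf, ummdr.LocusCombination((0, 1))), survf
                ).S,
                Zf,
                variant="km-ummdr",
            )
            fresh.append(res.W)
        fresh = np.array(fresh)
        se = np.sqrt(perm_W.var() / B + fresh.var() / B)
        assert abs(perm_W.mean() - fresh.mean()) < 3.5 * se
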