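"""Nominal scan correctness (FWL), permutation calibration, conditional pass."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hervmap import eqtl
from hervmap.simulate import (
    PlantedEffect,
    SimConfig,
    simulate_expression_with_eqtl,
    simulate_genotypes,
)


def _toy(seed, n=120, n_var=40, ld_rho=0.0, maf=(0.1, 0.5)):
    cfg = SimConfig(seed=seed, n_individuals=n, ld_rho=ld_rho, maf_range=maf,
                    n_cells_per_type={"T": 5})
    gt = simulate_genotypes(cfg, n_variants=n_var)
    return cfg, gt


def _meta(pheno_ids, tss=1_000_000):
    return pd.DataFrame({"chrom": "chr1", "tss": tss}, index=pheno_ids)


def _covariates(rng, individuals, k=3):
    cov = pd.DataFrame(rng.normal(size=(len(individuals), k)),
                       index=individuals, columns=[f"c{i}" for i in range(k)])
    return cov


class TestNominalScan:
    def test_equals_full_ols_t_statistic(self, rng):
        """Frisch-Waugh-Lovell: residual-correlation t == OLS coefficient t."""
        import statsmodels.api as sm

        cfg, gt = _toy(101)
        individuals = gt.dosages.index
        cov = _covariates(rng, individuals)
        for trial in range(50):
            y = pd.Series(rng.normal(size=len(individuals)) +
                          cov.to_numpy() @ rng.normal(size=3), index=individuals)
            phen = y.to_frame("P")
            res = eqtl.nominal_cis_scan(phen, _meta(["P"]), gt, cov)
            vid = res["variant_id"].iloc[trial % len(res)]
            row = res[res["variant_id"] == vid].iloc[0]
            X = sm.add_constant(np.column_stack([
                gt.dosages.loc[individuals, vid].to_numpy(dtype=float), cov.to_numpy()
            ]))
            fit = sm.OLS(y.to_numpy(), X).fit()
            assert row["t"] == pytest.approx(fit.tvalues[1], rel=1e-6)
            assert row["p_nominal"] == pytest.approx(fit.pvalues[1], rel=1e-6)
            assert row["beta"] == pytest.approx(fit.params[1], rel=1e-6)

    def test_window_boundary(self, rng):
        cfg, gt = _toy(103, n_var=5)
        gt.variants["pos"] = [500_000, 1_999_999, 2_000_000, 2_000_001, 3_500_000]
        individuals = gt.dosages.index
        cov = _covariates(rng, individuals)
        phen = pd.DataFrame({"P": rng.normal(size=len(individuals))}, index=individuals)
        res = eqtl.nominal_cis_scan(phen, _meta(["P"], tss=1_000_000), gt, cov)
        tested = set(res["variant_id"])
        vids = list(gt.variants.index)
        assert vids[2] in tested and vids[3] not in tested and vids[4] not in tested

    def test_pure_covariate_signal_uniform_p(self, rng):
        cfg, gt = _toy(107, n=150)
        individuals = gt.dosages.index
        cov = _covariates(rng, individuals)
        pvals = []
        for i in range(30):
            y = cov.to_numpy() @ np.array([2.0, -1.0, 0.5]) + rng.normal(size=len(individuals))
            phen = pd.DataFrame({"P": y}, index=individuals)
            res = eqtl.nominal_cis_scan(phen, _meta(["P"]), gt, cov)
            pvals.extend(res["p_nominal"])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_planted_effect_powered(self):
        hits = 0
        for seed in range(20):
            cfg, gt = _toy(2000 + seed, n=200)
            vid = gt.dosages.columns[7]
            cfg.eqtl_plan = [PlantedEffect("H", vid, "T", 0.8)]
            phen, cov, _ = simulate_expression_with_eqtl(cfg, gt, herv_ids=["H"])
            base = cov[["sex", "age"]]
            res = eqtl.nominal_cis_scan(phen["T"], _meta(["H"]), gt, base)
            if res[res["variant_id"] == vid]["p_nominal"].iloc[0] < 1e-6:
                hits += 1
        assert hits >= 19  # >= 95%


class TestPreparation:
    def test_presence_filter_strictly_greater(self, rng):
        cfg, gt = _toy(109, n=100)
        individuals = gt.dosages.index
        expr = pd.DataFrame(0.0, index=individuals, columns=["exact10", "eleven"])
        expr.iloc[:10, 0] = 1.0   # exactly 10%
        expr.iloc[:11, 1] = 1.0   # 11%
        base = pd.DataFrame({"sex": 0, "age": 50.0}, index=individuals)
        ph, cov = eqtl.prepare_phenotypes_covariates(expr, gt, base, n_pcs=2, n_factors=0)
        assert list(ph.columns) == ["eleven"]

    def test_pc_subspace_invariant_to_individual_order(self, rng):
        cfg, gt = _toy(113, n=80)
        individuals = list(gt.dosages.index)
        expr = pd.DataFrame(rng.normal(size=(80, 30)), index=individuals,
                            columns=[f"H{i}" for i in range(30)])
        base = pd.DataFrame({"sex": 0, "age": 50.0}, index=individuals)
        _, cov1 = eqtl.prepare_phenotypes_covariates(expr, gt, base, min_fraction=0.0,
                                                     n_pcs=3, n_factors=0)
        order = rng.permutation(individuals)
        gt2 = gt.subset_individuals(list(order))
        _, cov2 = eqtl.prepare_phenotypes_covariates(expr.loc[order], gt2,
                                                     base.loc[order], min_fraction=0.0,
                                                     n_pcs=3, n_factors=0)
        for i in range(1, 4):
            a = cov1.loc[cov2.index, f"PC{i}"]
            assert abs(np.corrcoef(a, cov2[f"PC{i}"])[0, 1]) > 0.999

    def test_planted_batch_factor_captured(self, rng):
        cfg, gt = _toy(127, n=100)
        individuals = gt.dosages.index
        batch = np.repeat([0.0, 1.0], 50)
        expr = pd.DataFrame(rng.normal(size=(100, 50)) + 3.0 * batch[:, None] + 5,
                            index=individuals, columns=[f"H{i}" for i in range(50)])
        base = pd.DataFrame({"sex": 0, "age": 50.0}, index=individuals)
        _, cov = eqtl.prepare_phenotypes_covariates(expr, gt, base, min_fraction=0.0,
                                                    n_pcs=2, n_factors=1)
        assert abs(np.corrcoef(cov["factor1"], batch)[0, 1]) > 0.9

    def test_too_few_individuals_refused(self, rng):
        cfg = SimConfig(seed=1, n_individuals=30)
        gt = simulate_genotypes(cfg, n_variants=10)
        expr = pd.DataFrame(rng.normal(size=(15, 5)),
                            index=gt.dosages.index[:15],
                            columns=[f"H{i}" for i in range(5)])
        base = pd.DataFrame({"sex": 0, "age": 50.0}, index=gt.dosages.index)
        with pytest.raises(ValueError, match="shared individuals"):
            eqtl.prepare_phenotypes_covariates(expr, gt, base)


class TestPermutationPass:
    def test_floor_when_observed_beats_all_permutations(self):
        cfg, gt = _toy(131, n=150)
        vid = gt.dosages.columns[3]
        cfg.eqtl_plan = [PlantedEffect("H", vid, "T", 1.5, noise_sd=0.3)]
        phen, cov, _ = simulate_expression_with_eqtl(cfg, gt, herv_ids=["H"])
        base = cov[["sex", "age"]]
        res = eqtl.permutation_pass(phen["T"], _meta(["H"]), gt, base,
                                    n_perm=200, seed=5)
        assert res["p_empirical"].iloc[0] == pytest.approx(1 / 201)

    def test_null_calibration_and_beta_consistency(self, rng):
        cfg, gt = _toy(137, n=100, n_var=30)
        individuals = gt.dosages.index
        phen = pd.DataFrame(rng.normal(size=(100, 60)), index=individuals,
                            columns=[f"N{i}" for i in range(60)])
        cov = _covariates(rng, individuals, k=2)
        res = eqtl.permutation_pass(phen, _meta(list(phen.columns)), gt, cov,
                                    n_perm=300, seed=9)
        frac = (res["p_empirical"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) < 3 * se + 1e-9
        rho = stats.spearmanr(res["p_beta"], res["p_empirical"]).statistic
        assert rho > 0.95

    def test_calibration_heavy_tailed_noise(self, rng):
        """Permutation p is distribution-free: holds under t(3) noise too."""
        cfg, gt = _toy(139, n=100, n_var=30)
        individuals = gt.dosages.index
        phen = pd.DataFrame(stats.t(3).rvs(size=(100, 50), random_state=7),
                            index=individuals, columns=[f"N{i}" for i in range(50)])
        cov = _covariates(rng, individuals, k=2)
        res = eqtl.permutation_pass(phen, _meta(list(phen.columns)), gt, cov,
                                    n_perm=300, seed=11)
        frac = (res["p_empirical"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(res)) + 1e-9

    def test_bit_reproducible(self, rng):
        cfg, gt = _toy(149, n=80, n_var=20)
        individuals = gt.dosages.index
        phen = pd.DataFrame(rng.normal(size=(80, 5)), index=individuals,
                            columns=[f"N{i}" for i in range(5)])
        cov = _covariates(rng, individuals, k=2)
        a = eqtl.permutation_pass(phen, _meta(list(phen.columns)), gt, cov,
                                  n_perm=100, seed=3)
        b = eqtl.permutation_pass(phen, _meta(list(phen.columns)), gt, cov,
                                  n_perm=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestFdr:
    def test_bh_closed_form(self):
        res = pd.DataFrame({"phenotype_id": list("abcd"),
                            "p_beta": [0.01, 0.02, 0.03, 0.04]})
        out = eqtl.phenotype_fdr(res)
        assert np.allclose(out["q_value"], 0.04)

    def test_all_ones(self):
        res = pd.DataFrame({"phenotype_id": list("ab"), "p_beta": [1.0, 1.0]})
        out = eqtl.phenotype_fdr(res)
        assert (out["q_value"] == 1.0).all()

    def test_q_monotone_in_p(self, rng):
        res = pd.DataFrame({"phenotype_id": [f"p{i}" for i in range(50)],
                            "p_beta": rng.uniform(size=50)})
        out = eqtl.phenotype_fdr(res).sort_values("p_beta")
        assert (np.diff(out["q_value"]) >= -1e-12).all()


class TestConditionalScan:
    def _run_panel(self, seed, plant, n=300, n_var=50, n_null=11, n_perm=250):
        cfg, gt = _toy(seed, n=n, n_var=n_var, ld_rho=0.5)
        plan, herv_ids = plant(gt)
        cfg.eqtl_plan = plan
        herv_ids = herv_ids + [f"N{i}" for i in range(n_null)]
        phen, cov, _ = simulate_expression_with_eqtl(cfg, gt, herv_ids=herv_ids)
        base = cov[["sex", "age"]]
        meta = _meta(herv_ids)
        perm = eqtl.permutation_pass(phen["T"], meta, gt, base, n_perm=n_perm, seed=seed)
        cutoff = eqtl.pbeta_significance_cutoff(perm)
        return gt, phen["T"], base, perm, cutoff

    def test_single_planted_yields_one_correct_signal(self):
        correct = total = 0
        for seed in range(20):
            def plant(gt):
                vid = gt.dosages.columns[9]
                return [PlantedEffect("H", vid, "T", 0.8)], ["H"]
            gt, phen, base, perm, cutoff = self._run_panel(3000 + seed, plant)
            if cutoff is None:
                continue
            row = perm[perm["phenotype_id"] == "H"].iloc[0]
            ind = eqtl.conditional_independent_scan(
                phen["H"], "chr1", 1_000_000, gt, base,
                row["beta_shape1"], row["beta_shape2"], cutoff)
            total += 1
            if len(ind) == 1 and ind["variant_id"].iloc[0] == gt.dosages.columns[9]:
                correct += 1
        assert total >= 15 and correct / total >= 0.9

    def test_two_independent_signals_recovered(self):
        two = total = 0
        for seed in range(15):
            def plant(gt):
                v1, v2 = gt.dosages.columns[5], gt.dosages.columns[35]  # distinct blocks
                return ([PlantedEffect("H", v1, "T", 0.8),
                         PlantedEffect("H", v2, "T", 0.8)], ["H"])
            cfg, gt = _toy(4000 + seed, n=300, n_var=50, ld_rho=0.5)
            v1, v2 = gt.dosages.columns[5], gt.dosages.columns[35]
            cfg.eqtl_plan = [PlantedEffect("H", v1, "T", 0.8)]
            herv_ids = ["H"] + [f"N{i}" for i in range(11)]
            phen, cov, _ = simulate_expression_with_eqtl(cfg, gt, herv_ids=herv_ids)
            # superpose the second standardized-dosage effect
            g2 = gt.dosages[v2].to_numpy(dtype=float)
            phen["T"]["H"] += 0.8 * (g2 - g2.mean()) / g2.std()
            base = cov[["sex", "age"]]
            perm = eqtl.permutation_pass(phen["T"], _meta(herv_ids), gt, base,
                                         n_perm=250, seed=seed)
            cutoff = eqtl.pbeta_significance_cutoff(perm)
            if cutoff is None:
                continue
            row = perm[perm["phenotype_id"] == "H"].iloc[0]
            ind = eqtl.conditional_independent_scan(
                phen["T"]["H"], "chr1", 1_000_000, gt, base,
                row["beta_shape1"], row["beta_shape2"], cutoff)
            total += 1
            if len(ind) == 2:
                two += 1
        assert total >= 10 and two / total >= 0.8

    def test_null_phenotype_zero_signals(self, rng):
        cfg, gt = _toy(151, n=200, n_var=40)
        individuals = gt.dosages.index
        y = pd.Series(rng.normal(size=200), index=individuals)
        cov = _covariates(rng, individuals, k=2)
        ind = eqtl.conditional_independent_scan(
            y, "chr1", 1_000_000, gt, cov, 1.0, 40.0, 0.01)
        assert len(ind) == 0
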