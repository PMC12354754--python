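"""SMR statistic, HEIDI heterogeneity, colocalization and mediation triads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hervmap import smr
from hervmap.pipeline import simulate_block_ld
from hervmap.simulate import CausalPlan, SimConfig, simulate_summary_stats
from hervmap.sumstats import SummaryStats, harmonize


def _stats(betas, ses, pos=None, a1="G", a2="A", n=10_000, freq=0.3):
    m = len(betas)
    pos = pos if pos is not None else np.arange(m) * 1000
    z = np.asarray(betas) / np.asarray(ses)
    return SummaryStats(pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(m)],
        "chrom": "chr1", "pos": pos, "a1": a1, "a2": a2, "freq": freq,
        "beta": betas, "se": ses, "p": 2 * stats.norm.sf(np.abs(z)), "n": n,
    }))


class TestSmrStatistic:
    def test_closed_form_z6_z5(self):
        exposure = _stats([6.0, 0.1], [1.0, 1.0])
        outcome = _stats([5.0, 0.1], [1.0, 1.0])
        res = smr.smr_test(exposure, outcome, instrument_p=1e-5)
        t_smr = (36 * 25) / (36 + 25)
        assert t_smr == pytest.approx(900 / 61)
        assert res.p_smr == pytest.approx(stats.chi2.sf(900 / 61, 1), rel=1e-6)
        assert res.b_xy == pytest.approx(5 / 6)

    def test_zero_outcome_z(self):
        res = smr.smr_test(_stats([6.0], [1.0]), _stats([0.0], [1.0]),
                           instrument_p=1e-5)
        assert res.p_smr == 1.0

    def test_symmetric_in_exposure_outcome_z(self):
        a = smr.smr_test(_stats([6.0], [1.0]), _stats([5.0], [1.0]), instrument_p=1e-5)
        b = smr.smr_test(_stats([5.0], [1.0]), _stats([6.0], [1.0]), instrument_p=1e-4)
        assert a.p_smr == pytest.approx(b.p_smr)

    def test_no_instrument_returns_none(self):
        assert smr.smr_test(_stats([2.0], [1.0]), _stats([2.0], [1.0])) is None

    @settings(deadline=None, max_examples=200)
    @given(z1=st.floats(-20, 20), z2=st.floats(-20, 20))
    def test_t_smr_bounded_by_component_chisq(self, z1, z2):
        denom = z1**2 + z2**2
        t = (z1**2 * z2**2) / denom if denom > 0 else 0.0
        assert t <= min(z1**2, z2**2) + 1e-9


class TestHarmonization:
    def test_flipped_alleles_negate_beta(self):
        e = _stats([6.0, 1.0], [1.0, 1.0], a1="G", a2="A")
        o = _stats([5.0, 1.0], [1.0, 1.0], a1="A", a2="G")  # swapped
        eh, oh = harmonize(e, o)
        assert np.allclose(oh.table["beta"], [-5.0, -1.0])
        res_flip = smr.smr_test(eh, oh, instrument_p=1e-5)
        o_same = _stats([-5.0, -1.0], [1.0, 1.0], a1="G", a2="A")
        res_direct = smr.smr_test(*harmonize(e, o_same), instrument_p=1e-5)
        assert res_flip.p_smr == pytest.approx(res_direct.p_smr)
        assert res_flip.b_xy == pytest.approx(res_direct.b_xy)

    def test_strand_ambiguous_dropped(self):
        e = _stats([6.0, 1.0], [1.0, 1.0], a1="A", a2="T")
        o = _stats([5.0, 1.0], [1.0, 1.0], a1="A", a2="T")
        eh, oh = harmonize(e, o)
        assert len(eh) == 0


class TestHeidi:
    def test_identical_bxy_gives_p_one(self):
        # outcome betas exactly proportional to exposure betas -> all b_xy equal
        be = np.array([1.0, 0.9, 0.8, 0.85, 0.95])
        e = _stats(be, np.full(5, 0.05))
        o = _stats(2 * be, np.full(5, 1e-6))
        ld = np.full((5, 5), 0.4)
        np.fill_diagonal(ld, 1.0)
        p, n = smr.heidi_test(e, o, ld, top_variant="rs0")
        assert n == 4 and p == pytest.approx(1.0)

    def test_too_few_snps_untested(self):
        e = _stats([6.0, 5.0], [1.0, 1.0])
        o = _stats([5.0, 4.0], [1.0, 1.0])
        ld = np.array([[1.0, 0.5], [0.5, 1.0]])
        p, n = smr.heidi_test(e, o, ld)
        assert np.isnan(p) and n < 3

    def test_satterthwaite_close_to_imhof(self):
        """The moment-matched default tracks the exact quadratic-form p:
        close in the body, same side of the 0.01 rejection cutoff."""
        cfg = SimConfig(seed=77)
        ld = simulate_block_ld(30, 0.6, 15)
        for off in range(8):
            e, o = simulate_summary_stats(cfg, ld, CausalPlan("shared", 7),
                                          seed_offset=off)
            res = smr.smr_test(e, o, instrument_p=1e-4)
            if res is None:
                continue
            top = res.top_variant
            p_sat, _ = smr.heidi_test(e, o, ld, top_variant=top, method="satterthwaite")
            p_im, _ = smr.heidi_test(e, o, ld, top_variant=top, method="imhof")
            if np.isnan(p_sat):
                continue
            assert abs(p_sat - p_im) < 0.1
            assert (p_sat < 0.01) == (p_im < 0.01)

    def test_discriminates_shared_from_linkage(self):
        cfg = SimConfig(seed=88)
        ld = simulate_block_ld(40, 0.6, 20)
        rej, tot = {"shared": 0, "distinct": 0}, {"shared": 0, "distinct": 0}
        offsets = {"shared": 10_000, "distinct": 20_000}
        n_runs = 60
        for mode in rej:
            plan = CausalPlan(mode, index_exposure=12, index_outcome=15)
            for i in range(n_runs):
                e, o = simulate_summary_stats(cfg, ld, plan,
                                              seed_offset=offsets[mode] + i)
                res = smr.smr_test(e, o)
                if res is None:
                    continue
                p, _ = smr.heidi_test(e, o, ld, top_variant=res.top_variant)
                if np.isnan(p):
                    continue
                tot[mode] += 1
                if p < 0.01:
                    rej[mode] += 1
        assert rej["shared"] <= 0.10 * tot["shared"]
        assert rej["distinct"] >= 0.50 * tot["distinct"]


class TestColoc:
    def test_probability_simplex_random_inputs(self, rng):
        for _ in range(20):
            m = int(rng.integers(10, 40))
            betas = rng.normal(scale=0.2, size=m)
            ses = rng.uniform(0.01, 0.2, size=m)
            s1 = _stats(betas, ses)
            s2 = _stats(rng.normal(scale=0.2, size=m), rng.uniform(0.01, 0.2, size=m))
            res = smr.coloc_abf(s1, s2)
            assert abs(sum(res.pp.values()) - 1.0) < 1e-10
            assert all(v >= 0 for v in res.pp.values())

    def test_self_colocalization_h4(self):
        betas = np.zeros(30)
        betas[13] = 0.5
        ses = np.full(30, 0.05)
        s = _stats(betas, ses)
        res = smr.coloc_abf(s, s)
        assert res.pp_h4 > 0.9 and res.top_shared_variant == "rs13"

    def test_pure_noise_h0(self, rng):
        betas = rng.normal(scale=0.05, size=25)
        ses = np.full(25, 0.1)  # all |z| < 1.5ish
        s1 = _stats(np.clip(betas, -0.09, 0.09), ses)
        s2 = _stats(np.clip(rng.normal(scale=0.05, size=25), -0.09, 0.09), ses)
        res = smr.coloc_abf(s1, s2)
        assert res.pp["H0"] > 0.5

    def test_min_variants_refused(self):
        s = _stats([0.1] * 5, [0.05] * 5)
        with pytest.raises(ValueError, match="5 shared"):
            smr.coloc_abf(s, s)

    def test_h4_monotone_in_gwas_sample_size(self):
        """Fixed per-allele effect, growing cohort: z scales with sqrt(n), so
        evidence for a shared causal variant strengthens with sample size."""
        ld = simulate_block_ld(40, 0.6, 20)
        pps = []
        sizes = [2_000, 8_000, 32_000, 128_000, 512_000]
        for n_gwas in sizes:
            lam = 2.0 * np.sqrt(n_gwas / 2_000)
            vals = []
            for i in range(10):
                cfg = SimConfig(seed=500 + i, n_gwas=n_gwas)
                e, o = simulate_summary_stats(
                    cfg, ld, CausalPlan("shared", 12, lam_outcome=lam), seed_offset=i)
                vals.append(smr.coloc_abf(e, o).pp_h4)
            pps.append(np.mean(vals))
        assert pps[-1] > pps[0]
        assert all(b >= a - 0.1 for a, b in zip(pps, pps[1:]))


class TestScreenAndTriads:
    def _pair(self, eid, oid, ct, typ, strong, seed):
        cfg = SimConfig(seed=seed)
        ld = simulate_block_ld(30, 0.5, 10)
        plan = CausalPlan("shared", 7) if strong else CausalPlan("null")
        e, o = simulate_summary_stats(cfg, ld, plan, seed_offset=seed)
        return {"exposure_id": eid, "outcome_id": oid, "celltype": ct,
                "assoc_type": typ, "exposure": e, "outcome": o, "ld": ld}

    def test_null_pairs_family_wise_control(self):
        pairs = [self._pair(f"H{i}", "D", "CD4-T", "herv-disease", False, 900 + i)
                 for i in range(60)]
        res = smr.smr_screen(pairs)
        assert res["significant"].sum() <= 1

    def test_planted_pair_detected_among_nulls(self):
        pairs = [self._pair(f"H{i}", "D", "CD4-T", "herv-disease", False, 700 + i)
                 for i in range(20)]
        pairs.append(self._pair("Hsig", "D", "CD4-T", "herv-disease", True, 799))
        res = smr.smr_screen(pairs)
        sig = res[res["significant"]]
        assert "Hsig" in set(sig["exposure_id"])

    def test_empty_input(self):
        assert smr.smr_screen([]).empty

    def test_mediation_disjoint_empty(self):
        cols = ["exposure_id", "outcome_id", "celltype", "significant"]
        hg = pd.DataFrame([["H1", "G1", "T", True]], columns=cols)
        hd = pd.DataFrame([["H2", "D1", "T", True]], columns=cols)
        gd = pd.DataFrame([["G1", "D1", "T", True]], columns=cols)
        assert smr.mediation_intersect(hg, hd, gd) == []

    def test_planted_triad_recovered(self):
        cols = ["exposure_id", "outcome_id", "celltype", "significant"]
        hg = pd.DataFrame([["H1", "G1", "T", True], ["H1", "G2", "T", False]], columns=cols)
        hd = pd.DataFrame([["H1", "D1", "T", True]], columns=cols)
        gd = pd.DataFrame([["G1", "D1", "T", True], ["G2", "D1", "T", True]], columns=cols)
        triads = smr.mediation_intersect(hg, hd, gd)
        assert triads == [smr.MediationTriad("H1", "G1", "D1", "T")]

    def test_matches_brute_force_triple_loop(self, rng):
        cols = ["exposure_id", "outcome_id", "celltype", "significant"]
        hervs = [f"H{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(5)]
        dis = [f"D{i}" for i in range(4)]
        cts = ["T", "B"]
        def rand_rows(a_list, b_list):
            return pd.DataFrame(
                [[a, b, c, bool(rng.random() < 0.4)]
                 for a in a_list for b in b_list for c in cts], columns=cols)
        hg, hd, gd = rand_rows(hervs, genes), rand_rows(hervs, dis), rand_rows(genes, dis)
        triads = set((t.herv_id, t.gene_id, t.disease_id, t.celltype)
                     for t in smr.mediation_intersect(hg, hd, gd))
        def sigset(df):
            return set(map(tuple, df[df.significant][cols[:3]].to_numpy()))
        shg, shd, sgd = sigset(hg), sigset(hd), sigset(gd)
        brute = {(h, g, d, c) for h in hervs for g in genes for d in dis for c in cts
                 if (h, g, c) in shg and (h, d, c) in shd and (g, d, c) in sgd}
        assert triads == brute
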