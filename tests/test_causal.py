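"""Harmonisation, clumping, Wald/IVW MR, triangulation, mediation."""

import numpy as np
import pandas as pd
import pytest

from methylink import meta
from methylink.causal import (clump, eaf_weights, harmonise, ivw, mediate,
                              mr_estimate, triangulate, wald_ratio,
                              bidirectional_mr)
from tests.conftest import make_summary


class TestHarmonise:
    def test_identical_alleles_unchanged(self):
        exp = make_summary(["s1"], [0.3], [0.05], ea="A", oa="G")
        out = make_summary(["s1"], [0.2], [0.04], ea="A", oa="G")
        aligned, log = harmonise(exp, out)
        assert aligned.loc[0, "beta_out"] == 0.2
        assert log.loc[0, "action"] == "kept"

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_summary(["s1"], [0.3], [0.05], eaf=[0.3], ea="A", oa="G")
        out = make_summary(["s1"], [0.3], [0.04], eaf=[0.7], ea="G", oa="A")
        aligned, log = harmonise(exp, out)
        assert aligned.loc[0, "beta_out"] == pytest.approx(-0.3)
        assert aligned.loc[0, "eaf_out"] == pytest.approx(0.3)
        assert log.loc[0, "action"] == "flipped"

    def test_ambiguous_palindromic_snp_dropped(self):
        exp = make_summary(["s1"], [0.3], [0.05], eaf=[0.5], ea="A", oa="T")
        out = make_summary(["s1"], [0.2], [0.04], eaf=[0.5], ea="A", oa="T")
        aligned, log = harmonise(exp, out)
        assert aligned.empty
        assert "palindromic" in log.loc[0, "reason"]

    def test_clear_palindromic_snp_retained(self):
        exp = make_summary(["s1"], [0.3], [0.05], eaf=[0.1], ea="A", oa="T")
        out = make_summary(["s1"], [0.2], [0.04], eaf=[0.1], ea="A", oa="T")
        aligned, _ = harmonise(exp, out)
        assert len(aligned) == 1

    def test_incompatible_alleles_dropped(self):
        exp = make_summary(["s1"], [0.3], [0.05], ea="A", oa="C")
        out = make_summary(["s1"], [0.2], [0.04], ea="A", oa="G")
        aligned, log = harmonise(exp, out)
        assert aligned.empty
        assert "incompatible" in log.loc[0, "reason"]

    def test_idempotent_after_first_pass(self):
        exp = make_summary(["s1", "s2"], [0.3, -0.1], [0.05, 0.05],
                           eaf=[0.2, 0.3], ea=["A", "C"], oa=["G", "T"])
        out = make_summary(["s1", "s2"], [0.3, 0.1], [0.04, 0.04],
                           eaf=[0.8, 0.3], ea=["G", "C"], oa=["A", "T"])
        once, _ = harmonise(exp, out)
        out2 = once[["snp_id", "effect_allele_out", "other_allele_out",
                     "eaf_out", "beta_out", "se_out", "p_out", "n_out"]]
        out2.columns = ["snp_id", "effect_allele", "other_allele", "eaf",
                        "beta", "se", "p", "n"]
        twice, log2 = harmonise(exp, out2)
        assert (log2["action"] == "kept").all()
        assert np.allclose(twice["beta_out"], once["beta_out"])


class TestClump:
    def ld(self, snps, pairs=()):
        m = pd.DataFrame(np.eye(len(snps)), index=snps, columns=snps)
        for a, b, r2 in pairs:
            m.loc[a, b] = m.loc[b, a] = r2
        return m

    def test_independent_snps_all_kept(self):
        s = make_summary(["a", "b", "c"], [0.1] * 3, [0.02] * 3)
        out = clump(s, self.ld(["a", "b", "c"]))
        assert set(out["snp_id"]) == {"a", "b", "c"}

    def test_correlated_pair_keeps_lowest_p(self):
        s = make_summary(["a", "b"], [0.30, 0.10], [0.02, 0.02])
        out = clump(s, self.ld(["a", "b"], [("a", "b", 0.9)]))
        assert list(out["snp_id"]) == ["a"]   # |z| larger -> lower p

    def test_chain_of_three_leaves_two(self):
        # r2(a,b)=0.9, r2(b,c)=0, r2(a,c)=0, p(a) lowest
        s = make_summary(["a", "b", "c"], [0.40, 0.30, 0.10], [0.02] * 3)
        out = clump(s, self.ld(["a", "b", "c"], [("a", "b", 0.9)]))
        assert set(out["snp_id"]) == {"a", "c"}

    def test_snp_missing_from_ld_kept(self):
        s = make_summary(["a", "zz"], [0.3, 0.1], [0.02, 0.02])
        out = clump(s, self.ld(["a"]))
        assert set(out["snp_id"]) == {"a", "zz"}


class TestWaldIvw:
    def test_wald_closed_form(self):
        est = wald_ratio(0.5, 0.01, 0.2, 0.05)
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.1)
        assert est.method == "wald"

    def test_unit_exposure_is_identity(self):
        est = wald_ratio(1.0, 0.01, 0.23, 0.04)
        assert (est.beta, est.se) == (0.23, 0.04)

    def test_negative_exposure_effect_flips_sign(self):
        est = wald_ratio(-0.5, 0.01, 0.2, 0.05)
        assert est.beta == pytest.approx(-0.4)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="irrelevant"):
            wald_ratio(0.0, 0.01, 0.2, 0.05)

    def test_ivw_of_identical_ratios_averages(self):
        r = [wald_ratio(1, 0.01, 0.4, 0.1) for _ in range(2)]
        est = ivw(r)
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))
        assert est.method == "ivw" and est.n_snps == 2

    def test_ivw_closed_form_and_shared_oracle(self):
        r = [wald_ratio(1, 0.01, 1.0, 1.0), wald_ratio(1, 0.01, 3.0, 1.0)]
        est = ivw(r)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / np.sqrt(2))
        oracle = meta.ivw([1.0, 3.0], [1.0, 1.0])
        assert est.beta == pytest.approx(oracle[0], abs=1e-12)
        assert est.se == pytest.approx(oracle[1], abs=1e-12)

    def test_single_ratio_defers_to_wald(self):
        est = ivw([wald_ratio(0.5, 0.01, 0.2, 0.05)])
        assert est.method == "wald"

    def test_combined_estimate_driven_by_stronger_instrument(self):
        # two instruments with very different precision: the pooled
        # estimate sits near the strong instrument's ratio
        strong = wald_ratio(0.5, 0.01, 0.10, 0.01, snp_id="strong")
        weak = wald_ratio(0.5, 0.01, 0.50, 0.20, snp_id="weak")
        est = ivw([strong, weak])
        assert abs(est.beta - strong.beta) < abs(est.beta - weak.beta)


class TestMrEstimate:
    def test_end_to_end_with_flip_and_clump(self):
        exp = make_summary(["a", "b"], [0.5, 0.5], [0.01, 0.01],
                           ea=["A", "C"], oa=["G", "T"])
        out = make_summary(["a", "b"], [-0.2, 0.2], [0.05, 0.05],
                           ea=["G", "C"], oa=["A", "T"])
        ld = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        est = mr_estimate(exp, out, ld)
        # SNP a flipped: outcome 0.2 -> ratio 0.4 for both
        assert est.beta == pytest.approx(0.4)
        assert est.n_snps == 2

    def test_no_shared_instruments_rejected(self):
        exp = make_summary(["a"], [0.5], [0.01])
        out = make_summary(["b"], [0.2], [0.05])
        with pytest.raises(ValueError, match="no usable"):
            mr_estimate(exp, out)


class TestEafWeights:
    def test_allele_variance_weighting(self):
        w = eaf_weights([0.5, 0.1])
        expected = np.array([2 * .25, 2 * .09])
        assert w == pytest.approx(expected / expected.sum())

    def test_plain_mode(self):
        assert eaf_weights([0.2, 0.6], mode="plain") == \
            pytest.approx([0.25, 0.75])


class TestTriangulate:
    def build_inputs(self, betas_ewas):
        cpgs = [f"cg{i}" for i in range(len(betas_ewas))]
        ewas = pd.DataFrame({"cpg_id": cpgs, "beta": betas_ewas})
        mqtl = make_summary([f"rs_{c}" for c in cpgs], [0.1] * len(cpgs),
                            [0.01] * len(cpgs))
        mqtl["cpg_id"] = cpgs
        gwas_snps = [f"rs_{c}" for c in cpgs] + ["inst1", "inst2"]
        gwas = make_summary(gwas_snps,
                            [0.05] * len(cpgs) + [0.08, 0.05],
                            [0.01] * (len(cpgs) + 2),
                            eaf=[0.3] * len(cpgs) + [0.4, 0.3])
        trans = pd.concat([
            make_summary(["inst1"] * len(cpgs), [0.002] * len(cpgs),
                         [0.001] * len(cpgs), eaf=[0.4] * len(cpgs))
            .assign(cpg_id=cpgs),
            make_summary(["inst2"] * len(cpgs), [0.001] * len(cpgs),
                         [0.001] * len(cpgs), eaf=[0.3] * len(cpgs))
            .assign(cpg_id=cpgs)])
        return ewas, mqtl, gwas, trans

    def test_perfect_prediction_gives_r_one(self):
        rng = np.random.default_rng(3)
        n = 12
        b_ewas = rng.normal(0.01, 0.004, n)
        ewas, mqtl, gwas, trans = self.build_inputs(b_ewas)
        # make the observed IL-6 effect exactly the predicted one
        gwas = gwas.set_index("snp_id")
        for cpg, b in zip(ewas["cpg_id"], b_ewas):
            gwas.loc[f"rs_{cpg}", "beta"] = 0.1 / b
        gwas = gwas.reset_index()
        cons, caus = triangulate(ewas, mqtl, gwas, trans,
                                 ["inst1", "inst2"])
        assert cons.r == pytest.approx(1.0, abs=1e-12)

    def test_zero_ewas_effect_excluded_with_reason(self):
        ewas, mqtl, gwas, trans = self.build_inputs([0.01, 0.0])
        cons, _ = triangulate(ewas, mqtl, gwas, trans, ["inst1", "inst2"])
        assert cons.exclusions == {"cg1": "zero EWAS effect"}

    def test_cpg_without_gwas_record_counted(self):
        ewas, mqtl, gwas, trans = self.build_inputs([0.01, 0.02])
        gwas = gwas[gwas["snp_id"] != "rs_cg0"]
        cons, _ = triangulate(ewas, mqtl, gwas, trans, ["inst1", "inst2"])
        assert "cg0" in cons.exclusions


class TestMediate:
    def leg(self, beta, se):
        return {"beta": beta, "se": se}

    def test_zero_a_means_no_mediation(self):
        rows = mediate([{"cpg_id": "c", "trait": "t",
                         "a": self.leg(0.0, 0.1), "b": self.leg(0.4, 0.2),
                         "c": self.leg(0.5, 0.1)}])
        r = rows.iloc[0]
        assert r["indirect"] == 0.0
        assert r["direct"] == 0.5
        assert r["p_indirect"] == 1.0

    def test_sobel_closed_form(self):
        rows = mediate([{"cpg_id": "c", "trait": "t",
                         "a": self.leg(0.5, 0.1), "b": self.leg(0.4, 0.2),
                         "c": self.leg(0.3, 0.1)}])
        r = rows.iloc[0]
        assert r["indirect"] == pytest.approx(0.2)
        assert r["se_indirect"] == pytest.approx(np.sqrt(0.0116))
        assert r["se_indirect"] == pytest.approx(0.1077, abs=2e-4)

    def test_second_order_delta_adds_cross_term(self):
        legs = [{"cpg_id": "c", "trait": "t",
                 "a": self.leg(0.5, 0.1), "b": self.leg(0.4, 0.2),
                 "c": self.leg(0.3, 0.1)}]
        r2 = mediate(legs, second_order=True).iloc[0]
        assert r2["se_indirect"] == pytest.approx(
            np.sqrt(0.0116 + 0.01 * 0.04))

    def test_decomposition_is_exact(self, rng):
        legs = [{"cpg_id": f"c{i}", "trait": "t",
                 "a": self.leg(rng.normal(), 0.1),
                 "b": self.leg(rng.normal(), 0.1),
                 "c": self.leg(rng.normal(), 0.1)} for i in range(20)]
        rows = mediate(legs)
        assert np.allclose(rows["indirect"] + rows["direct"], rows["c"],
                           atol=0.0)

    def test_missing_leg_skipped_with_reason(self):
        rows = mediate([{"cpg_id": "c", "trait": "t", "a": None,
                         "b": self.leg(0.4, 0.2), "c": self.leg(0.3, 0.1)}])
        assert len(rows) == 0
        assert rows.attrs["skipped"][0]["reason"] == "missing leg"

    def test_fdr_within_trait(self):
        legs = []
        for t in ("t1", "t2"):
            for i in range(4):
                legs.append({"cpg_id": f"c{i}", "trait": t,
                             "a": self.leg(0.5, 0.01),
                             "b": self.leg(0.4, 0.01),
                             "c": self.leg(0.3, 0.1)})
        rows = mediate(legs)
        for t, grp in rows.groupby("trait"):
            assert np.allclose(
                grp["q_fdr"], meta.bh_fdr(grp["p_indirect"].clip(
                    lower=np.nextafter(0, 1))))


class TestGeneticLayerRecovery:
    def test_reverse_mr_recovers_sign_with_strong_instruments(
            self, small_sim, small_layer, small_config):
        """2SMR on reverse-truth CpGs recovers the causal sign."""
        _, truth = small_sim
        layer = small_layer
        rev = truth[truth["direction"] == "reverse"].set_index("cpg_id")
        mr_df = bidirectional_mr(
            layer.mqtl[layer.mqtl["cpg_id"].isin(rev.index)],
            layer.il6_gwas,
            layer.trans_mqtl.iloc[0:0],
            layer.ld, layer.instruments)
        mr_df = mr_df[mr_df["direction"] == "reverse"]
        assert len(mr_df) == len(rev)
        signs = [np.sign(b) == np.sign(rev.loc[c, "true_effect"])
                 for c, b in zip(mr_df["cpg_id"], mr_df["beta"])]
        assert np.mean(signs) >= 0.9

    def test_forward_mr_finds_forward_not_null(self, small_sim,
                                               small_layer):
        _, truth = small_sim
        layer = small_layer
        mr_df = bidirectional_mr(layer.mqtl.iloc[0:0], layer.il6_gwas,
                                 layer.trans_mqtl, layer.ld,
                                 layer.instruments)
        merged = mr_df.merge(truth, on="cpg_id")
        fwd_hit = merged.loc[merged["direction_y"] == "forward",
                             "significant"]
        null_hit = merged.loc[merged["direction_y"] == "null",
                              "significant"]
        assert fwd_hit.mean() > 0.5
        assert null_hit.mean() < 0.1
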