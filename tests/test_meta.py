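"""Fixed-effects pooling, heterogeneity, FDR and DMR calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
import statsmodels.api as sm

from methylink.meta import (attenuation_filter, bh_fdr, call_dmrs,
                            heterogeneity_filter, ivw, ivw_pool,
                            pool_cohorts)


class TestIvw:
    def test_single_study_passes_through(self):
        beta, se, q = ivw([0.5], [0.1])
        assert (beta, se, q) == (0.5, 0.1, 0.0)

    def test_two_study_closed_form(self):
        beta, se, q = ivw([1.0, 3.0], [1.0, 1.0])
        assert beta == pytest.approx(2.0)
        assert se == pytest.approx(1 / np.sqrt(2))
        assert q == pytest.approx(2.0)
        rec = ivw_pool(pd.DataFrame({"beta": [1.0, 3.0], "se": [1, 1],
                                     "n": [10, 10]}))
        assert rec["I2"] == pytest.approx(50.0)

    def test_identical_records_have_no_heterogeneity(self):
        rec = ivw_pool(pd.DataFrame({"beta": [0.2] * 3, "se": [0.05] * 3,
                                     "n": [10] * 3}))
        assert rec["Q"] == pytest.approx(0.0)
        assert rec["I2"] == 0.0

    @given(st.lists(st.tuples(st.floats(-5, 5),
                              st.floats(0.01, 2)), min_size=2, max_size=8))
    @settings(deadline=None, derandomize=True)
    def test_matches_wls_oracle_and_order_invariance(self, studies):
        betas = [b for b, _ in studies]
        ses = [s for _, s in studies]
        beta, se, _ = ivw(betas, ses)
        fit = sm.WLS(betas, np.ones(len(betas)),
                     weights=1 / np.asarray(ses) ** 2).fit()
        assert beta == pytest.approx(fit.params[0], abs=1e-10)
        rev = ivw(betas[::-1], ses[::-1])
        assert rev[0] == pytest.approx(beta, abs=1e-12)
        assert rev[1] == pytest.approx(se, abs=1e-12)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            ivw([], [])
        with pytest.raises(ValueError):
            ivw([1.0], [0.0])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.5], [0.002, 0.5]),
    ])
    def test_hand_computed_examples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_matches_brute_force_definition(self, p):
        # q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values
        p = np.asarray(p)
        m = p.size
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)


class TestHeterogeneityFilter:
    def records(self, i2s):
        return pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(len(i2s))],
                             "I2": i2s})

    def test_boundary_is_kept_under_strict_default(self):
        kept, removed = heterogeneity_filter(self.records([90.0]))
        assert len(kept) == 1 and len(removed) == 0
        kept, removed = heterogeneity_filter(self.records([90.0]),
                                             strict=False)
        assert len(kept) == 0 and len(removed) == 1

    def test_high_heterogeneity_removed(self):
        kept, removed = heterogeneity_filter(self.records([95.0, 10.0]))
        assert list(removed["cpg_id"]) == ["cg0"]

    def test_planted_discordant_cpg_is_the_one_removed(self):
        cohorts = {
            c: pd.DataFrame({
                "cpg_id": ["stable", "wild"],
                "beta": [0.1, b],
                "se": [0.02, 0.02],
                "n": [100, 100],
            }) for c, b in zip("ABC", [0.5, -0.5, 0.02])}
        pooled = pool_cohorts(cohorts)
        kept, removed = heterogeneity_filter(pooled)
        assert list(removed["cpg_id"]) == ["wild"]
        assert list(kept["cpg_id"]) == ["stable"]


class TestPoolCohorts:
    def test_direction_string_follows_cohort_order(self):
        cohorts = {
            "A": pd.DataFrame({"cpg_id": ["cg1"], "beta": [0.2],
                               "se": [0.1], "n": [50]}),
            "B": pd.DataFrame({"cpg_id": ["cg1"], "beta": [-0.1],
                               "se": [0.1], "n": [60]}),
            "C": pd.DataFrame({"cpg_id": ["cg2"], "beta": [0.3],
                               "se": [0.1], "n": [70]}),
        }
        pooled = pool_cohorts(cohorts).set_index("cpg_id")
        assert pooled.loc["cg1", "direction"] == "+-?"
        assert pooled.loc["cg2", "direction"] == "??+"
        assert pooled.loc["cg1", "n_total"] == 110


class TestAttenuationFilter:
    def frame(self, cpgs, qs, betas=None):
        betas = betas if betas is not None else np.linspace(0.1, 0.5,
                                                            len(cpgs))
        return pd.DataFrame({"cpg_id": cpgs, "q_fdr": qs, "beta": betas})

    def test_boundary_follows_q_ge_alpha_rule(self):
        base = self.frame(["a", "b"], [0.01, 0.01])
        adj = self.frame(["a", "b"], [0.04, 0.05])
        res = attenuation_filter(base, adj)
        assert list(res.kept["cpg_id"]) == ["a"]
        assert res.reasons == {"b": "attenuated"}

    def test_identical_models_drop_nothing(self):
        base = self.frame(list("abc"), [0.01] * 3)
        res = attenuation_filter(base, base)
        assert len(res.dropped) == 0
        assert res.effect_correlation == pytest.approx(1.0)

    def test_untested_cpg_dropped_with_reason(self):
        base = self.frame(["a", "b"], [0.01, 0.01])
        adj = self.frame(["a"], [0.001])
        res = attenuation_filter(base, adj)
        assert res.reasons["b"] == "untested"


class TestCallDmrs:
    @staticmethod
    def probes(rows):
        return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos",
                                           "significant"])

    def test_no_significant_cpgs(self):
        p = self.probes([("a", "chr1", 100, False),
                         ("b", "chr1", 500, False)])
        dmrs, loci = call_dmrs(p)
        assert dmrs == [] and loci == 0

    def test_hand_traced_chain_with_internal_non_dmp(self):
        p = self.probes([("a", "chr1", 100, True),
                         ("b", "chr1", 500, True),
                         ("c", "chr1", 900, False),
                         ("d", "chr1", 1300, True)])
        dmrs, loci = call_dmrs(p)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.n_dmps, d.n_non_dmps) == (3, 1)
        assert d.member_cpgs == ["a", "b", "c", "d"]
        assert (d.start, d.end) == (99, 1300)
        assert loci == 3 - 3 + 1 == 1

    def test_gap_of_1kb_breaks_the_chain(self):
        p = self.probes([("a", "chr1", 100, True),
                         ("b", "chr1", 500, True),
                         ("c", "chr1", 1500, True)])
        dmrs, loci = call_dmrs(p)
        assert dmrs == []
        assert loci == 3

    def test_distinct_loci_direct_formula(self):
        # 10 DMPs, 6 of them inside 2 DMRs -> 10 - 6 + 2 = 6 loci
        rows = []
        for r, base in enumerate((10_000, 50_000)):
            for i in range(3):
                rows.append((f"r{r}_{i}", "chr2", base + 400 * i, True))
        for i in range(4):
            rows.append((f"iso{i}", "chr3", 10_000 + 5_000 * i, True))
        dmrs, loci = call_dmrs(self.probes(rows))
        assert len(dmrs) == 2
        assert loci == 10 - 6 + 2

    def test_non_dmp_budget_closes_region(self):
        rows = [("d0", "chr1", 100, True)]
        rows += [(f"n{i}", "chr1", 200 + 100 * i, False) for i in range(4)]
        rows += [(f"d{i}", "chr1", 700 + 100 * i, True) for i in range(1, 4)]
        dmrs, _ = call_dmrs(self.probes(rows))
        # the 4th consecutive non-DMP forces a restart; only the right-hand
        # run of three DMPs forms a region
        assert len(dmrs) == 1
        assert dmrs[0].n_dmps == 3
        assert dmrs[0].n_non_dmps == 0

    def test_unsorted_positions_rejected(self):
        p = self.probes([("a", "chr1", 500, True),
                         ("b", "chr1", 100, True)])
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(p)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_loci_never_exceed_dmps(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        pos = np.sort(r.choice(np.arange(100, 50_000, 50), n,
                               replace=False))
        sig = r.random(n) < 0.5
        p = self.probes([(f"c{i}", "chr1", int(pos[i]), bool(sig[i]))
                         for i in range(n)])
        dmrs, loci = call_dmrs(p)
        n_dmps = int(sig.sum())
        assert loci <= n_dmps
        assert (loci == n_dmps) == (len(dmrs) == 0)
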