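"""End-to-end pipeline driver and report generator.

Runs the whole analysis on synthetic data with known truth:
simulate -> per-cohort EWAS -> bias/inflation correction ->
fixed-effects meta-analysis -> heterogeneity / FDR / attenuation
filters -> DMR calling -> enrichment -> eQTM -> colocalisation ->
triangulation -> bidirectional MR -> mediation.  The report collects
the counts at every filter, the per-cohort bias/inflation estimates,
the triangulation correlations and the causal-inference tables, plus
an exclusion log naming every dropped record exactly once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bacon as bacon_mod
from . import causal, enrichment, integrate, meta, synthetic
from .config import PipelineConfig
from .ewas import ModelSpec, filter_probes, fit_ewas

__all__ = ["PipelineReport", "run_pipeline", "percentage"]


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """A printed percentage: ``round(100 * count / total, decimals)``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


@dataclass
class PipelineReport:
    seed: int
    counts: dict = field(default_factory=dict)
    bacon: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    triangulation: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    eqtm: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    mr: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    tables: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        def clean(x):
            if isinstance(x, dict):
                return {str(k): clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, (np.floating, float)):
                return round(float(x), 10)
            if isinstance(x, (np.integer, int)):
                return int(x)
            if isinstance(x, (np.bool_, bool)):
                return bool(x)
            return x

        doc = {k: clean(getattr(self, k)) for k in
               ("seed", "counts", "bacon", "correlations", "triangulation",
                "enrichment", "eqtm", "coloc", "mr", "mediation",
                "exclusions")}
        return json.dumps(doc, sort_keys=True, indent=1)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"CpGs tested:                 {c.get('tested', 0)}",
            f"FDR-significant (base):      {c.get('fdr_significant', 0)}",
            f"  removed, heterogeneity:    {c.get('heterogeneity_removed', 0)}",
            f"  removed, attenuation:      {c.get('attenuation_removed', 0)}",
            f"Final associated CpGs:       {c.get('significant_final', 0)}",
            f"DMRs / distinct loci:        {c.get('n_dmrs', 0)} / "
            f"{c.get('distinct_loci', 0)}",
            f"Triangulation R (causal):    "
            f"{self.triangulation.get('causal_r', float('nan')):.3f}",
            f"Triangulation R (conseq.):   "
            f"{self.triangulation.get('consequential_r', float('nan')):.3f}",
            f"Report hash:                 {self.hash[:16]}",
        ]
        return "\n".join(lines)


def _ewas_all_models(cohorts, cfg: PipelineConfig):
    """Fit base + sensitivity models in every cohort."""
    specs = {
        "base": ModelSpec("il6", frozenset(), cfg.thresholds.iqr_k),
        "cells": ModelSpec("il6", frozenset({"extended_cells"}),
                           cfg.thresholds.iqr_k),
        "smoking": ModelSpec("il6", frozenset({"smoking"}),
                             cfg.thresholds.iqr_k),
    }
    results: dict[str, dict[str, pd.DataFrame]] = {m: {} for m in specs}
    for cohort in cohorts:
        for model, spec in specs.items():
            results[model][cohort.name] = fit_ewas(cohort, spec,
                                                   cfg.lod_mode)
    return results


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full synthetic-data analysis.

    Deterministic given ``config``: rerunning with the same seed gives
    a byte-identical report (same hash).
    """
    cfg = config
    th = cfg.thresholds
    report = PipelineReport(seed=cfg.seed)

    # 1. simulate
    cohorts, truth = synthetic.simulate_cohorts(cfg.simulation)
    positions = truth[["cpg_id", "chrom", "pos"]]
    report.counts["n_cohorts"] = len(cohorts)
    report.counts["n_samples"] = int(sum(len(c.phenotypes) for c in cohorts))

    # 2. per-cohort EWAS, probe filters, bias/inflation correction
    results = _ewas_all_models(cohorts, cfg)
    adjusted: dict[str, dict[str, pd.DataFrame]] = {}
    for model, per_cohort in results.items():
        adjusted[model] = {}
        for cname, rec in per_cohort.items():
            rec = rec.dropna(subset=["beta", "se"])
            kept, flog = filter_probes(rec, min_n=th.min_n,
                                       positions=positions)
            for reason, n in flog.items():
                if n:
                    report.exclusions.append(
                        {"stage": f"probe_filter/{model}/{cname}",
                         "reason": reason, "n": int(n)})
            z = kept["beta"].to_numpy() / kept["se"].to_numpy()
            fit = bacon_mod.fit_null_mixture(
                z, n_iter=cfg.bacon.n_iter, burn_in=cfg.bacon.burn_in,
                seed=cfg.seed * 1000 + len(report.bacon),
                prior_alpha=cfg.bacon.prior_alpha,
                prior_beta=cfg.bacon.prior_beta,
                method=cfg.bacon.method)
            adjusted[model][cname] = bacon_mod.adjust_statistics(kept, fit)
            if model == "base":
                report.bacon[cname] = {
                    "mu": fit.mu, "sigma": fit.sigma,
                    "lambda_median": fit.diagnostics["lambda_median"]}

    # 3. meta-analysis per model
    pooled = {m: meta.pool_cohorts(per) for m, per in adjusted.items()}
    base = pooled["base"]
    report.counts["tested"] = len(base)

    # 4. heterogeneity, FDR, attenuation
    base_kept, het_removed = meta.heterogeneity_filter(
        base, th.i2_max, th.i2_strict)
    for cpg in het_removed["cpg_id"]:
        report.exclusions.append({"stage": "heterogeneity", "id": cpg,
                                  "reason": f"I2 > {th.i2_max}"})
    base_kept = base_kept.copy()
    base_kept["q_fdr"] = meta.bh_fdr(base_kept["p"])
    sig = base_kept[base_kept["q_fdr"] < th.fdr_alpha]
    report.counts["fdr_significant"] = len(sig) + len(
        het_removed[het_removed["q_fdr"] < th.fdr_alpha])
    report.counts["heterogeneity_removed"] = int(
        (het_removed["q_fdr"] < th.fdr_alpha).sum())

    surviving = sig
    n_attenuated = 0
    for model in ("cells", "smoking"):
        res = meta.attenuation_filter(surviving, pooled[model],
                                      th.fdr_alpha)
        report.correlations[f"base_vs_{model}"] = res.effect_correlation
        for cpg, reason in res.reasons.items():
            report.exclusions.append({"stage": f"attenuation/{model}",
                                      "id": cpg, "reason": reason})
        n_attenuated += len(res.dropped)
        surviving = res.kept
    report.counts["attenuation_removed"] = n_attenuated
    report.counts["significant_final"] = len(surviving)
    final_cpgs = set(surviving["cpg_id"])
    report.counts["final_inverse"] = int((surviving["beta"] < 0).sum())
    tp = truth.set_index("cpg_id")
    report.counts["true_causal_recovered"] = int(
        (tp.loc[list(final_cpgs), "direction"] != "null").sum())

    # 5. DMRs and distinct loci
    probes = positions.assign(
        significant=positions["cpg_id"].isin(final_cpgs))
    dmrs, loci = meta.call_dmrs(probes)
    report.counts["n_dmrs"] = len(dmrs)
    report.counts["distinct_loci"] = int(loci)
    report.tables["dmrs"] = dmrs

    # 6. enrichment (traits, chromatin states)
    states, catalog_raw, gmt, universe = synthetic.simulate_annotations(
        truth, seed=cfg.seed)
    background = set(base["cpg_id"])
    catalog = enrichment.filter_catalog(catalog_raw)
    traits_df = enrichment.annotation_family_enrichment(
        final_cpgs, catalog.restrict(background), background)
    states_df = enrichment.annotation_family_enrichment(
        final_cpgs, enrichment.AnnotationCatalog(states).restrict(background),
        background)
    report.enrichment["traits"] = traits_df.drop(
        columns=["ci_low", "ci_high"]).to_dict("records")
    report.enrichment["states"] = states_df.drop(
        columns=["ci_low", "ci_high"]).to_dict("records")

    # 7. eQTM in the largest cohort
    big = max(cohorts, key=lambda c: len(c.phenotypes))
    counts, gene_table, linked = synthetic.simulate_expression(
        big, truth, seed=cfg.seed)
    log_expr = integrate.log2_cpm(counts)
    rin = pd.DataFrame(
        np.vstack([integrate.rank_inverse_normal(log_expr.loc[g])
                   for g in log_expr.index]),
        index=log_expr.index, columns=log_expr.columns)
    cov_cols = (["age_years"]
                + [f"cp_{c}" for c in synthetic._CELLS_12[:-1]])
    covs = big.phenotypes[cov_cols].copy()
    covs["sex_female"] = (big.phenotypes["sex"] == "F").astype(float)
    pairs = integrate.map_cis_pairs(
        positions[positions["cpg_id"].isin(final_cpgs)],
        gene_table, th.window)
    eqtm = integrate.fit_eqtm(pairs, rin, big.beta, covs)
    sig_eqtm = eqtm[eqtm["q_fdr"] < th.fdr_alpha]
    report.eqtm = {
        "pairs_tested": len(eqtm),
        "pairs_significant": len(sig_eqtm),
        "unique_cpgs": int(sig_eqtm["cpg_id"].nunique()),
        "unique_genes": int(sig_eqtm["gene_id"].nunique()),
        "inverse": int((sig_eqtm["beta"] < 0).sum()),
    }
    report.tables["eqtm"] = eqtm

    # 8. colocalisation on the significant pairs (+ a null comparison set)
    linked_set = (set(zip(linked["cpg_id"], linked["gene_id"]))
                  if len(linked) else set())
    n_coloc = 0
    coloc_rows = []
    for i, (_, pr) in enumerate(sig_eqtm.head(12).iterrows()):
        shared = (pr["cpg_id"], pr["gene_id"]) in linked_set
        m_df, e_df = synthetic.simulate_coloc_region(
            seed=cfg.seed * 100 + i, shared=shared)
        res = integrate.coloc_abf(m_df, e_df, *th.coloc_priors,
                                  pp4_threshold=th.pp4,
                                  cpg_id=pr["cpg_id"], gene_id=pr["gene_id"])
        n_coloc += res.colocalised
        coloc_rows.append({"cpg_id": pr["cpg_id"], "gene_id": pr["gene_id"],
                           "pp_h4": float(res.pp[4]),
                           "colocalised": bool(res.colocalised)})
    report.coloc = {"pairs_tested": len(coloc_rows),
                    "colocalised": int(n_coloc),
                    "results": coloc_rows}

    # 9. genetic layer: triangulation, bidirectional MR, mediation
    layer = synthetic.simulate_genetic_layer(truth, cfg.simulation)
    ewas_for_tri = surviving[["cpg_id", "beta"]]
    mqtl_final = layer.mqtl[layer.mqtl["cpg_id"].isin(final_cpgs)]
    trans_final = layer.trans_mqtl[
        layer.trans_mqtl["cpg_id"].isin(final_cpgs)]
    cons, caus = causal.triangulate(
        ewas_for_tri, mqtl_final, layer.il6_gwas, trans_final,
        layer.instruments, layer.ld)
    report.triangulation = {
        "causal_r": caus.r, "causal_p": caus.p,
        "consequential_r": cons.r, "consequential_p": cons.p,
        "n_cpgs_causal": len(caus.table),
        "n_cpgs_consequential": len(cons.table),
    }

    mr_df = causal.bidirectional_mr(mqtl_final, layer.il6_gwas,
                                    trans_final, layer.ld,
                                    layer.instruments, th.fdr_alpha)
    if len(mr_df):
        report.mr = {
            d: {"tested": int((mr_df["direction"] == d).sum()),
                "significant": int(((mr_df["direction"] == d)
                                    & mr_df["significant"]).sum())}
            for d in ("forward", "reverse")}
    report.tables["mr"] = mr_df

    med_cpgs = [c for c in final_cpgs
                if tp.loc[c, "mediating"]] or sorted(final_cpgs)[:5]
    il6_inst = layer.il6_gwas[
        layer.il6_gwas["snp_id"].isin(layer.instruments)]
    legs = []
    for trait, gwas in layer.trait_gwas.items():
        for cpg in sorted(med_cpgs):
            entry = {"cpg_id": cpg, "trait": trait,
                     "a": None, "b": None, "c": None}
            try:
                entry["a"] = causal.mr_estimate(
                    il6_inst, layer.trans_mqtl[
                        layer.trans_mqtl["cpg_id"] == cpg],
                    exposure="il6", outcome=cpg)
                entry["b"] = causal.mr_estimate(
                    layer.mqtl[layer.mqtl["cpg_id"] == cpg], gwas,
                    layer.ld, th.r2_max, exposure=cpg, outcome=trait)
                entry["c"] = causal.mr_estimate(
                    il6_inst, gwas, exposure="il6", outcome=trait)
            except ValueError:
                pass
            legs.append(entry)
    med = causal.mediate(legs, th.fdr_alpha)
    report.mediation = {
        "rows": len(med),
        "significant": int(med["significant"].sum()) if len(med) else 0,
        "skipped": len(med.attrs.get("skipped", [])) if len(med) else 0,
    }
    report.tables["mediation"] = med
    return report
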