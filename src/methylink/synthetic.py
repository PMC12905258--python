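"""Synthetic multi-cohort EWAS data with known causal structure.

Generates the full stack of inputs the pipeline consumes — three
cohorts of individual-level methylation and phenotypes shaped like the
KORA F4 / LLS / NTR trio (sample sizes 799/668/2894, age and IL-6
distributions matched to the published cohort characteristics), plus a
genetic summary-statistics layer (cis-mQTLs, an IL-6 GWAS with two
instrument SNPs, trait GWAS) whose SNP effects propagate along known
causal arrows.  A truth table records, per CpG, whether IL-6 drives
methylation (forward), methylation drives IL-6 (reverse), or neither,
so every downstream stage has a parameter-recovery oracle.

Methylation beta-values are generated on the logit scale and squashed
through the logistic function, guaranteeing [0, 1].  Cell-type
confounding operates through regulatory T-cell proportions, a
subpopulation invisible to the base six-cell adjustment but captured
by the extended twelve-cell panel — which is exactly the contrast the
sensitivity-attenuation filter is designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

from .ewas import CohortTable

__all__ = [
    "SimulationConfig",
    "GeneticLayer",
    "simulate_cohorts",
    "simulate_genetic_layer",
    "simulate_meta_summary",
    "simulate_annotations",
    "simulate_expression",
    "simulate_coloc_region",
]

# published cohort characteristics (KORA F4, LLS, NTR order)
_COHORT_NAMES = ("KORA", "LLS", "NTR")
_AGE = ((68.8, 4.4), (58.8, 6.7), (37.6, 12.7))
_FEMALE = (0.488, 0.518, 0.664)
_SMOKING = ((0.086, 0.477), (0.127, 0.307), (0.210, 0.554))  # current, never
_IL6_MEDIAN_IQR = ((1.51, 1.26), (0.63, 0.43), (1.00, 0.90))
_CRP_MEDIAN_IQR = ((1.47, 2.25), (2.00, 2.33), (1.41, 2.80))

# 12-cell extended panel (proportions sum to 1); neutrophils dominate
_CELLS_12 = ("bas", "bmem", "bnv", "cd4mem", "cd4nv", "cd8mem", "cd8nv",
             "eos", "mono", "neu", "nk", "treg")
_CELL_MEANS = np.array([0.005, 0.02, 0.03, 0.08, 0.07, 0.04, 0.04,
                        0.025, 0.08, 0.55, 0.06, 0.02])
_CELL_CONCENTRATION = 150.0

_Z75 = 0.6744897501960817  # standard normal 75th percentile


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of ln(X) from the median and IQR of lognormal X."""
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return float(np.log(median)), sigma


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic EWAS.

    Defaults mirror the published three-cohort design: cohort sizes
    799/668/2894, a 1.2% below-LOD rate, per-unit-ln(IL-6) effects on
    the beta-value scale with SD ``effect_sd``, and a cohort-level
    random perturbation of each causal slope (``heterogeneity_sd``)
    so the I2 filter has something to act on.
    """
    n_cohorts: int = 3
    n_per_cohort: tuple = (799, 668, 2894)
    n_cpgs: int = 2000
    n_causal_forward: int = 50
    n_causal_reverse: int = 10
    effect_sd: float = 0.01          # beta-value change per +1 ln(IL-6)
    noise_beta_sd: float = 0.02      # residual methylation SD (beta scale)
    reverse_meth_sd: float = 0.05    # latent methylation spread, reverse CpGs
    heterogeneity_sd: float = 0.0    # between-cohort slope perturbation
    n_heterogeneous: int = 0         # forward CpGs with 8x the spread above
    confounding_strength: float = 0.0  # Treg loading on ln(IL-6), in SD units
    n_confounded: int = 0            # null CpGs that also load on Tregs
    lod_fraction: float = 0.012      # quantile of IL-6 placed below LOD
    n_mediating: int = 10            # forward CpGs with a downstream-trait arm
    traits: tuple = ("crp", "bmi")
    n_mqtl_study: int = 27_000
    n_il6_gwas: int = 67_000
    n_trait_gwas: int = 300_000
    seed: int = 0

    def __post_init__(self):
        self.n_per_cohort = tuple(int(n) for n in self.n_per_cohort)
        if len(self.n_per_cohort) != self.n_cohorts:
            raise ValueError("n_per_cohort length must equal n_cohorts")
        if min(self.n_per_cohort) <= 0 or self.n_cpgs <= 0:
            raise ValueError("all sizes must be positive")
        if self.n_causal_forward + self.n_causal_reverse > self.n_cpgs:
            raise ValueError("more causal CpGs than CpGs")
        if not 0 <= self.lod_fraction < 1:
            raise ValueError("lod_fraction must lie in [0, 1)")

    @property
    def ln_il6_sd(self) -> float:
        """Pooled SD of ln(IL-6) across the three reference cohorts."""
        sds = [_lognormal_params(*_IL6_MEDIAN_IQR[c % 3])[1]
               for c in range(self.n_cohorts)]
        return float(np.sqrt(np.mean(np.square(sds))))


@dataclass
class GeneticLayer:
    mqtl: pd.DataFrame            # cis-mQTL, long format with cpg_id
    trans_mqtl: pd.DataFrame      # IL-6 instruments x CpGs
    il6_gwas: pd.DataFrame
    trait_gwas: dict
    ld: pd.DataFrame
    instruments: list


def _positions(rng, n_cpgs: int) -> pd.DataFrame:
    """CpG coordinates on chr1..chr22 with occasional sub-kb clusters."""
    chroms, pos = [], []
    per_chrom = int(np.ceil(n_cpgs / 22))
    placed = 0
    for c in range(1, 23):
        p = 100_000
        while placed < n_cpgs and len([x for x in chroms if x == f"chr{c}"]) < per_chrom:
            k = 1 if rng.random() < 0.7 else int(rng.integers(3, 7))
            p += int(rng.integers(2_000, 50_000))
            for _ in range(k):
                if placed >= n_cpgs:
                    break
                chroms.append(f"chr{c}")
                pos.append(p)
                placed += 1
                p += int(rng.integers(100, 800))
        if placed >= n_cpgs:
            break
    return pd.DataFrame({"chrom": chroms[:n_cpgs], "pos": pos[:n_cpgs]})


def _make_truth(rng, config: SimulationConfig) -> pd.DataFrame:
    n = config.n_cpgs
    cpg_ids = [f"cg{i:07d}" for i in range(n)]
    positions = _positions(rng, n)
    direction = np.array(["null"] * n, dtype=object)

    # seed some forward CpGs inside sub-kb probe clusters so that DMR
    # calling has regions to find; the remainder are placed at random
    fwd_pool: list[int] = []
    if config.n_causal_forward >= 3:
        gaps_ok = ((positions["chrom"].shift() == positions["chrom"])
                   & (positions["pos"].diff() < 1000)).to_numpy()
        run = 0
        runs = []
        for i, ok in enumerate(gaps_ok):
            run = run + 1 if ok else 0
            if run >= 2:                      # indices i-2..i form a run
                runs.append((i - 2, i))
        for start, end in runs[: max(1, config.n_causal_forward // 10)]:
            fwd_pool.extend(range(start, end + 1))
    fwd_pool = list(dict.fromkeys(fwd_pool))[: config.n_causal_forward]
    order = rng.permutation([i for i in range(n) if i not in set(fwd_pool)])
    need = config.n_causal_forward - len(fwd_pool)
    fwd = np.array(fwd_pool + list(order[:need]), dtype=int)
    rev = order[need: need + config.n_causal_reverse]
    direction[fwd] = "forward"
    direction[rev] = "reverse"

    true_effect = np.zeros(n)
    true_effect[fwd] = rng.normal(0.0, config.effect_sd, fwd.size)
    # reverse effects: ln(IL-6) change per +1 beta-value, bounded away
    # from zero so the genetic layer carries a usable signal
    true_effect[rev] = (rng.choice([-1.0, 1.0], rev.size)
                        * rng.uniform(0.4, 1.2, rev.size))

    baseline = rng.uniform(0.1, 0.9, n)
    causal = direction != "null"
    baseline[causal] = rng.uniform(0.25, 0.75, int(causal.sum()))

    confounded = np.zeros(n, dtype=bool)
    nulls = np.flatnonzero(direction == "null")
    n_conf = min(config.n_confounded, nulls.size)
    if n_conf:
        confounded[rng.choice(nulls, n_conf, replace=False)] = True

    mediating = np.zeros(n, dtype=bool)
    if config.n_mediating and fwd.size:
        top = fwd[np.argsort(-np.abs(true_effect[fwd]))]
        mediating[top[:config.n_mediating]] = True

    heterogeneous = np.zeros(n, dtype=bool)
    if config.n_heterogeneous and fwd.size:
        heterogeneous[fwd[-config.n_heterogeneous:]] = True
        # give the planted heterogeneous CpGs a clearly nonzero average
        # effect so they reach significance before the I2 filter sees them
        boost = np.abs(true_effect[heterogeneous]) < 2 * config.effect_sd
        true_effect[heterogeneous] = np.where(
            boost, np.sign(true_effect[heterogeneous] + 1e-12)
            * 2.5 * config.effect_sd, true_effect[heterogeneous])

    truth = positions.copy()
    truth.insert(0, "cpg_id", cpg_ids)
    truth["direction"] = direction
    truth["heterogeneous"] = heterogeneous
    truth["true_effect"] = true_effect
    truth["true_mqtl_effect"] = (rng.choice([-1.0, 1.0], n)
                                 * rng.uniform(0.03, 0.15, n))
    truth["mediating"] = mediating
    truth["confounded"] = confounded
    truth["baseline"] = baseline
    truth["conf_loading"] = np.where(
        confounded, rng.choice([-1.0, 1.0], n) * rng.uniform(0.01, 0.03, n),
        0.0)
    return truth


def _aggregate_cells(ph: pd.DataFrame) -> pd.DataFrame:
    """Six-cell summary of the twelve-cell panel (granulocytes pooled)."""
    ph = ph.copy()
    ph["cp_cd8t"] = ph["cp_cd8mem"] + ph["cp_cd8nv"]
    ph["cp_cd4t"] = ph["cp_cd4mem"] + ph["cp_cd4nv"] + ph["cp_treg"]
    ph["cp_bcell"] = ph["cp_bmem"] + ph["cp_bnv"]
    return ph


def simulate_cohorts(config: SimulationConfig):
    """Generate the cohorts and the ground-truth table.

    Returns ``(cohorts, truth)`` where ``cohorts`` is a list of
    :class:`~methylink.ewas.CohortTable` and ``truth`` one row per CpG.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(rng, config)
    m0 = truth["baseline"].to_numpy()
    lgt0 = logit(m0)
    deriv = m0 * (1.0 - m0)              # d expit / d eta at the baseline
    a = truth["true_effect"].to_numpy()
    fwd = (truth["direction"] == "forward").to_numpy()
    rev = (truth["direction"] == "reverse").to_numpy()
    conf_load = truth["conf_loading"].to_numpy()

    cohorts = []
    for c in range(config.n_cohorts):
        n = config.n_per_cohort[c]
        name = _COHORT_NAMES[c % 3] if config.n_cohorts <= 3 else f"C{c + 1}"
        ref = c % 3
        sid = pd.Index([f"{name}_{i:05d}" for i in range(n)], name="sample_id")

        age = rng.normal(*_AGE[ref], n)
        sex = np.where(rng.random(n) < _FEMALE[ref], "F", "M")
        u = rng.random(n)
        cur, nev = _SMOKING[ref]
        smoking = np.where(u < cur, "current",
                           np.where(u < cur + (1 - cur - nev), "former",
                                    "never"))
        cells = rng.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, n)
        treg = cells[:, _CELLS_12.index("treg")]
        z_treg = (treg - treg.mean()) / treg.std()

        mu_l, sd_l = _lognormal_params(*_IL6_MEDIAN_IQR[ref])
        rho = min(abs(config.confounding_strength), 0.95)
        eps = rng.normal(0.0, 1.0, n)
        ln_il6 = mu_l + sd_l * (np.sqrt(1 - rho**2) * eps
                                + np.sign(config.confounding_strength)
                                * rho * z_treg)

        # reverse CpGs: latent methylation first, then its push on IL-6
        eta = np.tile(lgt0, (n, 1))
        if rev.any():
            u_lat = rng.normal(0.0, config.reverse_meth_sd, (n, rev.sum()))
            eta[:, rev] += u_lat / deriv[rev]
            beta_rev_centred = expit(eta[:, rev]) - m0[rev]
            ln_il6 = ln_il6 + beta_rev_centred @ a[rev]

        # forward CpGs respond to realised ln(IL-6)
        slope = np.where(fwd, a, 0.0)
        if config.heterogeneity_sd:
            het_sd = np.where(truth["heterogeneous"].to_numpy(),
                              8.0 * config.heterogeneity_sd,
                              config.heterogeneity_sd)
            slope = slope + np.where(
                fwd, rng.normal(0.0, 1.0, config.n_cpgs) * het_sd, 0.0)
        centred_il6 = ln_il6 - ln_il6.mean()
        eta += np.outer(centred_il6, slope / deriv)
        eta += np.outer(z_treg, conf_load / deriv)
        eta += rng.normal(0.0, 1.0, (n, config.n_cpgs)) \
            * (config.noise_beta_sd / deriv)
        beta = expit(eta)

        mu_c, sd_c = _lognormal_params(*_CRP_MEDIAN_IQR[ref])
        z_il6 = (ln_il6 - ln_il6.mean()) / ln_il6.std()
        ln_crp = mu_c + sd_c * (0.5 * z_il6
                                + np.sqrt(0.75) * rng.normal(0, 1, n))

        il6 = np.exp(ln_il6)
        lod = (float(np.quantile(il6, config.lod_fraction))
               if config.lod_fraction > 0 else None)

        ph = pd.DataFrame({
            "il6_pg_ml": il6,
            "hscrp_mg_l": np.exp(ln_crp),
            "age_years": age,
            "sex": sex,
            "smoking": smoking,
            "plate": [f"P{1 + (i % 8)}" for i in range(n)],
        }, index=sid)
        for j, cell in enumerate(_CELLS_12):
            ph[f"cp_{cell}"] = cells[:, j]
        ph = _aggregate_cells(ph)

        beta_df = pd.DataFrame(beta.T, index=truth["cpg_id"].to_numpy(),
                               columns=sid)
        cohorts.append(CohortTable(name=name, phenotypes=ph, beta=beta_df,
                                   technical=("plate",), lod=lod))
    return cohorts, truth


_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


def _alleles(rng, k):
    idx = rng.integers(0, len(_ALLELE_PAIRS), k)
    return ([_ALLELE_PAIRS[i][0] for i in idx],
            [_ALLELE_PAIRS[i][1] for i in idx])


def _finish_stats(df: pd.DataFrame) -> pd.DataFrame:
    z = df["beta"] / df["se"]
    df["p"] = np.maximum(2.0 * ndtr(-np.abs(z)), 1e-300)
    return df


def simulate_genetic_layer(truth: pd.DataFrame,
                           config: SimulationConfig) -> GeneticLayer:
    """SNP-level summary statistics propagating the true causal arrows.

    Every CpG receives 1-5 cis-mQTL SNPs (EAF in (0.05, 0.95); the top
    SNP carries ``true_mqtl_effect`` on the beta-value scale).  Two
    SNPs instrument IL-6.  Effects flow along the truth: for forward
    CpGs the IL-6 instruments acquire trans-mQTL effects
    ``b_gwas * true_effect``; for reverse CpGs the cis-mQTL SNPs
    acquire IL-6 GWAS effects ``b_mqtl * true_effect``.  Sampling noise
    matches the stated study sizes.  The LD matrix is block-diagonal:
    within a CpG's SNP set, a tagged pair has r^2 = 0.9, all other
    pairs are independent.
    """
    if "true_mqtl_effect" not in truth.columns:
        raise ValueError("truth table missing true_mqtl_effect")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    sd_lnil6 = config.ln_il6_sd
    sd_meth_resid = 0.03

    instruments = ["rs_il6_a", "rs_il6_b"]
    inst_beta = np.array([0.08, 0.05])
    inst_eaf = np.array([0.40, 0.30])

    mqtl_rows, ld_blocks = [], []
    il6_rows = []
    trait_rows = {t: [] for t in config.traits}

    # trait arms: b (DNAm -> trait) per mediating CpG, and totals c
    b_arm = {}
    for t in config.traits:
        med = truth.loc[truth["mediating"], "cpg_id"]
        b_arm[t] = {cpg: s * u for cpg, s, u in zip(
            med, rng.choice([-1.0, 1.0], len(med)),
            rng.uniform(0.2, 0.6, len(med)))}
    a_by_cpg = dict(zip(truth["cpg_id"], truth["true_effect"]))
    fwd_mask = truth.set_index("cpg_id")["direction"] == "forward"
    c_total = {t: 0.3 + sum(a_by_cpg[cpg] * b for cpg, b in b_arm[t].items())
               for t in config.traits}

    for _, row in truth.iterrows():
        cpg = row["cpg_id"]
        k = int(rng.integers(1, 6))
        eaf = rng.uniform(0.05, 0.95, k)
        ea, oa = _alleles(rng, k)
        b_true = np.empty(k)
        b_true[0] = row["true_mqtl_effect"]
        if k > 1:
            b_true[1:] = rng.normal(0.0, 0.05, k - 1)
        snps = [f"rs_{cpg}_{i}" for i in range(k)]
        se_m = sd_meth_resid / np.sqrt(
            2.0 * eaf * (1 - eaf) * config.n_mqtl_study)
        bhat = b_true + rng.normal(0.0, se_m)
        for i in range(k):
            mqtl_rows.append({
                "cpg_id": cpg, "snp_id": snps[i], "effect_allele": ea[i],
                "other_allele": oa[i], "eaf": eaf[i], "beta": bhat[i],
                "se": se_m[i], "n": config.n_mqtl_study})
        # tagged pair (r^2 = 0.9) with probability 1/2 when k >= 2
        block = np.eye(k)
        if k >= 2 and rng.random() < 0.5:
            block[0, 1] = block[1, 0] = 0.9
        ld_blocks.append((snps, block))

        # these SNPs in the IL-6 GWAS: nonzero only on the reverse path
        path = b_true * row["true_effect"] if row["direction"] == "reverse" \
            else np.zeros(k)
        se_g = sd_lnil6 / np.sqrt(2.0 * eaf * (1 - eaf) * config.n_il6_gwas)
        g_hat = path + rng.normal(0.0, se_g)
        for i in range(k):
            il6_rows.append({
                "snp_id": snps[i], "effect_allele": ea[i],
                "other_allele": oa[i], "eaf": eaf[i], "beta": g_hat[i],
                "se": se_g[i], "n": config.n_il6_gwas})
        # and in the trait GWAS: through DNAm -> trait (b arm)
        for t in config.traits:
            b_t = b_arm[t].get(cpg, 0.0)
            se_t = 1.0 / np.sqrt(
                2.0 * eaf * (1 - eaf) * config.n_trait_gwas)
            t_hat = b_true * b_t + rng.normal(0.0, se_t)
            for i in range(k):
                trait_rows[t].append({
                    "snp_id": snps[i], "effect_allele": ea[i],
                    "other_allele": oa[i], "eaf": eaf[i], "beta": t_hat[i],
                    "se": se_t[i], "n": config.n_trait_gwas})

    # IL-6 instrument SNPs: GWAS effects, trans-mQTL effects, trait totals
    ea_i, oa_i = ("A", "G"), ("G", "A")
    se_gi = sd_lnil6 / np.sqrt(2.0 * inst_eaf * (1 - inst_eaf)
                               * config.n_il6_gwas)
    bhat_i = inst_beta + rng.normal(0.0, se_gi)
    for i, snp in enumerate(instruments):
        il6_rows.append({"snp_id": snp, "effect_allele": ea_i[i],
                         "other_allele": oa_i[i], "eaf": inst_eaf[i],
                         "beta": bhat_i[i], "se": se_gi[i],
                         "n": config.n_il6_gwas})
    trans_rows = []
    fwd_effect = truth["true_effect"].to_numpy() * fwd_mask.to_numpy()
    for i, snp in enumerate(instruments):
        se_tm = sd_meth_resid / np.sqrt(
            2.0 * inst_eaf[i] * (1 - inst_eaf[i]) * config.n_mqtl_study)
        tm_true = inst_beta[i] * fwd_effect
        tm_hat = tm_true + rng.normal(0.0, se_tm, config.n_cpgs)
        for cpg, b in zip(truth["cpg_id"], tm_hat):
            trans_rows.append({
                "cpg_id": cpg, "snp_id": snp, "effect_allele": ea_i[i],
                "other_allele": oa_i[i], "eaf": inst_eaf[i], "beta": b,
                "se": se_tm, "n": config.n_mqtl_study})
        for t in config.traits:
            se_ti = 1.0 / np.sqrt(2.0 * inst_eaf[i] * (1 - inst_eaf[i])
                                  * config.n_trait_gwas)
            trait_rows[t].append({
                "snp_id": snp, "effect_allele": ea_i[i],
                "other_allele": oa_i[i], "eaf": inst_eaf[i],
                "beta": inst_beta[i] * c_total[t]
                + rng.normal(0.0, se_ti),
                "se": se_ti, "n": config.n_trait_gwas})

    all_snps = [s for snps, _ in ld_blocks for s in snps] + instruments
    ld = pd.DataFrame(np.eye(len(all_snps)), index=all_snps,
                      columns=all_snps)
    for snps, block in ld_blocks:
        ld.loc[snps, snps] = block

    return GeneticLayer(
        mqtl=_finish_stats(pd.DataFrame(mqtl_rows)),
        trans_mqtl=_finish_stats(pd.DataFrame(trans_rows)),
        il6_gwas=_finish_stats(pd.DataFrame(il6_rows)),
        trait_gwas={t: _finish_stats(pd.DataFrame(r))
                    for t, r in trait_rows.items()},
        ld=ld,
        instruments=instruments,
    )


def simulate_meta_summary(truth: pd.DataFrame, config: SimulationConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Summary-level EWAS consistent with the truth table.

    A fast stand-in for running the full individual-level EWAS and
    meta-analysis: the pooled slope of each CpG is its implied
    association with ln(IL-6) (forward CpGs: the true effect; reverse
    CpGs: the regression-attenuated ``t * var(beta) / var(ln IL-6)``;
    null CpGs: zero) plus sampling noise at the pooled sample size.
    Used by the causal-layer calibration tests.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 211]))
    n_total = sum(config.n_per_cohort)
    var_il6 = config.ln_il6_sd**2
    d = truth["direction"].to_numpy()
    t = truth["true_effect"].to_numpy()
    var_meth = np.where(d == "reverse", config.reverse_meth_sd**2,
                        config.noise_beta_sd**2)
    beta_true = np.where(
        d == "forward", t,
        np.where(d == "reverse", t * var_meth / var_il6, 0.0))
    se = np.sqrt(var_meth) / (config.ln_il6_sd * np.sqrt(n_total))
    beta_hat = beta_true + rng.normal(0.0, se)
    out = pd.DataFrame({
        "cpg_id": truth["cpg_id"],
        "beta": beta_hat,
        "se": se,
        "n": n_total,
    })
    return _finish_stats(out)


def simulate_annotations(truth: pd.DataFrame, seed: int = 0,
                         enh_hit_rate: float = 0.35,
                         enh_bg_rate: float = 0.05):
    """Chromatin states, an EWAS-style trait catalog and a GMT library.

    Causal CpGs are preferentially placed in the enhancer state, and
    the trait catalog over-samples causal CpGs, so the enrichment
    stages have planted signal to recover.  Returns
    ``(state_members, trait_catalog_raw, gmt, gene_universe)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 409]))
    causal = (truth["direction"] != "null").to_numpy()
    cpgs = truth["cpg_id"].to_numpy()
    p_enh = np.where(causal, enh_hit_rate, enh_bg_rate)
    in_enh = rng.random(len(cpgs)) < p_enh
    states = {"Enh": set(cpgs[in_enh])}
    rest = cpgs[~in_enh]
    lab = rng.choice(["TssA", "Tx", "ReprPC", "Quies"], rest.size,
                     p=[0.15, 0.25, 0.2, 0.4])
    for s in ("TssA", "Tx", "ReprPC", "Quies"):
        states[s] = set(rest[lab == s])

    rows = []
    for pmid, (trait, (enr, bg)) in enumerate((
            ("CRP", (0.5, 0.03)), ("BMI", (0.3, 0.04)),
            ("aging", (0.1, 0.08)), ("tiny_study", (0.5, 0.03)))):
        p = np.where(causal, enr, bg)
        members = cpgs[rng.random(len(cpgs)) < p]
        n_study = 120 if trait == "tiny_study" else 5000
        for cpg in members:
            rows.append({"trait": trait, "cpg_id": cpg,
                         "sample_size": n_study,
                         "n_cpgs": max(len(members), 1),
                         "pubmed_id": 10_000_000 + pmid})
    catalog_raw = pd.DataFrame(rows)

    genes = [f"GENE{i}" for i in range(200)]
    gmt = {
        "IMMUNE_SIGNALLING": set(genes[:40]),
        "GLYCOLYSIS": set(genes[40:70]),
        "HOUSEKEEPING": set(genes[70:160]),
    }
    return states, catalog_raw, gmt, set(genes)


def simulate_expression(cohort: CohortTable, truth: pd.DataFrame,
                        seed: int = 0, n_genes_linked: int = 30,
                        n_genes_null: int = 40):
    """RNA-seq-like counts for genes placed near CpGs.

    Linked genes sit within 100 kb of a causal CpG and their log
    expression tracks methylation with a (mostly negative) slope;
    null genes are placed near null CpGs with no dependence.  Returns
    ``(counts, gene_table, linked_pairs)`` where ``linked_pairs`` holds
    the planted CpG-gene truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 613]))
    causal = truth[truth["direction"] != "null"]
    nulls = truth[truth["direction"] == "null"]
    n_link = min(n_genes_linked, len(causal))
    n_null = min(n_genes_null, len(nulls))
    src = pd.concat([causal.iloc[:n_link], nulls.iloc[:n_null]])
    linked_flag = np.r_[np.ones(n_link, bool), np.zeros(n_null, bool)]

    genes, gene_rows, linked_pairs = [], [], []
    counts = np.empty((len(src), cohort.beta.shape[1]), dtype=np.int64)
    samples = cohort.beta.columns
    for g, ((_, row), is_linked) in enumerate(zip(src.iterrows(),
                                                  linked_flag)):
        gid = f"GENE{g}"
        offset = int(rng.integers(5_000, 60_000)) * int(rng.choice([-1, 1]))
        start = max(0, row["pos"] + offset)
        gene_rows.append({"gene_id": gid, "chrom": row["chrom"],
                          "start": start, "end": start + 8_000})
        base = rng.uniform(4.0, 8.0)
        m = cohort.beta.loc[row["cpg_id"], samples].to_numpy()
        if is_linked:
            slope = float(rng.choice([-1.0, -1.0, -1.0, 1.0])
                          * rng.uniform(2.0, 4.0))
            linked_pairs.append({"cpg_id": row["cpg_id"], "gene_id": gid,
                                 "slope": slope})
        else:
            slope = 0.0
        log_mu = base + slope * (m - m.mean())
        counts[g] = rng.poisson(np.exp(log_mu))
        genes.append(gid)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    return counts_df, pd.DataFrame(gene_rows), pd.DataFrame(linked_pairs)


def simulate_coloc_region(seed: int, shared: bool, n_snps: int = 60,
                          z_causal: float = 8.0):
    """A pair of regional association signals for colocalisation.

    ``shared=True`` plants one causal SNP driving both traits (H4);
    ``shared=False`` plants distinct causal SNPs (H3).  Returns
    ``(mqtl_df, eqtl_df)`` in the SummaryStats dialect with unit trait
    variance and n = 10,000.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 811]))
    n_study = 10_000
    eaf = rng.uniform(0.1, 0.9, n_snps)
    ea, oa = _alleles(rng, n_snps)
    se = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * n_study)
    snps = [f"rs_region_{i}" for i in range(n_snps)]
    i1 = int(rng.integers(0, n_snps))
    i2 = i1 if shared else int((i1 + 1 + rng.integers(0, n_snps - 1))
                               % n_snps)
    z1 = rng.normal(0.0, 1.0, n_snps)
    z2 = rng.normal(0.0, 1.0, n_snps)
    z1[i1] += z_causal
    z2[i2] += z_causal
    mk = lambda z: _finish_stats(pd.DataFrame({
        "snp_id": snps, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": z * se, "se": se, "n": n_study}))
    return mk(z1), mk(z2)
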