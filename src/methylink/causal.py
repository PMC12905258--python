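"""Summary-statistics causal inference between IL-6 and DNA methylation.

Three complementary procedures:

* **Triangulation** — correlates observed instrument-outcome effects
  with effects predicted through the exposure, in both directions
  (DNAm -> IL-6 via top cis-mQTLs; IL-6 -> DNAm via a two-SNP polygenic
  score), summarised as a Pearson R per direction.
* **Bidirectional two-sample MR** — Wald ratio for single instruments,
  fixed-effect IVW for multiple independent instruments, after allele
  harmonisation and LD clumping.
* **Two-step MR mediation** — decomposes the total genetically
  predicted effect of IL-6 on a trait (c) into an indirect path through
  methylation (a x b, delta-method SE) and a direct remainder (c - ab).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr, ivw as _ivw_pool

__all__ = [
    "MrEstimate",
    "TriangulationResult",
    "MediationRow",
    "harmonise",
    "clump",
    "wald_ratio",
    "ivw",
    "mr_estimate",
    "bidirectional_mr",
    "eaf_weights",
    "triangulate",
    "mediate",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_EAF = (0.42, 0.58)


@dataclass
class MrEstimate:
    exposure: str
    outcome: str
    method: str                 # "wald" or "ivw"
    beta: float
    se: float
    p: float
    n_snps: int
    instrument_ids: list
    q_fdr: float = float("nan")


@dataclass
class TriangulationResult:
    direction: str              # "consequential" (DNAm -> IL-6) or "causal"
    table: pd.DataFrame         # cpg_id, observed, predicted
    r: float
    p: float
    n_excluded: int
    exclusions: dict = field(default_factory=dict)


@dataclass
class MediationRow:
    cpg_id: str
    trait: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float
    se_indirect: float
    direct: float
    p_indirect: float
    q_fdr: float = float("nan")


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def harmonise(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_eaf: tuple = PALINDROMIC_EAF):
    """Align outcome summary stats to the exposure's effect alleles.

    Shared SNPs with identical allele pairs pass unchanged; swapped
    pairs flip the outcome beta sign and EAF; incompatible allele sets
    are dropped.  Palindromic SNPs (A/T or C/G) whose exposure or
    outcome EAF lies inside ``palindromic_eaf`` are dropped as strand
    ambiguous.  Returns ``(aligned, log)`` where ``aligned`` carries
    exposure columns suffixed ``_exp`` and outcome columns ``_out``,
    and ``log`` records one action per shared SNP.
    """
    merged = exposure.merge(outcome, on="snp_id", suffixes=("_exp", "_out"))
    rows, log = [], []
    lo, hi = palindromic_eaf
    for _, r in merged.iterrows():
        ea_e, oa_e = r["effect_allele_exp"], r["other_allele_exp"]
        ea_o, oa_o = r["effect_allele_out"], r["other_allele_out"]
        if {ea_e, oa_e} != {ea_o, oa_o}:
            log.append({"snp_id": r["snp_id"], "action": "dropped",
                        "reason": "incompatible alleles"})
            continue
        r = r.copy()
        if (ea_e, oa_e) == (ea_o, oa_o):
            action = "kept"
        else:  # swapped orientation
            r["beta_out"] = -r["beta_out"]
            r["eaf_out"] = 1.0 - r["eaf_out"]
            r["effect_allele_out"], r["other_allele_out"] = ea_e, oa_e
            action = "flipped"
        if _is_palindromic(ea_e, oa_e) and (
                lo <= r["eaf_exp"] <= hi or lo <= r["eaf_out"] <= hi):
            log.append({"snp_id": r["snp_id"], "action": "dropped",
                        "reason": "palindromic, ambiguous EAF"})
            continue
        log.append({"snp_id": r["snp_id"], "action": action, "reason": ""})
        rows.append(r)
    aligned = (pd.DataFrame(rows).reset_index(drop=True)
               if rows else merged.iloc[0:0])
    return aligned, pd.DataFrame(log, columns=["snp_id", "action", "reason"])


def clump(stats_df: pd.DataFrame, ld: pd.DataFrame,
          r2_max: float = 0.001) -> pd.DataFrame:
    """Greedy LD clumping: keep the lowest-p SNP, drop correlated ones.

    ``ld`` is a symmetric r^2 matrix indexed by SNP id; a SNP missing
    from it is treated as independent and kept.  Iterates: retain the
    most significant remaining SNP, remove every SNP with r^2 > r2_max
    to it, repeat.
    """
    remaining = stats_df.sort_values(["p", "snp_id"]).reset_index(drop=True)
    kept_rows = []
    while len(remaining):
        top = remaining.iloc[0]
        kept_rows.append(top)
        if top["snp_id"] in ld.index:
            r2 = ld.loc[top["snp_id"]]
            linked = {s for s in remaining["snp_id"]
                      if s in r2.index and r2[s] > r2_max}
            linked.add(top["snp_id"])
        else:
            linked = {top["snp_id"]}
        remaining = remaining[~remaining["snp_id"].isin(linked)]
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def wald_ratio(exp_beta: float, exp_se: float, out_beta: float,
               out_se: float, exposure: str = "", outcome: str = "",
               snp_id: str = "", second_order: bool = False) -> MrEstimate:
    """Single-instrument causal estimate ``out_beta / exp_beta``.

    First-order SE ``out_se / |exp_beta|`` by default (the uncertainty
    of the instrument-exposure association is ignored, as is
    conventional for strong instruments); ``second_order=True`` adds
    the instrument-exposure term of the delta expansion.
    """
    if exp_beta == 0:
        raise ValueError("irrelevant instrument: exposure effect is zero")
    beta = out_beta / exp_beta
    se = out_se / abs(exp_beta)
    if second_order:
        se = float(np.sqrt(out_se**2 / exp_beta**2
                           + out_beta**2 * exp_se**2 / exp_beta**4))
    z = beta / se
    return MrEstimate(exposure, outcome, "wald", float(beta), float(se),
                      float(2.0 * stats.norm.sf(abs(z))), 1,
                      [snp_id] if snp_id else [])


def ivw(ratios: list[MrEstimate], exposure: str = "",
        outcome: str = "") -> MrEstimate:
    """Fixed-effect IVW combination of per-SNP Wald ratios.

    Weights are 1/se^2 — the same pooling rule as the EWAS
    meta-analysis.  A single ratio defers to the Wald estimate.
    """
    if len(ratios) == 1:
        r = ratios[0]
        return MrEstimate(exposure or r.exposure, outcome or r.outcome,
                          "wald", r.beta, r.se, r.p, 1, r.instrument_ids)
    beta, se, _ = _ivw_pool([r.beta for r in ratios], [r.se for r in ratios])
    z = beta / se
    ids = [i for r in ratios for i in r.instrument_ids]
    return MrEstimate(exposure, outcome, "ivw", beta, se,
                      float(2.0 * stats.norm.sf(abs(z))), len(ratios), ids)


def mr_estimate(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
                ld: pd.DataFrame | None = None, r2_max: float = 0.001,
                exposure: str = "", outcome: str = "") -> MrEstimate:
    """Full 2SMR for one exposure-outcome pair.

    Harmonises, clumps the instruments (if an LD matrix is given), and
    combines the per-SNP Wald ratios by IVW (or returns the single Wald
    ratio).  Raises if no usable instrument survives.
    """
    aligned, _ = harmonise(exposure_stats, outcome_stats)
    if aligned.empty:
        raise ValueError("no usable shared instruments after harmonisation")
    inst = aligned.rename(columns={"beta_exp": "beta", "se_exp": "se",
                                   "p_exp": "p"})
    if ld is not None:
        inst = clump(inst, ld, r2_max)
    ratios = []
    for _, r in inst.iterrows():
        if r["beta"] == 0:
            continue
        ratios.append(wald_ratio(r["beta"], r["se"], r["beta_out"],
                                 r["se_out"], exposure, outcome, r["snp_id"]))
    if not ratios:
        raise ValueError("all surviving instruments have zero exposure effect")
    return ivw(ratios, exposure, outcome)


def bidirectional_mr(mqtl: pd.DataFrame, il6_gwas: pd.DataFrame,
                     trans_mqtl: pd.DataFrame, ld: pd.DataFrame | None,
                     instruments: list[str],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-CpG 2SMR in both directions, FDR within each direction.

    Forward rows test IL-6 -> DNAm (IL-6 GWAS instruments, trans-mQTL
    outcomes); reverse rows test DNAm -> IL-6 (cis-mQTL instruments,
    IL-6 GWAS outcomes).  ``mqtl``/``trans_mqtl`` are long SummaryStats
    tables with a ``cpg_id`` column.
    """
    rows = []
    il6_inst = il6_gwas[il6_gwas["snp_id"].isin(instruments)]
    for cpg, cis in mqtl.groupby("cpg_id"):
        try:
            est = mr_estimate(cis, il6_gwas, ld, exposure=str(cpg),
                              outcome="il6")
            rows.append({"direction": "reverse", "cpg_id": cpg,
                         "method": est.method, "beta": est.beta,
                         "se": est.se, "p": est.p, "n_snps": est.n_snps})
        except ValueError:
            continue
    for cpg, trans in trans_mqtl.groupby("cpg_id"):
        try:
            est = mr_estimate(il6_inst, trans, None, exposure="il6",
                              outcome=str(cpg))
            rows.append({"direction": "forward", "cpg_id": cpg,
                         "method": est.method, "beta": est.beta,
                         "se": est.se, "p": est.p, "n_snps": est.n_snps})
        except ValueError:
            continue
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_fdr"] = np.nan
    for d in out["direction"].unique():
        m = out["direction"] == d
        out.loc[m, "q_fdr"] = bh_fdr(
            out.loc[m, "p"].clip(lower=np.nextafter(0, 1)))
    out["significant"] = out["q_fdr"] < alpha
    return out


def eaf_weights(eaf, mode: str = "allele_var") -> np.ndarray:
    """Instrument weights from effect allele frequencies.

    ``allele_var`` (default): w_k proportional to 2 EAF_k (1 - EAF_k),
    the per-allele genotype variance; ``plain``: w_k proportional to
    EAF_k.  Normalised to sum to 1.
    """
    eaf = np.asarray(eaf, dtype=float)
    if mode == "allele_var":
        w = 2.0 * eaf * (1.0 - eaf)
    elif mode == "plain":
        w = eaf.copy()
    else:
        raise ValueError(f"unknown EAF weighting mode {mode!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate EAF weights")
    return w / total


def _top_mqtl(cis: pd.DataFrame, ld: pd.DataFrame | None) -> pd.Series:
    """Most significant cis-mQTL after clumping; ties by |beta| then id."""
    if ld is not None:
        cis = clump(cis, ld)
    order = cis.assign(_abs=-cis["beta"].abs()).sort_values(
        ["p", "_abs", "snp_id"])
    return order.iloc[0]


def triangulate(ewas: pd.DataFrame, mqtl: pd.DataFrame,
                il6_gwas: pd.DataFrame, trans_mqtl: pd.DataFrame,
                instruments: list[str], ld: pd.DataFrame | None = None,
                eaf_mode: str = "allele_var"):
    """Bidirectional triangulation over the IL-6-associated CpGs.

    Consequential direction (DNAm -> IL-6): per CpG the observed effect
    is the top cis-mQTL's association with ln(IL-6) in the GWAS; the
    predicted effect is beta_mQTL / beta_EWAS (the instrument effect on
    methylation propagated through the inverted EWAS slope).

    Causal direction (IL-6 -> DNAm): the observed effect is the
    EAF-weighted combination of the IL-6 instrument SNPs' trans-mQTL
    effects on the CpG; the predicted effect is the equivalently
    weighted PGS effect on IL-6 times the EWAS slope.

    Each direction is summarised by Pearson R and its p-value over
    CpGs.  Returns ``(consequential, causal)`` TriangulationResults.
    """
    ewas = ewas.set_index("cpg_id")
    gwas = il6_gwas.set_index("snp_id")

    # --- consequential: observed mQTL->IL-6 vs predicted b_mQTL / b_EWAS
    cons_rows, cons_excl = [], {}
    for cpg, cis in mqtl.groupby("cpg_id"):
        if cpg not in ewas.index:
            cons_excl[cpg] = "no EWAS record"
            continue
        b_ewas = ewas.loc[cpg, "beta"]
        if b_ewas == 0:
            cons_excl[cpg] = "zero EWAS effect"
            continue
        top = _top_mqtl(cis, ld)
        if top["snp_id"] not in gwas.index:
            cons_excl[cpg] = "top mQTL absent from IL-6 GWAS"
            continue
        cons_rows.append({
            "cpg_id": cpg,
            "observed": float(gwas.loc[top["snp_id"], "beta"]),
            "predicted": float(top["beta"] / b_ewas),
        })
    consequential = _summarise_direction("consequential", cons_rows, cons_excl)

    # --- causal: observed PGS->DNAm vs predicted b_PGS * b_EWAS
    inst = [s for s in instruments if s in gwas.index]
    w = eaf_weights(gwas.loc[inst, "eaf"], eaf_mode)
    b_pgs = float(np.sum(w * gwas.loc[inst, "beta"].to_numpy()))
    trans = trans_mqtl[trans_mqtl["snp_id"].isin(inst)]
    caus_rows, caus_excl = [], {}
    for cpg, grp in trans.groupby("cpg_id"):
        if cpg not in ewas.index:
            caus_excl[cpg] = "no EWAS record"
            continue
        grp = grp.set_index("snp_id")
        if not set(inst).issubset(grp.index):
            caus_excl[cpg] = "incomplete trans-mQTL data"
            continue
        observed = float(np.sum(w * grp.loc[inst, "beta"].to_numpy()))
        caus_rows.append({
            "cpg_id": cpg,
            "observed": observed,
            "predicted": float(b_pgs * ewas.loc[cpg, "beta"]),
        })
    causal = _summarise_direction("causal", caus_rows, caus_excl)
    return consequential, causal


def _summarise_direction(name, rows, exclusions) -> TriangulationResult:
    table = pd.DataFrame(rows, columns=["cpg_id", "observed", "predicted"])
    if (len(table) >= 3 and table["observed"].nunique() > 1
            and table["predicted"].nunique() > 1):
        r, p = stats.pearsonr(table["observed"], table["predicted"])
    else:
        r, p = float("nan"), float("nan")
    return TriangulationResult(name, table, float(r), float(p),
                               len(exclusions), exclusions)


def mediate(legs: list[dict], alpha: float = 0.05,
            second_order: bool = False) -> pd.DataFrame:
    """Two-step MR mediation decomposition.

    Each entry of ``legs`` supplies, for one CpG x trait combination,
    MrEstimates (or dicts with ``beta``/``se``) for:

    * ``a`` — IL-6 -> DNAm at the CpG,
    * ``b`` — DNAm at the CpG -> trait,
    * ``c`` — total IL-6 -> trait,

    plus ``cpg_id`` and ``trait``.  The indirect (mediated) effect is
    ``a*b`` with first-order delta-method (Sobel) SE
    ``sqrt(a^2 se_b^2 + b^2 se_a^2)`` (``second_order=True`` adds the
    ``se_a^2 se_b^2`` term); the direct effect is ``c - a*b`` so the
    decomposition is exact.  The indirect p-value is a normal z-test;
    BH-FDR is applied per trait across CpGs.  A leg missing from an
    entry skips the row (logged in the returned attrs).
    """
    rows, skipped = [], []
    for leg in legs:
        if any(leg.get(k) is None for k in ("a", "b", "c")):
            skipped.append({"cpg_id": leg.get("cpg_id"),
                            "trait": leg.get("trait"),
                            "reason": "missing leg"})
            continue
        a, b, c = (_coerce(leg[k]) for k in ("a", "b", "c"))
        indirect = a[0] * b[0]
        var_ind = a[0]**2 * b[1]**2 + b[0]**2 * a[1]**2
        if second_order:
            var_ind += a[1]**2 * b[1]**2
        se_ind = float(np.sqrt(var_ind))
        if indirect == 0 or se_ind == 0:
            p_ind = 1.0
        else:
            p_ind = float(2.0 * stats.norm.sf(abs(indirect / se_ind)))
        rows.append({
            "cpg_id": leg["cpg_id"], "trait": leg["trait"],
            "a": a[0], "se_a": a[1], "b": b[0], "se_b": b[1],
            "c": c[0], "se_c": c[1],
            "indirect": indirect, "se_indirect": se_ind,
            "direct": c[0] - indirect, "p_indirect": p_ind,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_fdr"] = np.nan
        for t in out["trait"].unique():
            m = out["trait"] == t
            out.loc[m, "q_fdr"] = bh_fdr(
                out.loc[m, "p_indirect"].clip(lower=np.nextafter(0, 1)))
        out["significant"] = out["q_fdr"] < alpha
    out.attrs["skipped"] = skipped
    return out


def _coerce(est) -> tuple[float, float]:
    if isinstance(est, MrEstimate):
        return est.beta, est.se
    return float(est["beta"]), float(est["se"])
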