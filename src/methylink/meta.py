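"""Fixed-effects meta-analysis of per-cohort EWAS records.

Cohort-level per-CpG estimates are pooled by inverse-variance weighting
(the METAL fixed-effects scheme), screened for between-cohort
heterogeneity (Cochran's Q / I-squared), corrected for multiple testing
by Benjamini-Hochberg FDR, subjected to a sensitivity-attenuation
filter, and finally summarised into differentially methylated regions
(DMRs) and a count of distinct genomic loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ivw",
    "ivw_pool",
    "pool_cohorts",
    "bh_fdr",
    "heterogeneity_filter",
    "attenuation_filter",
    "AttenuationResult",
    "Dmr",
    "call_dmrs",
]


def ivw(betas, ses):
    """Inverse-variance-weighted fixed-effect pooling.

    Parameters
    ----------
    betas, ses : array-like
        Per-study effect sizes and standard errors (all SEs > 0, finite).

    Returns
    -------
    (beta_pooled, se_pooled, Q) : tuple of floats
        Pooled estimate, its standard error ``sqrt(1/sum(w))`` and
        Cochran's heterogeneity statistic ``Q = sum w_i (b_i - b)^2``
        with weights ``w_i = 1/se_i^2``.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no records to pool")
    if not np.all(np.isfinite(b)) or not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("effect sizes must be finite and SEs positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    return beta, se, q


def _i2(q: float, df: int) -> float:
    if df <= 0 or q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def ivw_pool(records: pd.DataFrame) -> dict:
    """Pool the cohort records of a single CpG.

    ``records`` needs columns ``beta``, ``se`` and optionally ``n``.
    Returns a dict with pooled beta/se, z, p, Q, I2 and n_total.
    A single cohort passes through unchanged with Q = 0, I2 = 0.
    """
    beta, se, q = ivw(records["beta"], records["se"])
    df = len(records) - 1
    z = beta / se
    return {
        "beta": beta,
        "se": se,
        "z": z,
        "p": max(2.0 * stats.norm.sf(abs(z)), 1e-300),
        "Q": q,
        "I2": _i2(q, df),
        "n_cohorts": len(records),
        "n_total": int(records["n"].sum()) if "n" in records else len(records),
    }


def pool_cohorts(cohort_records: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse EwasRecord tables from several cohorts.

    Parameters
    ----------
    cohort_records : dict
        Maps cohort name -> EwasRecord table (columns ``cpg_id``,
        ``beta``, ``se``, ``n``).  Cohort order fixes the order of the
        per-cohort direction string (METAL convention: ``+``/``-`` for
        the sign of the cohort effect, ``?`` when a CpG is missing).

    Returns
    -------
    DataFrame with one MetaRecord row per CpG: ``cpg_id, beta, se, z, p,
    q_fdr, Q, I2, direction, n_cohorts, n_total``.  ``q_fdr`` is the
    Benjamini-Hochberg q-value across all pooled CpGs.
    """
    names = list(cohort_records)
    stacked = pd.concat(
        [df.assign(_cohort=name) for name, df in cohort_records.items()],
        ignore_index=True,
    )
    rows = []
    for cpg, grp in stacked.groupby("cpg_id", sort=True):
        grp = grp.set_index("_cohort")
        rec = ivw_pool(grp)
        rec["cpg_id"] = cpg
        rec["direction"] = "".join(
            ("+" if grp.loc[c, "beta"] > 0 else "-") if c in grp.index else "?"
            for c in names
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    cols = ["cpg_id", "beta", "se", "z", "p", "Q", "I2",
            "direction", "n_cohorts", "n_total"]
    out = out[cols]
    out["q_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def heterogeneity_filter(records: pd.DataFrame, i2_max: float = 90.0,
                         strict: bool = True):
    """Split MetaRecords on between-cohort heterogeneity.

    ``strict=True`` removes ``I2 > i2_max`` (a CpG sitting exactly on
    the threshold is retained); ``strict=False`` removes ``I2 >= i2_max``.
    Returns ``(kept, removed)``.
    """
    i2 = records["I2"].to_numpy()
    bad = i2 > i2_max if strict else i2 >= i2_max
    return records.loc[~bad].copy(), records.loc[bad].copy()


@dataclass
class AttenuationResult:
    kept: pd.DataFrame
    dropped: pd.DataFrame
    effect_correlation: float
    reasons: dict = field(default_factory=dict)


def attenuation_filter(base: pd.DataFrame, adjusted: pd.DataFrame,
                       alpha: float = 0.05) -> AttenuationResult:
    """Drop hits that lose FDR significance in an adjusted model.

    ``base`` holds the FDR-significant MetaRecords of the base model;
    ``adjusted`` the records of the extended model (q_fdr recomputed
    within that model).  A CpG is dropped when its adjusted
    ``q_fdr >= alpha`` or when the adjusted model did not test it
    (reason ``"untested"``).  The Pearson correlation of effect sizes
    between models over jointly tested CpGs is reported alongside.
    """
    adj = adjusted.set_index("cpg_id")
    keep_mask, reasons = [], {}
    for cpg in base["cpg_id"]:
        if cpg not in adj.index:
            keep_mask.append(False)
            reasons[cpg] = "untested"
        elif adj.loc[cpg, "q_fdr"] >= alpha:
            keep_mask.append(False)
            reasons[cpg] = "attenuated"
        else:
            keep_mask.append(True)
    keep_mask = np.asarray(keep_mask)
    common = base[base["cpg_id"].isin(adj.index)]
    if len(common) >= 2:
        r = float(stats.pearsonr(
            common["beta"], adj.loc[common["cpg_id"], "beta"])[0])
    else:
        r = float("nan")
    return AttenuationResult(
        kept=base.loc[keep_mask].copy(),
        dropped=base.loc[~keep_mask].copy(),
        effect_correlation=r,
        reasons=reasons,
    )


@dataclass
class Dmr:
    chrom: str
    start: int          # 0-based, inclusive (BED convention on output)
    end: int            # 0-based half-open
    member_cpgs: list
    n_dmps: int
    n_non_dmps: int


def call_dmrs(probes: pd.DataFrame, max_gap: int = 1000, min_dmps: int = 3,
              max_non_dmps: int = 3):
    """Chain differentially methylated positions into regions.

    ``probes`` requires columns ``cpg_id, chrom, pos, significant`` for
    every *tested* CpG (positions 1-based); the chaining rule measures
    the gap between consecutive tested probes, so non-significant probes
    participate as potential in-region non-DMPs.

    A region grows left-to-right from a DMP while the next tested probe
    lies less than ``max_gap`` bp away and the running non-DMP count
    stays at or below ``max_non_dmps``; it is emitted when it contains
    at least ``min_dmps`` DMPs.  Leading/trailing non-DMPs are trimmed,
    so regions start and end on DMPs.

    Returns ``(dmrs, distinct_loci)`` where ``distinct_loci`` is
    ``#DMPs - #DMPs_in_DMRs + #DMRs``.
    """
    required = {"cpg_id", "chrom", "pos", "significant"}
    if not required.issubset(probes.columns):
        raise ValueError(f"probes table needs columns {sorted(required)}")
    dmrs: list[Dmr] = []
    n_dmps_total = int(probes["significant"].sum())
    n_dmps_in_dmrs = 0

    for chrom, grp in probes.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on {chrom}")
        sig = grp["significant"].to_numpy(dtype=bool)
        ids = grp["cpg_id"].to_numpy()

        members: list[int] = []   # indices into grp
        non_dmps = 0

        def close():
            nonlocal members, non_dmps, n_dmps_in_dmrs
            # trim trailing non-DMPs so the region ends on a DMP
            while members and not sig[members[-1]]:
                members.pop()
            k = sum(1 for i in members if sig[i])
            if k >= min_dmps:
                n_inside_non = len(members) - k
                dmrs.append(Dmr(
                    chrom=str(chrom),
                    start=int(pos[members[0]]) - 1,
                    end=int(pos[members[-1]]),
                    member_cpgs=[ids[i] for i in members],
                    n_dmps=k,
                    n_non_dmps=n_inside_non,
                ))
                n_dmps_in_dmrs += k
            members, non_dmps = [], 0

        for i in range(len(pos)):
            if not members:
                if sig[i]:
                    members, non_dmps = [i], 0
                continue
            gap = pos[i] - pos[i - 1]
            if gap >= max_gap:
                close()
                if sig[i]:
                    members, non_dmps = [i], 0
                continue
            if not sig[i] and non_dmps >= max_non_dmps:
                close()
                continue
            members.append(i)
            if not sig[i]:
                non_dmps += 1
        close()

    distinct_loci = n_dmps_total - n_dmps_in_dmrs + len(dmrs)
    return dmrs, distinct_loci
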