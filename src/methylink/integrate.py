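"""cis eQTM regression and approximate-Bayes-factor colocalisation.

Links CpGs to expression of nearby genes two ways: directly, by
regressing rank-inverse-normal transformed log2CPM expression on
methylation beta-values within a +/-100 kb window; and genetically, by
testing whether the mQTL and eQTL signals of a CpG-gene pair share a
single causal variant (Wakefield ABFs combined over the five standard
colocalisation hypotheses H0..H4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, ndtri

from .meta import bh_fdr

__all__ = [
    "rank_inverse_normal",
    "log2_cpm",
    "map_cis_pairs",
    "fit_eqtm",
    "ColocResult",
    "coloc_abf",
    "estimate_sdy",
]

BLOM_C = 3.0 / 8.0


def rank_inverse_normal(x, c: float = BLOM_C) -> np.ndarray:
    """Rank-based inverse-normal (RIN) transform, Blom offset c = 3/8.

    Maps value with (average, for ties) rank r among n observations to
    ``ndtri((r - c) / (n - 2c + 1))``.  Invariant under monotone
    transforms of the input; a constant vector is rejected.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("RIN transform undefined for a constant vector")
    r = stats.rankdata(x, method="average")
    return ndtri((r - c) / (x.size - 2.0 * c + 1.0))


def log2_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count.

    ``counts`` is genes x samples, nonnegative.  Per sample:
    ``log2((c + prior) / (libsize + 1) * 1e6)``.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples {bad}")
    return np.log2((counts + prior).div(lib + 1.0, axis=1) * 1e6)


def map_cis_pairs(cpgs: pd.DataFrame, genes: pd.DataFrame,
                  window: int = 100_000) -> pd.DataFrame:
    """All CpG-gene pairs whose gene body overlaps the cis window.

    ``cpgs``: ``cpg_id, chrom, pos`` (1-based); ``genes``: ``gene_id,
    chrom, start, end`` (0-based half-open).  A gene is paired when its
    body intersects ``[pos - window, pos + window)``; distance is 0 for
    a CpG inside the gene, else the gap to the nearest gene edge.
    Strand is ignored.
    """
    gene_chroms = set(genes["chrom"])
    cpg_chroms = set(cpgs["chrom"])
    if gene_chroms and cpg_chroms and not (gene_chroms & cpg_chroms):
        raise ValueError(
            "no shared chromosome names between CpGs and genes: "
            f"{sorted(cpg_chroms)[:5]} vs {sorted(gene_chroms)[:5]}")
    rows = []
    gb = genes.groupby("chrom")
    for chrom, grp in cpgs.groupby("chrom"):
        if chrom not in gb.groups:
            continue
        g = gb.get_group(chrom)
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        gid = g["gene_id"].to_numpy()
        for cpg, pos in zip(grp["cpg_id"], grp["pos"]):
            p0 = pos - 1  # 0-based coordinate of the CpG
            sel = (s < p0 + window) & (e > p0 - window)
            for j in np.nonzero(sel)[0]:
                if s[j] <= p0 < e[j]:
                    dist = 0
                elif p0 < s[j]:
                    dist = int(s[j] - p0)
                else:
                    dist = int(p0 - (e[j] - 1))
                rows.append({"cpg_id": cpg, "gene_id": gid[j],
                             "chrom": chrom, "distance_bp": dist})
    return pd.DataFrame(rows, columns=["cpg_id", "gene_id", "chrom",
                                       "distance_bp"])


def fit_eqtm(pairs: pd.DataFrame, expression: pd.DataFrame,
             methylation: pd.DataFrame,
             covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-pair OLS of expression on methylation beta-values.

    ``expression``: genes x samples (already transformed, e.g. RIN of
    log2CPM); ``methylation``: CpGs x samples; ``covariates``: samples
    x p numeric design (age, sex, cell types, technical), optional.
    Samples are intersected across inputs; fewer than 10 matched
    samples is an error.  Returns pairs with ``beta, se, p, n, q_fdr``
    (BH across all testable pairs); a constant-methylation pair is
    reported with NaNs and excluded from FDR.
    """
    samples = expression.columns.intersection(methylation.columns)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    if len(samples) < 10:
        raise ValueError(f"only {len(samples)} matched samples (need >= 10)")
    cov = (covariates.loc[samples].to_numpy(dtype=float)
           if covariates is not None else np.empty((len(samples), 0)))
    rows = []
    for _, pair in pairs.iterrows():
        cpg, gene = pair["cpg_id"], pair["gene_id"]
        if cpg not in methylation.index or gene not in expression.index:
            continue
        m = methylation.loc[cpg, samples].to_numpy(dtype=float)
        y = expression.loc[gene, samples].to_numpy(dtype=float)
        ok = np.isfinite(m) & np.isfinite(y)
        rec = {"cpg_id": cpg, "gene_id": gene,
               "distance_bp": pair.get("distance_bp", np.nan)}
        if np.unique(m[ok]).size < 2:
            rec.update(beta=np.nan, se=np.nan, p=np.nan, n=int(ok.sum()))
        else:
            X = np.column_stack([np.ones(ok.sum()), m[ok], cov[ok]])
            rec.update(_ols_slope(X, y[ok]))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q_fdr"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q_fdr"] = bh_fdr(
            out.loc[tested, "p"].clip(lower=np.nextafter(0, 1)))
    return out


def _ols_slope(X: np.ndarray, y: np.ndarray, idx: int = 1) -> dict:
    """Slope, SE and t-based p for column ``idx`` of design ``X``."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - rank
    if df <= 0:
        return {"beta": np.nan, "se": np.nan, "p": np.nan, "n": n}
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[idx, idx]))
    beta = float(coef[idx])
    if se == 0:
        return {"beta": beta, "se": se, "p": np.nan, "n": n}
    p = float(2.0 * stats.t.sf(abs(beta / se), df))
    return {"beta": beta, "se": se, "p": p, "n": n}


# ---------------------------------------------------------------------------
# colocalisation

@dataclass
class ColocResult:
    cpg_id: str
    gene_id: str
    pp: np.ndarray                      # H0..H4, sums to 1
    n_snps: int
    priors: tuple = (1e-4, 1e-4, 5e-6)
    colocalised: bool = False
    dropped_snps: list = field(default_factory=list)


def _wakefield_labf(beta, se, sd_prior):
    """Wakefield log approximate Bayes factor per SNP.

    With V = se^2, W = sd_prior^2, r = W/(V+W):
    ``lABF = 0.5 * (log(1 - r) + r * z^2)``.
    """
    v = np.asarray(se, dtype=float) ** 2
    z2 = (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2
    r = sd_prior**2 / (sd_prior**2 + v)
    return 0.5 * (np.log1p(-r) + r * z2)


def estimate_sdy(varbeta, eaf, n) -> float:
    """Trait SD from summary statistics (regression through the origin
    of ``2 n eaf (1-eaf)`` on ``1/varbeta``; sdY = sqrt(slope))."""
    oneover = 1.0 / np.asarray(varbeta, dtype=float)
    nvx = 2.0 * np.asarray(n, dtype=float) * np.asarray(eaf) * (1 - np.asarray(eaf))
    slope = float(np.sum(nvx * oneover) / np.sum(oneover**2))
    if slope <= 0:
        raise ValueError("could not estimate a positive trait variance")
    return float(np.sqrt(slope))


def coloc_abf(mqtl: pd.DataFrame, eqtl: pd.DataFrame,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 5e-6,
              sdy_mqtl: float = 1.0, sdy_eqtl: float = 1.0,
              prior_scale: float = 0.15, pp4_threshold: float = 0.9,
              cpg_id: str = "", gene_id: str = "") -> ColocResult:
    """Single-causal-variant colocalisation of two regional signals.

    ``mqtl`` and ``eqtl`` are SummaryStats tables over one region
    (columns ``snp_id, effect_allele, other_allele, beta, se``); SNPs
    are intersected on id, alleles harmonised (outcome flipped when
    swapped, incompatible SNPs dropped).  Per-SNP Wakefield log-ABFs
    with prior effect SD ``prior_scale * sdY`` feed the standard
    enumeration of hypotheses H0 (no signal) .. H4 (shared variant);
    the pair is flagged colocalised when PP(H4) > ``pp4_threshold``.
    """
    merged = mqtl.merge(eqtl, on="snp_id", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no shared SNPs between the two signals")
    dropped = []
    keep, beta2 = [], []
    for _, r in merged.iterrows():
        if (r["effect_allele_1"] == r["effect_allele_2"]
                and r["other_allele_1"] == r["other_allele_2"]):
            keep.append(True)
            beta2.append(r["beta_2"])
        elif (r["effect_allele_1"] == r["other_allele_2"]
                and r["other_allele_1"] == r["effect_allele_2"]):
            keep.append(True)
            beta2.append(-r["beta_2"])
        else:
            keep.append(False)
            dropped.append(r["snp_id"])
    merged = merged.loc[keep].assign(beta_2=beta2)
    n = len(merged)
    if n == 0:
        raise ValueError("no allele-compatible shared SNPs")
    if n < 25:
        warnings.warn(f"only {n} shared SNPs; colocalisation may be "
                      "unreliable below 25", stacklevel=2)
    l1 = _wakefield_labf(merged["beta_1"], merged["se_1"],
                         prior_scale * sdy_mqtl)
    l2 = _wakefield_labf(merged["beta_2"], merged["se_2"],
                         prior_scale * sdy_eqtl)
    s1, s2 = logsumexp(l1), logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + s1
    lh[2] = np.log(p2) + s2
    # H3: different causal SNPs -> sum over i != j
    both = s1 + s2
    with np.errstate(divide="ignore"):
        diff = both + np.log1p(-np.exp(np.clip(s12 - both, None, 0.0)))
    lh[3] = np.log(p1) + np.log(p2) + diff
    lh[4] = np.log(p12) + s12
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(
        cpg_id=cpg_id, gene_id=gene_id, pp=pp, n_snps=n,
        priors=(p1, p2, p12),
        colocalised=bool(pp[4] > pp4_threshold),
        dropped_snps=dropped,
    )
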