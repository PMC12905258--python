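"""Annotation enrichment for CpG hit sets and linked gene sets.

Three analysis families, each FDR-corrected separately:

* trait enrichment against a curated catalog of published EWAS hits
  (logistic regression of hit status on trait membership);
* chromatin-state enrichment against the array background
  (same logistic model, one state at a time);
* gene-set / TF-regulon over-representation (one-sided hypergeometric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .meta import bh_fdr

__all__ = [
    "AnnotationCatalog",
    "EnrichmentResult",
    "filter_catalog",
    "logistic_enrichment",
    "annotation_family_enrichment",
    "hypergeom_ora",
    "map_intervals_to_cpgs",
]


@dataclass
class AnnotationCatalog:
    """Binary CpG annotations: annotation id -> member CpG set."""
    members: dict[str, set]
    metadata: pd.DataFrame | None = None

    def restrict(self, background: set) -> "AnnotationCatalog":
        return AnnotationCatalog(
            {k: v & background for k, v in self.members.items()},
            self.metadata,
        )


@dataclass
class EnrichmentResult:
    annotation_id: str
    n_overlap: int
    pct_overlap: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q_fdr: float = float("nan")


def filter_catalog(raw: pd.DataFrame, min_sample_size: int = 500,
                   min_n_cpgs: int = 100, require_pubmed: bool = True,
                   synonyms: dict[str, str] | None = None) -> AnnotationCatalog:
    """Reduce a raw EWAS catalog to large, peer-reviewed studies.

    ``raw`` has one row per reported (study, CpG): columns ``trait``,
    ``cpg_id``, ``sample_size``, ``n_cpgs``, ``pubmed_id``.  Studies
    must have sample size *above* ``min_sample_size`` and report *over*
    ``min_n_cpgs`` CpGs (both strict).  ``synonyms`` recodes trait
    names before merging (e.g. {"body mass index": "BMI"}); merged
    traits take the union of member CpGs.
    """
    df = raw.copy()
    keep = (df["sample_size"] > min_sample_size) & (df["n_cpgs"] > min_n_cpgs)
    if require_pubmed and "pubmed_id" in df.columns:
        keep &= df["pubmed_id"].notna()
    df = df.loc[keep]
    if synonyms:
        df["trait"] = df["trait"].map(lambda t: synonyms.get(t, t))
    members = {t: set(g["cpg_id"]) for t, g in df.groupby("trait")}
    meta_cols = [c for c in ("trait", "sample_size", "n_cpgs", "pubmed_id")
                 if c in df.columns]
    return AnnotationCatalog(members, df[meta_cols].drop_duplicates())


def _two_by_two(hits: set, annotation: set, background: set):
    a = len(hits & annotation)                      # hit, annotated
    b = len(hits) - a                               # hit, not annotated
    anno_bg = len(annotation & background)
    c = anno_bg - a                                 # non-hit, annotated
    d = len(background) - len(hits) - c             # non-hit, not annotated
    return a, b, c, d


def logistic_enrichment(hits: set, annotation: set,
                        background: set) -> EnrichmentResult:
    """Odds ratio of annotation membership among hits vs background.

    Fits a logistic regression of the hit indicator on the annotation
    indicator over the full background (hits included, mirroring an
    array-wide enrichment test); with a binary covariate this equals
    the 2x2 cross-product ratio.  The aggregated 2x2 is fitted as a
    frequency-weighted binomial GLM, which is exact and fast.

    Zero cells trigger the Haldane-Anscombe 0.5 correction (warning);
    annotation covering the whole background is degenerate and raises.
    """
    if not hits <= background:
        raise ValueError("hit set must be a subset of the background")
    anno_bg = annotation & background
    if not anno_bg:
        raise ValueError("annotation does not intersect the background")
    if anno_bg == background:
        raise ValueError("annotation equals background; OR undefined")
    a, b, c, d = _two_by_two(hits, annotation, background)
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        warnings.warn("zero cell in 2x2 table; applying Haldane-Anscombe "
                      "0.5 correction", stacklevel=2)
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    # rows: (hit, annotated), (hit, plain), (bg-rest annotated), (bg-rest plain)
    endog = np.array([1.0, 1.0, 0.0, 0.0])
    exog = sm.add_constant(np.array([1.0, 0.0, 1.0, 0.0]))
    fit = sm.GLM(endog, exog, family=sm.families.Binomial(),
                 freq_weights=cells).fit()
    coef, se = fit.params[1], fit.bse[1]
    z = coef / se
    return EnrichmentResult(
        annotation_id="",
        n_overlap=a,
        pct_overlap=100.0 * a / len(hits) if hits else float("nan"),
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


def annotation_family_enrichment(hits: set, catalog: AnnotationCatalog,
                                 background: set) -> pd.DataFrame:
    """Run logistic enrichment for every annotation in one family.

    FDR is applied across the family only; families (traits, chromatin
    states, ...) are never pooled.
    """
    rows = []
    for name, members in sorted(catalog.members.items()):
        if not (members & background):
            continue
        try:
            res = logistic_enrichment(hits, members, background)
        except ValueError:
            continue
        res.annotation_id = name
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=[
            "annotation_id", "n_overlap", "pct_overlap", "odds_ratio",
            "ci_low", "ci_high", "p", "q_fdr"])
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["q_fdr"] = bh_fdr(df["p"].clip(lower=np.nextafter(0, 1)))
    return df


def hypergeom_ora(gene_set: set, library: dict[str, set],
                  universe: set) -> pd.DataFrame:
    """One-sided hypergeometric over-representation across a GMT library.

    The draw is ``gene_set & universe``; each term is intersected with
    the universe; p = P(X >= k) under sampling without replacement.
    BH-FDR across terms of the library.
    """
    if not universe:
        raise ValueError("empty universe")
    draws = gene_set & universe
    m = len(universe)
    rows = []
    for term, genes in sorted(library.items()):
        k_term = len(genes & universe)
        overlap = len(genes & draws)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_term, len(draws)))
        rows.append({
            "annotation_id": term,
            "n_overlap": overlap,
            "pct_overlap": 100.0 * overlap / len(draws) if draws else 0.0,
            "n_term": k_term,
            "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q_fdr"] = bh_fdr(df["p"].clip(lower=np.nextafter(0, 1)))
    return df


def map_intervals_to_cpgs(intervals: pd.DataFrame,
                          cpg_positions: pd.DataFrame) -> AnnotationCatalog:
    """Annotate CpGs by point-in-interval overlap.

    ``intervals``: BED-like table ``chrom, start, end, name`` (0-based
    half-open); ``cpg_positions``: ``cpg_id, chrom, pos`` (1-based).  A
    CpG at 1-based position p falls in [start, end) iff
    ``start <= p-1 < end``.
    """
    members: dict[str, set] = {}
    cp = cpg_positions.groupby("chrom")
    for (chrom, name), grp in intervals.groupby(["chrom", "name"]):
        if chrom not in cp.groups:
            continue
        cpgs = cp.get_group(chrom)
        p0 = cpgs["pos"].to_numpy() - 1
        hit = np.zeros(len(cpgs), dtype=bool)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            hit |= (p0 >= s) & (p0 < e)
        members.setdefault(name, set()).update(cpgs.loc[hit, "cpg_id"])
    return AnnotationCatalog(members)
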