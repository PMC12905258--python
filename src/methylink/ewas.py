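"""Per-cohort EWAS: preprocessing and linear-model association.

For each CpG, methylation beta-values are regressed on the natural log
of the circulating exposure (IL-6 in pg/mL or hsCRP in mg/L), adjusting
for age, sex, predicted immune cell-type proportions and technical
covariates; optional extensions add smoking, twelve extended cell
types, or the other inflammatory exposure.  Sub-LOD exposure values
are censored (removed or capped), and both exposure and per-CpG
methylation are screened with a 3 x IQR outlier rule before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "ModelSpec",
    "CensorReport",
    "censor_lod",
    "remove_iqr_outliers",
    "fit_ewas",
    "filter_probes",
    "BASE_CELLS",
    "EXTENDED_CELLS",
]

# IDOL 6-cell deconvolution; neutrophils excluded from designs to keep
# the proportion simplex full rank.
BASE_CELLS = ("cd8t", "cd4t", "nk", "mono", "bcell")
EXTENDED_CELLS = (
    "bas", "bmem", "bnv", "cd4mem", "cd4nv", "cd8mem", "cd8nv",
    "eos", "mono", "nk", "treg",
)  # 12-cell IDOL-extended panel minus neutrophils


@dataclass
class CohortTable:
    """Individual-level data for one cohort.

    ``phenotypes``: samples x variables (``il6_pg_ml``, ``hscrp_mg_l``,
    ``age_years``, ``sex`` in {F, M}, ``smoking`` in
    {current, former, never}, cell-proportion columns, technical
    factors); ``beta``: CpG x sample methylation matrix in [0, 1].
    """
    name: str
    phenotypes: pd.DataFrame
    beta: pd.DataFrame
    technical: tuple = ("plate",)
    lod: float | None = None

    def __post_init__(self):
        b = self.beta.to_numpy()
        if np.nanmin(b) < 0 or np.nanmax(b) > 1:
            raise ValueError("beta-values must lie in [0, 1]")
        if not self.beta.columns.equals(self.phenotypes.index):
            missing = self.beta.columns.difference(self.phenotypes.index)
            if len(missing):
                raise ValueError(f"samples without phenotypes: "
                                 f"{list(missing)[:5]}")
            self.beta = self.beta[self.phenotypes.index]


@dataclass(frozen=True)
class ModelSpec:
    """Covariate specification for one EWAS model."""
    exposure: str = "il6"                 # "il6" or "hscrp"
    adjust: frozenset = frozenset()       # of {"smoking", "extended_cells",
                                          #     "other_exposure"}
    iqr_k: float = 3.0

    def __post_init__(self):
        if self.exposure not in ("il6", "hscrp"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        extra = set(self.adjust) - {"smoking", "extended_cells",
                                    "other_exposure"}
        if extra:
            raise ValueError(f"unknown adjustments {sorted(extra)}")

    @property
    def exposure_column(self) -> str:
        return {"il6": "il6_pg_ml", "hscrp": "hscrp_mg_l"}[self.exposure]


@dataclass
class CensorReport:
    n_total: int
    n_removed: int
    mode: str

    @property
    def pct_removed(self) -> float:
        return round(100.0 * self.n_removed / self.n_total, 2)


def censor_lod(values, lod: float, mode: str = "remove"):
    """Censor exposure values below the assay limit of detection.

    ``mode="remove"`` sets sub-LOD values to NaN (left censoring by
    removal); ``mode="cap"`` raises them to the LOD.  Returns the
    censored vector and a :class:`CensorReport`.  All values below the
    LOD leaves no usable exposure and is an error.
    """
    if lod <= 0:
        raise ValueError("LOD must be positive")
    if mode not in ("remove", "cap"):
        raise ValueError(f"unknown censoring mode {mode!r}")
    v = pd.Series(values).astype(float)
    finite = v.notna()
    below = finite & (v < lod)
    if finite.any() and below.sum() == finite.sum():
        raise ValueError("all exposure values below the LOD")
    out = v.copy()
    if mode == "remove":
        out[below] = np.nan
    else:
        out[below] = lod
    n_removed = int(below.sum()) if mode == "remove" else 0
    return out, CensorReport(int(finite.sum()), n_removed, mode)


def remove_iqr_outliers(values, k: float = 3.0) -> np.ndarray:
    """Flag values more than k IQR beyond the nearest quartile.

    Quartiles use linear interpolation (type-7).  When the IQR is zero
    but distinct extremes exist, every value different from the
    constant quartile value is flagged.  NaNs are never flagged.
    Returns a boolean outlier mask.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values")
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    mask = np.zeros(v.shape, dtype=bool)
    if iqr == 0:
        mask[finite] = v[finite] != q1
        return mask
    if np.isinf(k):
        return mask
    mask[finite] = (v[finite] < q1 - k * iqr) | (v[finite] > q3 + k * iqr)
    return mask


def _design_matrix(cohort: CohortTable, spec: ModelSpec,
                   exposure: pd.Series) -> pd.DataFrame:
    ph = cohort.phenotypes
    cols = {"ln_exposure": np.log(exposure)}
    cols["age"] = ph["age_years"].astype(float)
    cols["sex_female"] = (ph["sex"] == "F").astype(float)
    cells = EXTENDED_CELLS if "extended_cells" in spec.adjust else BASE_CELLS
    for c in cells:
        col = f"cp_{c}"
        if col in ph.columns:
            cols[col] = ph[col].astype(float)
    X = pd.DataFrame(cols, index=ph.index)
    for t in cohort.technical:
        if t in ph.columns:
            d = pd.get_dummies(ph[t].astype("category"), prefix=t,
                               drop_first=True, dtype=float)
            X = X.join(d)
    if "smoking" in spec.adjust:
        d = pd.get_dummies(ph["smoking"].astype("category"),
                           prefix="smoking", drop_first=True, dtype=float)
        X = X.join(d)
    if "other_exposure" in spec.adjust:
        other = {"il6": "hscrp_mg_l", "hscrp": "il6_pg_ml"}[spec.exposure]
        X["ln_other"] = np.log(ph[other].astype(float))
    X.insert(0, "intercept", 1.0)
    return X


def _check_rank(X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    ok = np.all(np.isfinite(arr), axis=1)
    rank = np.linalg.matrix_rank(arr[ok])
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(arr[ok], j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_ewas(cohort: CohortTable, spec: ModelSpec,
             lod_mode: str = "remove") -> pd.DataFrame:
    """Ordinary-least-squares EWAS of one cohort under one model.

    The exposure is censored at the cohort LOD (if set), natural-log
    transformed, and screened cohort-wide with the 3 x IQR rule;
    methylation outliers are removed per CpG with the same rule, so the
    effective sample size varies by CpG.  Rows with missing covariates
    are dropped listwise.  Slopes on ln(exposure) are tested against
    the t reference with residual degrees of freedom.

    Returns an EwasRecord table: ``cpg_id, beta, se, p, n, mean_beta,
    se_mean``.
    """
    ph = cohort.phenotypes
    exposure = ph[spec.exposure_column].astype(float)
    report = None
    if cohort.lod is not None and spec.exposure == "il6":
        exposure, report = censor_lod(exposure, cohort.lod, lod_mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = exposure > 0
    exposure = exposure.where(pos)
    out_mask = remove_iqr_outliers(exposure, spec.iqr_k)
    exposure = exposure.mask(out_mask)
    if exposure.dropna().nunique() < 2:
        raise ValueError("exposure constant (or empty) after censoring "
                         "and outlier removal")
    X = _design_matrix(cohort, spec, exposure)
    keep = X.notna().all(axis=1)
    X = X.loc[keep]
    _check_rank(X)
    Xa = X.to_numpy(dtype=float)
    samples = X.index

    beta_mat = cohort.beta[samples]
    records = []
    for cpg, row in beta_mat.iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() >= 4:
            ok &= ~remove_iqr_outliers(np.where(ok, y, np.nan), spec.iqr_k)
        n = int(ok.sum())
        rec = {"cpg_id": cpg, "n": n}
        if n <= Xa.shape[1]:
            rec.update(beta=np.nan, se=np.nan, p=np.nan,
                       mean_beta=np.nan, se_mean=np.nan)
            records.append(rec)
            continue
        Xi, yi = Xa[ok], y[ok]
        coef, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ coef
        df = n - rank
        sigma2 = resid @ resid / df
        cov = np.linalg.pinv(Xi.T @ Xi)
        j = X.columns.get_loc("ln_exposure")
        se = float(np.sqrt(sigma2 * cov[j, j]))
        b = float(coef[j])
        p = float(2.0 * stats.t.sf(abs(b / se), df)) if se > 0 else np.nan
        rec.update(beta=b, se=se, p=p,
                   mean_beta=float(yi.mean()),
                   se_mean=float(yi.std(ddof=1) / np.sqrt(n)))
        records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["cohort"] = cohort.name
    out.attrs["model"] = spec
    if report is not None:
        out.attrs["censoring"] = report
    return out


def filter_probes(records: pd.DataFrame, min_n: int = 50,
                  exclude_ids: set | None = None,
                  blacklist: pd.DataFrame | None = None,
                  positions: pd.DataFrame | None = None,
                  sex_chromosomes: tuple = ("chrX", "chrY", "X", "Y")):
    """Remove unreliable probes from an EwasRecord table.

    Drops probes estimated from fewer than ``min_n`` participants
    (``n >= min_n`` is kept), probes named in ``exclude_ids`` (e.g.
    cross-reactive or polymorphic lists), probes on sex chromosomes and
    probes inside ``blacklist`` BED intervals (both need ``positions``:
    ``cpg_id, chrom, pos``).  Returns ``(kept, log)`` with removal
    counts per reason; removal reasons are assessed on the input, so a
    probe can be counted under several reasons.
    """
    log = {"low_n": 0, "excluded_id": 0, "sex_chromosome": 0,
           "blacklist": 0}
    drop = pd.Series(False, index=records.index)

    low = records["n"] < min_n
    log["low_n"] = int(low.sum())
    drop |= low

    if exclude_ids:
        listed = records["cpg_id"].isin(exclude_ids)
        log["excluded_id"] = int(listed.sum())
        drop |= listed

    if positions is not None:
        pos = positions.set_index("cpg_id")
        chrom = records["cpg_id"].map(pos["chrom"])
        sexchr = chrom.isin(sex_chromosomes)
        log["sex_chromosome"] = int(sexchr.sum())
        drop |= sexchr.fillna(False)
        if blacklist is not None:
            coord = records["cpg_id"].map(pos["pos"])
            in_bl = pd.Series(False, index=records.index)
            for _, iv in blacklist.iterrows():
                in_bl |= ((chrom == iv["chrom"])
                          & (coord - 1 >= iv["start"])
                          & (coord - 1 < iv["end"]))
            log["blacklist"] = int(in_bl.sum())
            drop |= in_bl
    kept = records.loc[~drop].copy()
    if kept.empty:
        import warnings
        warnings.warn("all probes removed by filters", stacklevel=2)
    return kept, log
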