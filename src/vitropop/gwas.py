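"""Association mapping of in vitro POD phenotypes.

Single-variant GWAS of a per-individual phenotype (by default log10 of
the posterior-median EC10) on minor-allele counts: MAF >= 0.05 filter,
ordinary least squares with additive allele effects adjusted for sex and
three genotype principal components, t-statistic p-values with suggestive
(1e-5) and genome-wide (5e-8) thresholds, genomic-control lambda and QQ
diagnostics, a GRM-based single-variance-component mixed-model (MLMA)
alternative run per ancestry group, and a sample-size-weighted z-score
meta-analysis combining the groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GenotypeMatrix

__all__ = [
    "SUGGESTIVE_P",
    "SIGNIFICANT_P",
    "filter_maf",
    "genotype_pcs",
    "snp_association",
    "genomic_lambda",
    "InflationReport",
    "grm",
    "mlma_association",
    "meta_z",
    "regional_view",
    "overlap_loci",
    "phenotype_from_pods",
]

SUGGESTIVE_P = 1e-5
SIGNIFICANT_P = 5e-8


def phenotype_from_pods(pod: pd.DataFrame, log10: bool = True) -> pd.Series:
    """GWAS phenotype from a POD table: log10 posterior-median EC10."""
    s = pod.set_index("cell_line_id")["ec10_median"].astype(float)
    return np.log10(s) if log10 else s


def _counts(gm: GenotypeMatrix) -> np.ndarray:
    return gm.genotypes.to_numpy(dtype=float)


def _maf(x: np.ndarray) -> np.ndarray:
    freq = np.nanmean(x, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def filter_maf(gm: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with minor allele frequency >= threshold.

    MAF is computed over non-missing calls across all samples; the
    retained matrix is re-coded so counts refer to the minor allele
    (column mean / 2 <= 0.5)."""
    x = _counts(gm)
    freq = np.nanmean(x, axis=0) / 2.0
    flip = freq > 0.5
    x = np.where(flip[None, :], 2.0 - x, x)
    maf = np.nanmean(x, axis=0) / 2.0
    keep = maf >= threshold
    if not keep.any():
        raise ValueError(f"MAF filter at {threshold} removed every SNP")
    cols = gm.genotypes.columns[keep]
    geno = pd.DataFrame(x[:, keep], index=gm.genotypes.index, columns=cols)
    snps = gm.snps.loc[cols].copy()
    snps.index.name = gm.snps.index.name
    snps["maf"] = maf[keep]
    return GenotypeMatrix(genotypes=geno, snps=snps, samples=gm.samples.copy())


def _standardized(x: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls and column-standardize; errors on
    zero-variance SNPs (filter first)."""
    x = x.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance SNP reached standardization; "
                         "apply the MAF filter first")
    return (x - col_mean) / sd


def genotype_pcs(gm: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal components of the column-standardized genotype
    matrix.

    Deterministic up to sign; the sign of each PC is fixed so that its
    largest-magnitude sample score is positive.  ``k=0`` returns an empty
    covariate block.
    """
    if k == 0:
        return pd.DataFrame(index=gm.genotypes.index)
    if gm.n_samples < k + 1:
        raise ValueError(f"need >= {k + 1} samples for {k} PCs")
    z = _standardized(_counts(gm))
    u, s, _vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=gm.genotypes.index,
                        columns=[f"PC{j + 1}" for j in range(k)])


def _classify(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, "none", dtype=object)
    out[p < SUGGESTIVE_P] = "suggestive"
    out[p < SIGNIFICANT_P] = "significant"
    out[~np.isfinite(p)] = "untestable"
    return out


def _covariate_design(gm: GenotypeMatrix, covariates: pd.DataFrame | None,
                      samples: pd.Index) -> np.ndarray:
    """Intercept + sex (0/1) + any extra covariate columns."""
    sex = gm.samples.loc[samples, "sex"].map(
        lambda s: 1.0 if str(s).upper() in {"M", "MALE", "1"} else 0.0)
    cols = [np.ones(len(samples)), sex.to_numpy(dtype=float)]
    if covariates is not None and covariates.shape[1]:
        cols.extend(covariates.loc[samples].to_numpy(dtype=float).T)
    return np.column_stack(cols)


def _ols_scan(y: np.ndarray, x: np.ndarray, design: np.ndarray):
    """Vectorized per-SNP OLS via residualization against the shared
    covariate design (Frisch-Waugh).  Returns beta, se, t, p, df."""
    n, p_cov = design.shape
    q, _ = np.linalg.qr(design)
    y_r = y - q @ (q.T @ y)
    g_r = x - q @ (q.T @ x)
    gtg = np.einsum("ij,ij->j", g_r, g_r)
    testable = gtg > 1e-12
    df = n - p_cov - 1
    beta = np.full(x.shape[1], np.nan)
    se = np.full(x.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        gty = g_r.T @ y_r
        beta[testable] = gty[testable] / gtg[testable]
        rss = float(y_r @ y_r) - beta**2 * gtg
        sigma2 = rss / df
        se[testable] = np.sqrt(sigma2[testable] / gtg[testable])
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def snp_association(
    phenotype: pd.Series,
    gm: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive linear-model association scan (OLS per SNP).

    Regresses the phenotype on (intercept, allele count, sex, covariate
    PCs); reports the allele-count coefficient with its two-sided
    t-statistic p-value and hit class.  SNPs whose residualized genotype
    has no variance (monomorphic or collinear with covariates) are
    flagged ``untestable`` with NaN statistics.
    """
    samples = gm.genotypes.index
    y = phenotype.loc[samples].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite for all samples")
    design = _covariate_design(gm, covariates, samples)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    x = _counts(gm)
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    beta, se, t, p, _df = _ols_scan(y, x, design)
    out = gm.snps.rename_axis("snp_id").reset_index()[
        ["snp_id", "chrom", "pos", "maf"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["hit_class"] = _classify(p)
    return out


@dataclass
class InflationReport:
    lam: float
    acceptable: bool          # lambda within [0.9, 1.1]
    qq: pd.DataFrame          # expected/observed -log10 p quantiles
    n_pvalues: int


def genomic_lambda(pvals, n_qq: int = 200) -> InflationReport:
    """Genomic-control lambda: median association chi-square over its
    null median (0.4549 for 1 df), plus QQ plot data on the -log10 scale."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need >= 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    srt = np.sort(p)
    idx = np.unique(np.linspace(0, p.size - 1, min(n_qq, p.size)).astype(int))
    qq = pd.DataFrame({
        "expected_neglog10": -np.log10((idx + 0.5) / p.size),
        "observed_neglog10": -np.log10(srt[idx]),
    })
    return InflationReport(lam=lam, acceptable=bool(0.9 <= lam <= 1.1),
                           qq=qq, n_pvalues=p.size)


def grm(gm: GenotypeMatrix) -> np.ndarray:
    """Genetic relationship matrix from standardized allele counts:

        GRM_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

    Mean-imputes missing calls.  Under Hardy-Weinberg the diagonal
    averages ~1.  Fixed SNPs (p = 0 or 1) must be filtered first.
    """
    x = _counts(gm)
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    p = x.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fixed SNP (p in {0,1}) reached the GRM; filter first")
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (z @ z.T) / z.shape[1]


def _reml_variance_ratio(yt: np.ndarray, xt: np.ndarray,
                         d: np.ndarray) -> float:
    """Profile-REML estimate of lambda = sigma_g^2 / sigma_e^2 for the
    one-component model in the GRM eigenbasis.

    ``yt``/``xt``: phenotype and covariate design rotated into the GRM
    eigenbasis (eigenvalues ``d``), where the covariance is diagonal,
    lam * d + 1 up to the residual scale.  Maximizes the restricted
    likelihood over log-lambda (bounded scalar optimization); the fixed
    effects are profiled out by weighted least squares at each lambda.
    """
    from scipy.optimize import minimize_scalar

    k, p = xt.shape

    def neg_rll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam * d + 1.0
        sw = np.sqrt(w)
        yw = yt / sw
        xw = xt / sw[:, None]
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        r = yw - xw @ beta
        s2 = float(r @ r) / (k - p)
        _sign, logdet_xx = np.linalg.slogdet(xw.T @ xw)
        return 0.5 * ((k - p) * np.log(s2) + np.sum(np.log(w)) + logdet_xx)

    res = minimize_scalar(neg_rll, bounds=(-12.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError("REML variance-component estimation did not converge")
    lam = float(np.exp(res.x))
    return 0.0 if lam < 1e-5 else lam


def mlma_association(
    phenotype: pd.Series,
    gm: GenotypeMatrix,
    kinship: np.ndarray,
    covariates: pd.DataFrame | None = None,
    min_group_n: int = 10,
) -> pd.DataFrame:
    """Mixed-linear-model association with a polygenic random effect.

    Model: phenotype = covariates + SNP + g + e with Var(g) proportional
    to the GRM.  The variance ratio is estimated once by REML in the GRM
    eigenbasis, then every SNP is tested by generalized least squares
    with the implied weights.  With an identity GRM the estimated genetic
    component is 0 and the scan reduces exactly to OLS.
    """
    samples = gm.genotypes.index
    if len(samples) < min_group_n:
        raise ValueError(
            f"group has {len(samples)} samples; < {min_group_n} is refused")
    y = phenotype.loc[samples].to_numpy(dtype=float)
    kinship = np.asarray(kinship, dtype=float)
    if kinship.shape != (len(samples), len(samples)):
        raise ValueError("kinship matrix shape does not match samples")
    design = _covariate_design(gm, covariates, samples)
    d, u = np.linalg.eigh(kinship)
    d = np.clip(d, 0.0, None)

    # rotate into the eigenbasis: covariance becomes diagonal
    yt = u.T @ y
    xt = u.T @ design
    lam = _reml_variance_ratio(yt, xt, d)

    w = 1.0 / np.sqrt(lam * d + 1.0)   # whitening weights
    yw = w * yt
    dw = w[:, None] * xt
    g = _counts(gm)
    col_mean = np.nanmean(g, axis=0)
    nan_mask = np.isnan(g)
    if nan_mask.any():
        g[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    gw = w[:, None] * (u.T @ g)
    beta, se, t, p, _df = _ols_scan(yw, gw, dw)
    out = gm.snps.rename_axis("snp_id").reset_index()[
        ["snp_id", "chrom", "pos", "maf"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["hit_class"] = _classify(p)
    out.attrs["variance_ratio"] = lam
    return out


def meta_z(group_tables: dict[str, pd.DataFrame],
           group_n: dict[str, int]) -> pd.DataFrame:
    """Sample-size-weighted z-score meta-analysis across ancestry groups.

    Per-group z scores (signed, from the t statistics) are combined as
    z = sum_g w_g z_g with w_g = sqrt(n_g / sum_h n_h); two-sided normal
    p-values and hit classes are reported for the combined score.  SNP
    sets must match across groups (consistent effect-allele orientation
    is the caller's responsibility via a shared ``filter_maf`` pass).
    """
    if not group_tables:
        raise ValueError("no group tables supplied")
    names = list(group_tables)
    base = group_tables[names[0]]["snp_id"]
    for g in names[1:]:
        other = group_tables[g]["snp_id"]
        if not base.equals(other):
            missing = sorted(set(base) ^ set(other))
            raise ValueError(f"mismatched SNP sets across groups: {missing[:10]}")
    ntot = sum(group_n[g] for g in names)
    z = np.zeros(len(base))
    for g in names:
        tbl = group_tables[g]
        zg = stats.norm.isf(tbl["p"].to_numpy() / 2.0) * np.sign(
            tbl["t"].to_numpy())
        z += np.sqrt(group_n[g] / ntot) * zg
    p = 2.0 * stats.norm.sf(np.abs(z))
    first = group_tables[names[0]]
    out = first[["snp_id", "chrom", "pos", "maf"]].copy()
    out["z"] = z
    out["p"] = p
    out["hit_class"] = _classify(p)
    return out


def regional_view(table: pd.DataFrame, chrom, center: int,
                  width: int) -> pd.DataFrame:
    """SNPs within chrom:center +/- width, ordered by position, with
    -log10(p) for regional (LocusZoom-style) plotting.  An empty window
    returns an empty table."""
    sel = table[(table["chrom"] == chrom)
                & (table["pos"] >= center - width)
                & (table["pos"] <= center + width)].copy()
    sel = sel.sort_values("pos").reset_index(drop=True)
    with np.errstate(divide="ignore"):
        sel["neglog10_p"] = -np.log10(sel["p"])
    return sel


def overlap_loci(tables: dict[str, pd.DataFrame],
                 p_threshold: float = SUGGESTIVE_P,
                 min_substances: int = 2) -> pd.DataFrame:
    """SNPs reaching the threshold in >= ``min_substances`` phenotypes —
    cross-substance concordance of susceptibility loci."""
    hits: dict[str, list[str]] = {}
    for name, tbl in tables.items():
        for snp in tbl.loc[tbl["p"] < p_threshold, "snp_id"]:
            hits.setdefault(snp, []).append(name)
    rows = [dict(snp_id=snp, n_substances=len(subs),
                 substances=";".join(sorted(subs)))
            for snp, subs in hits.items() if len(subs) >= min_substances]
    out = pd.DataFrame(rows, columns=["snp_id", "n_substances", "substances"])
    return out.sort_values(["n_substances", "snp_id"],
                           ascending=[False, True]).reset_index(drop=True)
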