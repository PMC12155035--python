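"""Evaluation statistics: genotype PCA, covariate-adjusted GWAS, genomic
inflation, PVE, coordinate recovery, Moran's I, causal stratification and
Haseman-Elston heritability.

All association fits are ordinary least squares with the covariate block
projected out once via a QR factorization; per-variant statistics are then
simple inner products, so a GWAS over hundreds of thousands of variants is
a handful of chunked BLAS calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io_core import GenotypeMatrix, SampleTable

__all__ = [
    "CovariateSet",
    "GWASResult",
    "InflationEstimate",
    "MoranResult",
    "PVEResult",
    "genotype_pca",
    "pve",
    "coordinate_r2",
    "gwas_linear",
    "genomic_inflation",
    "morans_i",
    "rook_weights",
    "deme_means",
    "stratified_pvalue_comparison",
    "he_heritability",
]

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.4549364231

P_FLOOR = 1e-300


@dataclass
class CovariateSet:
    """An n x c block of fixed-effect covariates (no intercept column)."""

    samples: Optional[SampleTable]
    matrix: np.ndarray
    labels: Sequence[str]
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[0] == 1 and len(self.labels) == 1:
            self.matrix = self.matrix.T
        if not np.isfinite(self.matrix).all():
            raise ValueError("covariates contain non-finite entries")
        sd = self.matrix.std(axis=0)
        if (sd == 0).any():
            raise ValueError("constant covariate column (supply intercepts "
                             "implicitly; they are added by the fitters)")

    @property
    def c(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GWASResult:
    """Per-variant marginal association statistics under a covariate model."""

    table: pd.DataFrame  # beta, se, t, p, chi2, maf, n_used, flag
    covariate_kind: str = "custom"
    n_covariates: int = 0

    @property
    def usable(self) -> np.ndarray:
        return (self.table["flag"] == "ok").to_numpy()


@dataclass
class InflationEstimate:
    lambda_gc: float
    ci_low: float
    ci_high: float
    n_variants: int
    n_boot: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"lambda = {self.lambda_gc:.3f} "
            f"[CI: {self.ci_low:.3f}-{self.ci_high:.3f}] "
            f"({self.n_variants} variants, percentile bootstrap "
            f"B={self.n_boot})"
        )


@dataclass
class MoranResult:
    I: float
    weights_descriptor: str
    n: int

    @property
    def expected_null(self) -> float:
        return -1.0 / (self.n - 1)


@dataclass
class PVEResult:
    r2: float
    r2_adjusted: float
    c: int
    n: int


# ---------------------------------------------------------------------------
# design-matrix helpers


def _design(n: int, cov: Optional[CovariateSet]) -> np.ndarray:
    if cov is None:
        return np.ones((n, 1))
    X = np.column_stack([np.ones(n), cov.matrix])
    # drop collinear columns (rank-revealing QR via pivoted least squares)
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * diag.max()
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} collinear covariate columns")
        X = X[:, keep]
    return X


def _standardize_columns(
    d: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Mean-impute missing dosages, centre at 2p, scale by 1/sqrt(2p(1-p))."""
    Z = d.astype(np.float64)
    miss = Z < 0
    if miss.any():
        Z[miss] = np.broadcast_to(2.0 * p, Z.shape)[miss]
    Z -= 2.0 * p
    Z /= np.sqrt(2.0 * p * (1.0 - p))
    return Z


# ---------------------------------------------------------------------------
# PCA


def genotype_pca(
    g: GenotypeMatrix,
    k: int = 25,
    seed: int = 0,
    max_variants: Optional[int] = None,
    kind: str = "PC",
    chunk: int = 4096,
) -> CovariateSet:
    """Top-k principal components of the standardized genotype matrix.

    Columns are standardized to mean zero and variance 1/(2p(1-p));
    monomorphic variants are excluded automatically.  The PCs are the unit
    left singular vectors of the standardized matrix, obtained from a
    dense eigendecomposition of the n x n cross-product accumulated in
    variant chunks (exact, and deterministic regardless of ``seed``).
    ``max_variants`` thins the variant set by seeded subsampling first --
    standard practice when the full set is redundant for structure.
    """
    n = g.n_samples
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples for k={k} PCs")
    p = g.allele_freqs
    idx = np.where((p > 0) & (p < 1))[0]
    if idx.size < k:
        raise ValueError(f"only {idx.size} polymorphic variants for k={k} PCs")
    if max_variants is not None and idx.size > max_variants:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_variants, replace=False))

    C = np.zeros((n, n))
    for s in range(0, idx.size, chunk):
        b = idx[s : s + chunk]
        Z = _standardize_columns(g.dosages[:, b], p[b])
        C += Z @ Z.T
    vals, vecs = np.linalg.eigh(C)
    vecs = vecs[:, ::-1][:, :k]
    from .spectral import _fix_signs

    vecs = _fix_signs(vecs)
    return CovariateSet(
        samples=g.samples,
        matrix=vecs,
        labels=[f"{kind}{i + 1}" for i in range(k)],
        kind=kind,
    )


# ---------------------------------------------------------------------------
# variance explained


def pve(y: np.ndarray, cov: CovariateSet) -> PVEResult:
    """Proportion of phenotypic variance explained by the covariates.

    Raw R^2 from least squares of y on [1, cov], plus the adjusted version
    1 - (1 - R^2)(n - 1)/(n - c - 1), which removes the c/n chance level
    and is the comparable quantity at small n.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    X = _design(n, cov)
    c = X.shape[1] - 1
    if n <= c + 1:
        raise ValueError("need n > c + 1 samples")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    r2 = float(1.0 - resid @ resid / tss)
    adj = float(1.0 - (1.0 - r2) * (n - 1) / (n - c - 1))
    return PVEResult(r2=r2, r2_adjusted=adj, c=c, n=n)


def coordinate_r2(
    cov: CovariateSet, labels: np.ndarray
) -> Tuple[float, float]:
    """R^2 of OLS fits of the deme row and column indices on the covariates."""
    labels = np.asarray(labels)
    r2_v = pve(labels[:, 0].astype(float), cov).r2
    r2_h = pve(labels[:, 1].astype(float), cov).r2
    return r2_v, r2_h


# ---------------------------------------------------------------------------
# GWAS


def gwas_linear(
    g: GenotypeMatrix,
    y: np.ndarray,
    cov: Optional[CovariateSet] = None,
    chunk: int = 4096,
) -> GWASResult:
    """Covariate-adjusted per-variant linear regression.

    y and every genotype column are residualized on [1, cov] through one QR
    factorization; the per-variant slope, its standard error on n - c - 2
    residual degrees of freedom and the two-sided t p-value follow from
    inner products of the residual vectors.  This equals the multiple
    regression of y on [1, cov, variant] fitted per variant.  Monomorphic
    variants are reported with beta = 0, p = 1 and flagged.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if n != g.n_samples:
        raise ValueError("phenotype length != sample count")
    X = _design(n, cov)
    c = X.shape[1] - 1
    if n <= c + 2:
        raise ValueError("need n > c + 2 samples")
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    yty = yr @ yr
    dfree = n - c - 2

    m = g.n_variants
    p = g.allele_freqs
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    tstat = np.zeros(m)
    pval = np.ones(m)
    flags = np.full(m, "ok", dtype=object)

    mono = ~((p > 0) & (p < 1))
    flags[np.isnan(p)] = "all_missing"
    flags[mono & ~np.isnan(p)] = "monomorphic"
    idx = np.where(~mono & ~np.isnan(p))[0]

    for s in range(0, idx.size, chunk):
        b = idx[s : s + chunk]
        Zg = g.dosages[:, b].astype(np.float64)
        miss = Zg < 0
        if miss.any():
            Zg[miss] = np.broadcast_to(2.0 * p[b], Zg.shape)[miss]
        Zg -= Q @ (Q.T @ Zg)
        gty = Zg.T @ yr
        gtg = np.einsum("ij,ij->j", Zg, Zg)
        ok = gtg > 0
        bb = np.where(ok, gty / np.where(ok, gtg, 1.0), 0.0)
        rss = np.maximum(yty - bb * gty, 0.0)
        ss = np.sqrt(rss / dfree / np.where(ok, gtg, np.nan))
        tt = np.where(ss > 0, bb / ss, 0.0)
        beta[b], se[b], tstat[b] = bb, ss, tt
        pval[b] = np.maximum(2.0 * stats.t.sf(np.abs(tt), dfree), P_FLOOR)

    table = pd.DataFrame(
        {
            "id": g.variants["id"],
            "chromosome": g.variants["chromosome"],
            "position": g.variants["position"],
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": pval,
            "chi2": tstat**2,
            "maf": g.minor_allele_freqs,
            "n_used": (g.dosages >= 0).sum(axis=0),
            "flag": flags,
        }
    )
    return GWASResult(
        table=table,
        covariate_kind=cov.kind if cov is not None else "none",
        n_covariates=c,
    )


def genomic_inflation(
    res: Union[GWASResult, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
    min_variants: int = 100,
) -> InflationEstimate:
    """Genomic control lambda: median chi-square over the chi2_1 median.

    The 95% CI is a seeded percentile bootstrap over variants: no single
    convention exists for lambda confidence intervals, so the
    distribution-free bootstrap is used and reported as such.
    """
    if isinstance(res, GWASResult):
        chi2 = res.table.loc[res.usable, "chi2"].to_numpy()
    else:
        chi2 = np.asarray(res, dtype=np.float64)
    if chi2.size < min_variants:
        raise ValueError(
            f"only {chi2.size} usable variants (< {min_variants}); "
            "inflation estimate would be unstable"
        )
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.median(rng.choice(chi2, size=chi2.size, replace=True))
    boots /= CHI2_1_MEDIAN
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return InflationEstimate(
        lambda_gc=lam,
        ci_low=float(min(lo, lam)),
        ci_high=float(max(hi, lam)),
        n_variants=int(chi2.size),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Moran's I


def morans_i(
    values: np.ndarray, weights: Union[np.ndarray, sp.spmatrix],
    descriptor: str = "custom",
) -> MoranResult:
    """Moran's spatial autocorrelation I.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with W the total weight.  Weights must be symmetric, non-negative and
    zero on the diagonal; the null expectation is -1/(n-1).
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 units")
    if x.var() == 0:
        raise ValueError("Moran's I undefined for constant values")
    W = np.asarray(weights.todense()) if sp.issparse(weights) else np.asarray(weights, dtype=float)
    if W.shape != (n, n):
        raise ValueError("weights shape mismatch")
    if np.abs(np.diag(W)).max() > 0:
        raise ValueError("weights must have a zero diagonal")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    wsum = W.sum()
    if wsum == 0:
        raise ValueError("all weights are zero")
    z = x - x.mean()
    I = float(n / wsum * (z @ W @ z) / (z @ z))
    return MoranResult(I=I, weights_descriptor=descriptor, n=n)


def rook_weights(grid_n: int) -> np.ndarray:
    """Rook-adjacency 0/1 weights over the demes of an N x N grid."""
    nd = grid_n * grid_n
    W = np.zeros((nd, nd))
    for i in range(nd):
        ri, ci = divmod(i, grid_n)
        for j in range(nd):
            rj, cj = divmod(j, grid_n)
            if abs(ri - rj) + abs(ci - cj) == 1:
                W[i, j] = 1.0
    return W


def deme_means(values: np.ndarray, labels: np.ndarray, grid_n: int) -> np.ndarray:
    """Mean of per-sample values within each deme, in row-major deme order."""
    values = np.asarray(values, dtype=float)
    deme = labels[:, 0] * grid_n + labels[:, 1]
    out = np.full(grid_n * grid_n, np.nan)
    for d in range(grid_n * grid_n):
        sel = deme == d
        if sel.any():
            out[d] = values[sel].mean()
    return out


# ---------------------------------------------------------------------------
# causal stratification


def stratified_pvalue_comparison(
    res_a: GWASResult,
    res_b: GWASResult,
    causal_indices: np.ndarray,
    g: GenotypeMatrix,
    ld_r2_threshold: float = 0.1,
    window_bp: int = 1_000_000,
) -> dict:
    """Compare two covariate models within causal / LD / non-causal strata.

    A non-causal variant is promoted to the "ld" stratum when its squared
    correlation with any causal variant within ``window_bp`` strictly
    exceeds ``ld_r2_threshold``.  Within each stratum a Wilcoxon rank-sum
    test compares the -log10 p-values of the two models, alongside the mean
    absolute effect sizes.
    """
    ta, tb = res_a.table, res_b.table
    if not (ta["id"].to_numpy() == tb["id"].to_numpy()).all():
        raise ValueError("GWAS results are not on identical variant lists")
    m = len(ta)
    causal_indices = np.asarray(causal_indices, dtype=np.int64)
    stratum = np.full(m, "non_causal", dtype=object)
    stratum[causal_indices] = "causal"

    if causal_indices.size:
        p = g.allele_freqs
        pos = g.variants["position"].to_numpy()
        chrom = g.variants["chromosome"].to_numpy()
        Zc = _standardize_columns(g.dosages[:, causal_indices], p[causal_indices])
        Zc /= np.sqrt((Zc**2).sum(axis=0))
        cpos, cchrom = pos[causal_indices], chrom[causal_indices]
        cand = np.where(stratum == "non_causal")[0]
        for s in range(0, cand.size, 2048):
            b = cand[s : s + 2048]
            Z = _standardize_columns(g.dosages[:, b], p[b])
            norm = np.sqrt((Z**2).sum(axis=0))
            ok = norm > 0
            Z[:, ok] /= norm[ok]
            R2 = np.clip((Zc.T @ Z) ** 2, 0.0, 1.0)  # causal x candidate
            near = (np.abs(cpos[:, None] - pos[b][None, :]) <= window_bp) & (
                cchrom[:, None] == chrom[b][None, :]
            )
            hit = ((R2 > ld_r2_threshold) & near).any(axis=0) & ok
            stratum[b[hit]] = "ld"

    report: dict = {"ld_r2_threshold": ld_r2_threshold, "window_bp": window_bp,
                    "strata": {}}
    usable = res_a.usable & res_b.usable
    for name in ("causal", "ld", "non_causal"):
        sel = (stratum == name) & usable
        if not sel.any():
            report["strata"][name] = None
            continue
        la = -np.log10(ta.loc[sel, "p"].to_numpy())
        lb = -np.log10(tb.loc[sel, "p"].to_numpy())
        if np.array_equal(la, lb):
            wstat, wp = 0.0, 1.0
        else:
            wstat, wp = stats.ranksums(la, lb)
        report["strata"][name] = {
            "n": int(sel.sum()),
            "wilcoxon_stat": float(wstat),
            "wilcoxon_p": float(wp),
            "mean_abs_beta_a": float(np.abs(ta.loc[sel, "beta"]).mean()),
            "mean_abs_beta_b": float(np.abs(tb.loc[sel, "beta"]).mean()),
            "mean_neglog10p_a": float(la.mean()),
            "mean_neglog10p_b": float(lb.mean()),
        }
    return report


# ---------------------------------------------------------------------------
# Haseman-Elston regression


def make_grm(
    g: GenotypeMatrix,
    max_variants: Optional[int] = None,
    seed: int = 0,
    chunk: int = 4096,
) -> np.ndarray:
    """GRM_ij = (1/M) sum_m z_im z_jm over standardized polymorphic variants."""
    p = g.allele_freqs
    idx = np.where((p > 0) & (p < 1))[0]
    if max_variants is not None and idx.size > max_variants:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_variants, replace=False))
    n = g.n_samples
    K = np.zeros((n, n))
    for s in range(0, idx.size, chunk):
        b = idx[s : s + chunk]
        Z = _standardize_columns(g.dosages[:, b], p[b])
        K += Z @ Z.T
    return K / idx.size


def he_heritability(
    g_or_grm: Union[GenotypeMatrix, np.ndarray],
    y: np.ndarray,
    cov: Optional[CovariateSet] = None,
    max_variants: Optional[int] = None,
    seed: int = 0,
) -> dict:
    """Haseman-Elston regression heritability with a jackknife SE.

    The phenotype is residualized on [1, cov] and standardized; the
    cross-products y_i * y_j over all i < j pairs are regressed on the
    corresponding GRM entries.  The slope, clipped to [0, 1], estimates
    narrow-sense heritability; the SE is a delete-one-sample jackknife.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if n < 50:
        raise ValueError("Haseman-Elston needs at least 50 samples")
    K = (
        make_grm(g_or_grm, max_variants=max_variants, seed=seed)
        if isinstance(g_or_grm, GenotypeMatrix)
        else np.asarray(g_or_grm, dtype=np.float64)
    )
    if K.shape != (n, n):
        raise ValueError("GRM shape does not match phenotype length")

    X = _design(n, cov)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yr = y - X @ beta
    yr = (yr - yr.mean()) / yr.std()

    P = np.outer(yr, yr)
    mask = ~np.eye(n, dtype=bool)
    x = K[mask]  # each i<j pair appears twice; slope is unaffected
    v = P[mask]
    xm, vm = x.mean(), v.mean()
    Sxx = ((x - xm) ** 2).sum()
    Sxy = ((x - xm) * (v - vm)).sum()
    slope = Sxy / Sxx

    # delete-one jackknife via per-sample partial sums of the pair statistics
    Kc = K - np.diag(np.diag(K))
    Pc = P - np.diag(np.diag(P))
    npairs = n * (n - 1)
    sx_i = Kc.sum(axis=1) * 2
    sv_i = Pc.sum(axis=1) * 2
    sxx_i = (Kc**2).sum(axis=1) * 2
    sxy_i = (Kc * Pc).sum(axis=1) * 2
    SX, SV = x.sum(), v.sum()
    SXX, SXY = (x**2).sum(), (x * v).sum()
    n_i = npairs - 2 * (n - 1)
    SX_i, SV_i = SX - sx_i, SV - sv_i
    Sxx_i = (SXX - sxx_i) - SX_i**2 / n_i
    Sxy_i = (SXY - sxy_i) - SX_i * SV_i / n_i
    slopes_i = Sxy_i / Sxx_i
    se = float(np.sqrt((n - 1) / n * ((slopes_i - slopes_i.mean()) ** 2).sum()))

    return {"h2": float(np.clip(slope, 0.0, 1.0)), "h2_raw": float(slope), "se": se}
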