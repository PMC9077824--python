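"""Genotype PCA and a PC-regression outlier scan.

The scan regresses each standardized SNP column on the first K principal
component score vectors, converts the regression coefficients to z-scores,
and measures each SNP's multivariate outlyingness as a robust Mahalanobis
distance of its z-vector. Distances are rescaled by a genomic inflation
factor and referred to a chi-square with K degrees of freedom;
Benjamini-Hochberg q-values flag outliers, and each outlier is attributed to
the PC with the largest squared z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING, GenotypeMatrix

__all__ = ["PcaResult", "OutlierScan", "pca_genotypes", "pc_outlier_scan", "bh_qvalues"]


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # individuals x K
    loadings: np.ndarray  # SNPs x K (excluded SNPs carry NaN rows)
    var_explained: np.ndarray  # per-PC fraction of total variance
    kept_snps: np.ndarray  # indices of SNPs used (polymorphic)


@dataclass(frozen=True)
class OutlierScan:
    table: pd.DataFrame  # chrom, pos, locus_id, mahalanobis, p, q, top_pc, significant
    z: np.ndarray  # SNPs x K z-scores (NaN for excluded SNPs)
    gif: float
    K: int
    alpha: float


def _standardize(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and scale each SNP as (g - 2p)/sqrt(2p(1-p)).

    Returns the standardized matrix restricted to polymorphic SNPs and the
    indices of the SNPs kept.
    """
    G = gm.values.astype(np.float64)
    miss = gm.values == MISSING
    p = gm.allele_freq()
    # mean imputation, for PCA only
    fill = np.broadcast_to(2.0 * p, G.shape)
    G = np.where(miss, fill, G)
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNPs excluded from PCA", stacklevel=3
        )
    keep = np.flatnonzero(poly)
    pk = p[keep]
    Z = (G[:, keep] - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    return Z, keep


def pca_genotypes(gm: GenotypeMatrix, K: int) -> PcaResult:
    """Truncated SVD of the standardized genotype matrix.

    ``var_explained`` is each component's squared singular value over the
    total variance of the standardized matrix.
    """
    if not K < min(gm.n_individuals, gm.n_snps):
        raise ValueError("K must be smaller than both matrix dimensions")
    Z, keep = _standardize(gm)
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    total = (s**2).sum()
    scores = U[:, :K] * s[:K]
    loadings = np.full((gm.n_snps, K), np.nan)
    loadings[keep] = Vt[:K].T
    var_explained = s[:K] ** 2 / total
    return PcaResult(scores, loadings, var_explained, keep)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=np.float64)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _robust_location_scatter(
    X: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-covariance-determinant-style robust location and scatter."""
    from sklearn.covariance import MinCovDet

    if X.shape[1] == 1:
        # MCD in 1-D: median and a consistency-corrected trimmed variance
        med = np.median(X, axis=0)
        mad = stats.median_abs_deviation(X[:, 0], scale="normal")
        return med, np.array([[mad**2]])
    mcd = MinCovDet(random_state=seed).fit(X)
    return mcd.location_, mcd.covariance_


def pc_outlier_scan(
    gm: GenotypeMatrix,
    K: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
    robust: bool = True,
    gif_correction: bool = True,
) -> OutlierScan:
    """PC-regression outlier scan with robust Mahalanobis distances.

    Per SNP: multiple regression of the standardized genotype column on the K
    score vectors; coefficient z-scores; Mahalanobis distance² of the
    z-vector against a robust location/scatter across SNPs; genomic inflation
    factor gif = median(d²)/median(chi²_K); p = chi²_K upper tail of d²/gif;
    q-values by Benjamini-Hochberg; ``significant`` iff q < alpha;
    ``top_pc`` = argmax of squared z (1-based).
    """
    pca = pca_genotypes(gm, K)
    Z, keep = _standardize(gm)
    n = Z.shape[0]
    X = pca.scores - pca.scores.mean(axis=0)
    # least squares for all SNPs at once
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Z  # K x n_kept
    resid = Z - X @ B
    dof = n - K - 1
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        zmat = (B / se).T  # n_kept x K

    ok = np.isfinite(zmat).all(axis=1)
    zz = zmat[ok]
    if robust:
        loc, cov = _robust_location_scatter(zz, seed)
    else:
        loc = zz.mean(axis=0)
        cov = np.cov(zz, rowvar=False).reshape(K, K)
    covinv = np.linalg.inv(cov)
    diff = zz - loc
    d2 = np.einsum("ij,jk,ik->i", diff, covinv, diff)

    if gif_correction:
        gif = float(np.median(d2) / stats.chi2.median(K))
        if gif <= 0:
            gif = 1.0
    else:
        gif = 1.0
    p = stats.chi2.sf(d2 / gif, df=K)
    q = bh_qvalues(p)
    top = np.argmax(zz**2, axis=1) + 1

    n_snps = gm.n_snps
    full = lambda v, fillval=np.nan: _scatter(v, keep[ok], n_snps, fillval)
    zfull = np.full((n_snps, K), np.nan)
    zfull[keep[ok]] = zz
    table = pd.DataFrame(
        {
            "chrom": gm.variants.chrom,
            "pos": gm.variants.pos,
            "locus_id": gm.variants.locus_id,
            "mahalanobis": full(d2),
            "p": full(p),
            "q": full(q),
            "top_pc": _scatter(top.astype(float), keep[ok], n_snps, np.nan),
        }
    )
    table["significant"] = table["q"] < alpha
    return OutlierScan(table, zfull, gif, K, alpha)


def _scatter(v: np.ndarray, idx: np.ndarray, n: int, fill) -> np.ndarray:
    out = np.full(n, fill, dtype=np.float64)
    out[idx] = v
    return out
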