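"""Linear mixed-model association engine.

Single-trait model per tested variant i:

    y = 1 mu + x_i b_i + g + e,   g ~ N(0, sg2 G),  e ~ N(0, se2 I)

with G the VanRaden (method 1) genomic relationship matrix. The GRM is
eigendecomposed once (G = U L U'); rotating by U' diagonalizes the
covariance, so the null variance components are found by a one-dimensional
REML optimization over the variance ratio, and each variant is then tested
by weighted least squares with the ratio fixed at its null estimate (the
usual two-step approximation). The per-variant Wald statistic uses a
residual scale re-estimated per variant, so when sg2 -> 0 the test is
algebraically ordinary least squares, and p-values come from a t
distribution with n - #fixed - 1 degrees of freedom.

The multivariate model stacks T traits with genetic covariance Vg and
residual covariance Ve; (Vg, Ve) are estimated by an EM algorithm on the
rotated likelihood and each variant's T-vector of effects is tested with a
chi-square Wald statistic (df = T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, GwasResult, MtGwasResult, PhenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GRM and its eigendecomposition
# ---------------------------------------------------------------------------

@dataclass
class Grm:
    """VanRaden method-1 genomic relationship matrix."""

    matrix: np.ndarray
    n_markers: int
    method: str = "vanraden1"

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        avg_diag = float(np.mean(np.diag(self.matrix)))
        if not 0.8 <= avg_diag <= 1.5:
            logger.warning("GRM average diagonal %.3f outside [0.8, 1.5]", avg_diag)


@dataclass
class GrmEigen:
    """Eigendecomposition of a GRM, kept with its source for re-subsetting."""

    values: np.ndarray  # descending
    vectors: np.ndarray
    source: Grm | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, mask_or_index) -> "GrmEigen":
        """Re-decompose on a subset of individuals (missing-phenotype path)."""
        if self.source is None:
            raise ValueError("no source GRM retained; cannot re-subset")
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = Grm(
            matrix=self.source.matrix[np.ix_(idx, idx)],
            n_markers=self.source.n_markers,
            method=self.source.method,
        )
        return eigendecompose(sub)


def compute_grm(geno: GenotypeMatrix, marker_subset=None) -> Grm:
    """G = W W' / (2 sum_k p_k (1 - p_k)), W centered by twice the allele frequency.

    Monomorphic markers are excluded with a warning; missing dosages are
    mean-imputed (centered to zero) for the purpose of relationship
    estimation only.
    """
    dos = geno.dosages if marker_subset is None else geno.dosages[:, marker_subset]
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 1:
        raise ValueError("all markers monomorphic; cannot build a GRM")
    if (~poly).any():
        logger.warning("excluding %d monomorphic markers from GRM", int((~poly).sum()))
    dos = dos[:, poly]
    p = p[poly]
    W = dos - 2.0 * p
    W = np.nan_to_num(W, nan=0.0)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return Grm(matrix=(W @ W.T) / denom, n_markers=int(poly.sum()))


def eigendecompose(grm: Grm) -> GrmEigen:
    values, vectors = np.linalg.eigh(grm.matrix)
    order = np.argsort(values)[::-1]
    values = np.clip(values[order], 0.0, None)
    return GrmEigen(values=values, vectors=vectors[:, order], source=grm)


# ---------------------------------------------------------------------------
# null model (single trait)
# ---------------------------------------------------------------------------

@dataclass
class NullFit:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _reml_neg_loglik(
    log_ratio: float, lam: np.ndarray, Xr: np.ndarray, yr: np.ndarray
) -> tuple[float, float, float]:
    """Profile REML negative log-likelihood at ratio = sg2/se2 (rotated data).

    Returns (-loglik, sg2, se2) with the scale profiled out analytically.
    """
    ratio = np.exp(log_ratio)
    n, p = Xr.shape
    v = ratio * lam + 1.0  # V / se2
    w = 1.0 / v
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf, 0.0, 1.0
    r = yr - Xr @ beta
    rss = float(np.sum(r * r * w))
    df = n - p
    se2 = rss / df
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or se2 <= 0:
        return np.inf, 0.0, 1.0
    ll = -0.5 * (
        df * np.log(2 * np.pi * se2)
        + np.sum(np.log(v))
        + logdet_xtwx
        + df
    )
    return -ll, ratio * se2, se2


def fit_null(
    y: np.ndarray,
    eigen: GrmEigen,
    covariates: np.ndarray | None = None,
) -> NullFit:
    """REML variance components by 1-D optimization over the variance ratio.

    Missing phenotypes are handled by subsetting and re-decomposing the GRM.
    Fixed effects are an intercept plus any supplied covariate columns.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if covariates is not None:
        ok &= np.all(np.isfinite(covariates), axis=1)
    if not ok.all():
        eigen = eigen.subset(ok)
        y = y[ok]
        covariates = covariates[ok] if covariates is not None else None
    n = y.shape[0]
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    U, lam = eigen.vectors, eigen.values
    yr = U.T @ y
    Xr = U.T @ X

    res = optimize.minimize_scalar(
        lambda lr: _reml_neg_loglik(lr, lam, Xr, yr)[0],
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success) and -11.9 < res.x < 11.9
    nll, sg2, se2 = _reml_neg_loglik(res.x, lam, Xr, yr)
    if res.x <= -11.9:  # boundary: effectively sg2 = 0
        sg2 = 0.0
    return NullFit(sigma_g2=float(sg2), sigma_e2=float(se2), loglik=float(-nll),
                   converged=converged)


# ---------------------------------------------------------------------------
# single-trait scan
# ---------------------------------------------------------------------------

def _region_mask(variants: pd.DataFrame, region) -> np.ndarray:
    if region is None:
        return np.ones(len(variants), dtype=bool)
    chrom, start, end = region
    return (
        (variants["chrom"] == chrom)
        & (variants["pos"] >= start)
        & (variants["pos"] <= end)
    ).to_numpy()


def st_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    eigen: GrmEigen,
    null: NullFit,
    covariates: np.ndarray | None = None,
    region: tuple[str, int, int] | None = None,
    trait: str = "trait",
    covariate_names: list[str] | None = None,
) -> GwasResult:
    """Per-variant Wald tests with variance components fixed at the null fit.

    Covariate columns (e.g. conditioning variant dosages) enter as fixed
    effects. A variant collinear with the covariates (or monomorphic) is
    reported with NaN statistics. p-values use a t distribution with
    n - #fixed - 1 df; the residual scale is re-estimated per variant so the
    scan degenerates exactly to OLS when sigma_g2 = 0.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.shape[0]:
            covariates = covariates.T
        ok &= np.all(np.isfinite(covariates), axis=1)
    dos_all = geno.dosages
    if not ok.all():
        eigen = eigen.subset(ok)
    y = y[ok]
    n = y.shape[0]
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates[ok]]
    )
    p_fixed = X.shape[1]
    U, lam = eigen.vectors, eigen.values

    mask = _region_mask(geno.variants, region)
    cols = np.flatnonzero(mask)
    dos = dos_all[np.ix_(ok, cols)]
    if not np.all(np.isfinite(dos)):  # mean-impute missing dosages for testing
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(~np.isfinite(dos))
        dos = dos.copy()
        dos[nan_r, nan_c] = col_mean[nan_c]

    w = 1.0 / (null.sigma_g2 * lam + null.sigma_e2)
    sw = np.sqrt(w)
    yr = (U.T @ y) * sw
    Xr = (U.T @ X) * sw[:, None]
    Gr = (U.T @ dos) * sw[:, None]

    # residualize y and genotypes on the fixed effects (whitened scale)
    Q, _ = np.linalg.qr(Xr)
    ry = yr - Q @ (Q.T @ yr)
    RG = Gr - Q @ (Q.T @ Gr)

    sxx = np.einsum("ij,ij->j", RG, RG)
    sxy = RG.T @ ry
    syy = float(ry @ ry)
    df = n - p_fixed - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    # collinear-with-covariates or monomorphic: sxx ~ 0 relative to raw scale
    raw_scale = np.einsum("ij,ij->j", Gr, Gr)
    bad = sxx <= 1e-10 * np.maximum(raw_scale, 1e-30)
    beta[bad] = se[bad] = tstat[bad] = np.nan
    pvals = np.where(np.isnan(tstat), np.nan, 2.0 * stats.t.sf(np.abs(tstat), df=df))

    sub = geno.variants.iloc[cols]
    table = pd.DataFrame(
        {
            "variant_id": sub["variant_id"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "alt_freq": np.nanmean(dos, axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": pvals,
            "n": n,
            "reason": np.where(bad, "collinear_or_monomorphic", ""),
        }
    )
    return GwasResult(trait=trait, table=table,
                      covariates=list(covariate_names or []))


# ---------------------------------------------------------------------------
# multivariate null model (EM) and multi-trait scan
# ---------------------------------------------------------------------------

@dataclass
class MvNullFit:
    Vg: np.ndarray
    Ve: np.ndarray
    loglik: float
    converged: bool


def _floor_pd(mat: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Force symmetric positive definiteness by eigenvalue flooring."""
    mat = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(mat)
    floor = floor_frac * max(np.trace(mat), 1e-12)
    return vecs @ np.diag(np.clip(vals, floor, None)) @ vecs.T


def fit_null_mv(
    Y: np.ndarray,
    eigen: GrmEigen,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MvNullFit:
    """EM estimation of (Vg, Ve) on the eigen-rotated multivariate model.

    Rows with any missing trait are dropped listwise (with GRM
    re-decomposition). Convergence is declared when the log-likelihood
    improves by less than ``tol``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, T = Y.shape
    if T > 10:
        raise ValueError("multivariate model limited to at most 10 traits")
    ok = np.all(np.isfinite(Y), axis=1)
    if not ok.all():
        eigen = eigen.subset(ok)
        Y = Y[ok]
        n = Y.shape[0]
    U, lam = eigen.vectors, eigen.values
    Yr = U.T @ Y
    ones_r = U.T @ np.ones(n)

    emp = np.cov(Y, rowvar=False).reshape(T, T)
    Vg = 0.5 * emp
    Ve = 0.5 * emp + 1e-6 * np.eye(T)
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        Sigma = lam[:, None, None] * Vg[None] + Ve[None]  # (n, T, T)
        Sinv = np.linalg.inv(Sigma)
        # GLS intercept
        A = np.einsum("j,j,jab->ab", ones_r, ones_r, Sinv)
        b = np.einsum("j,jab,jb->a", ones_r, Sinv, Yr)
        mu = np.linalg.solve(A, b)
        R = Yr - np.outer(ones_r, mu)
        # log-likelihood
        sign, logdet = np.linalg.slogdet(Sigma)
        quad = np.einsum("ja,jab,jb->", R, Sinv, R)
        new_ll = -0.5 * (n * T * np.log(2 * np.pi) + logdet.sum() + quad)
        # E-step: posterior of the genetic component per rotated row
        SinvR = np.einsum("jab,jb->ja", Sinv, R)
        lamVg = lam[:, None, None] * Vg[None]
        Eg = np.einsum("jab,jb->ja", lamVg, SinvR)
        Covg = lamVg - lamVg @ Sinv @ lamVg
        Ee = R - Eg
        Cove = Ve[None] - Ve @ Sinv @ Ve
        # M-step; rows with lam ~ 0 carry no genetic information
        pos = lam > 1e-10
        npos = int(pos.sum())
        if npos:
            Sg = (
                np.einsum("ja,jb->jab", Eg[pos], Eg[pos]) + Covg[pos]
            ) / lam[pos, None, None]
            Vg_new = Sg.mean(axis=0)
        else:
            Vg_new = np.zeros_like(Vg)
        Se = np.einsum("ja,jb->jab", Ee, Ee) + Cove
        Ve_new = Se.mean(axis=0)
        Vg = 0.5 * (Vg_new + Vg_new.T)
        Ve = _floor_pd(Ve_new)
        if abs(new_ll - loglik) < tol:
            loglik = new_ll
            converged = True
            break
        loglik = new_ll
    return MvNullFit(Vg=Vg, Ve=Ve, loglik=float(loglik), converged=converged)


def mt_scan(
    Y: np.ndarray,
    geno: GenotypeMatrix,
    eigen: GrmEigen,
    null: MvNullFit,
    covariates: np.ndarray | None = None,
    region: tuple[str, int, int] | None = None,
    traits: list[str] | None = None,
    covariate_names: list[str] | None = None,
) -> MtGwasResult:
    """Per-variant T-dimensional GLS effects and chi-square Wald test (df=T).

    Fixed effects (intercept and covariates) get their own T-vector each;
    the tested variant's T-vector is compared to zero.
    """
    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    traits = traits or [f"trait{i + 1}" for i in range(T)]
    ok = np.all(np.isfinite(Y), axis=1)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        ok &= np.all(np.isfinite(covariates), axis=1)
    if not ok.all():
        eigen = eigen.subset(ok)
    Y = Y[ok]
    n = Y.shape[0]
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates[ok]]
    )
    k = C.shape[1]
    U, lam = eigen.vectors, eigen.values
    Yr = U.T @ Y
    Cr = U.T @ C
    mask = _region_mask(geno.variants, region)
    cols = np.flatnonzero(mask)
    dos = geno.dosages[np.ix_(np.flatnonzero(ok), cols)]
    if not np.all(np.isfinite(dos)):
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(~np.isfinite(dos))
        dos = dos.copy()
        dos[nan_r, nan_c] = col_mean[nan_c]
    Gr = U.T @ dos

    Sigma = lam[:, None, None] * null.Vg[None] + null.Ve[None]
    Sinv = np.linalg.inv(Sigma)

    # constant blocks: A_cc (kT x kT), and per-variant blocks via einsum
    Acc = np.einsum("ja,jb,jcd->acbd", Cr, Cr, Sinv).reshape(k * T, k * T)
    bc = np.einsum("ja,jcd,jd->ac", Cr, Sinv, Yr).reshape(k * T)
    SinvY = np.einsum("jcd,jd->jc", Sinv, Yr)

    m = Gr.shape[1]
    wald = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    betas = np.full((m, T), np.nan)
    reasons = np.array([""] * m, dtype=object)
    Acc_inv = np.linalg.inv(Acc)
    # per-variant cross blocks
    Axx = np.einsum("jm,jm,jcd->mcd", Gr, Gr, Sinv)  # (m, T, T)
    Axc = np.einsum("jm,ja,jcd->macd", Gr, Cr, Sinv).reshape(m, T, k * T)
    bx = np.einsum("jm,jc->mc", Gr, SinvY)

    raw_scale = np.einsum("jm,jm->m", Gr, Gr)
    for i in range(m):
        S_xx = Axx[i]
        S_xc = Axc[i]
        # Schur complement of the covariate block
        M = S_xx - S_xc @ Acc_inv @ S_xc.T
        rhs = bx[i] - S_xc @ (Acc_inv @ bc)
        det = np.linalg.det(M)
        if not np.isfinite(det) or det <= 1e-12 * max(raw_scale[i] ** T, 1e-30):
            reasons[i] = "collinear_or_monomorphic"
            continue
        beta = np.linalg.solve(M, rhs)
        betas[i] = beta
        wald[i] = float(beta @ M @ beta)
        pvals[i] = float(stats.chi2.sf(wald[i], df=T))

    sub = geno.variants.iloc[cols]
    table = pd.DataFrame(
        {
            "variant_id": sub["variant_id"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "wald": wald,
            "df": T,
            "p": pvals,
            "n": n,
            "reason": reasons,
        }
    )
    for t_i, name in enumerate(traits):
        table[f"beta_{name}"] = betas[:, t_i]
    return MtGwasResult(traits=list(traits), table=table,
                        covariates=list(covariate_names or []))


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def scan_all_traits(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    eigen: GrmEigen,
    covariates: np.ndarray | None = None,
) -> dict[str, GwasResult]:
    """Null fit + scan for every trait in a phenotype table."""
    out: dict[str, GwasResult] = {}
    for name in pheno.trait_names:
        y = pheno.trait(name)
        null = fit_null(y, eigen, covariates)
        out[name] = st_scan(y, geno, eigen, null, covariates, trait=name)
    return out
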