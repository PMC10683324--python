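"""Effective numbers of tests/traits and genome-wide significance thresholds.

The effective number of independent tests is estimated by repeating a
simple-regression genome scan on random permutations of the phenotype,
recording each scan's best p-value, and inverting the Sidak formula
``p_corrected = 1 - (1 - p)^meff`` pointwise on a grid of nominal p-values;
the reported meff is the median over grid points whose corrected p lies in
[0.01, 0.5], a range where the permutation estimate is stable. The
effective number of traits uses the Galwey estimator on the trait
correlation matrix, and the final threshold is a Bonferroni correction at
``alpha / (meff_tests * meff_traits)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix


@dataclass
class MeffEstimate:
    meff: float
    grid_p: np.ndarray
    grid_p_corrected: np.ndarray
    grid_meff: np.ndarray
    best_p: np.ndarray  # permutation best-p distribution (persisted)
    n_perm: int
    seed: int


@dataclass
class CalibrationResult:
    meff_tests: float
    meff_traits: float
    alpha: float
    threshold: float
    n_perm: int = 0
    seed: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def neglog10_threshold(self) -> float:
        return float(-np.log10(self.threshold))


def _best_p_per_permutation(
    y: np.ndarray, dosages: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Minimum simple-regression p-value over all variants, per permutation.

    The scan is plain intercept+dosage regression; for centered data the
    t statistic is a monotone function of |r|, so only correlations are
    needed and all permutations are one matrix product.
    """
    n, m = dosages.shape
    Xc = dosages - dosages.mean(axis=0)
    xnorm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    xnorm[xnorm == 0] = np.inf  # monomorphic: r = 0
    yc = y - y.mean()
    ynorm = float(np.sqrt(yc @ yc))
    rmax = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(5e7 // max(n, m))))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        perm = np.empty((hi - lo, n))
        for b in range(hi - lo):
            perm[b] = yc[rng.permutation(n)]
        R = (perm @ Xc) / (ynorm * xnorm[None, :])
        rmax[lo:hi] = np.abs(R).max(axis=1)
    rmax = np.clip(rmax, 0.0, 1.0 - 1e-15)
    tmax = rmax * np.sqrt((n - 2) / (1.0 - rmax**2))
    return 2.0 * stats.t.sf(tmax, df=n - 2)


def permutation_meff(
    y: np.ndarray,
    geno: GenotypeMatrix | np.ndarray,
    n_perm: int = 10_000,
    p_grid: np.ndarray | None = None,
    seed: int = 0,
) -> MeffEstimate:
    """Sidak-inverted effective number of independent tests.

    ``p_grid`` defaults to quantiles of the permutation best-p distribution
    chosen so the corrected p values cover (0.01, 0.5). Raises if the
    corrected p is degenerate (0 or 1) at every grid point, which signals
    too few permutations.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    dosages = geno.dosages if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    dosages = dosages[ok]
    if not np.all(np.isfinite(dosages)):
        col_mean = np.nanmean(dosages, axis=0)
        r_i, c_i = np.nonzero(~np.isfinite(dosages))
        dosages = dosages.copy()
        dosages[r_i, c_i] = col_mean[c_i]
    rng = np.random.default_rng(seed)
    best_p = _best_p_per_permutation(y, dosages, n_perm, rng)

    if p_grid is None:
        qs = np.linspace(0.02, 0.45, 24)
        p_grid = np.unique(np.quantile(best_p, qs))
    p_grid = np.asarray(p_grid, dtype=float)
    p_corr = np.array([(best_p <= p).mean() for p in p_grid])
    with np.errstate(divide="ignore", invalid="ignore"):
        meff_point = np.log1p(-p_corr) / np.log1p(-p_grid)
    usable = (p_corr >= 0.01) & (p_corr <= 0.5) & np.isfinite(meff_point)
    if not usable.any():
        raise ValueError(
            "corrected p degenerate at every grid point; increase n_perm"
        )
    meff = float(np.median(meff_point[usable]))
    return MeffEstimate(
        meff=meff,
        grid_p=p_grid,
        grid_p_corrected=p_corr,
        grid_meff=meff_point,
        best_p=best_p,
        n_perm=n_perm,
        seed=seed,
    )


def galwey_meff(trait_corr: np.ndarray) -> tuple[float, int]:
    """Galwey effective number of traits: (sum sqrt(l'))^2 / sum l'.

    Eigenvalues of the trait correlation matrix are floored at zero.
    Returns the raw value and its floored integer.
    """
    trait_corr = np.asarray(trait_corr, dtype=float)
    if trait_corr.ndim != 2 or trait_corr.shape[0] != trait_corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(trait_corr, trait_corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.clip(np.linalg.eigvalsh(trait_corr), 0.0, None)
    meff = float(np.sum(np.sqrt(lam)) ** 2 / np.sum(lam))
    return meff, int(np.floor(meff))


def significance_threshold(
    alpha: float, meff_tests: float, meff_traits: float = 1.0
) -> CalibrationResult:
    """Bonferroni threshold alpha / (meff_tests * meff_traits)."""
    if alpha <= 0 or meff_tests <= 0 or meff_traits <= 0:
        raise ValueError("alpha and meff values must be positive")
    thr = alpha / (meff_tests * meff_traits)
    return CalibrationResult(
        meff_tests=meff_tests,
        meff_traits=meff_traits,
        alpha=alpha,
        threshold=thr,
    )
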