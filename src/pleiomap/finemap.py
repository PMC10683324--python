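"""Credible-set construction: LD-based sets and IBSS fine-mapping.

Two kinds of credible set (CS) are built around association peaks. LD-based
CS take every variant whose r2 with the lead exceeds a threshold (0.90 or
0.80). IBSS CS come from a sum-of-single-effects regression on summary
statistics (z-scores plus the in-sample LD matrix): the model holds L
single-effect vectors, each fitted by a Bayesian single-effect regression
on the residual z-scores, iterated to convergence; each effect yields a 95%
credible set (the smallest posterior-ordered set reaching the coverage),
filtered by purity (minimum absolute pairwise correlation among members).

Multi-trait CS follow the qualification-and-merge rule: a trait group's
scan is used only when at least one member trait shows -log10 p > 7 in its
own scan; if both groups qualify their LD-based CS are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CredibleSet, GenotypeMatrix, GwasResult, MtGwasResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    """Signed dosage correlations for variants inside a window; r2 = r**2."""

    variant_ids: np.ndarray
    r: np.ndarray  # signed correlation, NaN where undefined (monomorphic)
    positions: np.ndarray | None = None

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id} not in LD matrix")
        return int(idx[0])


def ld_matrix(
    geno: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
) -> LdMatrix:
    """Pairwise dosage correlations over non-missing individuals.

    Monomorphic variants get NaN against every partner (undefined r).
    """
    if region is not None:
        chrom, start, end = region
        mask = (
            (geno.variants["chrom"] == chrom)
            & (geno.variants["pos"] >= start)
            & (geno.variants["pos"] <= end)
        ).to_numpy()
        geno = geno.subset_variants(mask)
    if geno.n_variants < 2:
        raise ValueError("need at least two variants to compute LD")
    dos = geno.dosages
    if np.all(np.isfinite(dos)):
        sd = dos.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(dos, rowvar=False)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    else:  # pairwise complete observations
        import pandas as pd

        r = pd.DataFrame(dos).corr(min_periods=2).to_numpy()
    return LdMatrix(
        variant_ids=geno.variant_ids.copy(),
        r=r,
        positions=geno.variants["pos"].to_numpy(),
    )


def ld_credible_set(
    lead: str,
    ld: LdMatrix,
    r2_min: float = 0.90,
    method: str | None = None,
    source: str | None = None,
) -> CredibleSet:
    """All variants with r2 >= ``r2_min`` to the lead; the lead is always in."""
    i = ld.index(lead)
    r2_lead = ld.r2[i]
    if not np.isfinite(r2_lead[i]):
        raise ValueError(f"lead variant {lead} is monomorphic; LD undefined")
    members_mask = np.isfinite(r2_lead) & (r2_lead >= r2_min)
    members_mask[i] = True
    members = [str(v) for v in ld.variant_ids[members_mask]]
    span = None
    if ld.positions is not None:
        pos = ld.positions[members_mask]
        span = (int(pos.min()), int(pos.max()))
    return CredibleSet(
        method=method or ("LD90" if r2_min >= 0.90 else "LD80"),
        lead=lead,
        members=members,
        source=source,
        r2_to_lead={str(v): float(r2_lead[ld.index(str(v))]) for v in members},
        span=span,
    )


# ---------------------------------------------------------------------------
# IBSS (sum of single effects on summary statistics)
# ---------------------------------------------------------------------------

def _ser_fit(
    Xtr: np.ndarray,
    d: np.ndarray,
    sigma2: float,
    prior_var_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Single-effect regression on residual sufficient statistics.

    Returns (alpha, posterior mean, posterior second moment, chosen prior
    variance). The prior variance is selected from the grid by maximizing
    the single-effect marginal likelihood under a uniform prior over
    variants.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        bhat = Xtr / d
        shat2 = sigma2 / d
    valid = np.isfinite(bhat) & (d > 0)
    z2 = np.where(valid, bhat**2 / shat2, 0.0)

    best = None
    for v0 in prior_var_grid:
        log_bf = np.where(
            valid,
            0.5 * np.log(shat2 / (shat2 + v0)) + 0.5 * z2 * v0 / (v0 + shat2),
            -np.inf,
        )
        mx = log_bf.max()
        loglik = mx + np.log(np.mean(np.exp(log_bf - mx)))
        if best is None or loglik > best[0]:
            best = (loglik, v0, log_bf)
    loglik, v0, log_bf = best
    w = np.exp(log_bf - log_bf.max())
    alpha = w / w.sum()
    post_var = 1.0 / (d / sigma2 + 1.0 / v0)
    post_var = np.where(valid, post_var, 0.0)
    mu1 = post_var * Xtr / sigma2
    mu2 = post_var + mu1**2
    return alpha, np.where(valid, mu1, 0.0), np.where(valid, mu2, 0.0), float(v0)


def _purity(members_idx: np.ndarray, r: np.ndarray) -> float:
    if members_idx.size == 1:
        return 1.0
    sub = np.abs(r[np.ix_(members_idx, members_idx)])
    iu = np.triu_indices(members_idx.size, 1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.min()) if vals.size else 0.0


@dataclass
class IbssFit:
    """Posterior summaries of the sum-of-single-effects fit."""

    alpha: np.ndarray  # (L, p) per-effect inclusion probabilities
    mu: np.ndarray  # (L, p) per-effect posterior means (given inclusion)
    pip: np.ndarray  # (p,) overall posterior inclusion probabilities
    prior_variances: np.ndarray  # (L,)
    n_iter: int


def ibss_fit(
    z_scores: np.ndarray,
    ld: LdMatrix,
    n: int,
    L: int = 10,
    max_iter: int = 200,
    tol: float = 1e-8,
    prior_var_grid: np.ndarray | None = None,
) -> IbssFit:
    """IBSS on summary statistics (z-scores plus in-sample LD).

    Summary statistics are mapped to the sufficient statistics of a
    regression with standardized genotypes and phenotype (X'X = (n-1) R,
    X'y = sqrt(n-1) z, y'y = n-1, residual variance fixed at 1), then each
    of L single-effect vectors is refitted in turn on residual statistics
    until the inclusion probabilities stabilize. Per effect, the prior
    effect variance is chosen on a geometric grid by maximizing the
    single-effect marginal likelihood.
    """
    z = np.asarray(z_scores, dtype=float)
    p = z.shape[0]
    if ld.r.shape[0] != p:
        raise ValueError("z-scores and LD matrix dimensions differ")
    R = np.nan_to_num(ld.r, nan=0.0)
    np.fill_diagonal(R, 1.0)
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < -1e-8:
        logger.info("LD matrix not PSD (min eig %.2e); regularizing", eigmin)
        R = R + 1e-4 * np.eye(p)

    nn = n - 1
    XtX = nn * R
    Xty = np.sqrt(nn) * z
    d = np.diag(XtX).copy()
    sigma2 = 1.0
    if prior_var_grid is None:
        prior_var_grid = np.geomspace(1e-4, 1.0, 13)

    L = min(L, p)
    alpha = np.full((L, p), 1.0 / p)
    mu1 = np.zeros((L, p))
    v0 = np.zeros(L)
    b_bar = np.zeros(p)
    it = 0
    for it in range(1, max_iter + 1):
        alpha_old = alpha.copy()
        for l in range(L):
            b_l = alpha[l] * mu1[l]
            b_others = b_bar - b_l
            Xtr = Xty - XtX @ b_others
            alpha[l], mu1[l], _, v0[l] = _ser_fit(Xtr, d, sigma2, prior_var_grid)
            b_bar = b_others + alpha[l] * mu1[l]
        if np.max(np.abs(alpha - alpha_old)) < tol:
            break
    pip = 1.0 - np.prod(1.0 - alpha, axis=0)
    return IbssFit(alpha=alpha, mu=mu1, pip=pip, prior_variances=v0, n_iter=it)


def ibss_finemap(
    z_scores: np.ndarray,
    ld: LdMatrix,
    n: int,
    L: int = 10,
    coverage: float = 0.95,
    purity_min: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-8,
    prior_var_grid: np.ndarray | None = None,
) -> list[CredibleSet]:
    """Credible sets from the sum-of-single-effects fit.

    Per effect, the smallest inclusion-ordered set reaching ``coverage``;
    sets below the purity threshold (minimum absolute pairwise correlation
    among members) and duplicate or catch-all sets are discarded.
    """
    fit = ibss_fit(
        z_scores, ld, n, L=L, max_iter=max_iter, tol=tol,
        prior_var_grid=prior_var_grid,
    )
    alpha, pip = fit.alpha, fit.pip
    L = alpha.shape[0]
    p = alpha.shape[1]
    sets: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for l in range(L):
        order = np.argsort(alpha[l])[::-1]
        csum = np.cumsum(alpha[l][order])
        k = int(np.searchsorted(csum, coverage) + 1)
        members_idx = np.sort(order[:k])
        if frozenset(members_idx) in seen:
            continue
        # effects that captured nothing spread mass over all variants
        if members_idx.size >= p or members_idx.size > 0.5 * p:
            continue
        if _purity(members_idx, ld.r) < purity_min:
            continue
        seen.add(frozenset(members_idx))
        ids = [str(v) for v in ld.variant_ids[members_idx]]
        lead = ids[int(np.argmax(alpha[l][members_idx]))]
        span = None
        if ld.positions is not None:
            pos = ld.positions[members_idx]
            span = (int(pos.min()), int(pos.max()))
        sets.append(
            CredibleSet(
                method="IBSS",
                lead=lead,
                members=ids,
                pip={i: float(pip[ld.index(i)]) for i in ids},
                coverage=coverage,
                span=span,
            )
        )
    return sets


# ---------------------------------------------------------------------------
# multi-trait CS and overlap summaries
# ---------------------------------------------------------------------------

def mt_credible_set(
    mt_results: dict[str, MtGwasResult],
    st_results: dict[str, GwasResult],
    trait_groups: dict[str, list[str]],
    ld: LdMatrix,
    region: tuple[str, int, int],
    r2_min: float = 0.90,
    qualify: float = 1e-7,
) -> CredibleSet | None:
    """Qualification-and-merge of the two trait-group scans in one region.

    A group qualifies when at least one of its traits has a single-trait
    p < ``qualify`` inside the region. Each qualifying group contributes an
    LD-based CS around its multi-trait lead; two qualifying groups have
    their CS merged ("MT-merged"); none qualifying yields None.
    """
    chrom, start, end = region

    def best_st_p(trait: str) -> float:
        t = st_results[trait].table
        sel = (
            (t["chrom"] == chrom) & (t["pos"] >= start) & (t["pos"] <= end)
            & t["p"].notna()
        )
        return float(t.loc[sel, "p"].min()) if sel.any() else 1.0

    group_cs: list[tuple[CredibleSet, float]] = []
    for gname, traits in trait_groups.items():
        if not any(best_st_p(tr) < qualify for tr in traits if tr in st_results):
            continue
        mt = mt_results[gname].table
        sel = (
            (mt["chrom"] == chrom) & (mt["pos"] >= start) & (mt["pos"] <= end)
            & mt["p"].notna()
        )
        if not sel.any():
            continue
        sub = mt[sel].sort_values(["p", "pos"], kind="mergesort")
        lead = str(sub.iloc[0]["variant_id"])
        group_cs.append(
            (ld_credible_set(lead, ld, r2_min=r2_min, source=gname),
             float(sub.iloc[0]["p"]))
        )
    if not group_cs:
        return None
    if len(group_cs) == 1:
        cs = group_cs[0][0]
        return CredibleSet(
            method="MT-merged",
            lead=cs.lead,
            members=cs.members,
            source=cs.source,
            r2_to_lead=cs.r2_to_lead,
            span=cs.span,
        )
    merged: list[str] = []
    for cs, _ in group_cs:
        merged.extend(m for m in cs.members if m not in merged)
    lead = min(group_cs, key=lambda cp: cp[1])[0].lead  # smallest MT Wald p
    spans = [cs.span for cs, _ in group_cs if cs.span]
    span = (min(s[0] for s in spans), max(s[1] for s in spans)) if spans else None
    return CredibleSet(
        method="MT-merged",
        lead=lead,
        members=merged,
        source="+".join(cs.source or "" for cs, _ in group_cs),
        span=span,
    )


def cs_overlap_summary(cs_list: list[CredibleSet]) -> dict:
    """Pairwise/global sharing of CS members and IBSS-in-LD containment."""
    if len(cs_list) < 2:
        raise ValueError("need at least two credible sets to summarize overlap")
    sets = [cs.member_set() for cs in cs_list]
    global_inter = set.intersection(*sets)
    pairwise = {}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise[(i, j)] = len(sets[i] & sets[j])
    ibss = [cs for cs in cs_list if cs.method == "IBSS"]
    ld_based = [cs for cs in cs_list if cs.method.startswith("LD") or cs.method == "MT-merged"]
    containment = {}
    for cs in ibss:
        containment[cs.lead] = any(
            cs.member_set() <= other.member_set() for other in ld_based
        )
    return {
        "n_cs": len(cs_list),
        "global_shared": len(global_inter),
        "share_at_least_one": all(v > 0 for v in pairwise.values()),
        "all_identical": all(s == sets[0] for s in sets[1:]),
        "pairwise_shared": pairwise,
        "ibss_contained_in_ld": containment,
    }
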