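"""Sharing of association signals between trait pairs within a QTL region.

For two traits' scans, all variants within a window (default 1 Mb) around
the lead of the stronger trait are taken, variants non-significant
(p > 0.05) in both traits are excluded, and the Pearson correlation of
t-values (primary) and of signed -log10 p-values (secondary) is reported.
A strongly negative correlation between a size trait and a muscling trait
is the simulated analogue of the antagonistic pleiotropy seen in selected
beef cattle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GwasResult


@dataclass
class PleiotropyResult:
    trait_a: str
    trait_b: str
    t_correlation: float | None
    signed_logp_correlation: float | None
    n_snps: int
    window: int
    lead: str
    reliable: bool


def pleiotropy_correlation(
    gwas_a: GwasResult,
    gwas_b: GwasResult,
    lead: str,
    window: int = 1_000_000,
    exclude_p: float = 0.05,
) -> PleiotropyResult:
    """Correlate per-variant statistics of two traits around a lead variant.

    Variants with p > ``exclude_p`` in both traits are dropped (effects are
    not expected to be shared for unassociated variants). With fewer than 3
    retained variants the result is flagged unreliable and correlations are
    omitted.
    """
    ta, tb = gwas_a.table, gwas_b.table
    lead_row = ta[ta["variant_id"] == lead]
    if lead_row.empty:
        lead_row = tb[tb["variant_id"] == lead]
    if lead_row.empty:
        raise KeyError(f"lead {lead} not found in either scan")
    chrom = lead_row.iloc[0]["chrom"]
    center = int(lead_row.iloc[0]["pos"])

    merged = pd.merge(
        ta, tb, on=["variant_id", "chrom", "pos"], suffixes=("_a", "_b")
    )
    sel = (
        (merged["chrom"] == chrom)
        & (merged["pos"] >= center - window)
        & (merged["pos"] <= center + window)
        & merged["t_a"].notna()
        & merged["t_b"].notna()
    )
    sub = merged[sel]
    keep = (sub["p_a"] <= exclude_p) | (sub["p_b"] <= exclude_p)
    sub = sub[keep]
    n = len(sub)
    if n < 3:
        return PleiotropyResult(
            trait_a=gwas_a.trait, trait_b=gwas_b.trait,
            t_correlation=None, signed_logp_correlation=None,
            n_snps=n, window=window, lead=lead, reliable=False,
        )
    t_corr = float(np.corrcoef(sub["t_a"], sub["t_b"])[0, 1])
    slp_a = np.sign(sub["beta_a"]) * (-np.log10(sub["p_a"]))
    slp_b = np.sign(sub["beta_b"]) * (-np.log10(sub["p_b"]))
    s_corr = float(np.corrcoef(slp_a, slp_b)[0, 1])
    return PleiotropyResult(
        trait_a=gwas_a.trait, trait_b=gwas_b.trait,
        t_correlation=t_corr, signed_logp_correlation=s_corr,
        n_snps=n, window=window, lead=lead, reliable=True,
    )


def pleiotropy_matrix(
    scans: dict[str, GwasResult], lead: str, window: int = 1_000_000
) -> pd.DataFrame:
    """Pairwise t-value correlation matrix across traits at one region."""
    names = list(scans)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = pleiotropy_correlation(scans[a], scans[b], lead, window)
            val = res.t_correlation if res.reliable else np.nan
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat
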