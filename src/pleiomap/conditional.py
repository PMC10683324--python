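"""Iterative conditional mapping within 10-Mb regions.

Candidate variants (coding variants in the credible set when available,
else lead variants) are fitted as fixed covariates in the mixed model and
the region is rescanned; traits are only rescanned when they showed prior
evidence (-log10 p > 7) in the initial genome scan. New leads exceeding the
region-level threshold (2.5e-6 for the first round, 2e-5 thereafter, both
derivable from region-level effective test counts) are appended to the
covariates and the procedure repeats until nothing new is found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, GwasResult
from .lmm import GrmEigen, MvNullFit, NullFit, fit_null, mt_scan, st_scan


@dataclass
class ConditionalRound:
    round_index: int
    region: tuple[str, int, int]
    covariate_ids: list[str]
    results: dict[str, GwasResult]
    threshold: float
    new_leads: list[str] = field(default_factory=list)


def region_around(
    geno: GenotypeMatrix, center_variant: str, span: int = 10_000_000
) -> tuple[str, int, int]:
    """10-Mb (default) window centered on a variant."""
    j = geno.variant_index(center_variant)
    chrom = str(geno.variants.loc[j, "chrom"])
    pos = int(geno.variants.loc[j, "pos"])
    return (chrom, max(1, pos - span // 2), pos + span // 2)


def conditional_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    eigen: GrmEigen,
    covariate_snps: list[str],
    region: tuple[str, int, int],
    null: NullFit | None = None,
    extra_covariates: np.ndarray | None = None,
    trait: str = "trait",
) -> GwasResult:
    """Single-trait scan of a region with candidate variants as fixed effects.

    The null variance components are re-estimated with the covariates in
    the model (cheap at region scale); covariate variants themselves come
    back flagged collinear.
    """
    cols = [geno.variant_index(v) for v in covariate_snps]
    cov = geno.dosages[:, cols] if cols else None
    if extra_covariates is not None:
        cov = (
            extra_covariates if cov is None
            else np.column_stack([cov, extra_covariates])
        )
    if null is None:
        null = fit_null(y, eigen, cov)
    return st_scan(
        y, geno, eigen, null, covariates=cov, region=region, trait=trait,
        covariate_names=list(covariate_snps),
    )


def conditional_scan_mv(
    Y: np.ndarray,
    geno: GenotypeMatrix,
    eigen: GrmEigen,
    null: MvNullFit,
    covariate_snps: list[str],
    region: tuple[str, int, int],
    traits: list[str] | None = None,
):
    cols = [geno.variant_index(v) for v in covariate_snps]
    cov = geno.dosages[:, cols] if cols else None
    return mt_scan(
        Y, geno, eigen, null, covariates=cov, region=region, traits=traits,
        covariate_names=list(covariate_snps),
    )


def conditional_rounds(
    phenos: dict[str, np.ndarray],
    geno: GenotypeMatrix,
    eigen: GrmEigen,
    initial_candidates: list[str],
    region: tuple[str, int, int],
    thresholds: list[float] = (2.5e-6, 2e-5),
    max_rounds: int = 3,
) -> list[ConditionalRound]:
    """Iterate conditional scans, absorbing new significant leads as covariates.

    ``phenos`` holds only the traits with prior evidence in the region. A
    variant can be added as covariate once (oscillation guard); rounds past
    the threshold list reuse its last entry.
    """
    covariates = list(initial_candidates)
    rounds: list[ConditionalRound] = []
    for k in range(max_rounds):
        thr = thresholds[min(k, len(thresholds) - 1)]
        results = {
            trait: conditional_scan(
                y, geno, eigen, covariates, region, trait=trait
            )
            for trait, y in phenos.items()
        }
        new_leads: list[str] = []
        for res in results.values():
            sig = res.significant(thr)
            if len(sig):
                lead = str(
                    sig.sort_values(["p", "pos"], kind="mergesort").iloc[0][
                        "variant_id"
                    ]
                )
                if lead not in covariates and lead not in new_leads:
                    new_leads.append(lead)
        rounds.append(
            ConditionalRound(
                round_index=k + 1,
                region=region,
                covariate_ids=list(covariates),
                results=results,
                threshold=thr,
                new_leads=new_leads,
            )
        )
        if not new_leads:
            break
        covariates.extend(new_leads)
    return rounds
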