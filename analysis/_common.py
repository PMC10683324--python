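"""Shared helpers for the numbered analysis drivers.

The drivers form a pipeline over one synthetic cohort: each reads what the
previous steps wrote under results/ and recomputes nothing it can load.
"""

from __future__ import annotations

import json
import os

import numpy as np

import pleiomap as pm

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

TRAIT_GROUPS = {
    "size": ["height", "length", "pelvis_length", "pelvis_width",
             "chest_width", "rib_shape"],
    "muscle": ["top_muscling", "shoulder_muscling", "buttock_side",
               "buttock_rear", "rump", "chest_width"],
}


def results_path(*parts: str) -> str:
    path = os.path.join(RESULTS, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def load_cohort():
    geno, _ = pm.read_genotypes(results_path("cohort", "genotypes.vcf"),
                                format="vcf")
    pheno = pm.read_phenotypes(results_path("cohort", "phenotypes.tsv"))
    annot = pm.read_annotations(results_path("cohort", "annotations.tsv"))
    with open(results_path("cohort", "truth.json")) as fh:
        truth = json.load(fh)
    return geno, pheno, annot, truth


def load_qc_cohort():
    """Cohort restricted to the variants retained by the QC driver."""
    geno, pheno, annot, truth = load_cohort()
    kept_file = results_path("gwas", "kept_variants.txt")
    if os.path.exists(kept_file):
        with open(kept_file) as fh:
            kept = set(fh.read().split())
        geno = geno.subset_variants(
            np.isin(geno.variant_ids, list(kept))
        )
    return geno, pheno, annot, truth


def grm_eigen(geno) -> pm.GrmEigen:
    """Eigendecomposition of the all-marker GRM, cached between drivers."""
    cache = results_path("cohort", "grm_eigen.npz")
    if os.path.exists(cache):
        dat = np.load(cache)
        grm = pm.Grm(matrix=dat["grm"], n_markers=int(dat["n_markers"]))
        return pm.GrmEigen(values=dat["values"], vectors=dat["vectors"],
                           source=grm)
    eigen = pm.eigendecompose(pm.compute_grm(geno))
    np.savez_compressed(
        cache, values=eigen.values, vectors=eigen.vectors,
        grm=eigen.source.matrix, n_markers=eigen.source.n_markers,
    )
    return eigen


def load_scans(trait_names) -> dict[str, pm.GwasResult]:
    import pandas as pd

    out = {}
    for trait in trait_names:
        table = pd.read_csv(results_path("gwas", f"{trait}.tsv"), sep="\t")
        table["reason"] = table.get("reason", "").fillna("")
        out[trait] = pm.GwasResult(trait=trait, table=table)
    return out
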