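"""Fine-map every QTL region: LD-based, IBSS and multi-trait credible sets.

Per region and significant trait: LD credible sets at r2 >= 0.90 / 0.80
around the trait lead, and IBSS 95% credible sets from the single-trait
z-scores with the in-sample LD. The two six-trait groups are scanned with
the multivariate model; groups qualifying (best single-trait p below the
suggestive level in the region) contribute a multi-trait LD credible set,
merged when both qualify. Writes results/credible_sets.tsv and an overlap
summary per region.
"""

import json

import pandas as pd

import pleiomap as pm
from _common import (TRAIT_GROUPS, grm_eigen, load_qc_cohort, load_scans,
                     results_path)


def main() -> None:
    geno, pheno, _, _ = load_qc_cohort()
    eigen = grm_eigen(geno)
    regions = pd.read_csv(results_path("qtl_regions.tsv"), sep="\t")
    with open(results_path("thresholds.json")) as fh:
        thr = json.load(fh)
    suggestive = min(10 * thr["cohort_threshold"], 1e-4)
    scans = load_scans(pheno.trait_names)

    mt_results = {}
    for gname, traits in TRAIT_GROUPS.items():
        Y = pheno.to_frame()[traits].to_numpy()
        mv = pm.fit_null_mv(Y, eigen)
        mt_results[gname] = pm.mt_scan(Y, geno, eigen, mv, traits=traits)
        mt_results[gname].table.to_csv(
            results_path("gwas", f"mt_{gname}.tsv"), sep="\t", index=False
        )

    cs_rows, overlap_rows = [], []
    for _, reg in regions.iterrows():
        window = (reg["chrom"], max(1, reg["span_start"] - 2_500_000),
                  reg["span_end"] + 2_500_000)
        ld = pm.ld_matrix(geno, region=window)
        region_sets = []
        for trait in reg["significant_traits"].split(","):
            table = scans[trait].table
            sel = (
                (table["chrom"] == reg["chrom"])
                & table["variant_id"].isin(ld.variant_ids)
                & table["p"].notna()
            )
            sub = table[sel].sort_values(["p", "pos"], kind="mergesort")
            lead = str(sub.iloc[0]["variant_id"])
            for r2_min in (0.90, 0.80):
                cs = pm.ld_credible_set(lead, ld, r2_min, source=trait)
                region_sets.append(cs)
            z = (sub.set_index("variant_id")
                 .loc[ld.variant_ids, "t"].to_numpy())
            for cs in pm.ibss_finemap(z, ld, n=int(sub["n"].iloc[0]), L=5):
                cs.source = trait
                region_sets.append(cs)
        mt_cs = pm.mt_credible_set(
            mt_results, scans, TRAIT_GROUPS, ld,
            region=window, qualify=suggestive,
        )
        if mt_cs is not None:
            region_sets.append(mt_cs)
        for cs in region_sets:
            for member in cs.members:
                cs_rows.append(
                    {
                        "region_id": reg["region_id"],
                        "method": cs.method,
                        "source": cs.source,
                        "lead": cs.lead,
                        "member": member,
                        "r2_to_lead": (cs.r2_to_lead or {}).get(member),
                        "pip": (cs.pip or {}).get(member),
                        "cs_size": cs.size,
                    }
                )
        if len(region_sets) >= 2:
            summary = pm.cs_overlap_summary(region_sets)
            overlap_rows.append(
                {
                    "region_id": reg["region_id"],
                    "n_cs": summary["n_cs"],
                    "share_at_least_one": summary["share_at_least_one"],
                    "all_identical": summary["all_identical"],
                    "ibss_contained_in_ld": json.dumps(
                        summary["ibss_contained_in_ld"]
                    ),
                }
            )
        mt_note = f", MT CS size {mt_cs.size}" if mt_cs else ""
        print(f"  {reg['region_id']}: {len(region_sets)} credible sets"
              f"{mt_note}")

    pd.DataFrame(cs_rows).to_csv(results_path("credible_sets.tsv"), sep="\t",
                                 index=False)
    pd.DataFrame(overlap_rows).to_csv(results_path("cs_overlap.tsv"),
                                      sep="\t", index=False)


if __name__ == "__main__":
    main()
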