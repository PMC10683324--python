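"""Conditional mapping in 10-Mb regions around the selected candidates.

Per QTL region the candidate variant is the coding member of the
multi-trait credible set when one exists, else the lead SNP. Candidates
are fitted as fixed covariates and the region rescanned for every trait
with prior evidence; new leads above the per-round threshold are absorbed
and the scan repeated.
"""

import json

import pandas as pd

import pleiomap as pm
from _common import load_qc_cohort, load_scans, results_path


def main() -> None:
    geno, pheno, annot, _ = load_qc_cohort()
    regions = pd.read_csv(results_path("qtl_regions.tsv"), sep="\t")
    cs = pd.read_csv(results_path("credible_sets.tsv"), sep="\t")
    with open(results_path("thresholds.json")) as fh:
        thr = json.load(fh)
    suggestive = min(10 * thr["cohort_threshold"], 1e-4)
    scans = load_scans(pheno.trait_names)
    coding = annot.coding_ids()
    eigen = None

    summary = []
    for _, reg in regions.iterrows():
        mt_members = cs[(cs["region_id"] == reg["region_id"])
                        & (cs["method"] == "MT-merged")]["member"]
        coding_in_cs = [v for v in mt_members if v in coding]
        candidate = coding_in_cs[0] if coding_in_cs else reg["lead"]
        region = pm.region_around(geno, candidate)
        # traits with prior evidence in the first scan
        tested = {}
        for trait in pheno.trait_names:
            t = scans[trait].table
            sel = ((t["chrom"] == region[0]) & (t["pos"] >= region[1])
                   & (t["pos"] <= region[2]) & t["p"].notna())
            if sel.any() and t.loc[sel, "p"].min() < suggestive:
                tested[trait] = pheno.trait(trait)
        if not tested:
            continue
        if eigen is None:
            from _common import grm_eigen

            eigen = grm_eigen(geno)
        rounds = pm.conditional_rounds(
            tested, geno, eigen, [candidate], region,
            thresholds=[thr["cohort_threshold"], 10 * thr["cohort_threshold"]],
        )
        for rnd in rounds:
            for trait, res in rnd.results.items():
                res.table.to_csv(
                    results_path("conditional",
                                 f"{reg['region_id'].replace(':', '_')}"
                                 f"_round{rnd.round_index}_{trait}.tsv"),
                    sep="\t", index=False,
                )
        last = rounds[-1]
        summary.append(
            {
                "region_id": reg["region_id"],
                "candidate": candidate,
                "candidate_is_coding": candidate in coding,
                "n_rounds": len(rounds),
                "final_covariates": ",".join(
                    last.covariate_ids + last.new_leads
                ),
                "n_traits_tested": len(tested),
                "secondary_signal": len(rounds) > 1,
            }
        )
        print(f"  {reg['region_id']}: candidate {candidate} "
              f"({'coding' if candidate in coding else 'lead'}), "
              f"{len(rounds)} round(s), "
              f"{'secondary QTL found' if len(rounds) > 1 else 'signal captured'}")
    pd.DataFrame(summary).to_csv(results_path("conditional_summary.tsv"),
                                 sep="\t", index=False)


if __name__ == "__main__":
    main()
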