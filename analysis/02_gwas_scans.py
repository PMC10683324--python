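"""QC the cohort, fit the mixed model and run all single-trait scans.

Reads results/cohort/, applies the marker and individual filters, builds
the VanRaden GRM, estimates variance components per trait by REML and
writes one association table per trait under results/gwas/.
"""

import json

import pleiomap as pm
from _common import grm_eigen, load_cohort, results_path


def main() -> None:
    geno, pheno, _, _ = load_cohort()
    geno, ind_report = pm.qc_individuals(geno)
    geno, var_report = pm.qc_variants(geno)
    var_report.to_json(results_path("gwas", "qc_report.json"))
    with open(results_path("gwas", "kept_variants.txt"), "w") as fh:
        fh.write("\n".join(map(str, geno.variant_ids)) + "\n")
    print(f"QC: {var_report.retained_variants}/{var_report.input_variants} "
          f"variants, {ind_report.retained_individuals} individuals retained")

    eigen = grm_eigen(geno)
    h2 = {}
    for trait in pheno.trait_names:
        y = pheno.trait(trait)
        null = pm.fit_null(y, eigen)
        h2[trait] = round(null.h2, 3)
        res = pm.st_scan(y, geno, eigen, null, trait=trait)
        res.table.to_csv(results_path("gwas", f"{trait}.tsv"), sep="\t",
                         index=False)
        top = res.table.loc[res.table["p"].idxmin()]
        print(f"  {trait:18s} h2={null.h2:.2f} top {top['variant_id']} "
              f"p={top['p']:.2e}")
    with open(results_path("gwas", "heritability.json"), "w") as fh:
        json.dump(h2, fh, indent=2)


if __name__ == "__main__":
    main()
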