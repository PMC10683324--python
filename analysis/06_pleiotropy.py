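"""Quantify signal sharing between traits within each QTL region.

For every pair of significant (or suggestive) traits in a region, the
Pearson correlation of t-values over the SNPs within 1 Mb of the lead
(excluding SNPs non-significant in both traits) measures whether one
pleiotropic variant or distinct linked variants drive the signals.
"""

import pandas as pd

import pleiomap as pm
from _common import load_qc_cohort, load_scans, results_path


def main() -> None:
    _, pheno, _, _ = load_qc_cohort()
    regions = pd.read_csv(results_path("qtl_regions.tsv"), sep="\t")
    scans = load_scans(pheno.trait_names)

    rows = []
    for _, reg in regions.iterrows():
        traits = reg["significant_traits"].split(",")
        if isinstance(reg["suggestive_traits"], str) and reg["suggestive_traits"]:
            traits += reg["suggestive_traits"].split(",")
        lead = reg["lead"]
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                res = pm.pleiotropy_correlation(scans[a], scans[b], lead)
                rows.append(
                    {
                        "region_id": reg["region_id"],
                        "trait_a": a,
                        "trait_b": b,
                        "t_correlation": res.t_correlation,
                        "signed_logp_correlation": res.signed_logp_correlation,
                        "n_snps": res.n_snps,
                        "reliable": res.reliable,
                    }
                )
    out = pd.DataFrame(rows)
    out.to_csv(results_path("pleiotropy.tsv"), sep="\t", index=False)
    ok = out[out["reliable"]]
    same = ok[ok["t_correlation"].abs() > 0.7]
    print(f"{len(ok)} reliable trait pairs across regions; "
          f"{len(same)} with |t correlation| > 0.7")
    for rid, sub in ok.groupby("region_id"):
        rng = sub["t_correlation"]
        print(f"  {rid}: t-correlations {rng.min():+.2f} .. {rng.max():+.2f}")


if __name__ == "__main__":
    main()
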