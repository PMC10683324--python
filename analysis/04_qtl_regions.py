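"""Call per-trait QTL and group them into cross-trait QTL regions.

Uses the cohort threshold from the calibration step, the 1-Mb grouping
rule and the suggestive level 1e-7 scaled to this cohort (the cohort
threshold itself, since the scans are far smaller than a sequence panel,
with the suggestive level one order of magnitude above it).
"""

import json

import pandas as pd

import pleiomap as pm
from _common import load_qc_cohort, load_scans, results_path


def main() -> None:
    geno, pheno, _, _ = load_qc_cohort()
    with open(results_path("thresholds.json")) as fh:
        thr = json.load(fh)
    threshold = thr["cohort_threshold"]
    suggestive = min(10 * threshold, 1e-4)
    scans = load_scans(pheno.trait_names)
    qtl_lists = {t: pm.call_qtl(s, threshold) for t, s in scans.items()}
    n_qtl = sum(len(v) for v in qtl_lists.values())
    regions = pm.build_qtlr(qtl_lists, scans, suggestive=suggestive)
    print(f"{n_qtl} QTL across traits -> {len(regions)} QTL regions "
          f"(threshold {threshold:.2e}, suggestive {suggestive:.2e})")

    rows = []
    for r in regions:
        lead_id, lead_pos, lead_p = r.best_lead
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "span_start": r.span[0],
                "span_end": r.span[1],
                "lead": lead_id,
                "lead_p": lead_p,
                "n_significant_traits": len(r.significant_traits),
                "significant_traits": ",".join(r.significant_traits),
                "suggestive_traits": ",".join(r.suggestive_traits),
            }
        )
        print(f"  {r.region_id}: lead {lead_id} (p={lead_p:.2e}), "
              f"{len(r.significant_traits)} significant traits "
              f"+ {len(r.suggestive_traits)} suggestive")
    pd.DataFrame(rows).to_csv(results_path("qtl_regions.tsv"), sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
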