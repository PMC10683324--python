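"""Coding-variant enrichment in the credible sets and variance explained.

Two layers: (i) the study-scale arithmetic from the published credible-set
sizes (11 multi-trait CS, 330 members, coding rate 0.34%) reproducing the
printed expectation of ~1.1 coding variants and its tail probabilities;
(ii) the same test on this cohort's own multi-trait credible sets and
annotations, plus jointly fitted candidate effects and the share of
genetic variance they explain.
"""

import json

import numpy as np
import pandas as pd

import pleiomap as pm
from _common import grm_eigen, load_qc_cohort, results_path

STUDY_CS_SIZES = [2, 57, 6, 1, 116, 11, 86, 5, 6, 20, 20]
STUDY_RATE = 0.0034


def main() -> None:
    geno, pheno, annot, truth = load_qc_cohort()
    out = {}

    study = pm.coding_enrichment(STUDY_CS_SIZES, STUDY_RATE,
                                 observed_total=6, observed_cs_with_coding=5)
    study80 = pm.coding_enrichment([73] * 11, STUDY_RATE,
                                   observed_total=11,
                                   observed_cs_with_coding=8)
    out["study_scale"] = {
        "expected_coding_total": round(study.expected_total, 3),
        "p_total_r2_090": study.p_total,
        "p_cs_count_r2_090": study.p_cs_count,
        "p_total_r2_080": study80.p_total,
        "p_lead_coding": pm.lead_coding_test(11, STUDY_RATE, 5),
    }
    print(f"study scale: expect {study.expected_total:.1f} coding in CS, "
          f"p_total={study.p_total:.1e}, r2>=0.80 p={study80.p_total:.1e}, "
          f"lead p={out['study_scale']['p_lead_coding']:.1e}")

    # this cohort's own MT credible sets
    cs = pd.read_csv(results_path("credible_sets.tsv"), sep="\t")
    mt = cs[cs["method"] == "MT-merged"]
    coding = annot.coding_ids()
    sizes, with_coding, total_coding, leads_coding = [], 0, 0, 0
    for _, sub in mt.groupby("region_id"):
        members = set(sub["member"])
        sizes.append(len(members))
        k = len(members & coding)
        total_coding += k
        with_coding += k > 0
        leads_coding += sub["lead"].iloc[0] in coding
    if sizes:
        own = pm.coding_enrichment(sizes, STUDY_RATE, total_coding,
                                   with_coding)
        out["cohort"] = {
            "n_mt_cs": len(sizes),
            "cs_sizes": sizes,
            "observed_coding": total_coding,
            "expected_coding": round(own.expected_total, 3),
            "p_total": own.p_total,
            "p_cs_count": own.p_cs_count,
            "p_lead_coding": pm.lead_coding_test(len(sizes), STUDY_RATE,
                                                 leads_coding),
        }
        print(f"cohort: {total_coding} coding in {len(sizes)} MT CS "
              f"(expected {own.expected_total:.2f}), p={own.p_total:.2e}")

    # joint candidate effects and genetic-variance shares per trait
    candidates = truth["causal_ids"]
    eigen = grm_eigen(geno)
    freqs = [float(geno.alt_freq()[geno.variant_index(v)])
             for v in candidates]
    shares = {}
    for trait in pheno.trait_names:
        y = pheno.trait(trait)
        null = pm.fit_null(y, eigen)
        betas, ses = pm.joint_variant_effects(y, geno, candidates, eigen,
                                              null)
        sg2_with = pm.refit_sigma_g2_with_candidates(y, geno, candidates,
                                                     eigen)
        vs = pm.variance_shares(candidates, betas, freqs, null.sigma_g2,
                                sigma_g2_with=sg2_with)
        shares[trait] = {
            "per_variant_share": dict(zip(candidates,
                                          np.round(vs.shares, 4))),
            "aggregate_share": round(vs.aggregate_share, 4),
            "polygenic_reduction": round(vs.polygenic_reduction, 4),
        }
    out["variance_shares"] = shares
    agg = [s["aggregate_share"] for s in shares.values()]
    red = [s["polygenic_reduction"] for s in shares.values()]
    print(f"variance explained by the 3 candidates: aggregate share "
          f"{min(agg):.1%}..{max(agg):.1%} per trait; polygenic reduction "
          f"{min(red):.1%}..{max(red):.1%}")

    with open(results_path("enrichment.json"), "w") as fh:
        json.dump(out, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
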