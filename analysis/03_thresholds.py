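"""Calibrate genome-wide significance thresholds for the cohort.

Estimates the effective number of independent tests by permutation of the
height phenotype (simple-regression scans, Sidak inversion), the effective
number of traits by the Galwey estimator on the trait correlation matrix,
and derives the Bonferroni threshold alpha / (meff_tests x meff_traits).
For reference the study-scale arithmetic (500,000 x 7 tests -> 1.43e-8)
is recomputed alongside.
"""

import json

import numpy as np

import pleiomap as pm
from _common import load_cohort, results_path


def main(n_perm: int = 2000, seed: int = 77) -> None:
    geno, pheno, _, _ = load_cohort()
    est = pm.permutation_meff(pheno.trait("height"), geno,
                              n_perm=n_perm, seed=seed)
    corr = np.corrcoef(pheno.values.T)
    meff_traits, floored = pm.galwey_meff(corr)
    cal = pm.significance_threshold(0.05, est.meff, max(floored, 1))
    study = pm.significance_threshold(0.05, 500_000, 7)
    out = {
        "meff_tests": est.meff,
        "n_variants": geno.n_variants,
        "n_permutations": est.n_perm,
        "meff_traits_raw": meff_traits,
        "meff_traits": max(floored, 1),
        "cohort_threshold": cal.threshold,
        "cohort_threshold_neglog10": cal.neglog10_threshold,
        "study_scale_threshold": study.threshold,
        "study_scale_threshold_neglog10": study.neglog10_threshold,
        "suggestive": 1e-7,
    }
    with open(results_path("thresholds.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"meff_tests={est.meff:.0f} of {geno.n_variants} variants; "
          f"meff_traits={meff_traits:.2f} (floored {floored})")
    print(f"cohort threshold {cal.threshold:.2e} "
          f"(-log10 {cal.neglog10_threshold:.2f}); study-scale "
          f"{study.threshold:.2e} (-log10 {study.neglog10_threshold:.2f})")


if __name__ == "__main__":
    main()
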