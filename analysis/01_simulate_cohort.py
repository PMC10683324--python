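"""Generate the synthetic mapping cohort and write it to results/cohort/.

The cohort stands in for a restricted-license beef-cattle dataset: 1,500
cows, three chromosomes of sequence-like dosages with LD blocks, 11
correlated conformation traits (six body-size, five muscling) with h2 =
0.3, three pleiotropic QTL (one recessive deleterious with favorable
additive effects), and VEP-like annotations with coding variants at 0.34%.
"""

import json
import sys

import numpy as np

import pleiomap as pm
from _common import results_path


def main(seed: int = 7) -> None:
    cfg = pm.default_cohort_config(seed=seed)
    print(f"simulating cohort: n={cfg.n_individuals}, "
          f"{cfg.n_chromosomes} chromosomes x {cfg.n_variants_per_chrom} "
          f"variants, {len(cfg.traits)} traits, seed={cfg.seed}")
    geno = pm.simulate_genotypes(cfg)
    pheno, truth = pm.simulate_phenotypes(geno, cfg)
    annot = pm.simulate_annotations(
        geno, coding_rate=cfg.coding_rate, seed=seed + 2,
        force_coding=[q.name for q in cfg.qtl_spec],
    )

    pm.write_vcf(geno, results_path("cohort", "genotypes.vcf"))
    pm.write_phenotypes(pheno, results_path("cohort", "phenotypes.tsv"))
    pm.write_annotations(annot, results_path("cohort", "annotations.tsv"))
    with open(results_path("cohort", "truth.json"), "w") as fh:
        json.dump(
            {
                "seed": seed,
                "causal_ids": truth.causal_ids,
                "effects": {k: list(v) for k, v in truth.effects.items()},
                "recessive_penalties": truth.recessive_penalties,
                "realized_Vg_diag": list(np.diag(truth.realized_Vg)),
                "realized_Ve_diag": list(np.diag(truth.realized_Ve)),
            },
            fh, indent=2,
        )
    print(f"wrote {geno.n_variants} variants, "
          f"{int(annot.coding_mask().sum())} coding "
          f"({annot.coding_mask().mean():.4%}); causal: {truth.causal_ids}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
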