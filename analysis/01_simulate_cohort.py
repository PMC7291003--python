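#!/usr/bin/env python
"""Generate the study cohorts with known ground truth.

Two datasets are written under results/sim/:

* a gene-drop cohort — 50 families (outbred / cousin / half-sib / full-sib
  matings in rotation), 4 genotyped offspring each, on a 6-chromosome genome
  at 50k-chip marker density, with the exact autozygous tracts of every
  offspring recorded;
* a Wright-Fisher cohort — constant Ne = 50, 200 generations, 200 sampled
  diploids, whose LD decay encodes the true Ne.
"""

from pathlib import Path

import pandas as pd

from rohpop.io import write_chromosome_table, write_ped_map, write_pedigree
from rohpop.simulate import cohort_pedigree, gene_drop, scaled_config, wright_fisher

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = scaled_config(n_chromosomes=6, chrom_length_bp=100_000_000,
                        n_markers_per_chrom=2028, missing_rate=0.01, seed=SEED)
    kinds = [["outbred", "cousin", "half_sib", "full_sib"][i % 4] for i in range(50)]
    ped, cohort = cohort_pedigree(kinds, n_offspring_per_family=4)
    gm, truth = gene_drop(ped, cfg, samples=cohort, seed=SEED)
    write_ped_map(gm, OUT / "cohort.ped", OUT / "cohort.map")
    write_pedigree(ped, OUT / "cohort_pedigree.tsv")
    write_chromosome_table(cfg.chromosome_table(), OUT / "chromosomes.tsv")
    truth.fractions.to_csv(OUT / "truth_fractions.tsv", sep="\t", index=False)
    truth.tracts.to_csv(OUT / "truth_tracts.tsv", sep="\t", index=False)
    print(f"gene-drop cohort: {gm.n_samples} samples x {gm.n_markers} markers")
    print(truth.fractions.groupby("true_f_ped")["autozygous_fraction"]
          .agg(["count", "mean"]).round(4).to_string())

    wf_cfg = scaled_config(n_chromosomes=4, chrom_length_bp=100_000_000,
                           n_markers_per_chrom=400, cm_per_mb=1.0, seed=SEED)
    gm_wf = wright_fisher(50, 200, 200, wf_cfg, seed=SEED)
    write_ped_map(gm_wf, OUT / "wf.ped", OUT / "wf.map")
    write_chromosome_table(wf_cfg.chromosome_table(), OUT / "wf_chromosomes.tsv")
    print(f"Wright-Fisher cohort (true Ne = 50): {gm_wf.n_samples} samples x {gm_wf.n_markers} markers")


if __name__ == "__main__":
    main()
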