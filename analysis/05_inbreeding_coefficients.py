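#!/usr/bin/env python
"""Three inbreeding coefficients on the cohort and their agreement.

F_PED (Wright, from the simulated pedigree), F_HOM (excess homozygosity) and
F_ROH (genome fraction in ROH, total and per size class) are computed per
sample, correlated pairwise (Spearman), and compared against the true
autozygous fraction known from the gene drop.
"""

from pathlib import Path

import pandas as pd

from rohpop.inbreeding import compare_coefficients, inbreeding_table, spearman
from rohpop.io import read_chromosome_table, read_ped_map, read_pedigree
from rohpop.roh import read_segments

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_ped_map(SIM / "cohort_qc.ped", SIM / "cohort_qc.map")
    seg = read_segments(OUT / "roh_segments.tsv")
    ped = read_pedigree(SIM / "cohort_pedigree.tsv")
    ct = read_chromosome_table(SIM / "chromosomes.tsv")

    coeffs = inbreeding_table(gm, seg, ped, l_auto_kb=ct.total_length_kb)
    truth = pd.read_csv(SIM / "truth_fractions.tsv", sep="\t")
    coeffs = coeffs.merge(truth[["sample_id", "autozygous_fraction"]], on="sample_id")
    coeffs.to_csv(OUT / "inbreeding.tsv", sep="\t", index=False)
    print(coeffs[["f_ped", "f_hom", "f_roh_total", "autozygous_fraction"]]
          .describe().loc[["mean", "std"]].round(4).to_string())

    cols = ["f_ped", "f_hom", "f_roh_total", "f_roh_short", "f_roh_intermediate", "f_roh_long"]
    usable = [c for c in cols if coeffs[c].nunique() > 1]
    corr = compare_coefficients(coeffs[["sample_id"] + usable])
    corr.to_csv(OUT / "inbreeding_correlations.tsv", sep="\t", index=False)
    get = corr.set_index(["coef_a", "coef_b"])["rho"]
    print(f"\nrho(F_HOM, F_ROH total)        = {get[('f_hom', 'f_roh_total')]:.3f}")
    print(f"rho(F_HOM, F_ROH long class)   = {get[('f_hom', 'f_roh_long')]:.3f}")
    print(f"rho(F_HOM, F_ROH short class)  = {get[('f_hom', 'f_roh_short')]:.3f}")
    rho, _ = spearman(coeffs["f_roh_total"], coeffs["autozygous_fraction"])
    print(f"rho(F_ROH total, TRUE fraction) = {rho:.3f}")


if __name__ == "__main__":
    main()
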