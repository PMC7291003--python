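#!/usr/bin/env python
"""Quality-control the gene-drop cohort: marker/sample call rate, MAF and
Hardy-Weinberg filters, reporting counts removed per step.

Relatedness pruning is deliberately left off here: the cohort is a designed
pedigree sample, so removing PI_HAT >= 0.5 pairs would discard the very
full-sib structure under study (the operation itself is exercised by the
test suite).
"""

from pathlib import Path

from rohpop.io import read_ped_map, write_ped_map
from rohpop.qc import run_qc

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_ped_map(SIM / "cohort.ped", SIM / "cohort.map")
    print(f"input: {gm.n_samples} samples x {gm.n_markers} markers")
    gm_qc, report = run_qc(gm, order=("marker_call_rate", "sample_call_rate", "maf", "hwe"))
    report.to_frame().to_csv(OUT / "qc_report.tsv", sep="\t", index=False)
    write_ped_map(gm_qc, SIM / "cohort_qc.ped", SIM / "cohort_qc.map")
    print(report.to_frame().to_string(index=False))
    print(f"post-QC: {gm_qc.n_samples} samples x {gm_qc.n_markers} markers")


if __name__ == "__main__":
    main()
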