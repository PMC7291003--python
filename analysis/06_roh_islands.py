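#!/usr/bin/env python
"""Pool ROH across the cohort, call top-1% islands, and write the
per-100-kb homozygosity track plus per-SNP allele frequency / gene
diversity, with a BED export of the islands for external annotation.
"""

from pathlib import Path

from rohpop.io import read_chromosome_table, read_ped_map
from rohpop.islands import (
    call_islands,
    export_islands_bed,
    gene_diversity,
    pool_overlaps,
    window_homozygosity_track,
)
from rohpop.roh import read_segments

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_ped_map(SIM / "cohort_qc.ped", SIM / "cohort_qc.map")
    seg = read_segments(OUT / "roh_segments.tsv")
    ct = read_chromosome_table(SIM / "chromosomes.tsv")

    regions = pool_overlaps(seg, gm.n_samples)
    regions.to_csv(OUT / "roh_regions.tsv", sep="\t", index=False)
    isl = call_islands(regions, top_fraction=0.01)
    isl.to_csv(OUT / "roh_islands.tsv", sep="\t", index=False)
    export_islands_bed(isl, OUT / "roh_islands.bed")
    print(f"{len(regions)} overlap regions pooled from {len(seg)} segments; "
          f"{len(isl)} islands in the top 1% (max coverage {isl['coverage'].max():.2f})")

    lengths = {int(r.chrom): int(r.length_bp) for r in ct.table.itertuples(index=False)}
    track = window_homozygosity_track(seg, gm.n_samples, lengths, window_kb=100.0)
    track.to_csv(OUT / "homozygosity_track.tsv", sep="\t", index=False)
    gene_diversity(gm).to_csv(OUT / "gene_diversity.tsv", sep="\t", index=False)
    print(f"100-kb homozygosity track: {len(track)} windows; "
          f"peak fraction {track['fraction'].max():.2f}")


if __name__ == "__main__":
    main()
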