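"""ROH pooling across individuals, top-percentile island calling, and the
per-window homozygosity / per-SNP diversity tracks.

Pooling is an exact breakpoint decomposition: all segment endpoints on a
chromosome cut the union of ROH into atomic intervals, each annotated with
the exact set of samples whose ROH spans it (so "containing the region"
means covering all of it); adjacent intervals supported by the same sample
set are merged back.  Regions whose coverage ranks in the top fraction
(default 1%, empirical percentile = rank/N, ties at the cutoff included)
are called islands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

REGION_COLUMNS = ["chrom", "start_bp", "end_bp", "n_samples", "coverage"]


def pool_overlaps(segments: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Breakpoint decomposition of pooled ROH.

    Coordinates are 1-based inclusive; coverage is the fraction of the
    *n_samples* cohort whose ROH covers the whole region.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rows = []
    for chrom, sub in segments.groupby("chrom"):
        starts = sub["start_bp"].to_numpy(np.int64)
        ends = sub["end_bp"].to_numpy(np.int64)
        sids = sub["sample_id"].to_numpy()
        # half-open sweep coordinates: [start, end+1)
        cuts = np.unique(np.concatenate([starts, ends + 1]))
        atom_starts = cuts[:-1]
        atom_ends = cuts[1:]  # exclusive
        supports: list[frozenset] = []
        keep = []
        for a, b in zip(atom_starts, atom_ends):
            covering = frozenset(sids[(starts <= a) & (ends + 1 >= b)])
            if covering:
                keep.append((int(a), int(b)))
                supports.append(covering)
        # merge adjacent atoms with identical supporting sets
        merged: list[tuple[int, int, frozenset]] = []
        for (a, b), sup in zip(keep, supports):
            if merged and merged[-1][1] == a and merged[-1][2] == sup:
                merged[-1] = (merged[-1][0], b, sup)
            else:
                merged.append((a, b, sup))
        for a, b, sup in merged:
            rows.append((chrom, a, b - 1, len(sup), len(sup) / n_samples))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def call_islands(regions: pd.DataFrame, top_fraction: float = 0.01) -> pd.DataFrame:
    """Regions whose coverage percentile (rank/N, descending) is within
    *top_fraction*; all ties at the cutoff coverage are included, and
    adjacent islands are merged (coverage of a merged island = max of parts).
    """
    if len(regions) == 0:
        raise ValueError("no regions to rank")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0,1]")
    cov = regions["coverage"].to_numpy()
    k = int(np.ceil(top_fraction * len(regions)))
    cutoff = np.sort(cov)[::-1][k - 1]
    isl = regions[cov >= cutoff].copy()
    isl["degenerate"] = bool((cov == cov[0]).all())
    isl = isl.sort_values(["chrom", "start_bp"], kind="mergesort").reset_index(drop=True)
    # merge islands that touch
    merged_rows = []
    for r in isl.itertuples(index=False):
        if (
            merged_rows
            and merged_rows[-1]["chrom"] == r.chrom
            and r.start_bp <= merged_rows[-1]["end_bp"] + 1
        ):
            merged_rows[-1]["end_bp"] = max(merged_rows[-1]["end_bp"], r.end_bp)
            merged_rows[-1]["coverage"] = max(merged_rows[-1]["coverage"], r.coverage)
            merged_rows[-1]["n_samples"] = max(merged_rows[-1]["n_samples"], r.n_samples)
        else:
            merged_rows.append(
                {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
                 "n_samples": r.n_samples, "coverage": r.coverage,
                 "degenerate": r.degenerate}
            )
    return pd.DataFrame(merged_rows)


def window_homozygosity_track(
    segments: pd.DataFrame,
    n_samples: int,
    chrom_length_bp: dict[int, int],
    window_kb: float = 100.0,
    rule: str = "majority",
) -> pd.DataFrame:
    """Per fixed window, the fraction of samples whose ROH covers it.

    rule: "any" (any overlap), "majority" (>= half the window, default) or
    "full" (whole window inside an ROH).
    """
    if rule not in ("any", "majority", "full"):
        raise ValueError(f"unknown window rule {rule!r}")
    need = {"any": 1e-9, "majority": 0.5, "full": 1.0}[rule]
    wbp = int(window_kb * 1000)
    rows = []
    for chrom, length in sorted(chrom_length_bp.items()):
        n_win = int(np.ceil(length / wbp))
        win_start = np.arange(n_win, dtype=np.int64) * wbp + 1
        win_end = np.minimum(win_start + wbp - 1, length)
        counts = np.zeros(n_win)
        sub = segments[segments["chrom"] == chrom]
        for sid, ssub in sub.groupby("sample_id"):
            overlap = np.zeros(n_win)
            for r in ssub.itertuples(index=False):
                ov = np.minimum(win_end, r.end_bp) - np.maximum(win_start, r.start_bp) + 1
                overlap += np.maximum(ov, 0)
            frac = overlap / (win_end - win_start + 1)
            counts += frac >= need
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "window_start_bp": win_start, "window_end_bp": win_end,
                 "n_homozygous": counts.astype(int), "fraction": counts / n_samples}
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "window_start_bp", "window_end_bp", "n_homozygous", "fraction"]
    )


def gene_diversity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP allele frequency p and gene diversity 2p(1-p)."""
    p = gm.allele_b_freq()
    if np.isnan(p).any():
        raise ValueError("gene diversity undefined for all-missing markers")
    return pd.DataFrame(
        {
            "marker_id": gm.markers["marker_id"],
            "chrom": gm.markers["chrom"],
            "pos_bp": gm.markers["pos_bp"],
            "allele_freq": p,
            "gene_diversity": 2.0 * p * (1.0 - p),
        }
    )


def export_islands_bed(islands: pd.DataFrame, path: str | Path) -> None:
    """Write islands as BED (0-based, half-open) with coverage in the score column."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tcoverage\n")
        for k, r in enumerate(islands.itertuples(index=False), 1):
            fh.write(
                f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\tisland_{k}\t{r.coverage:.6g}\n"
            )


def read_islands_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED written by :func:`export_islands_bed` back to 1-based inclusive."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, _name, cov = line.split("\t")
        rows.append((int(chrom), int(start) + 1, int(end), float(cov)))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "coverage"])
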