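"""Sliding-window detection of runs of homozygosity (ROH).

A window of ``window_snps`` consecutive SNPs passes if it contains at most
``max_het_per_window`` heterozygous and ``max_missing_per_window`` missing
calls.  A SNP is "in a run" if the fraction of windows covering it that pass
is at least ``window_hit_fraction``; only windows fully inside the chromosome
are slid, so SNPs near the ends are covered by fewer windows and the fraction
uses the actual covering-window count.  Maximal in-run stretches are split at
physical gaps larger than ``max_gap_kb`` between consecutive SNPs, then
filtered on ``min_snps`` and ``min_length_kb``.

Because the het/missing budget applies per window, a final segment may retain
an isolated heterozygote if the windows spanning it still pass — inherent to
the sliding-window design.

Segments at least 1 Mb long are classified by physical length into
short (1 to <5 Mb), intermediate (5 to <10 Mb) and long (>=10 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

SIZE_CLASSES = ("short", "intermediate", "long")

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb", "size_class"]


@dataclass(frozen=True)
class ROHParams:
    """Detection thresholds; defaults follow common 50k-chip practice."""

    min_length_kb: float = 1000.0
    min_snps: int = 10
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    max_gap_kb: float = 1000.0
    window_snps: int = 50
    window_hit_fraction: float = 0.05
    min_density_snps_per_mb: float | None = None  # optional, off by default

    def __post_init__(self) -> None:
        if min(self.min_length_kb, self.min_snps, self.max_gap_kb, self.window_snps) <= 0:
            raise ValueError("ROH parameters must be positive")
        if not 0 < self.window_hit_fraction <= 1:
            raise ValueError("window_hit_fraction must lie in (0,1]")
        if min(self.max_het_per_window, self.max_missing_per_window) < 0:
            raise ValueError("window budgets must be non-negative")


def classify_roh(length_kb: float) -> str:
    """Size class of a segment: <5 Mb short, 5 to <10 Mb intermediate, >=10 Mb long."""
    if length_kb < 5000:
        return "short"
    if length_kb < 10000:
        return "intermediate"
    return "long"


def _in_run_snps(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per-SNP in-run flags from the sliding-window vote."""
    m = het.size
    w = min(params.window_snps, m)  # truncate at short chromosomes
    n_windows = m - w + 1
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(miss)))
    het_in = ch[w:] - ch[:-w]
    mis_in = cm[w:] - cm[:-w]
    passing = (het_in <= params.max_het_per_window) & (mis_in <= params.max_missing_per_window)
    # windows covering SNP i start in [i-w+1, i] intersected with [0, n_windows-1]
    cp = np.concatenate(([0], np.cumsum(passing)))
    idx = np.arange(m)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, n_windows - 1)
    n_cover = hi - lo + 1
    n_pass = cp[hi + 1] - cp[lo]
    return n_pass / n_cover >= params.window_hit_fraction


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def call_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """Detect ROH for every sample; returns one row per segment.

    Columns: sample_id, chrom, start_bp, end_bp (1-based inclusive, positions
    of the first/last SNP of the run), n_snps, length_kb, size_class.
    """
    records: list[tuple] = []
    chrom_arr = gm.markers["chrom"].to_numpy()
    pos_all = gm.markers["pos_bp"].to_numpy()
    for chrom in gm.chromosomes():
        sel = chrom_arr == chrom
        pos = pos_all[sel]
        if pos.size == 0:
            continue
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"markers on chromosome {chrom} not strictly increasing")
        calls = gm.calls[:, sel]
        gap_bp = np.diff(pos)
        split_after = gap_bp > params.max_gap_kb * 1000.0
        for si, sid in enumerate(gm.samples):
            g = calls[si]
            in_run = _in_run_snps(g == 1, g == MISSING, params)
            for a, b in _runs(in_run):
                # split candidates at over-large physical gaps
                cut_points = [a] + [k + 1 for k in range(a, b) if split_after[k]] + [b + 1]
                for s, e in zip(cut_points[:-1], cut_points[1:]):
                    e -= 1
                    n_snps = e - s + 1
                    length_kb = (pos[e] - pos[s] + 1) / 1000.0
                    if n_snps < params.min_snps or length_kb < params.min_length_kb:
                        continue
                    if (
                        params.min_density_snps_per_mb is not None
                        and n_snps / (length_kb / 1000.0) < params.min_density_snps_per_mb
                    ):
                        continue
                    records.append(
                        (sid, int(chrom), int(pos[s]), int(pos[e]), n_snps,
                         length_kb, classify_roh(length_kb))
                    )
    return pd.DataFrame(records, columns=SEGMENT_COLUMNS)


def summarize_roh(segments: pd.DataFrame, samples: list[str]) -> dict[str, pd.DataFrame]:
    """Population / per-class / per-sample / per-chromosome ROH summaries.

    Class fractions are percentages of the total segment count; per-sample
    totals are in Mb (0 for samples with no segment).
    """
    total = len(segments)
    per_class_rows = []
    for cls in SIZE_CLASSES:
        sub = segments[segments["size_class"] == cls] if total else segments
        n = len(sub)
        per_class_rows.append(
            (cls, n, 100.0 * n / total if total else 0.0,
             sub["length_kb"].sum() / 1000.0 if total else 0.0)
        )
    per_class = pd.DataFrame(per_class_rows, columns=["size_class", "count", "pct", "total_mb"])

    per_sample = pd.DataFrame({"sample_id": samples})
    if total:
        agg = segments.groupby("sample_id")["length_kb"].agg(["count", "sum", "mean"])
        per_sample = per_sample.merge(agg, left_on="sample_id", right_index=True, how="left")
        per_sample = per_sample.fillna({"count": 0, "sum": 0.0, "mean": 0.0})
    else:
        per_sample[["count", "sum", "mean"]] = 0.0
    per_sample = per_sample.rename(columns={"count": "n_roh", "sum": "total_kb", "mean": "mean_kb"})
    per_sample["total_mb"] = per_sample["total_kb"] / 1000.0
    per_sample["n_roh"] = per_sample["n_roh"].astype(int)

    if total:
        per_chrom = (
            segments.groupby("chrom")["length_kb"]
            .agg(["count", "sum", "mean"])
            .rename(columns={"count": "n_roh", "sum": "total_kb", "mean": "mean_kb"})
            .reset_index()
        )
    else:
        per_chrom = pd.DataFrame(columns=["chrom", "n_roh", "total_kb", "mean_kb"])

    population = pd.DataFrame(
        [
            ("n_segments", total),
            ("mean_length_mb", segments["length_kb"].mean() / 1000.0 if total else 0.0),
            ("mean_total_mb_per_sample", per_sample["total_mb"].mean() if samples else 0.0),
        ],
        columns=["item", "value"],
    )
    return {
        "population": population,
        "per_class": per_class,
        "per_sample": per_sample,
        "per_chrom": per_chrom,
    }


def write_segments(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
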