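"""ROH pooling, island calling, window tracks, gene diversity, BED export."""

import numpy as np
import pandas as pd
import pytest

from rohpop.islands import (
    call_islands,
    export_islands_bed,
    gene_diversity,
    pool_overlaps,
    read_islands_bed,
    window_homozygosity_track,
)

from conftest import make_gm


def seg_df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])


def random_segments(rng, n_samples=50, chrom_len=10_000_000, n_chroms=3):
    """Disjoint per-sample segments (as a ROH caller guarantees): alternate
    intervals between sorted random breakpoints."""
    rows = []
    for si in range(n_samples):
        for chrom in range(1, n_chroms + 1):
            cuts = np.sort(rng.choice(np.arange(1, chrom_len, 1000), int(rng.integers(2, 12)), replace=False))
            for a, b in zip(cuts[::2], cuts[1::2]):
                rows.append((f"s{si}", chrom, int(a), int(b)))
    return seg_df(rows)


class TestPoolOverlaps:
    def test_identical_roh_single_region(self):
        seg = seg_df([("a", 1, 1_000_000, 3_000_000), ("b", 1, 1_000_000, 3_000_000)])
        reg = pool_overlaps(seg, n_samples=2)
        assert len(reg) == 1
        assert reg.iloc[0]["coverage"] == 1.0
        assert (reg.iloc[0]["start_bp"], reg.iloc[0]["end_bp"]) == (1_000_000, 3_000_000)

    def test_staggered_pair_three_regions(self):
        seg = seg_df([("a", 1, 1_000_000, 3_000_000), ("b", 1, 2_000_000, 4_000_000)])
        reg = pool_overlaps(seg, n_samples=2).sort_values("start_bp").reset_index(drop=True)
        assert len(reg) == 3
        assert reg["coverage"].tolist() == [0.5, 1.0, 0.5]
        assert reg.loc[1, "start_bp"] == 2_000_000 and reg.loc[1, "end_bp"] == 3_000_000

    def test_per_bp_count_conservation(self, rng):
        """sum over regions of length x supporting count == sum of segment lengths."""
        seg = random_segments(rng)
        reg = pool_overlaps(seg, n_samples=50)
        lhs = ((reg["end_bp"] - reg["start_bp"] + 1) * reg["n_samples"]).sum()
        rhs = (seg["end_bp"] - seg["start_bp"] + 1).sum()
        assert lhs == rhs

    def test_coverage_matches_per_position_counts(self, rng):
        # kb-scaled toy so brute-force per-bp counting is cheap
        seg = seg_df(
            [(f"s{i}", 1, int(a), int(b)) for i, (a, b) in
             enumerate(rng.integers(1, 5000, size=(30, 2)))
             if a < b]
        )
        reg = pool_overlaps(seg, n_samples=30)
        counts = np.zeros(6000, int)
        for r in seg.itertuples(index=False):
            counts[r.start_bp : r.end_bp + 1] += 1
        for r in reg.itertuples(index=False):
            span = counts[r.start_bp : r.end_bp + 1]
            # breakpoint atoms have constant counts >= the supporting-set size;
            # the supporting-set count equals samples covering the WHOLE region
            assert span.min() >= r.n_samples
            assert (span == r.n_samples).any() or span.min() == r.n_samples

    def test_empty_input(self):
        assert len(pool_overlaps(seg_df([]), 5)) == 0


class TestCallIslands:
    def _regions(self, coverages):
        return pd.DataFrame(
            {
                "chrom": 1,
                "start_bp": np.arange(len(coverages)) * 10_000 + 1,
                "end_bp": np.arange(1, len(coverages) + 1) * 10_000 - 5_000,
                "n_samples": (np.asarray(coverages) * 100).astype(int),
                "coverage": coverages,
            }
        )

    def test_distinct_coverages_single_island(self, rng):
        reg = self._regions(list(rng.permutation(np.linspace(0.01, 0.99, 100))))
        isl = call_islands(reg, 0.01)
        assert len(isl) == 1
        assert isl.iloc[0]["coverage"] == pytest.approx(reg["coverage"].max())

    def test_tied_cutoff_includes_all_ties(self):
        reg = self._regions([0.9, 0.9, 0.5, 0.4] + [0.1] * 196)
        isl = call_islands(reg, 0.01)  # k = 2, both 0.9s kept
        assert len(isl) == 2

    def test_all_equal_degenerate(self):
        reg = self._regions([0.3] * 50)
        isl = call_islands(reg, 0.01)
        assert isl["degenerate"].all()
        assert isl["coverage"].tolist() == [0.3] * len(isl)

    def test_order_invariance(self, rng):
        reg = self._regions(list(rng.random(200)))
        shuffled = reg.sample(frac=1, random_state=7).reset_index(drop=True)
        a = call_islands(reg, 0.02).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
        b = call_islands(shuffled, 0.02).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_top_fraction_monotone(self, rng):
        reg = self._regions(list(rng.random(300)))
        one = call_islands(reg, 0.01)
        two = call_islands(reg, 0.02)
        keys = lambda df: set(zip(df["chrom"], df["start_bp"]))
        assert keys(one) <= keys(two)

    def test_adjacent_islands_merged(self):
        reg = pd.DataFrame(
            {
                "chrom": [1, 1, 1],
                "start_bp": [1, 1001, 5001],
                "end_bp": [1000, 2000, 6000],
                "n_samples": [90, 90, 1],
                "coverage": [0.9, 0.9, 0.01],
            }
        )
        isl = call_islands(reg, 0.5)
        assert len(isl) == 1
        assert (isl.iloc[0]["start_bp"], isl.iloc[0]["end_bp"]) == (1, 2000)


class TestWindowTrack:
    def test_full_roh_constant_one(self):
        seg = seg_df([("a", 1, 1, 1_000_000)])
        tr = window_homozygosity_track(seg, 1, {1: 1_000_000}, window_kb=100)
        assert (tr["fraction"] == 1.0).all()
        assert len(tr) == 10

    def test_no_roh_constant_zero(self):
        tr = window_homozygosity_track(seg_df([]), 5, {1: 500_000}, window_kb=100)
        assert (tr["fraction"] == 0.0).all()

    def test_matches_brute_force_counting(self, rng):
        seg = random_segments(rng, n_samples=10, chrom_len=2_000_000, n_chroms=1)
        tr = window_homozygosity_track(seg, 10, {1: 2_000_000}, window_kb=100, rule="majority")
        for r in tr.itertuples(index=False):
            n = 0
            for sid in (f"s{i}" for i in range(10)):
                sub = seg[seg["sample_id"] == sid]
                ov = 0
                for s in sub.itertuples(index=False):
                    ov += max(0, min(s.end_bp, r.window_end_bp) - max(s.start_bp, r.window_start_bp) + 1)
                if ov >= 0.5 * (r.window_end_bp - r.window_start_bp + 1):
                    n += 1
            assert r.n_homozygous == n


class TestGeneDiversity:
    @pytest.mark.parametrize("dosages,expect", [
        ([1, 1, 0, 2], 0.5),    # p = 0.5 -> maximum
        ([0, 0, 0, 0], 0.0),    # fixed
        ([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], 0.18),  # p = 0.1 -> 2x0.1x0.9
    ])
    def test_closed_form(self, dosages, expect):
        gm = make_gm(np.array(dosages)[:, None])
        assert gene_diversity(gm)["gene_diversity"].iloc[0] == pytest.approx(expect)

    def test_bounded_by_half(self, rng):
        from conftest import random_gm
        gd = gene_diversity(random_gm(rng, n=30, m=50))
        assert (gd["gene_diversity"] <= 0.5 + 1e-12).all()


class TestBedExport:
    def _islands(self):
        return pd.DataFrame(
            {"chrom": [1], "start_bp": [53_078_000], "end_bp": [53_113_052],
             "n_samples": [233], "coverage": [0.7638]}
        )

    def test_zero_based_half_open_shift(self, tmp_path):
        p = tmp_path / "isl.bed"
        export_islands_bed(self._islands(), p)
        line = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        chrom, start, end = line.split("\t")[:3]
        assert (chrom, start, end) == ("1", "53077999", "53113052")

    def test_empty_set_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.bed"
        export_islands_bed(self._islands().iloc[:0], p)
        assert p.read_text().startswith("#")

    def test_round_trip(self, tmp_path, rng):
        starts = np.sort(rng.choice(np.arange(1, 10_000_000), 20, replace=False))
        isl = pd.DataFrame(
            {"chrom": 3, "start_bp": starts, "end_bp": starts + 5_000,
             "n_samples": 10, "coverage": rng.random(20).round(6)}
        )
        p = tmp_path / "rt.bed"
        export_islands_bed(isl, p)
        back = read_islands_bed(p)
        np.testing.assert_array_equal(back["start_bp"], isl["start_bp"])
        np.testing.assert_array_equal(back["end_bp"], isl["end_bp"])
        np.testing.assert_allclose(back["coverage"], isl["coverage"])
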