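"""F_HOM, F_ROH, Wright's F_PED and the Spearman comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rohpop.inbreeding import (
    KinshipCalculator,
    compare_coefficients,
    f_hom,
    f_ped,
    f_roh,
    f_roh_table,
    spearman,
)
from rohpop.io import MISSING, Pedigree
from rohpop.simulate import cohort_pedigree, family_pedigree

from conftest import make_gm, random_gm


def seg_df(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb", "size_class"]
    )


class TestFHom:
    def test_all_homozygous_is_one(self):
        gm = make_gm(np.array([[0, 2, 0, 2], [0, 1, 1, 2], [1, 1, 0, 0]]))
        assert f_hom(gm)["f_hom"].iloc[0] == pytest.approx(1.0)

    def test_definitional_zero_when_O_equals_E(self):
        # two markers with dosages (0,1): p=1/4, unbiased exp hom = 1/2 each;
        # sample s0 has one hom + one het -> O = E = 1 -> F_HOM = 0
        gm = make_gm(np.array([[0, 1], [1, 0]]))
        out = f_hom(gm)
        assert out["f_hom"].iloc[0] == pytest.approx(0.0)
        assert out["f_hom"].iloc[1] == pytest.approx(0.0)

    def test_matches_direct_summation(self, rng):
        gm = random_gm(rng, n=5, m=4, missing_rate=0.1)
        out = f_hom(gm).set_index("sample_id")
        p = gm.allele_b_freq()
        n_alleles = 2 * (gm.calls != MISSING).sum(axis=0)
        for i, sid in enumerate(gm.samples):
            O = E = L = 0.0
            for j in range(gm.n_markers):
                g = gm.calls[i, j]
                if g == MISSING or np.isnan(p[j]):
                    continue
                exp_hom = 1 - 2 * p[j] * (1 - p[j]) * n_alleles[j] / (n_alleles[j] - 1)
                L += 1
                E += exp_hom
                O += g in (0, 2)
            if L - E > 0:
                assert out.loc[sid, "f_hom"] == pytest.approx((O - E) / (L - E))

    def test_orientation_invariance(self, rng):
        gm = random_gm(rng, n=12, m=30)
        base = f_hom(gm)["f_hom"].to_numpy()
        flipped = gm.calls.copy()
        flipped[:, ::2] = 2 - flipped[:, ::2]
        out = f_hom(make_gm(flipped))["f_hom"].to_numpy()
        np.testing.assert_allclose(base, out, atol=1e-12)

    def test_monomorphic_panel_undefined(self):
        gm = make_gm(np.zeros((3, 5)))
        with pytest.raises(ValueError, match="monomorphic"):
            f_hom(gm)


class TestFRoh:
    def test_worked_fractions(self):
        # one long segment of the published per-individual total length
        s = seg_df([("x", 1, 1, 507_267_000, 100, 507_267.0, "long")])
        assert round(f_roh(s, 2_478_445.0 * 1), 3) == 0.205

    def test_class_filter(self):
        s = seg_df(
            [("x", 1, 1, 2, 10, 363_227.0, "long"), ("x", 2, 1, 2, 10, 122_216.0, "short")]
        )
        assert round(f_roh(s, 2_478_445.0, class_filter="long"), 3) == 0.147
        assert round(f_roh(s, 2_478_445.0, class_filter="short"), 3) == 0.049

    def test_empty_and_full(self):
        assert f_roh(seg_df([]), 1000.0) == 0.0
        s = seg_df([("x", 1, 1, 2, 10, 1000.0, "short")])
        assert f_roh(s, 1000.0) == 1.0

    def test_partition_identity(self, rng):
        rows = []
        for k in range(200):
            kb = float(rng.integers(1000, 30000))
            cls = "short" if kb < 5000 else ("intermediate" if kb < 10000 else "long")
            rows.append((f"s{rng.integers(10)}", 1, 1, int(kb * 1000), 10, kb, cls))
        table = f_roh_table(seg_df(rows), [f"s{i}" for i in range(10)], 2_478_445.0)
        lhs = table["f_roh_short"] + table["f_roh_intermediate"] + table["f_roh_long"]
        np.testing.assert_allclose(lhs, table["f_roh_total"], rtol=0, atol=1e-12)

    def test_multiple_samples_rejected(self):
        s = seg_df([("a", 1, 1, 2, 10, 1000.0, "short"), ("b", 1, 1, 2, 10, 1000.0, "short")])
        with pytest.raises(ValueError):
            f_roh(s)


class TestFPed:
    @pytest.mark.parametrize(
        "kind,expect", [("outbred", 0.0), ("cousin", 0.0625), ("half_sib", 0.125), ("full_sib", 0.25)]
    )
    def test_classical_values(self, kind, expect):
        ped, cohort = cohort_pedigree([kind])
        assert f_ped(ped, cohort[0]) == pytest.approx(expect)

    def test_kinship_symmetry_and_self(self):
        ped, _ = cohort_pedigree(["full_sib"])
        calc = KinshipCalculator(ped)
        c, d = "F0_full_sib_C", "F0_full_sib_D"
        assert calc.kinship(c, d) == calc.kinship(d, c) == pytest.approx(0.25)
        assert calc.kinship(c, c) == pytest.approx(0.5)  # non-inbred full sib

    def test_unknown_parent_treated_as_founder(self):
        ped = Pedigree(records=pd.DataFrame(
            [("kid", "sire", "0")], columns=["individual", "sire", "dam"]))
        assert f_ped(ped, "kid") == 0.0

    def test_looped_pedigree_matches_single_locus_drop(self, rng):
        """F_PED equals expected single-locus autozygosity from gene dropping."""
        from oracles import single_locus_drop

        ped, cohort = cohort_pedigree(["full_sib", "cousin", "half_sib"])
        R = 200_000
        observed = single_locus_drop(ped, cohort, R, rng)
        for target in cohort:
            expect = f_ped(ped, target)
            se = np.sqrt(max(expect * (1 - expect), 1e-6) / R)
            assert observed[target] == pytest.approx(expect, abs=max(3 * se, 1e-3))


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.arange(10.0)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_matches_rank_and_correlate_oracle(self, rng):
        x = rng.random(20)
        y = rng.random(20)
        rho, _ = spearman(x, y)
        expect = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(expect)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        _, p = spearman(x, y, exact_max_n=8)
        # 4! = 24 orderings; count |rho| >= observed by brute force is exact
        assert 0 < p <= 1


class TestCompare:
    def test_identical_vectors_rho_one(self, rng):
        v = rng.random(15)
        rec = pd.DataFrame({"sample_id": range(15), "a": v, "b": v, "c": v})
        out = compare_coefficients(rec)
        assert np.allclose(out["rho"], 1.0)

    def test_table_symmetric_unit_diagonal(self, rng):
        rec = pd.DataFrame({"a": rng.random(12), "b": rng.random(12)})
        out = compare_coefficients(rec).set_index(["coef_a", "coef_b"])
        assert out.loc[("a", "a"), "rho"] == 1.0
        assert out.loc[("a", "b"), "rho"] == pytest.approx(out.loc[("b", "a"), "rho"])
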