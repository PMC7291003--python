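"""Synthetic-data generators: pedigree designs, gene dropping, Wright-Fisher."""

import numpy as np
import pandas as pd
import pytest

from rohpop.inbreeding import f_ped
from rohpop.io import Pedigree
from rohpop.qc import run_qc
from rohpop.roh import call_roh
from rohpop.simulate import (
    LitterStructure,
    SimConfig,
    cohort_pedigree,
    gene_drop,
    scaled_config,
    simulate_pedigree,
    wright_fisher,
)


SMALL = scaled_config(n_chromosomes=3, chrom_length_bp=60_000_000, n_markers_per_chrom=400, seed=1)


class TestSimulatePedigree:
    def test_seed_determinism(self):
        a = simulate_pedigree(3, seed=42)
        b = simulate_pedigree(3, seed=42)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_outbred_design_all_f_zero(self):
        ped = simulate_pedigree(3, LitterStructure(sib_mating_fraction=0.0), seed=1)
        # founders and first generation are outbred by construction
        gen1 = [i for i in ped.individuals if i.startswith("G1_")]
        f = f_ped(ped).set_index("sample_id")
        assert (f.loc[gen1, "f_ped"] == 0).all()

    def test_sib_mating_produces_inbreeding(self):
        ped = simulate_pedigree(3, LitterStructure(sib_mating_fraction=1.0), seed=2)
        gen2 = [i for i in ped.individuals if i.startswith("G2_")]
        f = f_ped(ped).set_index("sample_id")
        assert f.loc[gen2, "f_ped"].to_numpy() == pytest.approx(0.25)

    def test_half_sib_litters_share_sires(self):
        ped = simulate_pedigree(2, LitterStructure(n_sires=2, n_dams=6), seed=3)
        sires = ped.records[ped.records["sire"] != "0"]["sire"].unique()
        assert len(sires) == 2  # 6 litters from 2 sires -> half-sib families

    def test_infeasible_structure_rejected(self):
        with pytest.raises(ValueError):
            LitterStructure(n_sires=0)
        with pytest.raises(ValueError):
            simulate_pedigree(1)


class TestGeneDrop:
    def test_seed_determinism(self):
        ped, cohort = cohort_pedigree(["full_sib"] * 3, 2)
        a, _ = gene_drop(ped, SMALL, samples=cohort, seed=9)
        b, _ = gene_drop(ped, SMALL, samples=cohort, seed=9)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_outbred_offspring_truth_zero(self):
        ped, cohort = cohort_pedigree(["outbred"] * 5, 2)
        _, truth = gene_drop(ped, SMALL, samples=cohort, seed=3)
        assert (truth.fractions["autozygous_fraction"] == 0).all()
        assert len(truth.tracts) == 0

    def test_selfing_autozygosity_half(self):
        # cloned founder used as both parents: expected autozygous fraction 1/2
        rows = [("A", "0", "0")] + [(f"kid{k}", "A", "A") for k in range(200)]
        ped = Pedigree(records=pd.DataFrame(rows, columns=["individual", "sire", "dam"]))
        cfg = scaled_config(n_chromosomes=3, chrom_length_bp=60_000_000,
                            n_markers_per_chrom=20, seed=4)
        _, truth = gene_drop(ped, cfg, samples=[f"kid{k}" for k in range(200)], seed=4)
        fr = truth.fractions["autozygous_fraction"]
        se = fr.std() / np.sqrt(len(fr))
        assert fr.mean() == pytest.approx(0.5, abs=3 * max(se, 1e-3))

    def test_truth_matches_f_ped_expectation(self):
        ped, cohort = cohort_pedigree(["full_sib"] * 60, 2)
        _, truth = gene_drop(ped, SMALL, samples=cohort, seed=6)
        fr = truth.fractions
        assert (fr["true_f_ped"] == 0.25).all()
        se = fr["autozygous_fraction"].std() / np.sqrt(len(fr))
        assert fr["autozygous_fraction"].mean() == pytest.approx(0.25, abs=3 * se)

    def test_tracts_within_genome_and_consistent_with_fraction(self):
        ped, cohort = cohort_pedigree(["full_sib"] * 10, 2)
        _, truth = gene_drop(ped, SMALL, samples=cohort, seed=8)
        t = truth.tracts
        assert (t["start_bp"] >= 1).all()
        assert (t["end_bp"] <= SMALL.chrom_length_bp).all()
        total = t.groupby("sample_id").apply(
            lambda d: (d["end_bp"] - d["start_bp"] + 1).sum(), include_groups=False
        )
        genome = SMALL.n_chromosomes * SMALL.chrom_length_bp
        fr = truth.fractions.set_index("sample_id")["autozygous_fraction"]
        for sid, bp in total.items():
            assert bp / genome == pytest.approx(fr[sid], abs=2e-6)

    def test_noise_settings_apply(self):
        ped, cohort = cohort_pedigree(["outbred"] * 5, 2)
        cfg = scaled_config(n_chromosomes=2, chrom_length_bp=50_000_000,
                            n_markers_per_chrom=500, missing_rate=0.2, seed=2)
        gm, _ = gene_drop(ped, cfg, samples=cohort, seed=2)
        miss = (gm.calls == -1).mean()
        assert 0.1 < miss < 0.3


class TestWrightFisher:
    def test_seed_determinism(self):
        cfg = scaled_config(n_chromosomes=2, chrom_length_bp=40_000_000,
                            n_markers_per_chrom=100, seed=3)
        a = wright_fisher(20, 10, 30, cfg, seed=5)
        b = wright_fisher(20, 10, 30, cfg, seed=5)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_drift_variance_one_round_chain(self):
        """Var of sample allele freq after k binomial(2N) rounds from p=0.5:
        p(1-p) (1 - (1 - 1/2N)^k) with k = founders + gens + final sample."""
        N, gens = 50, 3
        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=100_000_000,
                        n_markers_per_chrom=500, cm_per_mb=1.0,
                        maf_low=0.5, maf_high=0.5, seed=6)
        gm = wright_fisher(N, gens, N, cfg, seed=6)
        p_hat = gm.calls.mean(axis=0) / 2.0
        k = 1 + gens + 1
        expect = 0.25 * (1 - (1 - 1 / (2 * N)) ** k)
        assert p_hat.var() == pytest.approx(expect, rel=0.3)

    def test_pipeline_closure(self):
        """Gene-drop output flows through QC and ROH calling without friction."""
        cfg = scaled_config(n_chromosomes=2, chrom_length_bp=80_000_000,
                            missing_rate=0.02, seed=7)
        ped, cohort = cohort_pedigree(["full_sib"] * 20, 2)
        gm, truth = gene_drop(ped, cfg, samples=cohort, seed=7)
        gm, report = run_qc(gm, order=("marker_call_rate", "sample_call_rate", "maf"))
        report.check()
        seg = call_roh(gm)
        assert set(seg["sample_id"]) <= set(cohort)
        assert (seg["length_kb"] >= 1000).all()
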