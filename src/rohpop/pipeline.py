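"""End-to-end orchestration: (simulate | load) -> QC -> ROH -> LD/Ne ->
inbreeding -> islands, with a serialized config and TSV reports.

The config is a plain mapping (YAML-serializable); unknown keys are rejected
so typos fail loudly.  A copy of the resolved config is written into the
output directory, and reruns with the same config and seed are reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inbreeding, islands, ldne, qc, roh, simulate
from .io import (
    GenotypeMatrix,
    Pedigree,
    read_chromosome_table,
    read_ped_map,
    read_pedigree,
    write_ped_map,
)

logger = logging.getLogger(__name__)

_DEFAULTS: dict = {
    "seed": 0,
    "input": {  # either paths to PED/MAP (+ pedigree, chrom table) or null -> simulate
        "ped": None,
        "map": None,
        "pedigree": None,
        "chromosome_table": None,
    },
    "simulate": {  # used when input.ped is null
        "n_chromosomes": 6,
        "chrom_length_bp": 100_000_000,
        "n_families": 40,
        "family_kinds": ["outbred", "cousin", "half_sib", "full_sib"],
        "offspring_per_family": 4,
        "missing_rate": 0.01,
    },
    "qc": {
        "marker_call_rate": 0.95,
        "sample_call_rate": 0.95,
        "maf": 0.05,
        "hwe_alpha": 1.0e-4,
        "max_pi_hat": 0.5,
        "enabled": True,
        "relatedness": False,  # gene-drop cohorts are deliberately related
    },
    "roh": {f.name: f.default for f in dataclasses.fields(roh.ROHParams)},
    "ldne": {
        "targets_cm": list(ldne.DEFAULT_TARGETS_CM),
        "tol": ldne.DEFAULT_TOL,
        "units": "physical",
        "max_dist_mb": 10.0,
    },
    "inbreeding": {"l_auto_kb": None},  # null -> genome length from chromosome table
    "islands": {"top_fraction": 0.01, "window_kb": 100.0, "window_rule": "majority"},
}


class PipelineConfig(dict):
    """Validated nested mapping of all stage parameters."""

    @classmethod
    def from_mapping(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = cls(_merge(_DEFAULTS, overrides or {}))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = {}
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys at '{path or '.'}': {sorted(unknown)}")
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge(v, overrides.get(k, {}) or {}, f"{path}{k}.")
        else:
            out[k] = overrides.get(k, v)
    return out


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig | dict, outdir: str | Path) -> dict[str, Path]:
    """Run every stage, writing TSV reports under *outdir*.

    Returns a mapping of report name -> written path.  Numeric outputs are
    deterministic for a fixed config (including seed).
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_mapping(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    written: dict[str, Path] = {"config": outdir / "config.yaml"}

    gm, pedigree, chrom_table, truth = _load_or_simulate(cfg, outdir, written)
    logger.info("input: %d samples x %d markers", gm.n_samples, gm.n_markers)

    if cfg["qc"]["enabled"]:
        order = list(qc.DEFAULT_ORDER)
        if not cfg["qc"]["relatedness"]:
            order.remove("relatedness")
        th = {k: cfg["qc"][k] for k in ("marker_call_rate", "sample_call_rate", "maf", "hwe_alpha", "max_pi_hat")}
        gm, report = qc.run_qc(gm, thresholds=th, order=tuple(order))
        _write(report.to_frame(), outdir / "qc_report.tsv", written, "qc_report")

    params = roh.ROHParams(**cfg["roh"])
    segments = roh.call_roh(gm, params)
    _write(segments, outdir / "roh_segments.tsv", written, "roh_segments")
    summaries = roh.summarize_roh(segments, gm.samples)
    for name, df in summaries.items():
        _write(df, outdir / f"roh_summary_{name}.tsv", written, f"roh_summary_{name}")

    ne = ldne.ne_trajectory(
        gm,
        chrom_table,
        targets_cm=tuple(cfg["ldne"]["targets_cm"]),
        tol=cfg["ldne"]["tol"],
        units=cfg["ldne"]["units"],
        max_dist_bp=int(cfg["ldne"]["max_dist_mb"] * 1e6),
    )
    _write(ne.round({"mean_r2": 4, "ne": 1}), outdir / "ne_trajectory.tsv", written, "ne_trajectory")

    l_auto = cfg["inbreeding"]["l_auto_kb"] or chrom_table.total_length_kb
    coeffs = inbreeding.inbreeding_table(gm, segments, pedigree, l_auto_kb=l_auto)
    if truth is not None:
        coeffs = coeffs.merge(truth.fractions, on="sample_id", how="left")
    _write(coeffs, outdir / "inbreeding.tsv", written, "inbreeding")
    comp_cols = [c for c in ("f_ped", "f_hom", "f_roh_total", "f_roh_short",
                             "f_roh_intermediate", "f_roh_long") if c in coeffs]
    usable = [c for c in comp_cols if coeffs[c].dropna().nunique() > 1]
    if len(usable) >= 2:
        corr = inbreeding.compare_coefficients(coeffs[["sample_id"] + usable])
        _write(corr, outdir / "inbreeding_correlations.tsv", written, "inbreeding_correlations")

    regions = islands.pool_overlaps(segments, gm.n_samples)
    _write(regions, outdir / "roh_regions.tsv", written, "roh_regions")
    if len(regions):
        isl = islands.call_islands(regions, cfg["islands"]["top_fraction"])
        _write(isl, outdir / "roh_islands.tsv", written, "roh_islands")
        islands.export_islands_bed(isl, outdir / "roh_islands.bed")
        written["roh_islands_bed"] = outdir / "roh_islands.bed"
        lengths = {int(r.chrom): int(r.length_bp) for r in chrom_table.table.itertuples(index=False)}
        track = islands.window_homozygosity_track(
            segments, gm.n_samples, lengths,
            window_kb=cfg["islands"]["window_kb"], rule=cfg["islands"]["window_rule"],
        )
        _write(track, outdir / "homozygosity_track.tsv", written, "homozygosity_track")
    _write(islands.gene_diversity(gm), outdir / "gene_diversity.tsv", written, "gene_diversity")
    logger.info("pipeline complete: %d reports in %s", len(written), outdir)
    return written


@_stage("input")
def _load_or_simulate(cfg, outdir: Path, written: dict):
    truth = None
    if cfg["input"]["ped"]:
        gm = read_ped_map(cfg["input"]["ped"], cfg["input"]["map"])
        pedigree = read_pedigree(cfg["input"]["pedigree"]) if cfg["input"]["pedigree"] else None
        if not cfg["input"]["chromosome_table"]:
            raise ValueError("a chromosome table is required with PED/MAP input")
        chrom_table = read_chromosome_table(cfg["input"]["chromosome_table"])
    else:
        sc = cfg["simulate"]
        config = simulate.scaled_config(
            n_chromosomes=sc["n_chromosomes"],
            chrom_length_bp=sc["chrom_length_bp"],
            seed=cfg["seed"],
            missing_rate=sc["missing_rate"],
        )
        kinds = [sc["family_kinds"][i % len(sc["family_kinds"])] for i in range(sc["n_families"])]
        pedigree, cohort = simulate.cohort_pedigree(kinds, sc["offspring_per_family"])
        gm, truth = simulate.gene_drop(pedigree, config, samples=cohort, seed=cfg["seed"])
        chrom_table = config.chromosome_table()
        write_ped_map(gm, outdir / "simulated.ped", outdir / "simulated.map")
        written["simulated_ped"] = outdir / "simulated.ped"
        _write(truth.fractions, outdir / "truth_fractions.tsv", written, "truth_fractions")
    return gm, pedigree, chrom_table, truth


def _write(df: pd.DataFrame, path: Path, written: dict, name: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    written[name] = path
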