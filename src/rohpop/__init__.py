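"""rohpop: runs of homozygosity, LD-based effective population size and
inbreeding coefficients for SNP-chip genotype data, with a synthetic-data
generator (gene dropping, Wright-Fisher) providing exact ground truth."""

from importlib.resources import files as _files

import pandas as _pd

from .io import (
    MISSING,
    ChromosomeTable,
    GenotypeMatrix,
    Pedigree,
    read_chromosome_table,
    read_ped_map,
    read_pedigree,
    write_ped_map,
)
from .roh import ROHParams, call_roh, classify_roh, summarize_roh
from .ldne import estimate_ne, generations_for_distance, ne_trajectory, pairwise_r2
from .inbreeding import f_hom, f_ped, f_roh, spearman, compare_coefficients
from .islands import call_islands, pool_overlaps
from .simulate import SimConfig, gene_drop, simulate_pedigree, wright_fisher
from .pipeline import PipelineConfig, run_pipeline

__version__ = "0.1.0"


def load_reference_ld_table() -> _pd.DataFrame:
    """Published per-chromosome LD summary for a Piétrain 50k-chip cohort:
    cM/Mb rate, mean r² per physical distance bin, and the reported Ne."""
    path = _files("rohpop.data") / "pietrain_ld_ne_reference.tsv"
    return _pd.read_csv(path, sep="\t", comment="#")
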