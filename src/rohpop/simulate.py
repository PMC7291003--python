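"""Synthetic genotype data with known ground truth.

Two generators back every pipeline stage:

* **Gene dropping** — founder chromosomes carry unique haplotype labels that
  are transmitted through a pedigree with Haldane recombination (Poisson
  crossover counts, uniform breakpoints, no interference).  Wherever an
  individual's two label mosaics carry the same founder haplotype the genome
  is truly autozygous, so ROH callers and inbreeding coefficients can be
  checked against exact tract-level truth.
* **Wright-Fisher forward simulation** — a constant-size random-mating
  diploid population whose LD decay encodes the chosen true Ne, for
  recovery tests of the LD-based Ne estimator.

The default genome emulates a 50k chip on the 18 pig autosomes: total length
2,478,445 kb, ~2,790 markers per chromosome, founder MAF ~ Uniform(0.05, 0.5),
no genotyping error or missingness (so truth comparisons are exact unless
noise is switched on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .inbreeding import KinshipCalculator
from .io import MISSING, UNKNOWN_PARENT, ChromosomeTable, GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Genome and genotyping model for both simulators."""

    n_chromosomes: int = 18
    chrom_length_bp: int = 137_691_389  # equal-length autosomes, total ~2,478,445 kb
    cm_per_mb: float = 1.1057
    n_markers_per_chrom: int = 2793    # ~50k genome-wide
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 2 or self.n_markers_per_chrom < 1:
            raise ValueError("genome dimensions must be positive")
        if not 0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("founder MAF range must satisfy 0 <= low <= high <= 0.5")
        for r in (self.missing_rate, self.error_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0,1)")

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length_bp / 1e6 * self.cm_per_mb / 100.0

    @property
    def total_length_kb(self) -> float:
        return self.n_chromosomes * self.chrom_length_bp / 1e3

    def chromosome_table(self) -> ChromosomeTable:
        chroms = list(range(1, self.n_chromosomes + 1))
        return ChromosomeTable.from_lengths(
            chroms,
            [self.chrom_length_bp] * self.n_chromosomes,
            [self.morgans_per_chrom * 100.0] * self.n_chromosomes,
        )

    def draw_markers(self, rng: np.random.Generator) -> pd.DataFrame:
        """Uniformly placed, sorted, distinct marker positions per chromosome."""
        rows = []
        for chrom in range(1, self.n_chromosomes + 1):
            pos = np.sort(
                rng.choice(self.chrom_length_bp - 1, size=self.n_markers_per_chrom, replace=False) + 1
            )
            for k, p in enumerate(pos, 1):
                rows.append((f"snp_{chrom}_{k}", chrom, int(p)))
        df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"])
        df["allele_a"] = "A"
        df["allele_b"] = "B"
        return df


def scaled_config(n_chromosomes: int = 6, chrom_length_bp: int = 100_000_000, seed: int = 0, **kw) -> SimConfig:
    """A smaller genome at the same marker density as the default chip."""
    base = SimConfig()
    density = base.n_markers_per_chrom / base.chrom_length_bp
    n_markers = kw.pop("n_markers_per_chrom", max(10, int(round(density * chrom_length_bp))))
    return SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length_bp=chrom_length_bp,
        n_markers_per_chrom=n_markers,
        seed=seed,
        **kw,
    )


@dataclass
class TruthTable:
    """Ground truth from gene dropping."""

    tracts: pd.DataFrame     # sample_id, chrom, start_bp, end_bp (1-based inclusive)
    fractions: pd.DataFrame  # sample_id, autozygous_fraction, true_f_ped


# ---------------------------------------------------------------------------
# pedigree designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LitterStructure:
    """Mating design for the generational pedigree simulator."""

    n_sires: int = 5
    n_dams: int = 15
    litter_size: int = 8
    sib_mating_fraction: float = 0.0   # fraction of matings between full sibs
    half_sib_litters: bool = True      # sires serve several dams (half-sib litters)

    def __post_init__(self) -> None:
        if min(self.n_sires, self.n_dams, self.litter_size) < 1:
            raise ValueError("litter structure counts must be positive")
        if not 0 <= self.sib_mating_fraction <= 1:
            raise ValueError("sib_mating_fraction must lie in [0,1]")


def simulate_pedigree(
    gens: int, litter_structure: LitterStructure = LitterStructure(), seed: int = 0
) -> Pedigree:
    """Multi-generation pedigree with half-sib litters and optional full-sib loops.

    Generation 0 holds unrelated founders; in each later generation every dam
    produces one litter.  With ``half_sib_litters`` each sire is mated to
    several dams, so litters of one sire are half sibs.  A
    ``sib_mating_fraction`` of the matings take both partners from the same
    previous-generation litter (full-sib mating, consanguineous loop).
    Deterministic for a given seed.
    """
    if gens < 2:
        raise ValueError("need at least two generations")
    st = litter_structure
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    sires = [f"G0_S{i}" for i in range(st.n_sires)]
    dams = [f"G0_D{i}" for i in range(st.n_dams)]
    for x in sires + dams:
        rows.append((x, UNKNOWN_PARENT, UNKNOWN_PARENT))
    litters: list[list[str]] = []  # previous generation litters (for sib mating)
    for g in range(1, gens):
        new_litters: list[list[str]] = []
        new_sires: list[str] = []
        new_dams: list[str] = []
        n_lit = st.n_dams
        for li in range(n_lit):
            if litters and rng.random() < st.sib_mating_fraction:
                # full-sib mating within a random previous litter of >= 2
                big = [L for L in litters if len(L) >= 2]
                if not big:
                    raise ValueError("sib mating requested but no litter has two members")
                lit = big[rng.integers(len(big))]
                a, b = rng.choice(len(lit), size=2, replace=False)
                sire, dam = lit[a], lit[b]
            else:
                sire = sires[li % len(sires)] if st.half_sib_litters else sires[rng.integers(len(sires))]
                dam = dams[li % len(dams)]
            kids = []
            for k in range(st.litter_size):
                kid = f"G{g}_L{li}_K{k}"
                rows.append((kid, sire, dam))
                kids.append(kid)
            new_litters.append(kids)
            half = len(kids) // 2
            new_sires.extend(kids[:max(1, half)])
            new_dams.extend(kids[max(1, half):] or kids[:1])
        sires, dams, litters = new_sires, new_dams, new_litters
    return Pedigree(records=pd.DataFrame(rows, columns=["individual", "sire", "dam"]))


#: Wright's F of the terminal offspring for each canned family design.
FAMILY_DESIGNS = {
    "outbred": 0.0,
    "cousin": 0.0625,
    "half_sib": 0.125,
    "full_sib": 0.25,
}


def family_pedigree(kind: str, family_id: str, n_offspring: int = 1) -> pd.DataFrame:
    """Pedigree records for one family whose terminal offspring have a known F.

    outbred: two founders.  full_sib: offspring of two full sibs (F = 0.25).
    half_sib: offspring of paternal half sibs (F = 0.125).  cousin: offspring
    of first cousins (F = 0.0625).
    """
    p = f"{family_id}_"
    U = UNKNOWN_PARENT
    rows: list[tuple[str, str, str]] = []

    def kids(sire: str, dam: str) -> None:
        for k in range(n_offspring):
            rows.append((f"{p}kid{k}", sire, dam))

    if kind == "outbred":
        rows += [(p + "A", U, U), (p + "B", U, U)]
        kids(p + "A", p + "B")
    elif kind == "full_sib":
        rows += [(p + "A", U, U), (p + "B", U, U)]
        rows += [(p + "C", p + "A", p + "B"), (p + "D", p + "A", p + "B")]
        kids(p + "C", p + "D")
    elif kind == "half_sib":
        rows += [(p + "A", U, U), (p + "B", U, U), (p + "C", U, U)]
        rows += [(p + "D", p + "A", p + "B"), (p + "E", p + "A", p + "C")]
        kids(p + "D", p + "E")
    elif kind == "cousin":
        rows += [(p + "A", U, U), (p + "B", U, U), (p + "U", U, U), (p + "V", U, U)]
        rows += [(p + "E", p + "A", p + "B"), (p + "F", p + "A", p + "B")]
        rows += [(p + "I", p + "E", p + "U"), (p + "J", p + "F", p + "V")]
        kids(p + "I", p + "J")
    else:
        raise ValueError(f"unknown family design {kind!r}")
    return pd.DataFrame(rows, columns=["individual", "sire", "dam"])


def cohort_pedigree(kinds: list[str], n_offspring_per_family: int = 1) -> tuple[Pedigree, list[str]]:
    """Concatenate family designs; returns the pedigree and the terminal
    offspring ids (the genotyped cohort)."""
    frames, cohort = [], []
    for fi, kind in enumerate(kinds):
        fam = family_pedigree(kind, f"F{fi}_{kind}", n_offspring_per_family)
        frames.append(fam)
        cohort.extend(fam.loc[fam["individual"].str.contains("_kid"), "individual"])
    return Pedigree(records=pd.concat(frames, ignore_index=True)), cohort


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------
# A haplotype on one chromosome is a label mosaic stored as (ends, labels):
# segment i covers the half-open bp interval [ends[i-1], ends[i]) with
# ends[-1] == chromosome length.


def _meiosis(hap0, hap1, length_bp: int, morgans: float, rng: np.random.Generator):
    """One Haldane meiosis over a label-mosaic pair."""
    k = rng.poisson(morgans)
    phase = int(rng.integers(2))
    if k == 0:
        return hap0 if phase == 0 else hap1
    cuts = np.sort(rng.uniform(0, length_bp, size=k))
    bounds = np.concatenate(([0.0], cuts, [float(length_bp)]))
    parts_ends: list[np.ndarray] = []
    parts_labels: list[np.ndarray] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if b <= a:
            continue
        ends, labels = (hap0, hap1)[(phase + i) % 2]
        i0 = int(np.searchsorted(ends, a, side="right"))
        j = i0 + int(np.searchsorted(ends[i0:], b, side="left"))
        seg_ends = np.concatenate((ends[i0:j], [b]))
        seg_labels = labels[i0 : j + 1]
        parts_ends.append(seg_ends)
        parts_labels.append(seg_labels)
    ends = np.concatenate(parts_ends)
    labels = np.concatenate(parts_labels)
    # merge adjacent segments with equal labels
    keep = np.concatenate((labels[:-1] != labels[1:], [True]))
    return ends[keep], labels[keep]


def _autozygous_intervals(hapA, hapB) -> list[tuple[float, float]]:
    """Half-open intervals where the two mosaics carry the same label."""
    endsA, labsA = hapA
    endsB, labsB = hapB
    cuts = np.union1d(endsA, endsB)
    starts = np.concatenate(([0.0], cuts[:-1]))
    mids = (starts + cuts) / 2.0
    la = labsA[np.searchsorted(endsA, mids, side="right").clip(max=len(labsA) - 1)]
    lb = labsB[np.searchsorted(endsB, mids, side="right").clip(max=len(labsB) - 1)]
    same = la == lb
    out: list[tuple[float, float]] = []
    for s, e, eq in zip(starts, cuts, same):
        if not eq:
            continue
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def gene_drop(
    pedigree: Pedigree,
    config: SimConfig = SimConfig(),
    samples: list[str] | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Drop labeled founder chromosomes through *pedigree*.

    Returns genotypes for *samples* (default: every pedigree individual) and
    the exact autozygosity truth: per-sample tracts where the two gametes
    share a founder haplotype, the genome fraction they cover, and Wright's
    F from the pedigree.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples = list(pedigree.topological_order) if samples is None else list(samples)
    markers = config.draw_markers(rng)
    L = config.chrom_length_bp
    n_chrom = config.n_chromosomes

    genomes: dict[str, tuple[list, list]] = {}
    next_label = 0
    for ind in pedigree.topological_order:
        sire, dam = pedigree.parents(ind)
        gametes = []
        for parent in (sire, dam):
            if parent == UNKNOWN_PARENT or parent not in genomes:
                lab = next_label
                next_label += 1
                gametes.append(
                    [(np.array([float(L)]), np.array([lab])) for _ in range(n_chrom)]
                )
            else:
                pg = genomes[parent]
                gametes.append(
                    [
                        _meiosis(pg[0][c], pg[1][c], L, config.morgans_per_chrom, rng)
                        for c in range(n_chrom)
                    ]
                )
        genomes[ind] = (gametes[0], gametes[1])

    # founder-haplotype alleles: Bernoulli(p_m) per marker, p ~ U(maf range)
    n_markers = len(markers)
    p = rng.uniform(config.maf_low, config.maf_high, size=n_markers)
    alleles = (rng.random((next_label, n_markers)) < p).astype(np.int8)

    pos_by_chrom = {
        c: markers.loc[markers["chrom"] == c, "pos_bp"].to_numpy() for c in range(1, n_chrom + 1)
    }
    col0 = {c: int(markers.index[markers["chrom"] == c][0]) for c in range(1, n_chrom + 1)}

    calls = np.empty((len(samples), n_markers), dtype=np.int8)
    tract_rows = []
    frac_rows = []
    kin = KinshipCalculator(pedigree)
    for si, sid in enumerate(samples):
        hapA, hapB = genomes[sid]
        auto_len = 0.0
        for c in range(1, n_chrom + 1):
            pos = pos_by_chrom[c]
            j0 = col0[c]
            for hap, out in ((hapA[c - 1], 0), (hapB[c - 1], 1)):
                ends, labels = hap
                idx = np.searchsorted(ends, pos - 1, side="right").clip(max=len(labels) - 1)
                lab = labels[idx]
                if out == 0:
                    labA = lab
                else:
                    cols = np.arange(j0, j0 + len(pos))
                    calls[si, cols] = alleles[labA, cols] + alleles[lab, cols]
            for a, b in _autozygous_intervals(hapA[c - 1], hapB[c - 1]):
                auto_len += b - a
                tract_rows.append((sid, c, int(np.floor(a)) + 1, int(np.floor(b))))
        frac_rows.append((sid, auto_len / (n_chrom * L), kin.inbreeding(sid)))

    if config.error_rate > 0:
        flip = rng.random(calls.shape) < config.error_rate
        calls = np.where(flip, rng.integers(0, 3, size=calls.shape, dtype=np.int8), calls)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate, MISSING, calls).astype(np.int8)

    gm = GenotypeMatrix(samples=samples, markers=markers, calls=calls)
    truth = TruthTable(
        tracts=pd.DataFrame(tract_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]),
        fractions=pd.DataFrame(frac_rows, columns=["sample_id", "autozygous_fraction", "true_f_ped"]),
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation
# ---------------------------------------------------------------------------


def wright_fisher(
    ne_true: int,
    n_gens: int,
    sample_n: int,
    config: SimConfig = SimConfig(),
    seed: int | None = None,
    min_polymorphic: int = 2,
    resample: bool = False,
) -> GenotypeMatrix:
    """Constant-size diploid Wright-Fisher population; returns a final sample.

    The population holds ``ne_true`` diploids per generation; after ``n_gens``
    generations of random mating, ``sample_n`` offspring are generated from
    the final parental generation (so the sample may exceed the population
    size, as in a cross-sectional genotyping cohort).  LD at equilibrium
    (recommended n_gens >= 4 Ne) encodes ne_true through Sved's relation.
    """
    if ne_true < 2:
        raise ValueError("ne_true must be at least 2")
    if n_gens < 4 * ne_true:
        logger.warning(
            "n_gens=%d < 4*Ne=%d: LD may not have reached drift-recombination equilibrium",
            n_gens, 4 * ne_true,
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    markers = config.draw_markers(rng)
    pos_by_chrom = [
        markers.loc[markers["chrom"] == c, "pos_bp"].to_numpy().astype(float)
        for c in range(1, config.n_chromosomes + 1)
    ]
    m_total = len(markers)
    p0 = rng.uniform(config.maf_low, config.maf_high, size=m_total)
    H = (rng.random((2 * ne_true, m_total)) < p0).astype(np.int8)
    L = float(config.chrom_length_bp)
    morgans = config.morgans_per_chrom
    col0 = np.concatenate(([0], np.cumsum([len(p) for p in pos_by_chrom])))[:-1]

    def gamete(hap_pool: np.ndarray, parent: int) -> np.ndarray:
        g = np.empty(m_total, dtype=np.int8)
        for ci, pos in enumerate(pos_by_chrom):
            k = rng.poisson(morgans)
            start = int(rng.integers(2))
            if k == 0:
                phase = np.full(pos.size, start)
            else:
                cuts = np.sort(rng.uniform(0, L, size=k))
                phase = (start + np.searchsorted(cuts, pos)) % 2
            j = col0[ci]
            seg = np.where(
                phase == 0,
                hap_pool[2 * parent, j : j + pos.size],
                hap_pool[2 * parent + 1, j : j + pos.size],
            )
            g[j : j + pos.size] = seg
        return g

    for _gen in range(n_gens):
        new = np.empty_like(H)
        parents = rng.integers(ne_true, size=(ne_true, 2))
        for i in range(ne_true):
            new[2 * i] = gamete(H, int(parents[i, 0]))
            new[2 * i + 1] = gamete(H, int(parents[i, 1]))
        H = new

    # expanded final sampling generation
    calls = np.empty((sample_n, m_total), dtype=np.int8)
    parents = rng.integers(ne_true, size=(sample_n, 2))
    for i in range(sample_n):
        calls[i] = gamete(H, int(parents[i, 0])) + gamete(H, int(parents[i, 1]))

    freq = calls.mean(axis=0) / 2.0
    n_poly = int(((freq > 0) & (freq < 1)).sum())
    if n_poly < min_polymorphic:
        msg = f"only {n_poly} polymorphic markers after drift"
        if resample:
            logger.warning("%s; resampling with a new derived seed", msg)
            return wright_fisher(
                ne_true, n_gens, sample_n, config,
                seed=int(rng.integers(2**31 - 1)), min_polymorphic=min_polymorphic,
                resample=True,
            )
        logger.warning(msg)

    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate, MISSING, calls).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"wf_{i + 1}" for i in range(sample_n)], markers=markers, calls=calls
    )
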