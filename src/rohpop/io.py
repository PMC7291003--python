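"""Genotype, marker-map, pedigree and chromosome-table I/O.

Genotypes are held as an allele-dosage matrix (samples x markers) over the
4-state alphabet {0, 1, 2, MISSING}, counting copies of ``allele_b``.  By
default ``allele_b`` is the minor allele observed in the file, so a dosage of
2 means "homozygous for the minor allele".  Coordinates are 1-based and
inclusive throughout; BED export (see :mod:`rohpop.islands`) converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a no-call genotype.
MISSING: int = -1

#: Pig autosome labels; non-autosomal markers are dropped at load.
PIG_AUTOSOMES: tuple[int, ...] = tuple(range(1, 19))

#: Sentinel for an unknown parent in pedigree files.
UNKNOWN_PARENT: str = "0"

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "allele_a", "allele_b"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix plus its marker map.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.
    markers : pandas.DataFrame
        One row per marker with columns ``marker_id, chrom, pos_bp,
        allele_a, allele_b``, sorted by ``(chrom, pos_bp)``.
    calls : numpy.ndarray of int8, shape (n_samples, n_markers)
        Dosage of ``allele_b`` in {0, 1, 2} or :data:`MISSING`.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"calls outside {{0,1,2,MISSING}}: {bad}")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {list(dup[:5])}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        marker_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to boolean masks over samples / markers."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        mmask = np.ones(self.n_markers, bool) if marker_mask is None else np.asarray(marker_mask, bool)
        return GenotypeMatrix(
            samples=[s for s, k in zip(self.samples, smask) if k],
            markers=self.markers.loc[mmask].reset_index(drop=True),
            calls=self.calls[np.ix_(smask, mmask)].copy(),
        )

    def allele_b_freq(self) -> np.ndarray:
        """Per-marker frequency of allele_b among non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def call_rate_markers(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def chromosomes(self) -> list[int]:
        return sorted(self.markers["chrom"].unique())


@dataclass
class ChromosomeTable:
    """Per-chromosome physical and genetic lengths with the cM/Mb rate."""

    table: pd.DataFrame  # chrom, length_bp, length_cm, cm_per_mb

    def __post_init__(self) -> None:
        t = self.table
        if (t["length_bp"] <= 0).any() or (t["length_cm"] <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        if not np.isfinite(t["cm_per_mb"]).all():
            raise ValueError("cm_per_mb must be finite")

    @classmethod
    def from_lengths(cls, chroms: Sequence[int], length_bp: Sequence[int], length_cm: Sequence[float]) -> "ChromosomeTable":
        df = pd.DataFrame({"chrom": chroms, "length_bp": length_bp, "length_cm": length_cm})
        df["cm_per_mb"] = df["length_cm"] / (df["length_bp"] / 1e6)
        return cls(df)

    def cm_per_mb(self, chrom: int) -> float:
        row = self.table.loc[self.table["chrom"] == chrom, "cm_per_mb"]
        if row.empty:
            raise KeyError(f"chromosome {chrom} not in table")
        return float(row.iloc[0])

    def length_bp(self, chrom: int) -> int:
        row = self.table.loc[self.table["chrom"] == chrom, "length_bp"]
        if row.empty:
            raise KeyError(f"chromosome {chrom} not in table")
        return int(row.iloc[0])

    def mean_cm_per_mb(self) -> float:
        """Genome-wide rate: unweighted arithmetic mean over chromosomes."""
        return float(self.table["cm_per_mb"].mean())

    @property
    def total_length_kb(self) -> float:
        return float(self.table["length_bp"].sum()) / 1e3


@dataclass
class Pedigree:
    """Trio records (individual, sire, dam) with unknown parents as "0".

    The record list is validated to be acyclic; ``topological_order`` lists
    every individual parents-first, implicit founders (parents that never
    appear as individuals) included.
    """

    records: pd.DataFrame  # individual, sire, dam (str; UNKNOWN_PARENT sentinel)
    topological_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.astype(str).reset_index(drop=True)
        if df["individual"].duplicated().any():
            dup = df.loc[df["individual"].duplicated(), "individual"]
            raise ValueError(f"duplicate pedigree records: {list(dup[:5])}")
        self.records = df
        if not self.topological_order:
            self.topological_order = _toposort_pedigree(df)
        self._parents = {
            r.individual: (r.sire, r.dam) for r in df.itertuples(index=False)
        }

    def parents(self, individual: str) -> tuple[str, str]:
        """(sire, dam) of *individual*; implicit founders have unknown parents."""
        return self._parents.get(individual, (UNKNOWN_PARENT, UNKNOWN_PARENT))

    @property
    def individuals(self) -> list[str]:
        return list(self.records["individual"])

    def founders(self) -> list[str]:
        """Individuals (explicit or implicit) with both parents unknown."""
        return [
            i for i in self.topological_order
            if self.parents(i) == (UNKNOWN_PARENT, UNKNOWN_PARENT)
        ]

    def depth(self) -> int:
        """Generation depth = number of individuals on the longest ancestral path."""
        d: dict[str, int] = {}
        for ind in self.topological_order:
            s, dam = self.parents(ind)
            d[ind] = 1 + max(d.get(s, 0), d.get(dam, 0))
        return max(d.values(), default=0)


def _toposort_pedigree(df: pd.DataFrame) -> list[str]:
    """Kahn's algorithm over parent->child edges; raises on a cycle, naming it."""
    nodes: set[str] = set(df["individual"])
    parents: dict[str, tuple[str, str]] = {}
    for r in df.itertuples(index=False):
        parents[r.individual] = (r.sire, r.dam)
        for p in (r.sire, r.dam):
            if p != UNKNOWN_PARENT:
                nodes.add(p)
    indeg = {n: 0 for n in nodes}
    children: dict[str, list[str]] = {n: [] for n in nodes}
    for ind, (s, d) in parents.items():
        for p in (s, d):
            if p != UNKNOWN_PARENT:
                indeg[ind] += 1
                children[p].append(ind)
    order = [n for n in sorted(nodes) if indeg[n] == 0]
    out: list[str] = []
    queue = list(order)
    while queue:
        n = queue.pop(0)
        out.append(n)
        for c in sorted(children[n]):
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != len(nodes):
        cycle = sorted(n for n in nodes if indeg[n] > 0)
        raise ValueError(f"pedigree contains a cycle involving: {cycle}")
    return out


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------


def read_map(map_path: str | Path, autosomes: Iterable[int] = PIG_AUTOSOMES) -> pd.DataFrame:
    """Read a MAP file (chrom, marker_id[, cM], bp). Non-autosomes are kept here;
    :func:`read_ped_map` drops them together with their genotype columns."""
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) == 4:
            chrom, mid, _cm, pos = f
        elif len(f) == 3:
            chrom, mid, pos = f
        else:
            raise ParseError(f"{map_path}:{ln}: expected 3 or 4 columns, got {len(f)}")
        rows.append((mid, chrom, int(pos)))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"])
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"]
        raise ParseError(f"duplicate marker ids in {map_path}: {list(dup[:5])}")
    return df


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    autosomes: Iterable[int] = PIG_AUTOSOMES,
    orient: str = "minor",
) -> GenotypeMatrix:
    """Read whitespace-separated PED/MAP into a dosage :class:`GenotypeMatrix`.

    Parameters
    ----------
    orient : {"minor", "lexicographic"}
        How to pick the dosage-counted allele (``allele_b``): the minor allele
        after counting (default, ties broken lexicographically-second), or
        simply the lexicographically second observed allele.
    """
    if orient not in ("minor", "lexicographic"):
        raise ValueError(f"unknown orient {orient!r}")
    raw_map = read_map(map_path)
    m_all = len(raw_map)

    samples: list[str] = []
    rows: list[list[str]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * m_all:
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * m_all} fields "
                f"({m_all} markers), got {len(f)}"
            )
        samples.append(f[1])
        rows.append(f[6:])

    # restrict to the declared autosome set
    autoset = {str(a) for a in autosomes}
    keep = raw_map["chrom"].isin(autoset).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d non-autosomal markers", n_drop)
    raw_map = raw_map.loc[keep].reset_index(drop=True)
    raw_map["chrom"] = raw_map["chrom"].astype(int)

    a1 = np.empty((len(samples), m_all), dtype="U8")
    a2 = np.empty((len(samples), m_all), dtype="U8")
    for i, r in enumerate(rows):
        a1[i] = r[0::2]
        a2[i] = r[1::2]
    a1, a2 = a1[:, keep], a2[:, keep]

    calls = np.full((len(samples), len(raw_map)), MISSING, dtype=np.int8)
    allele_a = np.empty(len(raw_map), dtype=object)
    allele_b = np.empty(len(raw_map), dtype=object)
    for j in range(len(raw_map)):
        c1, c2 = a1[:, j], a2[:, j]
        obs = (c1 != "0") & (c2 != "0")
        alleles = sorted(set(c1[obs]) | set(c2[obs]))
        if len(alleles) > 2:
            raise ParseError(
                f"marker {raw_map['marker_id'][j]} has >2 alleles: {alleles}"
            )
        if not alleles:
            allele_a[j], allele_b[j] = None, None
            continue
        if len(alleles) == 1:
            ref, alt = alleles[0], None
        else:
            ref, alt = alleles
            if orient == "minor":
                n_alt = int((c1[obs] == alt).sum() + (c2[obs] == alt).sum())
                if n_alt > obs.sum():  # alt is the major allele -> swap
                    ref, alt = alt, ref
        allele_a[j], allele_b[j] = ref, alt
        if alt is None:
            calls[obs, j] = 0
        else:
            calls[obs, j] = (c1[obs] == alt).astype(np.int8) + (c2[obs] == alt).astype(np.int8)
    if orient == "minor":
        logger.info("dosage allele set to the minor allele at %d markers", len(raw_map))

    raw_map["allele_a"] = allele_a
    raw_map["allele_b"] = allele_b
    gm = GenotypeMatrix(samples=samples, markers=raw_map, calls=calls)
    return sort_markers(gm)


def sort_markers(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Sort markers by (chrom, pos_bp); drop duplicate positions (keep first)."""
    order = np.lexsort((gm.markers["pos_bp"].to_numpy(), gm.markers["chrom"].to_numpy()))
    markers = gm.markers.iloc[order].reset_index(drop=True)
    calls = gm.calls[:, order]
    dup = markers.duplicated(subset=["chrom", "pos_bp"]).to_numpy()
    if dup.any():
        logger.warning("dropping %d markers at duplicate positions (kept first)", int(dup.sum()))
        markers = markers.loc[~dup].reset_index(drop=True)
        calls = calls[:, ~dup]
    return GenotypeMatrix(samples=gm.samples, markers=markers, calls=calls.copy())


def write_ped_map(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP; allele labels default to A/B where the source had none."""
    with open(map_path, "w") as fh:
        for r in gm.markers.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.pos_bp}\n")
    aa = [a if a else "A" for a in gm.markers["allele_a"]] if "allele_a" in gm.markers else ["A"] * gm.n_markers
    bb = [b if b else "B" for b in gm.markers["allele_b"]] if "allele_b" in gm.markers else ["B"] * gm.n_markers
    code = {
        0: [(a, a) for a in aa],
        1: [(a, b) for a, b in zip(aa, bb)],
        2: [(b, b) for b in bb],
        MISSING: [("0", "0")] * gm.n_markers,
    }
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.samples):
            fields = [f"FAM{i + 1}", sid, "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(gm.n_markers):
                g = code[int(row[j])][j]
                fields.extend(g)
            fh.write(" ".join(fields) + "\n")


def read_vcf(vcf_path: str | Path, autosomes: Iterable[int] = PIG_AUTOSOMES) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (requires cyvcf2); ALT allele is allele_b."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    autoset = {str(a) for a in autosomes}
    rows, dosages = [], []
    for v in vcf:
        if v.CHROM not in autoset or len(v.ALT) != 1:
            continue
        gts = np.asarray(v.genotype.array())[:, :2]
        dose = np.where((gts < 0).any(axis=1), MISSING, gts.clip(0).sum(axis=1))
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", int(v.CHROM), v.POS, v.REF, v.ALT[0]))
        dosages.append(dose.astype(np.int8))
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    calls = np.column_stack(dosages) if dosages else np.zeros((len(samples), 0), np.int8)
    return sort_markers(GenotypeMatrix(samples=samples, markers=markers, calls=calls))


# ---------------------------------------------------------------------------
# chromosome table, pedigree files
# ---------------------------------------------------------------------------


def read_chromosome_table(path: str | Path) -> ChromosomeTable:
    """Read a chromosome table (chrom, length_bp, length_cM), tab/comma separated."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "length_bp", "length_cm"}
    if not required.issubset(df.columns):
        raise ParseError(f"chromosome table needs columns {sorted(required)}, got {list(df.columns)}")
    return ChromosomeTable.from_lengths(
        df["chrom"].astype(int), df["length_bp"].astype(int), df["length_cm"].astype(float)
    )


def write_chromosome_table(ct: ChromosomeTable, path: str | Path) -> None:
    ct.table[["chrom", "length_bp", "length_cm"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path, sentinel: str = UNKNOWN_PARENT) -> Pedigree:
    """Read a 3+ column pedigree file (individual, sire, dam); '' / NA -> unknown."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str, header=None)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: pedigree needs >=3 columns")
    first = df.iloc[0].str.lower().tolist()
    if first[:3] in (["individual", "sire", "dam"], ["id", "sire", "dam"]):
        df = df.iloc[1:]
    df = df.iloc[:, :3]
    df.columns = ["individual", "sire", "dam"]
    for col in ("sire", "dam"):
        df[col] = df[col].fillna(sentinel).replace({"": sentinel, "NA": sentinel, sentinel: UNKNOWN_PARENT})
    df["individual"] = df["individual"].astype(str)
    return Pedigree(records=df.reset_index(drop=True))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.records.to_csv(path, sep="\t", index=False, header=False)
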