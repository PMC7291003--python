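"""Three inbreeding coefficients and their comparison.

* ``F_PED`` — Wright's pedigree inbreeding coefficient: the kinship of the
  parents, computed by the recursive kinship (coancestry) algorithm with
  founders unrelated and non-inbred.
* ``F_HOM`` — excess homozygosity (O - E) / (L - E) over genotyped autosomal
  SNPs, with E the expected homozygous count under Hardy-Weinberg using
  unbiased (n/(n-1)-corrected) per-marker heterozygosity.
* ``F_ROH`` — fraction of the autosomal genome covered by ROH,
  sum(L_ROH) / L_auto, optionally restricted to a segment size class.

Coefficients are compared with Spearman rank correlations.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, UNKNOWN_PARENT, GenotypeMatrix, Pedigree
from .roh import SIZE_CLASSES

#: Autosomal genome length of the pig reference assembly (kb).
PIG_AUTOSOME_KB: float = 2_478_445.0


# ---------------------------------------------------------------------------
# F_HOM
# ---------------------------------------------------------------------------


def f_hom(gm: GenotypeMatrix, unbiased: bool = True) -> pd.DataFrame:
    """Per-sample excess-homozygosity coefficient.

    O counts the sample's non-missing homozygous calls; E sums, over the
    markers the sample is genotyped at, the expected homozygosity
    1 - 2 p q n/(n-1) (or 1 - 2 p q when *unbiased* is off) with p the panel
    allele frequency and n the non-missing allele count at the marker; L is
    the sample's non-missing marker count.
    """
    obs = gm.calls != MISSING
    p = gm.allele_b_freq()
    n_alleles = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = 2.0 * p * (1.0 - p)
        if unbiased:
            het = het * n_alleles / (n_alleles - 1.0)
    exp_hom = 1.0 - het  # per marker
    usable = obs & np.isfinite(exp_hom)
    O = (usable & ((gm.calls == 0) | (gm.calls == 2))).sum(axis=1).astype(float)
    E = np.where(usable, exp_hom, 0.0).sum(axis=1)
    L = usable.sum(axis=1).astype(float)
    denom = L - E
    if np.any(denom <= 0):
        bad = [s for s, d in zip(gm.samples, denom) if d <= 0]
        raise ValueError(f"F_HOM undefined (all markers monomorphic) for samples {bad[:5]}")
    return pd.DataFrame({"sample_id": gm.samples, "O": O, "E": E, "L": L,
                         "f_hom": (O - E) / denom})


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------


def f_roh(
    segments: pd.DataFrame,
    l_auto_kb: float = PIG_AUTOSOME_KB,
    class_filter: str | None = None,
) -> float:
    """sum(L_ROH)/L_auto for one sample's segments, optionally one size class."""
    if l_auto_kb <= 0:
        raise ValueError("l_auto_kb must be positive")
    if len(segments) and segments["sample_id"].nunique() > 1:
        raise ValueError("f_roh expects segments of a single sample")
    if class_filter is not None:
        if class_filter not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {class_filter!r}")
        segments = segments[segments["size_class"] == class_filter]
    return float(segments["length_kb"].sum()) / l_auto_kb if len(segments) else 0.0


def f_roh_table(
    segments: pd.DataFrame, samples: list[str], l_auto_kb: float = PIG_AUTOSOME_KB
) -> pd.DataFrame:
    """Per-sample F_ROH total and per size class (exact partition of the total)."""
    df = pd.DataFrame({"sample_id": samples})
    if len(segments):
        tot = segments.groupby("sample_id")["length_kb"].sum()
        df["f_roh_total"] = df["sample_id"].map(tot).fillna(0.0) / l_auto_kb
        for cls in SIZE_CLASSES:
            sub = segments[segments["size_class"] == cls].groupby("sample_id")["length_kb"].sum()
            df[f"f_roh_{cls}"] = df["sample_id"].map(sub).fillna(0.0) / l_auto_kb
    else:
        df["f_roh_total"] = 0.0
        for cls in SIZE_CLASSES:
            df[f"f_roh_{cls}"] = 0.0
    return df


# ---------------------------------------------------------------------------
# F_PED (Wright's coefficient via recursive kinship)
# ---------------------------------------------------------------------------


class KinshipCalculator:
    """Recursive kinship f(a,b) over a pedigree.

    f(a,a) = (1 + F_a)/2 with F_a the kinship of a's parents; for a != b,
    with a the individual later in topological order,
    f(a,b) = [f(sire_a, b) + f(dam_a, b)] / 2.  Unknown parents are unique
    unrelated, non-inbred founders (kinship 0 with everyone).
    """

    def __init__(self, pedigree: Pedigree):
        self.ped = pedigree
        self._rank = {ind: k for k, ind in enumerate(pedigree.topological_order)}
        self._memo: dict[tuple[str, str], float] = {}

    def kinship(self, a: str, b: str) -> float:
        if a not in self._rank or b not in self._rank:
            raise KeyError(f"individual not in pedigree: {a if a not in self._rank else b}")
        return self._kin(a, b)

    def _kin(self, a: str, b: str) -> float:
        if self._rank[a] < self._rank[b]:
            a, b = b, a
        key = (a, b)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        sire, dam = self.ped.parents(a)
        if a == b:
            val = 0.5 * (1.0 + self._parent_kin(sire, dam))
        else:
            val = 0.5 * (self._side(sire, b) + self._side(dam, b))
        self._memo[key] = val
        return val

    def _side(self, parent: str, b: str) -> float:
        return 0.0 if parent == UNKNOWN_PARENT else self._kin(parent, b)

    def _parent_kin(self, sire: str, dam: str) -> float:
        if UNKNOWN_PARENT in (sire, dam):
            return 0.0
        return self._kin(sire, dam)

    def inbreeding(self, individual: str) -> float:
        """F of *individual* = kinship of its parents (0 for founders)."""
        sire, dam = self.ped.parents(individual)
        return self._parent_kin(sire, dam)


def f_ped(pedigree: Pedigree, individual: str | None = None):
    """Wright's inbreeding coefficient for one individual, or a table for all."""
    calc = KinshipCalculator(pedigree)
    if individual is not None:
        return calc.inbreeding(individual)
    return pd.DataFrame(
        {
            "sample_id": pedigree.individuals,
            "f_ped": [calc.inbreeding(i) for i in pedigree.individuals],
        }
    )


# ---------------------------------------------------------------------------
# Spearman comparison
# ---------------------------------------------------------------------------


def spearman(x, y, exact_max_n: int = 0) -> tuple[float, float]:
    """Spearman rho with average ranks for ties; two-sided p.

    The p-value uses the t approximation; if n <= *exact_max_n* (and <= 10)
    an exact permutation p-value is computed instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if 3 <= x.size <= min(exact_max_n, 10):
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        p = count / total
    return float(rho), float(p)


def compare_coefficients(records: pd.DataFrame, exact_max_n: int = 0) -> pd.DataFrame:
    """All pairwise Spearman correlations between coefficient columns.

    *records* has one row per sample and one column per coefficient (plus an
    optional sample_id column); rows with any NaN among the compared columns
    are dropped and the n used is reported per pair.
    """
    cols = [c for c in records.columns if c != "sample_id"]
    if len(cols) < 2:
        raise ValueError("need at least two coefficient columns")
    rows = []
    for a in cols:
        for b in cols:
            sub = records[[a, b]].dropna()
            if a == b:
                rows.append((a, b, 1.0, 0.0, len(sub)))
                continue
            rho, p = spearman(sub[a], sub[b], exact_max_n=exact_max_n)
            rows.append((a, b, rho, p, len(sub)))
    return pd.DataFrame(rows, columns=["coef_a", "coef_b", "rho", "p_value", "n"])


def inbreeding_table(
    gm: GenotypeMatrix,
    segments: pd.DataFrame,
    pedigree: Pedigree | None = None,
    l_auto_kb: float = PIG_AUTOSOME_KB,
) -> pd.DataFrame:
    """Per-sample InbreedingRecord table: F_HOM, F_ROH (total + classes), F_PED.

    F_PED is present only for samples found in *pedigree*; the comparison
    operations use the intersection and report n.
    """
    out = f_hom(gm)[["sample_id", "f_hom"]].merge(
        f_roh_table(segments, gm.samples, l_auto_kb), on="sample_id"
    )
    if pedigree is not None:
        out = out.merge(f_ped(pedigree), on="sample_id", how="left")
    return out
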