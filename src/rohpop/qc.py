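"""Marker and sample quality control for chip genotypes.

Four filters plus relatedness pruning, each reporting what it removed:

1. marker call rate (default >= 0.95)
2. sample call rate (default >= 0.95)
3. minor allele frequency (default >= 0.05)
4. Hardy-Weinberg exact test (default p >= 1e-4)
5. pairwise IBD pruning (default PI_HAT < 0.5)

The default ordering follows the listing above; ``run_qc`` accepts any
permutation and the per-step report makes the order auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "marker_call_rate": 0.95,
    "sample_call_rate": 0.95,
    "maf": 0.05,
    "hwe_alpha": 1e-4,
    "max_pi_hat": 0.5,
}

DEFAULT_ORDER = ("marker_call_rate", "sample_call_rate", "maf", "hwe", "relatedness")


@dataclass
class QCReport:
    """Per-step removal counts; reconciles in-counts minus removals to out-counts."""

    n_samples_in: int
    n_markers_in: int
    thresholds: dict = field(default_factory=dict)
    removed_markers: dict = field(default_factory=dict)  # step -> count
    removed_samples: dict = field(default_factory=dict)
    n_samples_out: int = 0
    n_markers_out: int = 0

    def check(self) -> None:
        if self.n_samples_in - sum(self.removed_samples.values()) != self.n_samples_out:
            raise AssertionError("sample counts do not reconcile")
        if self.n_markers_in - sum(self.removed_markers.values()) != self.n_markers_out:
            raise AssertionError("marker counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_in", self.n_samples_in), ("markers_in", self.n_markers_in)]
        rows += [(f"markers_removed_{k}", v) for k, v in self.removed_markers.items()]
        rows += [(f"samples_removed_{k}", v) for k, v in self.removed_samples.items()]
        rows += [("samples_out", self.n_samples_out), ("markers_out", self.n_markers_out)]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["item", "value"])


def _empty_guard(gm: GenotypeMatrix, step: str) -> None:
    if gm.n_markers == 0 or gm.n_samples == 0:
        raise ValueError(
            f"QC step {step!r} removed everything; review thresholds"
        )


# ---------------------------------------------------------------------------
# call rate
# ---------------------------------------------------------------------------


def filter_call_rate(
    gm: GenotypeMatrix, marker_min: float = 0.95, sample_min: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-call-rate markers, then low-call-rate samples (order logged)."""
    for t in (marker_min, sample_min):
        if not 0 <= t <= 1:
            raise ValueError("call-rate thresholds must lie in [0,1]")
    rep = QCReport(gm.n_samples, gm.n_markers,
                   thresholds={"marker_call_rate": marker_min, "sample_call_rate": sample_min})
    keep_m = gm.call_rate_markers() >= marker_min
    rep.removed_markers["call_rate"] = int((~keep_m).sum())
    gm = gm.subset(marker_mask=keep_m)
    _empty_guard(gm, "marker_call_rate")
    keep_s = gm.call_rate_samples() >= sample_min
    rep.removed_samples["call_rate"] = int((~keep_s).sum())
    gm = gm.subset(sample_mask=keep_s)
    _empty_guard(gm, "sample_call_rate")
    logger.info("call-rate filter: markers first, then samples; removed %d / %d",
                rep.removed_markers["call_rate"], rep.removed_samples["call_rate"])
    rep.n_samples_out, rep.n_markers_out = gm.n_samples, gm.n_markers
    rep.check()
    return gm, rep


# ---------------------------------------------------------------------------
# minor allele frequency
# ---------------------------------------------------------------------------


def maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency min(p, 1-p); NaN where all calls missing."""
    p = gm.allele_b_freq()
    return np.minimum(p, 1.0 - p)


def filter_maf(gm: GenotypeMatrix, min_maf: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    rep = QCReport(gm.n_samples, gm.n_markers, thresholds={"maf": min_maf})
    m = maf(gm)
    all_missing = np.isnan(m)
    keep = (~all_missing) & (m >= min_maf)
    rep.removed_markers["all_missing"] = int(all_missing.sum())
    rep.removed_markers["maf"] = int(((~keep) & ~all_missing).sum())
    gm = gm.subset(marker_mask=keep)
    _empty_guard(gm, "maf")
    rep.n_samples_out, rep.n_markers_out = gm.n_samples, gm.n_markers
    rep.check()
    return gm, rep


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg p-value from genotype counts.

    The exact test conditions on the observed allele counts and sums the
    probabilities of all heterozygote counts no more probable than the one
    observed.  A monomorphic marker cannot deviate and returns p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative with positive sum")
    if method == "chi2":
        return _hwe_chi2(n_AA, n_Aa, n_aa)
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | n, n_rare) up to the common normalizer
    n_common = 2 * n - n_rare
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln((n_common - hets) / 2 + 1)
        - gammaln(hets + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_Aa][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    obs = np.array([n_AA, n_Aa, n_aa], float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def hwe_pvalues(gm: GenotypeMatrix, method: str = "exact") -> np.ndarray:
    counts0 = (gm.calls == 0).sum(axis=0)
    counts1 = (gm.calls == 1).sum(axis=0)
    counts2 = (gm.calls == 2).sum(axis=0)
    out = np.ones(gm.n_markers)
    for j in range(gm.n_markers):
        tot = counts0[j] + counts1[j] + counts2[j]
        if tot > 0:
            out[j] = hwe_test(int(counts0[j]), int(counts1[j]), int(counts2[j]), method)
    return out


def filter_hwe(gm: GenotypeMatrix, alpha: float = 1e-4, method: str = "exact") -> tuple[GenotypeMatrix, QCReport]:
    rep = QCReport(gm.n_samples, gm.n_markers, thresholds={"hwe_alpha": alpha})
    keep = hwe_pvalues(gm, method) >= alpha
    rep.removed_markers["hwe"] = int((~keep).sum())
    gm = gm.subset(marker_mask=keep)
    _empty_guard(gm, "hwe")
    rep.n_samples_out, rep.n_markers_out = gm.n_samples, gm.n_markers
    rep.check()
    return gm, rep


# ---------------------------------------------------------------------------
# relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------


def _ibs_expectations(p: np.ndarray) -> tuple[float, float, float, float]:
    """Summed per-locus IBS-count expectations under IBD state 0 and 1."""
    q = 1.0 - p
    e0_ibs0 = float((2 * p**2 * q**2).sum())
    e0_ibs1 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e1_ibs1 = float((2 * p**2 * q + 2 * p * q**2).sum())  # = sum 2pq
    e0_ibs2 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    return e0_ibs0, e0_ibs1, e1_ibs1, e0_ibs2


def pi_hat(gm: GenotypeMatrix, i: int, j: int, min_markers: int = 50) -> float:
    """Method-of-moments genome-wide IBD proportion for one sample pair."""
    mat = pairwise_pi_hat(gm, pairs=[(i, j)], min_markers=min_markers)
    return float(mat["pi_hat"].iloc[0])


def pairwise_pi_hat(
    gm: GenotypeMatrix,
    pairs: list[tuple[int, int]] | None = None,
    min_markers: int = 50,
) -> pd.DataFrame:
    """PI_HAT = P(IBD=1)/2 + P(IBD=2) for the given (or all) sample pairs.

    Moments: observed IBS0/1/2 counts are equated to their expectations given
    sample allele frequencies; the resulting P(IBD=k) are clipped to [0,1]
    and renormalized, so PI_HAT lands in [0,1].
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    if pairs is None:
        pairs = [(i, j) for i in range(gm.n_samples) for j in range(i + 1, gm.n_samples)]
    freqs = gm.allele_b_freq()
    poly = (~np.isnan(freqs)) & (freqs > 0) & (freqs < 1)
    calls = gm.calls[:, poly]
    p_all = freqs[poly]
    rows = []
    for i, j in pairs:
        gi, gj = calls[i], calls[j]
        obs = (gi != MISSING) & (gj != MISSING)
        if int(obs.sum()) < min_markers:
            raise ValueError(
                f"pair ({gm.samples[i]}, {gm.samples[j]}): only {int(obs.sum())} "
                f"informative markers (< {min_markers})"
            )
        p = p_all[obs]
        diff = np.abs(gi[obs].astype(np.int16) - gj[obs].astype(np.int16))
        o_ibs0 = int((diff == 2).sum())
        o_ibs1 = int((diff == 1).sum())
        o_ibs2 = int((diff == 0).sum())
        e0_ibs0, e0_ibs1, e1_ibs1, e0_ibs2 = _ibs_expectations(p)
        L = len(p)
        p0 = o_ibs0 / e0_ibs0 if e0_ibs0 > 0 else 0.0
        p1 = (o_ibs1 - p0 * e0_ibs1) / e1_ibs1 if e1_ibs1 > 0 else 0.0
        e1_ibs2 = L - e1_ibs1
        p2 = (o_ibs2 - p0 * e0_ibs2 - p1 * e1_ibs2) / L
        probs = np.clip([p0, p1, p2], 0.0, 1.0)
        s = probs.sum()
        if s > 0:
            probs = probs / s
        ph = float(np.clip(probs[1] / 2 + probs[2], 0.0, 1.0))
        rows.append((gm.samples[i], gm.samples[j], ph))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "pi_hat"])


def prune_related(
    gm: GenotypeMatrix, max_pi_hat: float = 0.5, min_markers: int = 50
) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy pruning: repeatedly drop one member of the highest-PI_HAT pair.

    The member with the lower call rate is dropped; ties drop the sample that
    comes later in the sample ordering.
    """
    rep = QCReport(gm.n_samples, gm.n_markers, thresholds={"max_pi_hat": max_pi_hat})
    table = pairwise_pi_hat(gm, min_markers=min_markers)
    call_rate = dict(zip(gm.samples, gm.call_rate_samples()))
    index = {s: k for k, s in enumerate(gm.samples)}
    flagged = table[table["pi_hat"] >= max_pi_hat].sort_values(
        "pi_hat", ascending=False, kind="mergesort"
    )
    dropped: set[str] = set()
    for r in flagged.itertuples(index=False):
        if r.sample_i in dropped or r.sample_j in dropped:
            continue
        ci, cj = call_rate[r.sample_i], call_rate[r.sample_j]
        if ci < cj:
            victim = r.sample_i
        elif cj < ci:
            victim = r.sample_j
        else:
            victim = r.sample_i if index[r.sample_i] > index[r.sample_j] else r.sample_j
        dropped.add(victim)
    rep.removed_samples["relatedness"] = len(dropped)
    gm = gm.subset(sample_mask=np.array([s not in dropped for s in gm.samples]))
    _empty_guard(gm, "relatedness")
    rep.n_samples_out, rep.n_markers_out = gm.n_samples, gm.n_markers
    rep.check()
    return gm, rep


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------


def run_qc(
    gm: GenotypeMatrix,
    thresholds: dict | None = None,
    order: tuple[str, ...] = DEFAULT_ORDER,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the filters in *order*, merging the per-step reports."""
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    rep = QCReport(gm.n_samples, gm.n_markers, thresholds=dict(th))
    for step in order:
        if step == "marker_call_rate":
            keep = gm.call_rate_markers() >= th["marker_call_rate"]
            rep.removed_markers["call_rate"] = int((~keep).sum())
            gm = gm.subset(marker_mask=keep)
        elif step == "sample_call_rate":
            keep = gm.call_rate_samples() >= th["sample_call_rate"]
            rep.removed_samples["call_rate"] = int((~keep).sum())
            gm = gm.subset(sample_mask=keep)
        elif step == "maf":
            gm, sub = filter_maf(gm, th["maf"])
            rep.removed_markers.update(sub.removed_markers)
        elif step == "hwe":
            gm, sub = filter_hwe(gm, th["hwe_alpha"], method=hwe_method)
            rep.removed_markers.update(sub.removed_markers)
        elif step == "relatedness":
            gm, sub = prune_related(gm, th["max_pi_hat"])
            rep.removed_samples.update(sub.removed_samples)
        else:
            raise ValueError(f"unknown QC step {step!r}")
        _empty_guard(gm, step)
        logger.info("QC step %s -> %d samples x %d markers", step, gm.n_samples, gm.n_markers)
    rep.n_samples_out, rep.n_markers_out = gm.n_samples, gm.n_markers
    rep.check()
    return gm, rep
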