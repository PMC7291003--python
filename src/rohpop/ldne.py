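"""Pairwise LD (r²), distance binning, and LD-based Ne trajectories.

The estimator is Sved's drift-recombination relation

    Ne(c) = (1 / 4c) * (1 / E(r²) - 1),        t = 1 / (2c)

where c is the linkage map distance in Morgans between the SNP pairs whose
mean squared dosage correlation is E(r²), and t is the number of generations
ago that the estimate reflects.  Distance bins may be formed in physical
units (100..5000 kb, with c = bin length in Mb x the chromosome's cM/Mb rate;
the default, which reproduces published per-chromosome tables built this way)
or in genetic units (0.1..5 cM with c the nominal bin distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, ChromosomeTable, GenotypeMatrix

#: Nominal distance bin targets in cM; under the physical convention a target
#: of x cM means a physical distance of x Mb.
DEFAULT_TARGETS_CM = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
DEFAULT_TOL = 0.05
MAX_DIST_BP = 10_000_000


@dataclass(frozen=True)
class DistanceBin:
    target_cm: float
    mean_r2: float
    n_pairs: int


def pairwise_r2(
    gm: GenotypeMatrix,
    chromosome: int,
    max_dist_bp: int = MAX_DIST_BP,
    min_complete: int = 4,
) -> pd.DataFrame:
    """r² (squared Pearson correlation of dosages) for all same-chromosome
    pairs within *max_dist_bp*; complete-case per pair.

    Pairs with fewer than *min_complete* joint non-missing samples, or with a
    zero-variance marker in the complete-case subset, are skipped (the count
    of skipped pairs is in ``df.attrs["n_skipped"]``).
    """
    sel = (gm.markers["chrom"] == chromosome).to_numpy()
    pos = gm.markers.loc[sel, "pos_bp"].to_numpy()
    m = pos.size
    if m < 2:
        raise ValueError(f"chromosome {chromosome} has fewer than 2 markers")
    X = gm.calls[:, sel].astype(np.float64)
    obs = X != MISSING
    Z = np.where(obs, X, 0.0)
    M = obs.astype(np.float64)
    # complete-case moments for every pair via matrix products
    N = M.T @ M
    Sxy = Z.T @ Z
    Sx = Z.T @ M      # Sx[i,j] = sum of x_i over samples observed at both i and j
    Sxx = (Z * Z).T @ M
    ii, jj = np.triu_indices(m, k=1)
    dist = pos[jj] - pos[ii]
    in_range = dist <= max_dist_bp
    ii, jj, dist = ii[in_range], jj[in_range], dist[in_range]
    n = N[ii, jj]
    sx, sy = Sx[ii, jj], Sx[jj, ii]
    sxx, syy = Sxx[ii, jj], Sxx[jj, ii]
    sxy = Sxy[ii, jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        cov = n * sxy - sx * sy
        r2 = (cov * cov) / (vx * vy)
    ok = (n >= min_complete) & (vx > 0) & (vy > 0)
    out = pd.DataFrame(
        {
            "marker_i": gm.markers.loc[sel, "marker_id"].to_numpy()[ii[ok]],
            "marker_j": gm.markers.loc[sel, "marker_id"].to_numpy()[jj[ok]],
            "distance_bp": dist[ok].astype(np.int64),
            "r2": r2[ok],
        }
    )
    out.attrs["n_skipped"] = int((~ok).sum())
    out.attrs["chromosome"] = chromosome
    return out


def bin_by_genetic_distance(
    pairs: pd.DataFrame,
    cm_per_mb: float,
    targets_cm=DEFAULT_TARGETS_CM,
    tol: float = DEFAULT_TOL,
    units: str = "genetic",
) -> list[DistanceBin]:
    """Mean r² per distance bin; a pair is in bin k iff its distance lies in
    [target*(1-tol), target*(1+tol)].

    units="genetic": distance compared in cM (bp x cM/Mb / 1e6).
    units="physical": the nominal x-cM target is the x-Mb physical bin.
    Empty bins are reported with n_pairs = 0 and mean_r2 = NaN.
    """
    if units not in ("genetic", "physical"):
        raise ValueError(f"unknown units {units!r}")
    dist_bp = pairs["distance_bp"].to_numpy(np.float64)
    r2 = pairs["r2"].to_numpy()
    out = []
    for t in targets_cm:
        if units == "genetic":
            d = dist_bp * cm_per_mb / 1e6  # cM
        else:
            d = dist_bp / 1e6  # "cM" target read as Mb
        mask = (d >= t * (1 - tol)) & (d <= t * (1 + tol))
        n = int(mask.sum())
        out.append(DistanceBin(t, float(r2[mask].mean()) if n else float("nan"), n))
    return out


def estimate_ne(e_r2: float, c_morgans: float) -> float:
    """Sved's Ne = (1/(4c)) (1/E(r²) - 1); zero when E(r²) = 1."""
    if not 0 < e_r2 <= 1:
        raise ValueError(f"E(r2) must lie in (0, 1], got {e_r2}")
    if c_morgans <= 0:
        raise ValueError(f"c must be positive Morgans, got {c_morgans}")
    return (1.0 / (4.0 * c_morgans)) * (1.0 / e_r2 - 1.0)


def generations_for_distance(c_morgans: float) -> float:
    """t = 1/(2c): the generation depth an Ne estimate at distance c reflects."""
    if c_morgans <= 0:
        raise ValueError(f"c must be positive Morgans, got {c_morgans}")
    return 1.0 / (2.0 * c_morgans)


def _c_morgans(target_cm: float, cm_per_mb: float, units: str) -> float:
    if units == "physical":
        # target read as Mb of physical distance; convert via the chromosome rate
        return target_cm * cm_per_mb / 100.0
    return target_cm / 100.0


def ne_trajectory(
    gm: GenotypeMatrix,
    chrom_table: ChromosomeTable,
    targets_cm=DEFAULT_TARGETS_CM,
    tol: float = DEFAULT_TOL,
    units: str = "physical",
    max_dist_bp: int = MAX_DIST_BP,
    min_complete: int = 4,
    sample_size_correction: bool = False,
) -> pd.DataFrame:
    """Per-chromosome and genome-wide Ne(t) table.

    One row per (scope, bin); the genome-wide scope ("total") averages the
    per-chromosome Ne values (unweighted) and uses the mean cM/Mb rate.
    Chromosomes with an empty bin are excluded from that bin's mean.
    The generation label always uses the nominal genetic target
    (0.1 cM -> 500 generations), matching the published convention.
    If *sample_size_correction* is set, 1/n is subtracted from each bin mean
    r² before the Ne formula (off by default).
    """
    rows = []
    for chrom in gm.chromosomes():
        rate = chrom_table.cm_per_mb(chrom)
        pairs = pairwise_r2(gm, chrom, max_dist_bp, min_complete)
        for b in bin_by_genetic_distance(pairs, rate, targets_cm, tol, units=units):
            c = _c_morgans(b.target_cm, rate, units)
            e_r2 = b.mean_r2
            if sample_size_correction and b.n_pairs:
                e_r2 = max(e_r2 - 1.0 / gm.n_samples, 1e-12)
            ne = estimate_ne(e_r2, c) if b.n_pairs and 0 < e_r2 <= 1 else float("nan")
            rows.append(
                (chrom, b.target_cm, c, e_r2, b.n_pairs, ne,
                 generations_for_distance(b.target_cm / 100.0))
            )
    df = pd.DataFrame(
        rows, columns=["scope", "target_cm", "c_morgans", "mean_r2", "n_pairs", "ne", "generations"]
    )
    # genome-wide summary row per bin
    mean_rate = chrom_table.mean_cm_per_mb()
    totals = []
    for t in targets_cm:
        sub = df[(df["target_cm"] == t) & np.isfinite(df["ne"])]
        totals.append(
            ("total", t, _c_morgans(t, mean_rate, units),
             float(df[df["target_cm"] == t]["mean_r2"].mean()),
             int(df[df["target_cm"] == t]["n_pairs"].sum()),
             float(sub["ne"].mean()) if len(sub) else float("nan"),
             generations_for_distance(t / 100.0))
        )
    return pd.concat([df, pd.DataFrame(totals, columns=df.columns)], ignore_index=True)


def trajectory_from_summary(
    summary: pd.DataFrame,
    targets_cm=DEFAULT_TARGETS_CM,
    r2_columns=None,
) -> pd.DataFrame:
    """Ne table from an already-binned LD summary (one row per chromosome with
    a cM/Mb rate and one mean-r² column per physical distance bin).

    This is how a published per-chromosome LD table is turned back into Ne
    estimates: c = bin length (Mb) x cM/Mb / 100.
    """
    if r2_columns is None:
        r2_columns = [f"r2_{int(t * 1000)}" for t in targets_cm]
    rows = []
    for r in summary.itertuples(index=False):
        rate = r.cm_per_mb
        for t, col in zip(targets_cm, r2_columns):
            c = t * rate / 100.0
            e_r2 = float(getattr(r, col))
            rows.append((r.chrom, t, c, e_r2, estimate_ne(e_r2, c),
                         generations_for_distance(t / 100.0)))
    df = pd.DataFrame(rows, columns=["scope", "target_cm", "c_morgans", "mean_r2", "ne", "generations"])
    mean_rate = float(summary["cm_per_mb"].mean())
    totals = [
        ("total", t, t * mean_rate / 100.0,
         float(df[df["target_cm"] == t]["mean_r2"].mean()),
         float(df[df["target_cm"] == t]["ne"].mean()),
         generations_for_distance(t / 100.0))
        for t in targets_cm
    ]
    return pd.concat([df, pd.DataFrame(totals, columns=df.columns)], ignore_index=True)
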