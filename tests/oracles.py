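"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (enumeration, direct scanning,
single-locus Monte Carlo) kept separate from the implementations they check.
"""

from fractions import Fraction
from math import comb

import numpy as np

from rohpop.io import MISSING


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_b = 2 * n_aa + n_Aa  # allele-b count
    probs = {}
    for h in range(n_b % 2, min(n_b, 2 * n - n_b) + 1, 2):
        naa = (n_b - h) // 2
        nAA = n - naa - h
        probs[h] = Fraction(2**h * comb(n, nAA) * comb(n - nAA, h), 1)
    total = sum(probs.values())
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs) / total)


def brute_force_runs(calls, pos, params, missing_ok):
    """Maximal homozygous stretches with gap / min-SNP / min-length rules;
    the expected output of the ROH caller at window_snps=1, hit fraction 1."""
    ok = (calls == 0) | (calls == 2)
    if missing_ok:
        ok |= calls == MISSING
    segs = []
    i = 0
    m = len(calls)
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and ok[j + 1]:
            j += 1
        cuts = [i] + [k + 1 for k in range(i, j) if pos[k + 1] - pos[k] > params.max_gap_kb * 1000] + [j + 1]
        for s, e in zip(cuts[:-1], cuts[1:]):
            e -= 1
            n_snps = e - s + 1
            kb = (pos[e] - pos[s] + 1) / 1000
            if n_snps >= params.min_snps and kb >= params.min_length_kb:
                segs.append((int(pos[s]), int(pos[e]), n_snps))
        i = j + 1
    return segs


def single_locus_drop(pedigree, targets, n_replicates, rng):
    """Monte-Carlo expected autozygosity at one locus per target individual.

    Labels for founder gametes are unique; each inheritance picks one of the
    parent's two labels.  The expectation over replicates is Wright's F.
    """
    labels = {}
    nxt = 0
    for ind in pedigree.topological_order:
        sire, dam = pedigree.parents(ind)
        gam = []
        for par in (sire, dam):
            if par == "0" or par not in labels:
                gam.append(np.full(n_replicates, nxt))
                nxt += 1
            else:
                pick = rng.random(n_replicates) < 0.5
                gam.append(np.where(pick, labels[par][0], labels[par][1]))
        labels[ind] = gam
    return {t: float((labels[t][0] == labels[t][1]).mean()) for t in targets}
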