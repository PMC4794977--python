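"""Independent brute-force oracles used by the property tests."""

from math import comb

import numpy as np

from autozyg.genotype_io import MISSING


def fisher_one_sided_enumeration(a, b, c, d, direction="greater"):
    """Exact one-sided Fisher p by enumerating all tables with fixed margins."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    denom = comb(n, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    if direction == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    return sum(p for k, p in probs.items() if k <= a)


def bh_naive(p_values, m_total):
    """Quadratic min-scan Benjamini-Hochberg step-up."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    for i, idx in enumerate(order):
        candidates = [p[order[j]] * m_total / (j + 1) for j in range(i, p.size)]
        q[idx] = min(1.0, min(candidates))
    return q


def roh_brute_force(dataset, params):
    """Maximal zero-heterozygote runs with the ROH filters applied.

    Enumerates, per individual and chromosome, the maximal runs of
    consecutive non-heterozygous calls (missing allowed), splits them at
    inter-SNP gaps above max_gap_kb and keeps runs passing the SNP-count,
    length and density thresholds.  Returns a set of
    (sample_id, chrom, start_bp, end_bp) tuples.
    """
    out = set()
    chrom_arr = dataset.variants["chrom"].to_numpy()
    bp_arr = dataset.variants["bp"].to_numpy()
    ids = dataset.samples["id"].to_numpy()
    for c in np.unique(chrom_arr):
        sel = np.nonzero(chrom_arr == c)[0]
        bp = bp_arr[sel]
        for s in range(dataset.n_samples):
            g = dataset.calls[s, sel]
            runs = []
            start = None
            for j in range(g.size + 1):
                inside = j < g.size and g[j] != 1
                if inside and start is None:
                    start = j
                elif not inside and start is not None:
                    runs.append((start, j - 1))
                    start = None
            for lo, hi in runs:
                pieces = [[lo]]
                for k in range(lo, hi):
                    if (bp[k + 1] - bp[k]) / 1000.0 > params.max_gap_kb:
                        pieces[-1].append(k)
                        pieces.append([k + 1])
                pieces[-1].append(hi)
                for plo, phi in pieces:
                    n_snp = phi - plo + 1
                    kb = (bp[phi] - bp[plo] + 1) / 1000.0
                    if n_snp < params.min_snp or kb < params.min_kb:
                        continue
                    if kb / n_snp > params.min_density_kb_per_snp:
                        continue
                    out.add((ids[s], int(c), int(bp[plo]), int(bp[phi])))
    return out


def interval_overlap_components(intervals):
    """Connected components of the interval-overlap graph, brute force O(n^2)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 <= e2 and s2 <= e1:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(frozenset(v) for v in comps.values())
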