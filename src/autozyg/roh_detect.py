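"""Sliding-window detection of runs of homozygosity (ROH).

The scanning algorithm follows the classical SNP-count windowing scheme of
array-era ROH callers: windows of ``window_snp`` SNPs slide along each
chromosome, a window is *homozygous* when it contains at most ``window_het``
heterozygous and at most ``window_missing`` missing calls, and a SNP is
ROH-eligible when the fraction of overlapping homozygous windows exceeds
``window_threshold``.  Runs of eligible SNPs form segment cores which are
extended outward over consecutive non-heterozygous calls (a heterozygous
call terminates a segment when ``window_het = 0``), split at inter-SNP gaps
above ``max_gap_kb``, and finally filtered on SNP count, physical length
and SNP density.  With the default parameters the emitted segments coincide
with the maximal zero-heterozygote runs passing the same filters.

``min_roh_snps`` computes the cohort-calibrated minimum run length: the
smallest L with ``(1 - het)^L * n_snps * n_samples <= alpha``, i.e. less
than ``alpha`` expected chance runs of length L in the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from autozyg.genotype_io import MISSING, GenotypeDataset

__all__ = ["ROHParams", "min_roh_snps", "count_tag_groups", "scan_roh"]


@dataclass(frozen=True)
class ROHParams:
    """ROH scan parameters (PLINK 1.07 defaults, het-free windows, 75-SNP runs)."""

    window_snp: int = 50
    window_het: int = 0
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 75
    min_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.window_snp < 1 or self.min_snp < 1:
            raise ValueError("window_snp and min_snp must be >= 1")
        if min(self.window_het, self.window_missing, self.window_threshold,
               self.min_kb, self.min_density_kb_per_snp, self.max_gap_kb) < 0:
            raise ValueError("ROH parameters must be non-negative")


#: columns of the segment table emitted by :func:`scan_roh` (PLINK .hom style)
SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snp", "length_kb"]


def min_roh_snps(mean_het: float, n_snps: int, n_samples: int,
                 alpha: float = 0.05) -> int:
    """Smallest run length L with ``(1-mean_het)^L * n_snps * n_samples <= alpha``.

    This bounds the expected number of chance (LD-free) homozygous runs of
    length L across the whole cohort by ``alpha``.
    """
    if not 0 < mean_het < 1:
        raise ValueError("mean_het must lie in (0, 1)")
    if n_snps < 1 or n_samples < 1:
        raise ValueError("n_snps and n_samples must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    hom = 1.0 - mean_het
    total = float(n_snps) * float(n_samples)
    # closed form, then adjust for floating-point edge effects
    L = max(1, int(np.ceil(np.log(alpha / total) / np.log(hom))))
    while L > 1 and hom ** (L - 1) * total <= alpha:
        L -= 1
    while hom ** L * total > alpha:
        L += 1
    return L


def effective_min_snp(min_independent: int, reduction: float) -> int:
    """Inflate an independent-SNP run length for inter-SNP LD.

    ``reduction`` is the fraction of SNPs tagged by another SNP (e.g. from
    :func:`count_tag_groups`: ``1 - n_groups / n_snps``); the returned
    length ``ceil(L / (1 - reduction))`` spans roughly ``min_independent``
    independent calls.
    """
    if not 0 <= reduction < 1:
        raise ValueError("reduction must lie in [0, 1)")
    return int(np.ceil(min_independent / (1.0 - reduction)))


def count_tag_groups(dataset: GenotypeDataset, r2_threshold: float = 0.8,
                     window_kb: float = 250.0) -> int:
    """Greedy count of LD tag groups (proxy for independent SNP calls).

    Walking left to right within each chromosome, a SNP joins the current
    group when it lies within ``window_kb`` of the group's seed SNP and its
    genotype-dosage r^2 with the seed exceeds ``r2_threshold``; otherwise it
    seeds a new group.  Returns the number of groups.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in (0, 1]")
    chrom = dataset.variants["chrom"].to_numpy()
    bp = dataset.variants["bp"].to_numpy()
    calls = dataset.calls
    n_groups = 0
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        seed = None
        for j in idx:
            if seed is not None and (bp[j] - bp[seed]) <= window_kb * 1000:
                if _dosage_r2(calls[:, seed], calls[:, j]) > r2_threshold:
                    continue
            seed = j
            n_groups += 1
    return n_groups


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r


def scan_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every individual.

    Returns a PLINK ``.hom``-style table with columns
    ``sample_id, chrom, start_bp, end_bp, n_snp, length_kb`` (1-based
    inclusive bounds; ``length_kb = (end - start + 1)/1000``).
    """
    if params is None:
        params = ROHParams()
    dataset.validate()  # raises on unsorted/malformed input
    chrom_arr = dataset.variants["chrom"].to_numpy()
    bp_arr = dataset.variants["bp"].to_numpy()
    sample_ids = dataset.samples["id"].to_numpy()

    rows: list[tuple] = []
    for c in np.unique(chrom_arr):
        sel = np.nonzero(chrom_arr == c)[0]
        bp = bp_arr[sel]
        sub = dataset.calls[:, sel]
        gaps_kb = np.diff(bp) / 1000.0
        for s in range(dataset.n_samples):
            for lo, hi in _segments_one(sub[s], bp, gaps_kb, params):
                n_snp = hi - lo + 1
                start, end = int(bp[lo]), int(bp[hi])
                length_kb = (end - start + 1) / 1000.0
                rows.append((sample_ids[s], int(c), start, end, n_snp, length_kb))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _segments_one(g: np.ndarray, bp: np.ndarray, gaps_kb: np.ndarray,
                  params: ROHParams) -> list[tuple[int, int]]:
    """Index bounds (inclusive) of emitted segments for one individual/chromosome."""
    n = g.size
    het = g == 1
    miss = g == MISSING
    w = min(params.window_snp, n)
    if n == 0:
        return []

    # sliding window homozygosity; window i covers SNPs [i, i+w-1]
    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    het_in = het_c[w:] - het_c[:-w]
    miss_in = miss_c[w:] - miss_c[:-w]
    hom_win = (het_in <= params.window_het) & (miss_in <= params.window_missing)

    # per-SNP fraction of overlapping windows that are homozygous
    hom_c = np.concatenate([[0], np.cumsum(hom_win)])
    j = np.arange(n)
    first = np.maximum(0, j - w + 1)
    last = np.minimum(j, n_win - 1)
    denom = np.maximum(last - first + 1, 0)
    num = np.where(denom > 0, hom_c[np.maximum(last + 1, 0)] - hom_c[first], 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
    eligible = frac > params.window_threshold

    # cores: maximal runs of eligible SNPs
    cores = _runs(eligible)
    if not cores:
        return []

    # extend cores over consecutive non-heterozygous calls; a het call
    # terminates a segment (only meaningful when window_het == 0 -- with
    # het-tolerant windows the eligible runs are kept as-is)
    extended: set[tuple[int, int]] = set()
    if params.window_het == 0:
        for lo, hi in cores:
            while lo > 0 and not het[lo - 1]:
                lo -= 1
            while hi < n - 1 and not het[hi + 1]:
                hi += 1
            extended.add((lo, hi))
    else:
        extended.update(cores)

    out = []
    for lo, hi in sorted(extended):
        # split at large inter-SNP gaps
        pieces = [[lo]]
        for k in range(lo, hi):
            if gaps_kb[k] > params.max_gap_kb:
                pieces[-1].append(k)
                pieces.append([k + 1])
        pieces[-1].append(hi)
        for plo, phi in pieces:
            n_snp = phi - plo + 1
            length_kb = (bp[phi] - bp[plo] + 1) / 1000.0
            if n_snp < params.min_snp or length_kb < params.min_kb:
                continue
            if length_kb / n_snp > params.min_density_kb_per_snp:
                continue
            out.append((plo, phi))
    # merging of overlapping extensions: identical (lo, hi) deduplicated by
    # the set; distinct extended runs cannot overlap (they are separated by
    # blocking het calls), so the list is disjoint and sorted
    return sorted(set(out))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive index bounds of maximal True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))
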