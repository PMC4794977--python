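"""Pooling of overlapping ROH segments, consensus regions and their tests.

Pools are connected components of the per-chromosome interval-overlap graph
(single-linkage closure), mirroring the behaviour of PLINK's
``--homozyg-group``.  A pool's *consensus* region is the strict
intersection of its member intervals (max of starts to min of ends); under
transitive pooling that intersection can be empty, in which case the pool
is flagged and excluded from the recurrent-ROH list rather than split.
Recurrent ROHs are pools carried by more than five distinct individuals
(>= 6) with a consensus of at least 500 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from autozyg.genotype_io import MISSING, GenotypeDataset
from autozyg.stats_core import (
    ContingencyTable2x2,
    TestResult,
    chi2_2x2,
    two_sample_t,
)

__all__ = [
    "ConsensusPool",
    "pool_overlapping",
    "consensus_region",
    "filter_recurrent",
    "common_roh_groups",
    "carrier_association",
    "homozygosity_proportion_test",
]


@dataclass
class ConsensusPool:
    """A group of overlapping ROH segments with its consensus interval."""

    pool_id: int
    chrom: int
    members: pd.DataFrame = field(repr=False)
    consensus_start_bp: int | None = None
    consensus_end_bp: int | None = None
    consensus_n_snp: int | None = None
    n_cases: int = 0
    n_controls: int = 0
    flag: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_distinct_samples(self) -> int:
        return self.members["sample_id"].nunique()

    @property
    def consensus_length_kb(self) -> float | None:
        if self.consensus_start_bp is None or self.flag == "non_consensus":
            return None
        return (self.consensus_end_bp - self.consensus_start_bp + 1) / 1000.0


def pool_overlapping(segments: pd.DataFrame,
                     phenotype_by_sample: dict | None = None
                     ) -> list[ConsensusPool]:
    """Group segments into per-chromosome overlap pools.

    Pools are the connected components of the interval-overlap graph
    (segments sharing >= 1 bp, closed transitively); each segment belongs to
    exactly one pool and the result is independent of input order.
    ``phenotype_by_sample`` (sample_id -> 0/1) fills the case/control
    carrier counts.
    """
    if len(segments) == 0:
        return []
    pools: list[ConsensusPool] = []
    pool_id = 0
    for c, grp in segments.groupby("chrom", sort=True):
        grp = grp.sort_values(["start_bp", "end_bp"], kind="stable")
        current: list[int] = []
        max_end = -1
        for idx, row in grp.iterrows():
            if current and row["start_bp"] > max_end:
                pools.append(_make_pool(pool_id, int(c), grp.loc[current],
                                        phenotype_by_sample))
                pool_id += 1
                current = []
                max_end = -1
            current.append(idx)
            max_end = max(max_end, int(row["end_bp"]))
        if current:
            pools.append(_make_pool(pool_id, int(c), grp.loc[current],
                                    phenotype_by_sample))
            pool_id += 1
    return pools


def _make_pool(pool_id: int, chrom: int, members: pd.DataFrame,
               phenotype_by_sample: dict | None) -> ConsensusPool:
    start = int(members["start_bp"].max())
    end = int(members["end_bp"].min())
    pool = ConsensusPool(pool_id=pool_id, chrom=chrom,
                         members=members.reset_index(drop=True))
    if start > end:
        pool.flag = "non_consensus"
    else:
        pool.consensus_start_bp = start
        pool.consensus_end_bp = end
    if phenotype_by_sample is not None:
        samp = members["sample_id"].drop_duplicates()
        ph = samp.map(phenotype_by_sample)
        pool.n_cases = int((ph == 1).sum())
        pool.n_controls = int((ph == 0).sum())
    return pool


def consensus_region(pool: ConsensusPool, variant_map: pd.DataFrame
                     ) -> tuple[int, int, int, float]:
    """(start_bp, end_bp, n_snp, length_kb) of a pool's consensus interval.

    ``variant_map`` needs columns ``chrom, bp``.  Raises ``ValueError`` for
    a flagged (empty-intersection) pool.
    """
    if pool.flag == "non_consensus" or pool.consensus_start_bp is None:
        raise ValueError(f"pool {pool.pool_id} has an empty consensus intersection")
    start, end = pool.consensus_start_bp, pool.consensus_end_bp
    on = variant_map[(variant_map["chrom"] == pool.chrom)
                     & (variant_map["bp"] >= start)
                     & (variant_map["bp"] <= end)]
    n_snp = int(len(on))
    pool.consensus_n_snp = n_snp
    return start, end, n_snp, (end - start + 1) / 1000.0


def filter_recurrent(pools: list[ConsensusPool], min_samples: int = 6,
                     min_kb: float = 500.0) -> list[ConsensusPool]:
    """Keep pools with >= ``min_samples`` distinct carriers and a consensus
    of >= ``min_kb`` (non-consensus pools are excluded)."""
    out = []
    for pool in pools:
        if pool.flag == "non_consensus":
            continue
        if pool.n_distinct_samples < min_samples:
            continue
        if pool.consensus_length_kb < min_kb:
            continue
        out.append(pool)
    return out


def common_roh_groups(segments: pd.DataFrame, min_snp: int = 75) -> pd.DataFrame:
    """Group segments with exactly identical (chrom, start, end) coordinates.

    Only segments with ``n_snp >= min_snp`` qualify.  Returns one row per
    group: ``chrom, start_bp, end_bp, n_snp, size`` (size = member count);
    groups of size 1 are included so callers can count the multi-member ones.
    """
    ok = segments[segments["n_snp"] >= min_snp]
    if len(ok) == 0:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "n_snp", "size"])
    grp = (ok.groupby(["chrom", "start_bp", "end_bp"], sort=True)
             .agg(n_snp=("n_snp", "max"), size=("sample_id", "nunique"))
             .reset_index())
    return grp


def carrier_association(n_case_carriers: int, n_control_carriers: int,
                        n_cases_total: int, n_controls_total: int) -> TestResult:
    """Uncorrected 2x2 chi-square of ROH carrier status vs case status."""
    if n_case_carriers > n_cases_total or n_control_carriers > n_controls_total:
        raise ValueError("carrier counts cannot exceed stratum totals")
    tab = ContingencyTable2x2(
        n_case_carriers, n_cases_total - n_case_carriers,
        n_control_carriers, n_controls_total - n_control_carriers,
    )
    a, b, c, d = tab
    if min(a + b, c + d, a + c, b + d) == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          flag="untestable")
    return chi2_2x2(tab)


def homozygosity_proportion_test(pool: ConsensusPool, dataset: GenotypeDataset
                                 ) -> TestResult:
    """One-tailed t-test of per-SNP homozygote proportions, cases > controls.

    For every SNP inside the pool's consensus region the homozygote
    proportion is computed among all cases and among all controls
    (non-missing calls); the two per-SNP proportion vectors are compared
    with an unpaired one-tailed Student's t-test (H1: cases higher).
    """
    start, end, n_snp, _ = consensus_region(pool, dataset.variants)
    if n_snp < 2:
        raise ValueError("consensus region must contain at least 2 SNPs")
    sel = ((dataset.variants["chrom"] == pool.chrom)
           & (dataset.variants["bp"] >= start)
           & (dataset.variants["bp"] <= end)).to_numpy()
    cases, controls = dataset.case_control_masks()
    props = []
    for mask in (cases, controls):
        sub = dataset.calls[np.ix_(mask, sel)]
        hom = ((sub == 0) | (sub == 2)).sum(axis=0)
        nonmiss = (sub != MISSING).sum(axis=0)
        props.append(np.where(nonmiss > 0, hom / np.maximum(nonmiss, 1), np.nan))
    case_p, ctrl_p = props
    ok = ~np.isnan(case_p) & ~np.isnan(ctrl_p)
    return two_sample_t(case_p[ok], ctrl_p[ok], tails=1)
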