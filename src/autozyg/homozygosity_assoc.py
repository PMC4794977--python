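"""Genome-wide SNP-by-SNP homozygosity association scan.

For every SNP the two homozygote classes are pooled (AA/BB vs AB) and the
case/control x hom/het 2x2 table is tested with an uncorrected chi-square;
a one-sided Fisher's exact test (direction: greater homozygosity in cases)
supplies the odds ratio, and Benjamini-Hochberg q-values control the FDR
over all testable SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from autozyg.genotype_io import MISSING, GenotypeDataset
from autozyg.stats_core import (
    ContingencyTable2x2,
    bh_fdr,
    chi2_2x2,
    fisher_exact_one_sided,
    odds_ratio_woolf,
)

__all__ = ["snp_homozygosity_scan"]


def snp_homozygosity_scan(dataset: GenotypeDataset,
                          m_total: int | None = None) -> pd.DataFrame:
    """Per-SNP homozygosity vs case-status scan.

    Missing genotypes reduce the individual SNP's table only.  SNPs whose
    2x2 table has a zero marginal are flagged ``untestable`` and excluded
    from the FDR ranking.  ``m_total`` defaults to the number of SNPs
    scanned and may be larger (e.g. the full array size when scanning a
    subset).
    """
    cases, controls = dataset.case_control_masks()
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("need at least one case and one control")
    calls = dataset.calls
    hom = (calls == 0) | (calls == 2)
    het = calls == 1

    counts = pd.DataFrame(
        {
            "id": dataset.variants["id"],
            "chrom": dataset.variants["chrom"],
            "bp": dataset.variants["bp"],
            "cases_hom": hom[cases].sum(axis=0),
            "cases_het": het[cases].sum(axis=0),
            "controls_hom": hom[controls].sum(axis=0),
            "controls_het": het[controls].sum(axis=0),
        }
    )

    chi2 = np.full(len(counts), np.nan)
    p = np.full(len(counts), np.nan)
    or_fisher = np.full(len(counts), np.nan)
    p_fisher = np.full(len(counts), np.nan)
    ci_lo = np.full(len(counts), np.nan)
    ci_hi = np.full(len(counts), np.nan)
    testable = np.zeros(len(counts), dtype=bool)

    it = counts[["cases_hom", "cases_het", "controls_hom", "controls_het"]].to_numpy()
    for i, (a, b, c, d) in enumerate(it):
        tab = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        res = chi2_2x2(tab)
        chi2[i], p[i] = res.statistic, res.p_value
        fis = fisher_exact_one_sided(tab, direction="greater")
        or_fisher[i], p_fisher[i] = fis.estimate, fis.p_value
        wo = odds_ratio_woolf(tab)
        ci_lo[i], ci_hi[i] = wo.ci_low, wo.ci_high
        testable[i] = True

    q = np.full(len(counts), np.nan)
    if testable.any():
        m = int(testable.sum()) if m_total is None else int(m_total)
        q[testable] = bh_fdr(p[testable], m_total=m)

    counts["chi2"] = chi2
    counts["p"] = p
    counts["q"] = q
    counts["p_fisher"] = p_fisher
    counts["or_fisher"] = or_fisher
    counts["or_ci_low"] = ci_lo
    counts["or_ci_high"] = ci_hi
    counts["untestable"] = ~testable
    return counts
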