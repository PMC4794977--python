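"""Per-individual ROH burden, case-control burden tests and F_ROH.

F_ROH is the ROH-based genomic inbreeding measure: the summed
length of an individual's ROHs above a criterion length (default 1000 kb)
divided by the SNP-mappable autosomal genome length L_AUTO.  The default
L_AUTO (2,677,608,286 bp) is the standard array-era estimate of the
centromere-excluded autosomal genome; override it for synthetic maps.
ROHs are additionally split at 1500 kb into a short and a long class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from autozyg.stats_core import (
    ContingencyTable2x2,
    TestResult,
    chi2_2x2,
    odds_ratio_woolf,
    two_sample_t,
)

__all__ = [
    "L_AUTO_BP",
    "individual_burden",
    "f_roh",
    "burden_t_tests",
    "burden_category_or",
]

#: SNP-mappable autosomal genome length in bp (centromeres excluded)
L_AUTO_BP: int = 2_677_608_286

#: boundary between the short and long ROH classes, kb
SHORT_LONG_SPLIT_KB: float = 1500.0


def f_roh(lengths_kb, l_auto_bp: int = L_AUTO_BP, min_kb: float = 1000.0
          ) -> tuple[float, float, float]:
    """(overall, short-class, long-class) F_ROH from segment lengths in kb.

    Only segments >= ``min_kb`` count; the short class is
    ``[min_kb, 1500)`` kb and the long class ``>= 1500`` kb, so
    overall = short + long.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    lengths = np.asarray(list(lengths_kb), dtype=float)
    lengths = lengths[lengths >= min_kb]
    short = lengths[lengths < SHORT_LONG_SPLIT_KB].sum() * 1000.0 / l_auto_bp
    long_ = lengths[lengths >= SHORT_LONG_SPLIT_KB].sum() * 1000.0 / l_auto_bp
    return short + long_, short, long_


def individual_burden(segments: pd.DataFrame, sample_ids=None,
                      min_kb: float = 1000.0,
                      l_auto_bp: int = L_AUTO_BP) -> pd.DataFrame:
    """Per-individual ROH burden summary.

    ``segments`` is a :func:`autozyg.roh_detect.scan_roh` table.  Only
    segments >= ``min_kb`` are counted.  ``sample_ids`` (optional) lists the
    full cohort so that individuals without segments appear with zeros.
    Returns columns ``sample_id, n_roh, total_kb, mean_kb, f_roh,
    f_roh_short, f_roh_long``.
    """
    if min_kb < 0:
        raise ValueError("min_kb must be non-negative")
    if sample_ids is None:
        sample_ids = segments["sample_id"].unique()
    rows = []
    grouped = dict(tuple(segments.groupby("sample_id"))) if len(segments) else {}
    for sid in sample_ids:
        grp = grouped.get(sid)
        lengths = grp["length_kb"].to_numpy() if grp is not None else np.array([])
        lengths = lengths[lengths >= min_kb]
        n = int(lengths.size)
        total = float(lengths.sum())
        overall, short, long_ = f_roh(lengths, l_auto_bp=l_auto_bp, min_kb=min_kb)
        rows.append((sid, n, total, total / n if n else 0.0,
                     overall, short, long_))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "n_roh", "total_kb", "mean_kb",
                 "f_roh", "f_roh_short", "f_roh_long"],
    )


def burden_t_tests(burden: pd.DataFrame, phenotype, tails: int = 2
                   ) -> dict[str, TestResult]:
    """Student's t-tests of ROH count, total length and mean length, cases
    vs controls.  ``phenotype`` aligns with the rows of ``burden``
    (1 = case, 0 = control)."""
    ph = np.asarray(phenotype)
    cases = ph == 1
    controls = ph == 0
    if cases.sum() < 2 or controls.sum() < 2:
        raise ValueError("each stratum needs at least 2 individuals")
    out = {}
    for metric in ("n_roh", "total_kb", "mean_kb"):
        vals = burden[metric].to_numpy(dtype=float)
        out[metric] = two_sample_t(vals[cases], vals[controls], tails=tails)
    return out


def _categories(values: np.ndarray, cutoffs) -> tuple[np.ndarray, list[str]]:
    """Assign right-closed categories; ties go to the lower category."""
    if isinstance(cutoffs, str):
        if cutoffs not in ("quartiles", "q4"):
            raise ValueError("cutoffs must be increasing numbers or 'quartiles'")
        cuts = np.quantile(values, [0.25, 0.5, 0.75])
        cuts = np.unique(cuts)
    else:
        cuts = np.asarray(list(cutoffs), dtype=float)
        if cuts.size == 0 or np.any(np.diff(cuts) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
    cat = np.searchsorted(cuts, values, side="left")  # value <= cut -> lower
    labels = [f"<={cuts[0]:g}"]
    labels += [f"({cuts[i]:g}, {cuts[i + 1]:g}]" for i in range(cuts.size - 1)]
    labels += [f">{cuts[-1]:g}"]
    return cat, labels


def burden_category_or(burden: pd.DataFrame, phenotype, metric: str = "n_roh",
                       cutoffs="quartiles", level: float = 0.95) -> pd.DataFrame:
    """Categorical odds ratios of ROH burden vs the lowest-burden category.

    ``metric`` is ``'n_roh'`` or ``'total_mb'`` (total length in Mb).
    ``cutoffs`` is a strictly increasing list, or ``'quartiles'`` for
    empirical quartiles of the pooled case+control distribution
    (right-closed intervals, ties to the lower category).  Each category is
    compared against the reference with a Woolf-CI odds ratio and an
    uncorrected chi-square p; empty categories are flagged, not dropped.
    """
    if metric == "n_roh":
        values = burden["n_roh"].to_numpy(dtype=float)
    elif metric == "total_mb":
        values = burden["total_kb"].to_numpy(dtype=float) / 1000.0
    else:
        raise ValueError("metric must be 'n_roh' or 'total_mb'")
    ph = np.asarray(phenotype)
    cat, labels = _categories(values, cutoffs)

    n_cat = len(labels)
    case_counts = np.array([(cat == k)[ph == 1].sum() for k in range(n_cat)])
    ctrl_counts = np.array([(cat == k)[ph == 0].sum() for k in range(n_cat)])

    rows = []
    ref = (int(case_counts[0]), int(ctrl_counts[0]))
    for k in range(n_cat):
        a, c = int(case_counts[k]), int(ctrl_counts[k])
        row = {"category": labels[k], "cases": a, "controls": c,
               "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "p": np.nan, "flag": None}
        if k == 0:
            row["odds_ratio"] = 1.0
            row["flag"] = "reference"
        elif a + c == 0:
            row["flag"] = "empty"
        else:
            # (cases_k, cases_ref; controls_k, controls_ref):
            # OR = cases_k * controls_ref / (controls_k * cases_ref)
            tab = ContingencyTable2x2(a, ref[0], c, ref[1])
            wo = odds_ratio_woolf(tab, level=level)
            row["odds_ratio"] = wo.estimate
            row["ci_low"], row["ci_high"] = wo.ci_low, wo.ci_high
            try:
                row["p"] = chi2_2x2(tab).p_value
            except ValueError:
                row["flag"] = "untestable"
        rows.append(row)
    return pd.DataFrame(rows)
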