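"""SNP-based genomic inbreeding coefficients and their case-control tests.

Three per-individual estimators, all averaging a per-SNP term over that
individual's non-missing SNPs (x = allele-b count, p = sample frequency,
q = 1 - p):

* F1 -- variance of additive genotypes:  mean[(x - 2p)^2 / (2pq)] - 1
* F2 -- excess homozygosity:             mean[1 - x(2 - x) / (2pq)]
* F3 -- correlation of uniting gametes:  mean[(x^2 - (1+2p)x + 2p^2) / (2pq)]

All three are unbiased for the inbreeding coefficient F under
Hardy-Weinberg genotype frequencies with inbreeding
(p^2 + pqF, 2pq(1-F), q^2 + pqF).  F3's per-individual value equals the
corresponding GRM diagonal minus one (same formula, same frequencies).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from autozyg.genotype_io import MISSING, GenotypeDataset
from autozyg.stats_core import TestResult, two_sample_t

__all__ = [
    "allele_frequencies",
    "inbreeding_coefficients",
    "per_chromosome_f",
    "inbreeding_glm",
]


def allele_frequencies(dataset: GenotypeDataset) -> np.ndarray:
    """Allele-b frequency per SNP from all non-missing calls (cases + controls)."""
    calls = dataset.calls
    nonmiss = (calls != MISSING).sum(axis=0)
    counts = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(nonmiss > 0, counts / (2.0 * nonmiss), np.nan)


def _estimator_terms(calls: np.ndarray, p: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-call F1/F2/F3 terms and the usable-call mask (NaN elsewhere)."""
    q = 1.0 - p
    two_pq = 2.0 * p * q
    usable = (calls != MISSING) & (two_pq > 0)
    x = np.where(usable, calls, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (x - 2 * p) ** 2 / two_pq - 1.0
        t2 = 1.0 - x * (2.0 - x) / two_pq
        t3 = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / two_pq
    return t1, t2, t3, usable


def inbreeding_coefficients(dataset: GenotypeDataset, freq: np.ndarray | None = None,
                            mode: str = "mean_of_ratios") -> pd.DataFrame:
    """Per-individual F1, F2, F3.

    SNPs with p in {0, 1} are skipped.  ``freq`` overrides the sample
    allele frequencies (e.g. known generating frequencies).  ``mode``
    selects averaging of per-SNP ratios (default) or the ratio-of-sums
    variant (sums of numerators over the sum of 2pq).  Individuals with no
    usable SNPs get NaN and ``missing_profile = True``.
    """
    if mode not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError("mode must be 'mean_of_ratios' or 'ratio_of_sums'")
    p = allele_frequencies(dataset) if freq is None else np.asarray(freq, float)
    t1, t2, t3, usable = _estimator_terms(dataset.calls, p)
    m_used = usable.sum(axis=1)
    if mode == "mean_of_ratios":
        denom = np.maximum(m_used, 1)
        f1 = np.where(usable, t1, 0).sum(axis=1) / denom
        f2 = np.where(usable, t2, 0).sum(axis=1) / denom
        f3 = np.where(usable, t3, 0).sum(axis=1) / denom
    else:
        q = 1.0 - p
        two_pq = np.where(2 * p * q > 0, 2 * p * q, np.nan)
        w = np.where(usable, two_pq, 0)
        denom = np.maximum(w.sum(axis=1), 1e-300)
        f1 = (np.where(usable, t1, 0) * w).sum(axis=1) / denom
        f2 = (np.where(usable, t2, 0) * w).sum(axis=1) / denom
        f3 = (np.where(usable, t3, 0) * w).sum(axis=1) / denom
    out = pd.DataFrame(
        {
            "sample_id": dataset.samples["id"],
            "f1": np.where(m_used > 0, f1, np.nan),
            "f2": np.where(m_used > 0, f2, np.nan),
            "f3": np.where(m_used > 0, f3, np.nan),
            "n_snp_used": m_used,
            "missing_profile": m_used == 0,
        }
    )
    return out


def per_chromosome_f(dataset: GenotypeDataset, freq: np.ndarray | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome F1/F2/F3 profiles and case-control t-tests.

    Returns ``(profiles, tests)``: ``profiles`` is long-format
    (sample_id, chrom, f1, f2, f3, n_snp_used); ``tests`` has one row per
    chromosome and estimator with the Student's t and two-sided p
    (requires phenotypes; chromosomes with < 2 usable SNPs are omitted
    with a warning).  The frequencies are shared with the genome-wide
    estimator, so the genome-wide value equals the SNP-count-weighted mean
    of the per-chromosome values.
    """
    p = allele_frequencies(dataset) if freq is None else np.asarray(freq, float)
    chrom_arr = dataset.variants["chrom"].to_numpy()
    cases, controls = dataset.case_control_masks()
    profiles = []
    tests = []
    for c in np.unique(chrom_arr):
        sel = chrom_arr == c
        q = 1 - p[sel]
        usable_snps = int(((p[sel] > 0) & (q > 0)).sum())
        if usable_snps < 2:
            warnings.warn(f"chromosome {c}: fewer than 2 usable SNPs; omitted",
                          stacklevel=2)
            continue
        sub = GenotypeDataset(dataset.variants.loc[sel].reset_index(drop=True),
                              dataset.samples, dataset.calls[:, sel])
        prof = inbreeding_coefficients(sub, freq=p[sel])
        prof.insert(1, "chrom", int(c))
        profiles.append(prof)
        if cases.sum() >= 2 and controls.sum() >= 2:
            for est in ("f1", "f2", "f3"):
                vals = prof[est].to_numpy()
                res = two_sample_t(vals[cases], vals[controls], tails=2)
                tests.append({"chrom": int(c), "estimator": est,
                              "t": res.statistic, "p": res.p_value,
                              "mean_cases": float(np.nanmean(vals[cases])),
                              "mean_controls": float(np.nanmean(vals[controls]))})
    profiles_df = pd.concat(profiles, ignore_index=True) if profiles else pd.DataFrame()
    return profiles_df, pd.DataFrame(tests)


def inbreeding_glm(f_values, phenotype, covariates: pd.DataFrame | None = None
                   ) -> pd.DataFrame:
    """Logistic regression of case status on an inbreeding coefficient.

    ``f_values`` is the per-individual coefficient (F1, F2, F3 or F_ROH);
    ``covariates`` optionally adds columns such as sex, principal
    components and per-sample missingness.  Returns the fitted coefficient
    table (term, coef, se, z, p); perfect separation or rank deficiency is
    flagged by raising ``ValueError``.
    """
    f = np.asarray(f_values, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    X = pd.DataFrame({"F": f})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # statsmodels signals separation variously
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    out = pd.DataFrame({
        "term": X.columns,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "z": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return out
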