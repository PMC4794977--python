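"""Synthetic case-control genotype cohorts with LD, autozygosity and risk loci.

The generator emulates the structure of a GWAS-quality case-control SNP
panel at desk scale:

* biallelic autosomal SNPs on a configurable number of chromosomes, allele
  frequencies drawn from ``maf_range`` (defaults chosen so mean
  heterozygosity is ~35%, matching a typical filtered array);
* LD blocks: each block of ``ld_block_snps`` consecutive SNPs carries a
  small founder-haplotype pool, and every individual draws two haplotype
  indices per block i.i.d. with replacement, giving nonzero r^2 within
  blocks and exact Binomial(2, f) single-SNP genotype margins;
* inbreeding: an individual with coefficient F receives contiguous
  autozygous tracts (Poisson count, exponential lengths) covering an
  expected fraction F of the genome; inside a tract one haplotype is copied
  over both, so every SNP there is homozygous and the per-SNP autozygosity
  probability is F;
* planted ROH tracts at fixed coordinates with per-phenotype carrier
  fractions, and recessive risk loci whose minor-allele homozygotes get a
  log-odds increment on disease risk, with case-control ascertainment.

All randomness flows through one ``numpy`` Generator keyed by ``seed``; the
same seed reproduces the same cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from autozyg.genotype_io import MISSING, PHENO_MISSING, GenotypeDataset

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "plant_autozygosity",
    "assign_phenotypes",
    "simulate_case_control",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``inbreeding_f`` may be a scalar (every individual), a sequence of
    per-individual values, or a ``("exponential", mean)`` tuple sampling
    each individual's F.  ``planted_roh`` entries are
    ``(chrom, start_bp, length_kb, carrier_frac_cases, carrier_frac_controls)``.
    ``recessive_loci`` entries are ``(variant_index, homozygote_odds_ratio)``.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_snps: int = 20_000
    n_chroms: int = 4
    snp_spacing_bp: int = 3_000
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_block_snps: int = 20
    ld_copy_prob: float = 0.7
    haplotype_pool_size: int = 20
    inbreeding_f: object = 0.0
    mean_tract_kb: float = 2_500.0
    planted_roh: list = field(default_factory=list)
    recessive_loci: list = field(default_factory=list)
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.002
    max_draw_factor: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_cases, self.n_controls, self.n_snps, self.n_chroms,
               self.ld_block_snps, self.haplotype_pool_size) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------

@dataclass
class _Panel:
    """Fixed marker map plus per-block founder haplotype pools."""

    variants: pd.DataFrame
    blocks: list[slice]
    pools: list[np.ndarray]          # (H, block_len) 0/1 alleles per block
    pool_freq: np.ndarray            # realised allele-b frequency per SNP


def _variant_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random marker map: chromosomes of equal SNP count, exponential gaps."""
    per_chrom = config.n_snps // config.n_chroms
    counts = [per_chrom] * config.n_chroms
    counts[-1] += config.n_snps - per_chrom * config.n_chroms
    rows = []
    for c, cnt in enumerate(counts, start=1):
        gaps = rng.exponential(config.snp_spacing_bp, size=cnt).astype(np.int64) + 1
        bp = np.cumsum(gaps) + 10_000
        rows.append(pd.DataFrame({"chrom": c, "bp": bp}))
    variants = pd.concat(rows, ignore_index=True)
    variants["id"] = [f"snp{i + 1}" for i in range(len(variants))]
    variants["allele_a"] = "A"
    variants["allele_b"] = "B"
    return variants[["id", "chrom", "bp", "allele_a", "allele_b"]]


def _block_slices(variants: pd.DataFrame, block_snps: int) -> list[slice]:
    """Consecutive-SNP blocks, never spanning a chromosome boundary."""
    slices = []
    for _, grp in variants.groupby("chrom", sort=True):
        lo, hi = int(grp.index[0]), int(grp.index[-1]) + 1
        for s in range(lo, hi, block_snps):
            slices.append(slice(s, min(s + block_snps, hi)))
    return slices


def _build_panel(config: SimConfig, rng: np.random.Generator) -> _Panel:
    variants = _variant_map(config, rng)
    m = len(variants)
    H = config.haplotype_pool_size
    blocks = _block_slices(variants, config.ld_block_snps)
    # one nominal frequency per LD block; pool allele counts pinned at
    # round(H*p) so the realised single-SNP frequency equals the pool
    # frequency exactly
    pool_counts = np.empty(m, dtype=int)
    pools = []
    for blk in blocks:
        L = blk.stop - blk.start
        maf = rng.uniform(*config.maf_range)
        k = int(np.clip(np.rint(maf * H), 1, H - 1))
        pool_counts[blk] = k
        pool = np.zeros((H, L), dtype=np.int8)
        carriers = rng.choice(H, size=k, replace=False)
        for j in range(L):
            # adjacent SNPs share their carrier haplotypes with probability
            # ld_copy_prob (perfect within-run LD), else redraw fresh
            if j > 0 and rng.random() >= config.ld_copy_prob:
                carriers = rng.choice(H, size=k, replace=False)
            pool[carriers, j] = 1
        pools.append(pool)
    return _Panel(variants, blocks, pools, pool_counts / H)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

def _resolve_f(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    spec = config.inbreeding_f
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "exponential":
        f = np.clip(rng.exponential(float(spec[1]), size=n), 0.0, 0.99)
    elif np.isscalar(spec):
        f = np.full(n, float(spec))
    else:
        f = np.asarray(spec, dtype=float)
        if f.shape != (n,):
            raise ValueError(f"inbreeding_f must be scalar or length-{n}")
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("inbreeding F must satisfy 0 <= F < 1")
    return f


def _autozygous_mask(config: SimConfig, variants: pd.DataFrame,
                     f: np.ndarray, rng: np.random.Generator
                     ) -> tuple[np.ndarray, list[list[tuple[int, int, int]]]]:
    """Per-individual autozygosity mask from a stationary tract process.

    Each chromosome is tiled by an alternating renewal process with
    exponential sojourns: autozygous stretches of mean ``mean_tract_kb`` and
    non-autozygous stretches of mean ``mean_tract_kb * (1-F)/F``, started in
    the stationary state.  The marginal probability that any position is
    autozygous is therefore exactly F.  Returns the mask and the realised
    per-individual tract intervals (chrom, start_bp, end_bp).
    """
    n = f.size
    m = len(variants)
    mask = np.zeros((n, m), dtype=bool)
    intervals: list[list[tuple[int, int, int]]] = [[] for _ in range(n)]
    mean_auto = config.mean_tract_kb * 1_000.0
    chrom_arr = variants["chrom"].to_numpy()
    bp_arr = variants["bp"].to_numpy()
    chroms = [(c, np.nonzero(chrom_arr == c)[0]) for c in np.unique(chrom_arr)]
    for i in np.nonzero(f > 0)[0]:
        fi = f[i]
        mean_non = mean_auto * (1.0 - fi) / fi
        for c, sel in chroms:
            bp = bp_arr[sel]
            lo, hi = bp[0], bp[-1]
            pos = float(lo)
            state = rng.random() < fi
            while pos <= hi:
                length = rng.exponential(mean_auto if state else mean_non)
                if state:
                    cover = (bp >= pos) & (bp < pos + length)
                    if cover.any():
                        mask[i, sel] |= cover
                        intervals[i].append(
                            (int(c), int(bp[cover][0]), int(bp[cover][-1])))
                pos += length
                state = not state
    return mask, intervals


def _draw_individuals(panel: _Panel, config: SimConfig, n: int,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, dict]:
    """Draw genotypes for ``n`` individuals from a fixed founder panel."""
    f = _resolve_f(config, n, rng)
    auto_mask, auto_intervals = _autozygous_mask(config, panel.variants, f, rng)
    m = len(panel.variants)
    H = config.haplotype_pool_size
    calls = np.empty((n, m), dtype=np.int8)
    for blk, pool in zip(panel.blocks, panel.pools):
        idx1 = rng.integers(0, H, size=n)
        idx2 = rng.integers(0, H, size=n)
        # autozygosity applies at block granularity, keyed on the block's
        # first SNP: its stationary marginal is exactly F, so block-snapping
        # does not bias the covered fraction
        blk_auto = auto_mask[:, blk.start]
        idx2 = np.where(blk_auto, idx1, idx2)
        auto_mask[:, blk] = blk_auto[:, None]
        calls[:, blk] = pool[idx1] + pool[idx2]
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        calls[miss] = MISSING
    truth = {
        "f": f,
        "autozygous_intervals": auto_intervals,
        "autozygous_fraction": auto_mask.mean(axis=1),
    }
    return calls, truth


def _sample_frame(n: int, rng: np.random.Generator,
                  phenotype=PHENO_MISSING) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"S{i + 1:05d}" for i in range(n)],
            "sex": rng.integers(1, 3, size=n),
            "phenotype": phenotype,
        }
    )


def simulate_genotypes(config: SimConfig, n_samples: int | None = None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeDataset, dict]:
    """Generate genotypes for ``n_samples`` individuals (phenotypes missing).

    Returns the dataset and a truth record with keys ``maf`` (realised pool
    frequencies), ``f``, ``autozygous_intervals`` and
    ``autozygous_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples if n_samples is None else int(n_samples)
    panel = _build_panel(config, rng)
    calls, truth = _draw_individuals(panel, config, n, rng)
    dataset = GenotypeDataset(panel.variants, _sample_frame(n, rng), calls)
    truth["maf"] = panel.pool_freq
    return dataset, truth


def plant_autozygosity(dataset: GenotypeDataset, spec: Sequence[tuple],
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeDataset, list[dict]]:
    """Force zero-heterozygote tracts at fixed coordinates.

    ``spec`` entries are ``(sample_index, chrom, start_bp, end_bp)``.  Within
    each tract every call of that individual is made homozygous by resolving
    heterozygous (and missing) calls to one allele at random with
    frequency-weighted probability; overlapping tracts in one individual are
    merged with a warning.  Returns the modified dataset and the realised
    truth intervals.
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(0)
    ds = dataset.copy()
    chrom = ds.variants["chrom"].to_numpy()
    bp = ds.variants["bp"].to_numpy()
    nonmiss = np.maximum((ds.calls != MISSING).sum(axis=0), 1)
    freq = np.where(ds.calls == MISSING, 0, ds.calls).sum(axis=0) / (2.0 * nonmiss)

    seen: dict[int, list[tuple[int, int, int]]] = {}
    truth = []
    for samp, c, start, end in spec:
        cover = (chrom == int(c)) & (bp >= start) & (bp <= end)
        idx = np.nonzero(cover)[0]
        if idx.size == 0:
            raise ValueError(f"planted tract chrom {c}:{start}-{end} covers no SNPs")
        prior = seen.setdefault(int(samp), [])
        if any(c == pc and start <= pe and end >= ps for pc, ps, pe in prior):
            warnings.warn(f"overlapping planted tracts for sample {samp}; merging",
                          stacklevel=2)
        prior.append((int(c), int(start), int(end)))
        g = ds.calls[samp, idx].astype(np.int8)
        unresolved = (g == 1) | (g == MISSING)
        draw = rng.random(int(unresolved.sum())) < freq[idx][unresolved]
        g[unresolved] = np.where(draw, 2, 0).astype(np.int8)
        ds.calls[samp, idx] = g
        truth.append({"sample_index": int(samp), "chrom": int(c),
                      "start_bp": int(bp[idx[0]]), "end_bp": int(bp[idx[-1]]),
                      "n_snp": int(idx.size)})
    return ds, truth


def assign_phenotypes(dataset: GenotypeDataset, config: SimConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw 0/1 phenotypes under a logistic recessive-risk model.

    ``P(case) = expit(logit(baseline_prevalence) + sum_l ln(OR_l) *
    1[x_l == 2])``: only allele-b homozygotes at the configured recessive
    loci shift risk.  Returns the phenotype vector without mutating the
    dataset.
    """
    from scipy.special import expit, logit

    if rng is None:
        rng = np.random.default_rng(config.seed)
    eta = np.full(dataset.n_samples, logit(config.baseline_prevalence))
    for var_idx, or_hom in config.recessive_loci:
        if not 0 <= var_idx < dataset.n_variants:
            raise ValueError(f"recessive locus index {var_idx} out of range")
        eta[dataset.calls[:, var_idx] == 2] += np.log(or_hom)
    return (rng.random(dataset.n_samples) < expit(eta)).astype(int)


def simulate_case_control(config: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[GenotypeDataset, dict]:
    """Full cohort: genotypes, ascertained phenotypes, planted ROH tracts.

    One founder panel is built, then individuals are drawn in batches and
    sampled into the case and control strata until the configured counts are
    reached (case-control ascertainment).  Raises if the draw budget
    (``max_draw_factor * cohort size``) is exhausted first.  The returned
    samples are ordered cases first.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = _build_panel(config, rng)
    need = {1: config.n_cases, 0: config.n_controls}
    kept_calls, kept_pheno, kept_f, kept_auto = [], [], [], []
    drawn = 0
    budget = config.max_draw_factor * config.n_samples
    batch = max(256, config.n_samples)
    while need[1] > 0 or need[0] > 0:
        if drawn >= budget:
            raise RuntimeError(
                f"could not ascertain {config.n_cases}/{config.n_controls} "
                f"cases/controls within {budget} draws")
        calls, truth = _draw_individuals(panel, config, batch, rng)
        ds = GenotypeDataset(panel.variants, _sample_frame(batch, rng), calls)
        pheno = assign_phenotypes(ds, config, rng=rng)
        drawn += batch
        for stratum in (1, 0):
            take = np.nonzero(pheno == stratum)[0][: need[stratum]]
            kept_calls.append(calls[take])
            kept_pheno.append(np.full(take.size, stratum))
            kept_f.append(truth["f"][take])
            kept_auto.extend(truth["autozygous_intervals"][i] for i in take)
            need[stratum] -= take.size

    calls = np.concatenate(kept_calls, axis=0)
    pheno = np.concatenate(kept_pheno)
    order = np.argsort(-pheno, kind="stable")  # cases first
    calls, pheno = calls[order], pheno[order]
    f = np.concatenate(kept_f)[order]
    auto = [kept_auto[i] for i in order]

    dataset = GenotypeDataset(panel.variants,
                              _sample_frame(len(pheno), rng, phenotype=pheno),
                              calls)

    planted_truth = []
    if config.planted_roh:
        vmap = dataset.variants
        case_idx = np.nonzero(pheno == 1)[0]
        ctrl_idx = np.nonzero(pheno == 0)[0]
        spec = []
        for c, start_bp, length_kb, frac_cases, frac_controls in config.planted_roh:
            end_bp = int(start_bp + length_kb * 1000 - 1)
            on_chrom = vmap.loc[vmap["chrom"] == c, "bp"]
            if on_chrom.empty or end_bp > int(on_chrom.max()):
                raise ValueError(
                    f"planted ROH chrom {c}:{start_bp}+{length_kb}kb exceeds map")
            for idx_pool, frac in ((case_idx, frac_cases), (ctrl_idx, frac_controls)):
                k = int(round(frac * idx_pool.size))
                carriers = rng.choice(idx_pool, size=k, replace=False)
                spec.extend((int(s), c, start_bp, end_bp) for s in carriers)
        dataset, planted_truth = plant_autozygosity(dataset, spec, rng=rng)

    truth = {
        "f": f,
        "autozygous_intervals": auto,
        "planted": planted_truth,
        "risk_loci": list(config.recessive_loci),
        "maf": panel.pool_freq,
        "n_drawn": drawn,
    }
    return dataset, truth
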