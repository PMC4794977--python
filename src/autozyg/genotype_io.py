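"""Genotype container and PLINK binary (.bed/.bim/.fam) input/output.

Conventions
-----------
* Genotype calls count copies of ``allele_b`` (the .bim A2 allele); the .bim
  A1 allele is ``allele_a``.  Missing calls are stored as :data:`MISSING`.
* Coordinates are 1-based; genomic intervals are inclusive at both ends.
* Only autosomes 1-22 are retained; variants on other chromosome codes are
  dropped with a warning.
* Phenotype coding in memory: 0 = control, 1 = case, -9 = missing.
  Sex coding follows PLINK: 1 = male, 2 = female, 0 = unknown.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING: int = -9

#: sentinel for a missing phenotype
PHENO_MISSING: int = -9

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK v1.00 SNP-major


class PlinkFormatError(ValueError):
    """Raised when a PLINK binary fileset is malformed."""


@dataclass
class GenotypeDataset:
    """Samples x variants biallelic genotype matrix with maps.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``id, chrom, bp, allele_a, allele_b``; within each chromosome
        rows are sorted by ascending ``bp``.
    samples : pandas.DataFrame
        Columns ``id, sex, phenotype`` (phenotype 0=control, 1=case,
        -9=missing).
    calls : numpy.ndarray
        ``int8`` matrix of shape (n_samples, n_variants) holding counts of
        ``allele_b`` in {0, 1, 2} or :data:`MISSING`.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        v = self.variants
        if not v["chrom"].between(1, 22).all():
            raise ValueError("variant chromosomes must be autosomes 1-22")
        if (v["bp"] < 1).any():
            raise ValueError("variant bp positions must be >= 1")
        for _, grp in v.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing:
                raise ValueError("variants must be sorted by bp within chromosome")
        if self.samples["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes present: {bad}")

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.variants.copy(), self.samples.copy(), self.calls.copy()
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeDataset":
        """New dataset keeping variants where ``mask`` is True (samples kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            self.variants.loc[mask].reset_index(drop=True),
            self.samples.copy(),
            self.calls[:, mask].copy(),
        )

    def case_control_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (cases, controls) masks; missing phenotypes in neither."""
        ph = self.samples["phenotype"].to_numpy()
        return ph == 1, ph == 0


# ---------------------------------------------------------------------------
# PLINK binary codec
# ---------------------------------------------------------------------------

# 2-bit PLINK code -> allele_b count: 00 hom A1 (=a/a, x=0), 01 missing,
# 10 het, 11 hom A2 (=b/b, x=2)
_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_ENCODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


def read_plink_binary(bed_path, bim_path=None, fam_path=None) -> GenotypeDataset:
    """Read a PLINK v1 binary fileset into a :class:`GenotypeDataset`.

    ``bim_path``/``fam_path`` default to ``bed_path`` with swapped suffixes.
    Variants on chromosomes outside 1-22 are dropped with a warning.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path is not None else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path is not None else bed_path.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "allele_a", "allele_b"],
        dtype={"chrom": str, "id": str, "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "id", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "id": str},
    )

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not SNP-major PLINK v1)")
    n_samples, n_variants = len(fam), len(bim)
    bytes_per_variant = (n_samples + 3) // 4
    expected = 3 + bytes_per_variant * n_variants
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: size {len(raw)} != expected {expected} for "
            f"{n_samples} samples x {n_variants} variants"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3)
    data = data.reshape(n_variants, bytes_per_variant)
    # unpack 2-bit fields, sample-minor within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_variants, bytes_per_variant * 4)[:, :n_samples]
    calls = _DECODE[codes].T  # (n_samples, n_variants)

    chrom_num = pd.to_numeric(bim["chrom"], errors="coerce")
    keep = chrom_num.between(1, 22).to_numpy()
    if not keep.all():
        n_drop = int((~keep).sum())
        warnings.warn(
            f"dropping {n_drop} non-autosomal variant(s) from {bim_path.name}",
            stacklevel=2,
        )
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": chrom_num.fillna(-1).astype(int),
            "bp": bim["bp"].astype(int),
            "allele_a": bim["allele_a"],
            "allele_b": bim["allele_b"],
        }
    ).loc[keep].reset_index(drop=True)

    pheno = fam["pheno"].astype(int).map({1: 0, 2: 1}).fillna(PHENO_MISSING)
    samples = pd.DataFrame(
        {
            "id": fam["id"],
            "sex": fam["sex"].astype(int),
            "phenotype": pheno.astype(int),
        }
    )
    return GenotypeDataset(variants, samples, np.ascontiguousarray(calls[:, keep]))


def write_plink_binary(dataset: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write ``dataset`` as PLINK ``prefix``.bed/.bim/.fam; return the paths."""
    if dataset.n_samples == 0 or dataset.n_variants == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path, bim_path, fam_path = (
        prefix.with_suffix(".bed"),
        prefix.with_suffix(".bim"),
        prefix.with_suffix(".fam"),
    )

    n = dataset.n_samples
    codes = np.empty_like(dataset.calls, dtype=np.uint8)
    for geno, code in _ENCODE.items():
        codes[dataset.calls == geno] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((pad, dataset.n_variants), dtype=np.uint8)], axis=0
        )
    codes = codes.T.reshape(dataset.n_variants, -1, 4)  # variant-major
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)

    bed_path.write_bytes(_BED_MAGIC + packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": dataset.variants["chrom"],
            "id": dataset.variants["id"],
            "cm": 0,
            "bp": dataset.variants["bp"],
            "a1": dataset.variants["allele_a"],
            "a2": dataset.variants["allele_b"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    pheno = dataset.samples["phenotype"].map({0: 1, 1: 2}).fillna(-9).astype(int)
    fam = pd.DataFrame(
        {
            "fid": dataset.samples["id"],
            "id": dataset.samples["id"],
            "pat": 0,
            "mat": 0,
            "sex": dataset.samples["sex"],
            "pheno": pheno,
        }
    )
    fam.to_csv(fam_path, sep=" ", header=False, index=False)
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# summaries and filters
# ---------------------------------------------------------------------------

def per_variant_stats(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-variant allele-b frequency, het/missing rates and genotype counts.

    Frequencies use non-missing calls only; a variant with no non-missing
    calls gets ``freq_b = NaN`` and ``freq_undefined = True`` (flagged, never
    raised).
    """
    calls = dataset.calls
    n = dataset.n_samples
    miss = calls == MISSING
    het = calls == 1
    nonmiss = n - miss.sum(axis=0)
    b_count = np.where(miss, 0, calls).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_b = np.where(nonmiss > 0, b_count / (2.0 * nonmiss), np.nan)
        het_rate = np.where(nonmiss > 0, het.sum(axis=0) / nonmiss, np.nan)
    out = pd.DataFrame(
        {
            "id": dataset.variants["id"],
            "freq_b": freq_b,
            "het_rate": het_rate,
            "missing_rate": miss.sum(axis=0) / n,
            "hom_count": ((calls == 0) | (calls == 2)).sum(axis=0),
            "het_count": het.sum(axis=0),
            "missing_count": miss.sum(axis=0),
            "freq_undefined": nonmiss == 0,
        }
    )
    return out


def per_sample_stats(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-sample missing and heterozygosity rates (over all variants)."""
    if dataset.n_variants == 0:
        raise ValueError("dataset has no variants")
    calls = dataset.calls
    m = dataset.n_variants
    miss = (calls == MISSING).sum(axis=1)
    het = (calls == 1).sum(axis=1)
    nonmiss = m - miss
    with np.errstate(divide="ignore", invalid="ignore"):
        het_rate = np.where(nonmiss > 0, het / nonmiss, np.nan)
    return pd.DataFrame(
        {
            "id": dataset.samples["id"],
            "missing_rate": miss / m,
            "het_rate": het_rate,
        }
    )


def exclude_regions(dataset: GenotypeDataset, regions, flank_bp: int = 0) -> GenotypeDataset:
    """Drop variants falling in any of ``regions`` extended by ``flank_bp``.

    ``regions`` is an iterable of ``(chrom, start_bp, end_bp)`` with 1-based
    inclusive bounds and ``start_bp <= end_bp``.  All samples are kept.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    chrom = dataset.variants["chrom"].to_numpy()
    bp = dataset.variants["bp"].to_numpy()
    drop = np.zeros(dataset.n_variants, dtype=bool)
    for c, start, end in regions:
        if start > end:
            raise ValueError(f"region on chrom {c}: start {start} > end {end}")
        lo = start - flank_bp
        hi = end + flank_bp
        drop |= (chrom == int(c)) & (bp >= lo) & (bp <= hi)
    if drop.any():
        logger.info("exclude_regions: removing %d variants", int(drop.sum()))
    return dataset.subset_variants(~drop)


def read_region_list(path) -> list[tuple[int, int, int]]:
    """Read a 3-column (chrom, start_bp, end_bp) region list, 1-based inclusive."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end"])
    return [(int(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]
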