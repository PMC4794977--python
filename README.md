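# autozyg

Runs-of-homozygosity and genomic-inbreeding analysis for case-control SNP
cohorts.

Long stretches of consecutive homozygous genotypes (runs of homozygosity,
ROH) arise when both chromosome copies descend from a recent common
ancestor. Their abundance, and SNP-based inbreeding coefficients derived
from the same data, can reveal recessive components of disease risk that
per-allele association scans miss. `autozyg` is a compact, tested pipeline
for this analysis on PLINK-binary genotype data, aimed at statistical
geneticists who want each stage available as a plain Python function:

* **ROH detection** — sliding-window caller (windows of 50 SNPs, no
  heterozygote tolerated, ≥ 75 SNPs and ≥ 1000 kb per segment), plus the
  cohort-calibrated minimum run length: the smallest L with
  `(1 − h̄)^L · n_SNP · n_ind ≤ α`.
* **SNP-level homozygosity association** — per-SNP case/control × hom/het
  chi-square (no continuity correction), one-sided Fisher odds ratios, and
  Benjamini–Hochberg q-values with an externally specified test count.
* **ROH burden and F_ROH** — per-individual counts/lengths, category odds
  ratios with Woolf CIs, Student t contrasts, and
  `F_ROH = Σ L_ROH / L_AUTO` (default `L_AUTO` = 2,677,608,286 bp) with
  <1500 kb / ≥1500 kb subclasses.
* **Consensus ROH** — single-linkage pooling of overlapping segments,
  strict-intersection consensus regions, recurrent-ROH filter (> 5
  carriers, ≥ 500 kb), carrier chi-squares and per-SNP homozygosity
  proportion t-tests.
* **Genomic inbreeding** — the three SNP-based estimators
  F̂1 = mean[(x−2p)²/2pq] − 1, F̂2 = mean[1 − x(2−x)/2pq],
  F̂3 = mean[(x² − (1+2p)x + 2p²)/2pq], per chromosome and genome-wide,
  with case-control t-tests and a covariate-adjusted logistic model.
* **GREML heritability** — allele-frequency-standardised GRMs, PCA,
  average-information REML with EM fallback, and the liability transform
  `h_l² = h_o² K(1−K)/z²`.
* **Synthetic cohorts** — a seeded generator with LD blocks, exact-F
  autozygous tracts, planted ROHs and recessive risk loci, so the whole
  pipeline is testable without external data.

## Worked example

```bash
autozyg simulate --seed 17 --out cohort          # 200/200 x 20,000 SNPs
autozyg roh cohort --out segments.tsv
autozyg burden cohort --segments segments.tsv --out burden.tsv
autozyg assoc-hom cohort --out assoc.tsv
```

On the default simulated cohort this prints:

```
wrote 400 samples x 20000 SNPs to cohort.bed/.bim/.fam
0 segments -> segments.tsv
n_roh: t = 0.000, p = 1
total_kb: t = 0.000, p = 1
mean_kb: t = 0.000, p = 1
burden table -> burden.tsv; OR table -> burden.or.tsv
20000 SNPs tested, 0 with q < 0.05 -> assoc.tsv
```

An outbred null cohort carries no ≥ 1 Mb ROHs and no homozygosity
associations — both t and q behave as expected under the null. Inbreeding
produces real signal: with `inbreeding_f: 0.08` in a YAML config
(`autozyg simulate --config sim.yaml --seed 17 --out inbred`) the caller
finds 590 segments, and
`autozyg burden inbred --segments ... --l-auto-bp map` reports a mean
per-individual `f_roh` of 0.0788 — the genomic fraction in ≥ 1 Mb
autozygous runs, recovering the simulated F = 0.08 (`--l-auto-bp map`
scales the denominator to the synthetic marker map instead of the real
autosomal genome). The same stages are available as library calls
(`autozyg.roh_detect.scan_roh`, `autozyg.roh_burden.individual_burden`,
`autozyg.inbreeding.inbreeding_coefficients`,
`autozyg.heritability.reml_fit`, ...), which is how the test suite uses
them.

For the scientific background, parameter defaults and the generator's
assumptions, see [docs/methods.md](docs/methods.md).

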