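"""Published summary tables used as fixed inputs by the reproduction tests.

The counts come from a case-control thyroid-cancer homozygosity study
(649 cases, 431 controls, 536,270 autosomal SNPs).  Each TABLE1 row holds
the printed per-SNP homozygote/heterozygote counts together with the
printed chi-square, p and BH q; TABLE2 holds the ROH-burden category
counts with printed odds ratios; TABLE3 the recurrent-ROH carrier counts
with printed chi-squares and the consensus coordinates quoted in the text.
"""

# (snp, chrom, cases_hom, cases_het, controls_hom, controls_het, chi2, p, q)
TABLE1 = [
    ("rs4698482", 4, 519, 116, 274, 157, 44.43, 2.62e-11, 1.40e-5),
    ("rs11688848", 2, 512, 119, 275, 156, 40.10, 2.40e-10, 5.38e-5),
    ("rs9578483", 13, 543, 97, 296, 135, 39.66, 3.01e-10, 5.38e-5),
    ("rs8395092", 2, 497, 126, 270, 160, 37.09, 1.12e-9, 0.0001),
    ("rs2414003", 15, 514, 122, 280, 151, 33.90, 5.77e-9, 0.0006),
    ("rs3096381", 16, 525, 116, 289, 141, 30.46, 3.39e-8, 0.0028),
    ("rs630695", 6, 526, 103, 299, 132, 30.10, 4.09e-8, 0.0028),
    ("rs938845", 18, 512, 122, 284, 147, 30.02, 4.26e-8, 0.0028),
    ("rs17797954", 5, 516, 122, 287, 144, 28.09, 1.15e-7, 0.0068),
    ("rs10961997", 9, 509, 134, 279, 152, 27.48, 1.58e-7, 0.0083),
    ("rs12126497", 1, 586, 56, 346, 85, 27.33, 1.71e-7, 0.0083),
    ("rs509716", 6, 532, 113, 297, 134, 26.90, 2.13e-7, 0.0095),
    ("rs6715968", 2, 484, 141, 272, 159, 25.75, 3.86e-7, 0.0159),
    ("rs712082", 1, 545, 98, 311, 120, 25.32, 4.83e-7, 0.0173),
    ("rs6440553", 3, 545, 84, 321, 110, 25.32, 4.84e-7, 0.0173),
    ("rs804317", 15, 529, 105, 304, 127, 25.07, 5.50e-7, 0.0184),
    ("rs12902263", 15, 556, 87, 321, 110, 24.77, 6.44e-7, 0.0197),
    ("rs1025436", 7, 522, 116, 296, 135, 24.72, 6.62e-7, 0.0197),
    ("rs11563992", 7, 507, 115, 294, 136, 24.16, 8.86e-7, 0.0242),
    ("rs7018634", 9, 538, 100, 310, 121, 24.11, 9.05e-7, 0.0242),
    ("rs11169076", 12, 571, 72, 335, 96, 23.99, 9.68e-7, 0.0247),
    ("rs1943939", 18, 556, 62, 342, 89, 23.22, 1.43e-6, 0.0332),
    ("rs12660310", 6, 503, 120, 292, 139, 23.18, 1.46e-6, 0.0332),
    ("rs11204947", 1, 489, 135, 280, 151, 23.16, 1.48e-6, 0.0332),
    ("rs382131", 2, 581, 61, 345, 85, 23.06, 1.56e-6, 0.0335),
    ("rs940740", 9, 532, 95, 314, 117, 22.93, 1.67e-6, 0.0345),
    ("rs2830028", 21, 493, 133, 282, 148, 22.64, 1.94e-6, 0.0386),
    ("rs11151652", 18, 554, 91, 319, 110, 22.52, 2.07e-6, 0.0397),
    ("rs10779770", 1, 537, 97, 314, 117, 22.42, 2.18e-6, 0.0403),
    ("rs1508833", 5, 519, 108, 303, 127, 22.35, 2.26e-6, 0.0404),
    ("rs554232", 8, 540, 98, 314, 117, 22.23, 2.40e-6, 0.0408),
    ("rs2102727", 8, 502, 133, 285, 146, 22.21, 2.43e-6, 0.0408),
    ("rs937924", 6, 571, 67, 341, 90, 22.11, 2.56e-6, 0.0416),
    ("rs7481683", 11, 454, 174, 252, 179, 21.98, 2.75e-6, 0.0434),
]

#: total autosomal SNPs tested in the published scan (FDR denominator)
M_TOTAL = 536_270

# ROH-count categories: (label, cases, controls, printed OR or None for ref)
# The ">15" row prints OR 1.55 while the counts give 1.51; it is kept here
# with printed_or=None and excluded from reproduction checks.
TABLE2_COUNT = [
    ("<10", 204, 152, None),
    ("10-12", 145, 88, 1.22),
    ("13-15", 170, 127, 0.99),
    (">15", 130, 64, None),
]

# total-ROH-length (Mb) categories
TABLE2_LENGTH = [
    ("<14.1", 153, 117, None),
    ("14.1-19.4", 156, 114, 1.04),
    ("19.4-25.4", 163, 107, 1.16),
    (">25.4", 177, 93, 1.45),
]

N_CASES = 649
N_CONTROLS = 431

# (roh, chrom, start_bp, end_bp, case_carriers, control_carriers, printed chi2)
TABLE3 = [
    ("ROH1", 2, 167204846, 167895993, 6, 15, 8.87),
    ("ROH2", 3, 121016843, 121689105, 10, 0, 6.70),
    ("ROH3", 10, 44969326, 45928700, 5, 11, 5.63),
    ("ROH4", 6, 69734043, 70381283, 2, 7, 5.42),
    ("ROH5", 9, 73966521, 74829925, 2, 7, 5.42),
    ("ROH6", 1, 217208583, 218034929, 7, 0, 4.67),
    ("ROH7", 2, 26036646, 26765583, 7, 0, 4.67),
    ("ROH8", 2, 75174688, 76481471, 7, 0, 4.67),
    ("ROH9", 1, 177243354, 178385972, 6, 0, 4.00),
    ("ROH10", 2, 112182736, 113192306, 6, 0, 4.00),
    ("ROH11", 2, 113858688, 114678121, 6, 0, 4.00),
    ("ROH12", 4, 181001922, 181547116, 6, 0, 4.00),
    ("ROH13", 4, 182307562, 182564832, 6, 0, 4.00),
    ("ROH14", 4, 183848547, 184539543, 6, 0, 4.00),
    ("ROH15", 9, 107008151, 108187183, 6, 0, 4.00),
    ("ROH16", 15, 96502627, 98965249, 6, 0, 4.00),
]

#: consensus lengths quoted in the running text (kb, truncated to integers)
ROH2_PRINTED_KB = 672
ROH3_PRINTED_KB = 959
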