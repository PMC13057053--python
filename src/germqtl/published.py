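"""Published summary tables for the wheat DH drought / ZnO nano-priming study.

The raw phenotype and genotype data of the study are not public; what the
publication prints are summaries: the linkage-map geometry (21 chromosomes,
3,567 SNPs, 3,150.71 cM), the twelve single-marker QTL records, and
genotype-mean F ratios for the germination traits.  These summaries are
inputs to parts of the pipeline -- the map template drives the population
simulator, and the QTL table exercises the report bookkeeping -- so they are
kept here as plain constants.

All values are stored exactly as printed (including one QTL record whose
LOD and PVE are mutually inconsistent at the published population size;
it is bookkeeping input, never recomputed).
"""

from __future__ import annotations

# (chromosome, number of SNP markers, map length in cM)
LINKAGE_MAP_SUMMARY: list[tuple[str, int, float]] = [
    ("1A", 143, 177.29),
    ("1B", 373, 144.39),
    ("1D", 127, 94.39),
    ("2A", 266, 281.13),
    ("2B", 320, 200.77),
    ("2D", 85, 111.91),
    ("3A", 179, 199.84),
    ("3B", 103, 174.65),
    ("3D", 22, 45.19),
    ("4A", 88, 163.54),
    ("4B", 173, 131.02),
    ("4D", 4, 22.23),
    ("5A", 316, 258.94),
    ("5B", 299, 200.54),
    ("5D", 33, 67.04),
    ("6A", 230, 173.31),
    ("6B", 247, 136.15),
    ("6D", 67, 14.54),
    ("7A", 225, 270.24),
    ("7B", 240, 184.26),
    ("7D", 27, 99.34),
]

#: Fields of one published QTL record, in report column order.
QTL_REPORT_COLUMNS = (
    "qtl", "trait", "chrom", "pos", "left_marker", "right_marker",
    "lod", "pve", "add", "ci_left", "ci_right", "environment",
)

# The twelve QTLs reported for germination / seedling-establishment traits.
QTL_REPORT: list[tuple] = [
    ("QRL_C4A", "RL_C", "4A", 101.00, "Kukri_c48943_1149", "Excalibur_c3988_1660",
     2.73, 16.70, -1.82, 89.50, 113.50, "Control"),
    ("QFW_D3A", "FW_D", "3A", 33.00, "Tdurum_contig52302_649", "BobWhite_c37325_92",
     2.74, 14.43, -0.10, 31.50, 33.50, "Drought"),
    ("QFW_D3B", "FW_D", "3B", 102.00, "IAAV6566", "Tdurum_contig100004_204",
     3.43, 18.59, -0.12, 90.50, 106.50, "Drought"),
    ("QSL_D2A", "SL_D", "2A", 85.00, "RAC875_c4015_2175", "BobWhite_c1611_1685",
     2.85, 21.72, 0.74, 83.50, 92.50, "Drought"),
    ("QFG%_D7B", "FG%_D", "7B", 181.00, "RAC875_rep_c108382_824", "BS00063821_51",
     2.54, 17.22, 5.62, 179.50, 181.50, "Drought"),
    ("QCVt_D3B", "CVt_D", "3B", 97.00, "RAC875_c81076_317", "IAAV6566",
     2.50, 16.43, 7.30, 87.50, 106.50, "Drought"),
    ("QFW_CN3B", "FW_CN", "3B", 83.00, "RAC875_c5799_224", "RAC875_c81076_317",
     2.76, 19.36, -0.16, 62.50, 98.50, "Control and Nano"),
    ("QFW_DN3B", "FW_DN", "3B", 102.00, "IAAV6566", "Tdurum_contig100004_204",
     2.60, 17.59, -0.11, 89.50, 106.50, "Drought and Nano"),
    ("QSL_DN1A", "SL_DN", "1A", 13.00, "wsnp_Ex_c7965_13520238", "wsnp_Ku_c5756_10191339",
     2.51, 17.00, -0.79, 11.50, 16.50, "Drought and Nano"),
    ("QRNo_DN1A", "RNo_DN", "1A", 111.00, "BobWhite_c12977_65", "BS00039378_51",
     2.79, 18.45, -0.32, 102.50, 110.50, "Drought and Nano"),
    ("QCVt_DN2B", "CVt_DN", "2B", 168.00, "RAC875_c27650_216", "Excalibur_c7051_1027",
     14.07, 3.45, 17.83, 166.50, 168.50, "Drought and Nano"),
    ("QFG%_DN7B", "FG%_DN", "7B", 175.00, "CAP12_c194_240", "Excalibur_c24639_398",
     2.07, 14.19, 6.08, 161.50, 179.50, "Drought and Nano"),
]

# Published genotype-mean F ratios (3 replicates) for a few germination /
# seedling traits, used to exercise the F -> entry-mean heritability path:
# key = (trait, treatment), value = F ratio of the genotype mean square.
GENOTYPE_F_RATIOS: dict[tuple[str, str], float] = {
    ("RNo", "C"): 24.31,
    ("CVt", "D"): 6.27,
    ("SL", "D"): 38.30,
}

#: Replicates per genotype x treatment in the published design.
N_REPLICATES = 3

#: Lines actually carried through the published QTL scan.
N_MAPPED_LINES = 63
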