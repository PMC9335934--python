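"""Bundled worked-example data: a 27-line fast-neutron soybean cohort.

Per-line variant counts, the affected-transcript consequence table, spectrum
class counts, and the de novo diversity inputs from a resequencing study of
27 soybean inbred lines irradiated with fast neutrons (8–32 Gy, 3–8 selfing
generations, M92-220 background) contrasted with standing variation in a
diverse panel.  These tables let the summary statistics run as worked
examples without any VCF input.
"""

from __future__ import annotations

import pandas as pd

# sample, selfing_generations, dosage_gy, indels, snps; "*"/"+" mark the two
# three-sibling families derived from the same mutagenized plant
_FN_LINES = [
    ("2012BM7F223", 7, 8, None, 25, 56),
    ("2012CM7F040P05", 7, 16, "F1", 38, 76),
    ("2012CM7F040P06", 7, 16, "F1", 47, 72),
    ("2012CM7F040P07", 7, 16, "F1", 9, 23),
    ("2012CM8F030P02", 8, 16, "F2", 27, 39),
    ("2012CM8F030P07", 8, 16, "F2", 18, 20),
    ("2012CM8F030P09", 8, 16, "F2", 18, 35),
    ("2012DM8F016P02", 8, 16, None, 51, 89),
    ("4R30C22acr626MN13", 6, 16, None, 34, 41),
    ("5R39C03Dr334cMN12", 3, 32, None, 14, 8),
    ("FN0112228.06.02.01.M5", 5, 16, None, 53, 62),
    ("FN0112885.02.06.03.M5", 5, 16, None, 32, 49),
    ("FN0131633.06.01.M4", 4, 16, None, 33, 56),
    ("FN0163764.04.01.M4", 4, 32, None, 36, 63),
    ("FN0164160.03.02.01.01.M6", 6, 32, None, 50, 87),
    ("FN0164472.x3.06.01.M5", 5, 32, None, 49, 83),
    ("FN0170228.07.35.01.M5", 5, 16, None, 38, 64),
    ("FN0170712.06.41.01.M5", 5, 16, None, 41, 80),
    ("FN0171501.01.02.M4", 4, 32, None, 38, 67),
    ("FN0172932.09.08.01.M5", 5, 16, None, 15, 16),
    ("FN0173217.03.09.01.M5", 5, 16, None, 25, 56),
    ("FN0175143.05.06.01.M5", 5, 16, None, 34, 45),
    ("FN0175501.x2.02.01.M5", 5, 16, None, 29, 50),
    ("FN0190069.01.01.M4", 4, 32, None, 31, 70),
    ("R18C55Dhaar437MN13", 6, 32, None, 23, 25),
    ("R52C55Dadr564MN13", 5, 32, None, 20, 22),
    ("RP8DM5r597MN13", 6, 32, None, 41, 79),
]

# affected-transcript counts per consequence class: (label, FN, common, rare)
_CONSEQUENCES = [
    ("splice_donor", 0, 1_786, 939),
    ("splice_acceptor", 5, 1_838, 922),
    ("stop_gained", 0, 4_539, 2_797),
    ("frameshift", 34, 11_359, 6_364),
    ("stop_lost", 0, 819, 235),
    ("start_lost", 0, 810, 317),
    ("inframe_insertion", 0, 4_959, 1_665),
    ("inframe_deletion", 0, 4_603, 2_490),
    ("protein_altering", 0, 242, 127),
    ("missense", 68, 204_987, 87_537),
    ("splice_region", 13, 38_143, 14_205),
    ("start_retained", 0, 112, 28),
    ("synonymous", 29, 167_608, 58_830),
    ("stop_retained", 0, 436, 148),
    ("coding_sequence", 0, 486, 256),
    ("5_prime_UTR", 19, 140_683, 48_300),
    ("3_prime_UTR", 28, 213_299, 73_596),
    ("intron", 263, 1_789_836, 639_990),
    ("upstream", 905, 5_325_487, 1_721_428),
    ("downstream", 820, 4_764_026, 1_572_140),
    ("intergenic", 886, 3_364_380, 1_458_227),
]

#: de novo singleton SNP count and reference genome length for θπ
FN_SINGLETON_SNPS = 1_430
FN_HAPLOID_N = 27
GENOME_LENGTH_BP = 966e6

#: strand-collapsed spectrum counts used in the worked examples
FN_CT_COUNT = 655  # C>T* among the de novo SNPs
STANDING_SNPS = 9_708_345
STANDING_CT_COUNT = 4_035_491  # most abundant class
STANDING_CG_COUNT = 532_675  # least abundant class (C>G*)

#: standing-variation indel direction totals
STANDING_INSERTIONS = 756_095
STANDING_DELETIONS = 860_649

#: spontaneous per-site per-generation mutation rates (plant MA lines)
SPONTANEOUS_SNP_RATE = 6.53e-9
SPONTANEOUS_INDEL_RATE = 0.47e-9


def fn_line_counts() -> pd.DataFrame:
    """Per-line SNP and indel counts with dosage/selfing metadata."""
    df = pd.DataFrame(
        _FN_LINES,
        columns=["sample", "selfing_generations", "dosage_gy", "family", "indels", "snps"],
    )
    df["total"] = df["snps"] + df["indels"]
    return df.set_index("sample", drop=False)


def consequence_counts() -> pd.DataFrame:
    """Affected-transcript counts per consequence class and cohort."""
    return pd.DataFrame(_CONSEQUENCES, columns=["label", "fn", "common", "rare"])
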