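"""Published reference values from a low-coverage survey of the sunflower
(Helianthus annuus) genome.

These tables carry the printed read counts, sequence censuses and
region-coverage values from the sunflower genome survey that this
package's procedure models. They serve as worked-example inputs for the
table arithmetic (composition percentages, class abundance ratios,
redundancy threshold, LTR / inter-LTR ratios) and as cross-checks that
the arithmetic reproduces the printed numbers exactly.
"""

from __future__ import annotations

from .composition import LTRRatioRecord

# --- read mapping statistics (4x short-read set mapped to the merged
# whole-genome assembled sequence set, "WGSAS") -------------------------

SUNFLOWER_READ_COUNTS = {
    "repeated": 61_860_742,
    "unique_or_low_redundant": 14_586_474,
    "unmatched_nuclear": 42_217_465,
    "organellar": 11_680_927,
}
SUNFLOWER_TOTAL_NUCLEAR = 118_664_681
SUNFLOWER_TOTAL_READS = 130_345_608

# --- per-class matched read counts ------------------------------------

SUNFLOWER_CLASS_READ_COUNTS = {
    "DNA transposons / Unclassified": 521_152,
    "DNA transposons / Subclass I": 445_239,
    "DNA transposons / Subclass II": 348_166,
    "DNA transposons / MITE": 641_043,
    "Retrotransposons / Unclassified": 347_042,
    "Retrotransposons / LTR-Copia": 14_693_697,
    "Retrotransposons / LTR-Gypsy": 37_625_059,
    "Retrotransposons / LTR-Unknown": 7_569_830,
    "Retrotransposons / Non-LTR": 541_494,
    "Retrotransposons / Pararetrovirus": 20_624,
    "Tandem repeats": 457_613,
    "rDNA": 266_528,
    "Unknown repeats / Unclassified": 3_888_190,
    "Unknown repeats / Contig-61 type": 2_148_599,
}

SUNFLOWER_RETRO_SUBCLASS_TOTAL = 60_797_746  # sum of the retrotransposon rows

# --- repeat database (redundant contig set) census ---------------------

SUNFLOWER_REPEAT_DB_SIZE = 47_924
SUNFLOWER_WGSAS_SIZE = 283_800
SUNFLOWER_LOW_COPY_SIZE = 235_876
SUNFLOWER_DB_GYPSY_COUNT = 19_726
SUNFLOWER_DB_COPIA_COUNT = 8_605
SUNFLOWER_LARGEST_FAMILY_SIZE = 96

# --- redundancy threshold calibration ----------------------------------

SUNFLOWER_REFERENCE_GENE_MEAN_COVERAGE = 6.6
SUNFLOWER_THRESHOLD_MULTIPLIER = 5

# --- LTR vs inter-LTR region coverage of 19 intact elements -------------

SUNFLOWER_LTR_COVERAGE_RECORDS = [
    LTRRatioRecord("DESRLC1", "Copia", 1037.85, 830.65),
    LTRRatioRecord("DHNRLC1", "Copia", 186.63, 3303.45),
    LTRRatioRecord("LTPRLC1", "Copia", 62.72, 13.47),
    LTRRatioRecord("LTPRLC2", "Copia", 12.54, 1367.95),
    LTRRatioRecord("LTPRLC3", "Copia", 340.37, 415.11),
    LTRRatioRecord("DESRLG1f", "Gypsy", 9239.29, 2288.53),
    LTRRatioRecord("DESRLG2", "Gypsy", 2337.58, 659.22),
    LTRRatioRecord("DESRLG3", "Gypsy", 14003.10, 3932.65),
    LTRRatioRecord("DHNRLG1", "Gypsy", 2345.90, 560.36),
    LTRRatioRecord("DHNRLG2", "Gypsy", 976.16, 1776.89),
    LTRRatioRecord("LTPRLG1", "Gypsy", 6267.76, 10258.53),
    LTRRatioRecord("LTPRLG2", "Gypsy", 823.73, 125.25),
    LTRRatioRecord("LTPRLG3", "Gypsy", 6016.77, 1024.56),
    LTRRatioRecord("DESRLX1", "Unknown", 234.20, 104.46),
    LTRRatioRecord("DESRLX2", "Unknown", 2064.22, 1827.43),
    LTRRatioRecord("DHNRLX1", "Unknown", 702.73, 5577.56),
    LTRRatioRecord("DHNRLX2", "Unknown", 519.09, 791.34),
    LTRRatioRecord("LTPRLX1", "Unknown", 1053.57, 1875.62),
    LTRRatioRecord("LTPRLX2", "Unknown", 956.69, 356.17),
]

#: printed per-record ratios, in the same order, for cross-checking
SUNFLOWER_LTR_PRINTED_RATIOS = [
    1.25, 0.06, 4.66, 0.01, 0.82,
    4.04, 3.55, 3.56, 4.19, 0.55, 0.61, 6.58, 5.87,
    2.24, 1.13, 0.13, 0.66, 0.56, 2.69,
]
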