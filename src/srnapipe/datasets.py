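"""Bundled reference numbers from a published two-library experiment.

A hypoxia-vs-control tomato-root small-RNA sequencing study provides a
convenient worked example for the reporting layer: its category count
table (reads per RNA class in each library), its DE call summary and
the abundance of a highly expressed novel miRNA family.  Only printed
summary numbers are bundled — the underlying raw libraries are not
public — so these serve as inputs to the reporting arithmetic, not as
fixtures for the read-level stages (the synthetic generator covers
those).
"""

from __future__ import annotations

__all__ = [
    "CATEGORY_COUNTS",
    "CLEAN_TOTALS",
    "MAPPED_READS",
    "DE_SUMMARY",
    "NOVEL_MIR1_TPM",
]

#: clean-read totals per library (control "ck", treated "hypoxia").
CLEAN_TOTALS = {"ck": 26_260_294, "hypoxia": 26_874_882}

#: reads per category per library.
CATEGORY_COUNTS = {
    "un_mapped": {"ck": 16_529_042, "hypoxia": 16_398_714},
    "Repeat": {"ck": 4_170_780, "hypoxia": 4_981_128},
    "Intergenic": {"ck": 2_849_292, "hypoxia": 3_137_662},
    "miRNA": {"ck": 643_669, "hypoxia": 389_909},
    "rRNA": {"ck": 675_383, "hypoxia": 443_956},
    "Exon": {"ck": 669_852, "hypoxia": 721_513},
    "Intron": {"ck": 670_160, "hypoxia": 759_226},
    "sRNA": {"ck": 33_612, "hypoxia": 26_651},
    "Precursor": {"ck": 5_962, "hypoxia": 7_150},
    "tRNA": {"ck": 5_067, "hypoxia": 2_239},
    "snoRNA": {"ck": 4_327, "hypoxia": 3_148},
    "snRNA": {"ck": 3_148, "hypoxia": 3_586},
}

#: the corresponding printed frequencies (% of clean reads, 2 decimals).
CATEGORY_FREQUENCIES = {
    "un_mapped": {"ck": 62.94, "hypoxia": 61.02},
    "Repeat": {"ck": 15.88, "hypoxia": 18.53},
    "Intergenic": {"ck": 10.85, "hypoxia": 11.68},
    "miRNA": {"ck": 2.45, "hypoxia": 1.45},
    "rRNA": {"ck": 2.57, "hypoxia": 1.65},
    "Exon": {"ck": 2.55, "hypoxia": 2.68},
    "Intron": {"ck": 2.55, "hypoxia": 2.83},
    "sRNA": {"ck": 0.13, "hypoxia": 0.10},
    "Precursor": {"ck": 0.02, "hypoxia": 0.03},
    "tRNA": {"ck": 0.02, "hypoxia": 0.01},
    "snoRNA": {"ck": 0.02, "hypoxia": 0.01},
    "snRNA": {"ck": 0.01, "hypoxia": 0.01},
}

#: perfectly genome-matched reads per library.
MAPPED_READS = {"ck": 9_731_252, "hypoxia": 10_476_168}

#: known-miRNA DE outcome: 36 called, 33 down-regulated under hypoxia;
#: 101 / 96 known miRNAs detected in control / hypoxia.
DE_SUMMARY = {"n_called": 36, "n_down": 33, "detected_ck": 101, "detected_hypoxia": 96}

#: novel miR1 family abundance (TPM) per library.
NOVEL_MIR1_TPM = {"ck": 854.24, "hypoxia": 1272.13}
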