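#!/usr/bin/env python
"""Assign tags to RNA categories and quantify the known miRNAs.

Builds the category table (the partition of clean reads into un_mapped,
Repeat, Intergenic, miRNA, rRNA, ... classes) and the per-miRNA raw
count table using the perfect-precursor-match ±2-nt 5'-window rule.
"""

from pathlib import Path

from srnapipe.annotate import CategoryReferences, GenomeIndex, categorize, category_table
from srnapipe.known import quantify, read_annotations
from srnapipe.tags import TagLibrary, read_collapsed_fasta

BASE = Path(__file__).resolve().parent.parent / "results"
EXP = BASE / "experiment"
CATEGORIES = ["rRNA", "tRNA", "snoRNA", "snRNA", "sRNA", "Repeat", "Exon", "Intron"]


def load_library() -> TagLibrary:
    return TagLibrary.from_conditions(
        read_collapsed_fasta(BASE / "tags" / "ck_tags.fa"),
        read_collapsed_fasta(BASE / "tags" / "hypoxia_tags.fa"),
    )


def main() -> None:
    out = BASE / "annotation"
    out.mkdir(parents=True, exist_ok=True)
    library = load_library()
    genome = "".join(
        l.strip() for l in open(EXP / "genome.fa") if not l.startswith(">")
    )
    annotations = read_annotations(EXP / "precursors.fa", EXP / "mature.fa")
    refs = CategoryReferences.from_fastas(
        {c: EXP / f"{c}.fa" for c in CATEGORIES}, annotations
    )
    assignment = categorize(library, GenomeIndex(genome), refs)
    table = category_table(library, assignment)
    table.to_csv(out / "category_table.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    counts = quantify(library, annotations)
    counts.to_csv(out / "known_mirna_counts.tsv", sep="\t", index=False)
    print(
        f"\nknown miRNAs detected: {(counts['count_ck'] > 0).sum()} (control), "
        f"{(counts['count_hypoxia'] > 0).sum()} (hypoxia) of {len(annotations)}"
    )


if __name__ == "__main__":
    main()
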