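#!/usr/bin/env python
"""Discover novel miRNA loci among the unannotated genome-mapped tags.

Removes every annotated class (known miRNA, structural RNAs, repeats,
exons), excises candidate windows around the remaining well-supported
tags, folds them and applies the structural + miRNA*/100-TPM rules.
The planted pair of loci sharing one mature sequence should surface as
a single two-locus family.
"""

from pathlib import Path

from srnapipe.annotate import CategoryReferences, GenomeIndex, categorize
from srnapipe.known import read_annotations
from srnapipe.novel import discover_novel, group_families
from srnapipe.tags import TagLibrary, read_collapsed_fasta

BASE = Path(__file__).resolve().parent.parent / "results"
EXP = BASE / "experiment"
CATEGORIES = ["rRNA", "tRNA", "snoRNA", "snRNA", "sRNA", "Repeat", "Exon", "Intron"]


def main() -> None:
    out = BASE / "novel"
    out.mkdir(parents=True, exist_ok=True)
    library = TagLibrary.from_conditions(
        read_collapsed_fasta(BASE / "tags" / "ck_tags.fa"),
        read_collapsed_fasta(BASE / "tags" / "hypoxia_tags.fa"),
    )
    genome = "".join(
        l.strip() for l in open(EXP / "genome.fa") if not l.startswith(">")
    )
    annotations = read_annotations(EXP / "precursors.fa", EXP / "mature.fa")
    refs = CategoryReferences.from_fastas(
        {c: EXP / f"{c}.fa" for c in CATEGORIES}, annotations
    )
    assignment = categorize(library, GenomeIndex(genome), refs)
    unannotated = {}
    for seq, cat in assignment.items():
        if cat not in ("Intergenic", "Intron"):
            continue
        starts, pos = [], genome.find(seq)
        while pos >= 0:
            starts.append(pos)
            pos = genome.find(seq, pos + 1)
        if starts:
            unannotated[seq] = starts
    print(f"{len(unannotated)} unannotated mapped tag sequences enter discovery")

    candidates = discover_novel(unannotated, library, genome)
    families = group_families(candidates)
    families.to_csv(out / "novel_mirna_families.tsv", sep="\t", index=False)
    with open(out / "structures.txt", "w") as fh:
        for c in candidates:
            fh.write(f">{c.family_id} locus={c.locus[0]}-{c.locus[1]} "
                     f"star_detected={c.star_detected}\n")
            fh.write(c.structure.sequence + "\n" + c.structure.dot_bracket() + "\n")
    print(families.to_string(index=False) if len(families) else "no novel families")


if __name__ == "__main__":
    main()
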