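"""Category annotation of collapsed tags (genome mapping + RNA classes).

Tags are first split into genome-mapped vs. un_mapped by exact substring
search (either strand) against the genome sequence, then each mapped tag
is assigned to exactly one RNA category by a fixed priority:

    miRNA > rRNA > tRNA > snoRNA > snRNA > sRNA > Precursor
          > Repeat > Exon > Intron > Intergenic

miRNA means the tag passes the known-miRNA matching rule (perfect
precursor match, 5' start within ±2 nt of the mature); Precursor means
it maps perfectly to a hairpin but outside that mature window (e.g.
miRNA* or loop fragments); the named classes match their reference
sequence sets by exact substring; Intergenic is the mapped remainder.
The category read totals partition the clean reads, which is what makes
the frequency table sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import canonical, revcomp, round_half_up
from .known import MiRNAAnnotation, assign_tag
from .tags import TagLibrary

__all__ = [
    "CategoryReferences",
    "GenomeIndex",
    "CATEGORY_PRIORITY",
    "TABLE_ROW_ORDER",
    "map_to_genome",
    "categorize",
    "category_table",
]

#: assignment priority for mapped tags (first match wins).
CATEGORY_PRIORITY = [
    "miRNA", "rRNA", "tRNA", "snoRNA", "snRNA", "sRNA",
    "Precursor", "Repeat", "Exon", "Intron", "Intergenic",
]

#: row order of the reporting table.
TABLE_ROW_ORDER = [
    "Clean", "un_mapped", "Repeat", "Intergenic", "miRNA", "rRNA",
    "Exon", "Intron", "sRNA", "Precursor", "tRNA", "snoRNA", "snRNA",
]

_SEQ_CATEGORIES = ["rRNA", "tRNA", "snoRNA", "snRNA", "sRNA", "Repeat", "Exon", "Intron"]


@dataclass
class CategoryReferences:
    """Reference sets: per-category sequence lists plus miRNA annotations."""

    sequences: dict[str, list[str]] = field(default_factory=dict)
    annotations: list[MiRNAAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.sequences) - set(_SEQ_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown reference categories: {sorted(unknown)}")
        self.sequences = {
            cat: [canonical(s) for s in seqs] for cat, seqs in self.sequences.items()
        }

    @classmethod
    def from_fastas(
        cls,
        category_fastas: dict[str, str | Path],
        annotations: list[MiRNAAnnotation],
    ) -> "CategoryReferences":
        from Bio import SeqIO

        seqs = {
            cat: [canonical(str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
            for cat, path in category_fastas.items()
        }
        return cls(seqs, annotations)


class GenomeIndex:
    """Exact-substring membership over a fixed window of query lengths.

    Pre-extracts every genome substring whose length falls in
    [min_len, max_len] (the retained tag-length window) into a hash set,
    so per-tag lookups are O(1) instead of a full-genome scan.  Queries
    outside the indexed length range fall back to a direct search.
    Strand-agnostic: a tag matches if it or its reverse complement occurs.
    """

    def __init__(self, genome: str, min_len: int = 17, max_len: int = 30):
        self.genome = canonical(genome)
        self.min_len, self.max_len = min_len, max_len
        g = self.genome
        self._kmers = {
            g[i : i + k]
            for k in range(min_len, max_len + 1)
            for i in range(len(g) - k + 1)
        }

    def __contains__(self, seq: str) -> bool:
        seq = canonical(seq)
        if self.min_len <= len(seq) <= self.max_len:
            return seq in self._kmers or revcomp(seq) in self._kmers
        return seq in self.genome or revcomp(seq) in self.genome


def map_to_genome(
    library: TagLibrary, genome: str | GenomeIndex
) -> tuple[set[str], set[str]]:
    """Partition tag sequences into (mapped, unmapped) by exact search.

    A tag maps iff its sequence or reverse complement occurs as an exact
    substring of the genome ("perfect match", no mismatches).  Pass a
    prebuilt GenomeIndex when calling repeatedly on the same genome.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(canonical(genome))
    mapped, unmapped = set(), set()
    for seq in library.counts:
        (mapped if seq in index else unmapped).add(seq)
    return mapped, unmapped


def categorize(
    library: TagLibrary,
    genome: str | GenomeIndex,
    references: CategoryReferences,
    window: int = 2,
) -> dict[str, str]:
    """Assign every tag sequence its single category (priority above)."""
    mapped, unmapped = map_to_genome(library, genome)
    # one concatenated haystack per category keeps the search at C speed;
    # '#' cannot occur in a tag, so matches never span two references.
    blobs = {
        cat: "#".join(references.sequences.get(cat, []))
        for cat in _SEQ_CATEGORIES
    }
    precursor_blob = "#".join(a.precursor_seq for a in references.annotations)

    result: dict[str, str] = {seq: "un_mapped" for seq in unmapped}
    for seq in mapped:
        if seq in precursor_blob and assign_tag(seq, references.annotations, window):
            result[seq] = "miRNA"
            continue
        for cat in ("rRNA", "tRNA", "snoRNA", "snRNA", "sRNA"):
            if blobs[cat] and seq in blobs[cat]:
                result[seq] = cat
                break
        else:
            if seq in precursor_blob:
                result[seq] = "Precursor"
            else:
                for cat in ("Repeat", "Exon", "Intron"):
                    if blobs[cat] and seq in blobs[cat]:
                        result[seq] = cat
                        break
                else:
                    result[seq] = "Intergenic"
    return result


def category_table(
    library: TagLibrary, assignment: dict[str, str], ndigits: int = 2
) -> pd.DataFrame:
    """Reads and frequency (%) per category and condition.

    Frequencies are percentages of clean reads, rounded half-up to
    `ndigits`; the Clean row anchors the table at 100%.
    """
    reads = {cat: [0, 0] for cat in TABLE_ROW_ORDER}
    reads["Clean"] = [library.total_clean_ck, library.total_clean_hypoxia]
    for seq, (n_ck, n_hyp) in library.counts.items():
        cat = assignment[seq]
        reads[cat][0] += n_ck
        reads[cat][1] += n_hyp
    rows = []
    for cat in TABLE_ROW_ORDER:
        n_ck, n_hyp = reads[cat]
        rows.append(
            {
                "category": cat,
                "reads_ck": n_ck,
                "frequency_ck": round_half_up(
                    100 * n_ck / library.total_clean_ck, ndigits
                ) if library.total_clean_ck else 0.0,
                "reads_hypoxia": n_hyp,
                "frequency_hypoxia": round_half_up(
                    100 * n_hyp / library.total_clean_hypoxia, ndigits
                ) if library.total_clean_hypoxia else 0.0,
            }
        )
    return pd.DataFrame(rows)
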