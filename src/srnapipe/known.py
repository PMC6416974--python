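"""Known-miRNA quantification against miRBase-style annotations.

A tag counts toward a mature miRNA iff it maps *perfectly* (exact
substring, no mismatches) onto the miRNA's precursor and its 5' start
lies within 2 nt of the annotated mature 5' end — the standard isomiR
window that tolerates imprecise Dicer/DCL processing at the 5' end while
leaving 3'-end variation unconstrained.  Tags matching several miRNAs
(sequence families) contribute their full count to each and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import canonical
from .tags import TagLibrary

__all__ = [
    "MiRNAAnnotation",
    "assign_tag",
    "quantify",
    "read_annotations",
    "write_annotation_fastas",
    "START_WINDOW",
]

#: allowed |tag 5' start - mature 5' start| on the precursor.
START_WINDOW = 2


@dataclass(frozen=True)
class MiRNAAnnotation:
    """One mature miRNA on its precursor (0-based half-open coordinates)."""

    mirna_id: str
    precursor_id: str
    precursor_seq: str
    mature_start: int
    mature_seq: str
    star_start: int | None = None
    star_seq: str | None = None

    def __post_init__(self) -> None:
        pre = canonical(self.precursor_seq)
        mat = canonical(self.mature_seq)
        object.__setattr__(self, "precursor_seq", pre)
        object.__setattr__(self, "mature_seq", mat)
        if self.star_seq is not None:
            object.__setattr__(self, "star_seq", canonical(self.star_seq))
        if pre[self.mature_start : self.mature_start + len(mat)] != mat:
            raise ValueError(
                f"{self.mirna_id}: mature sequence does not sit at offset "
                f"{self.mature_start} of precursor {self.precursor_id}"
            )

    @property
    def mature_end(self) -> int:
        return self.mature_start + len(self.mature_seq)


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos >= 0:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def assign_tag(
    tag: str, annotations: list[MiRNAAnnotation], window: int = START_WINDOW
) -> list[str]:
    """All miRNA ids the tag matches under the perfect-match ±window rule.

    Every occurrence of the tag within each precursor is considered; one
    occurrence whose start is within `window` nt of the mature 5' end
    suffices for a match.
    """
    tag = canonical(tag)
    hits = []
    for ann in annotations:
        for pos in _occurrences(tag, ann.precursor_seq):
            if abs(pos - ann.mature_start) <= window:
                hits.append(ann.mirna_id)
                break
    return hits


def quantify(
    library: TagLibrary,
    annotations: list[MiRNAAnnotation],
    window: int = START_WINDOW,
    multi_mode: str = "full",
) -> pd.DataFrame:
    """Per-miRNA raw counts from a collapsed tag library.

    multi_mode 'full' credits a multi-matching tag's whole count to every
    matched miRNA (family-level reporting); 'unique' drops such tags.
    Returns columns mirna_id, count_ck, count_hypoxia, n_tags,
    multi_match (True if any contributing tag matched > 1 miRNA).
    miRNAs with zero count in both conditions are omitted.
    """
    ids = [a.mirna_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate mirna_id in annotations: {dupes}")
    if multi_mode not in ("full", "unique"):
        raise ValueError("multi_mode must be 'full' or 'unique'")

    # cheap prefilter: a matching tag must occur in some precursor.
    # Precursors are short, so the full substring set is small and makes
    # the per-tag screen O(1).
    lengths = {len(s) for s in library.counts}
    sub = {
        a.precursor_seq[i : i + k]
        for a in annotations
        for k in lengths
        for i in range(len(a.precursor_seq) - k + 1)
    }
    acc: dict[str, dict] = {}
    for seq, (n_ck, n_hyp) in library.counts.items():
        if seq not in sub:
            continue
        hits = assign_tag(seq, annotations, window=window)
        if not hits:
            continue
        if multi_mode == "unique" and len(hits) > 1:
            continue
        multi = len(hits) > 1
        for mid in hits:
            rec = acc.setdefault(
                mid,
                {"mirna_id": mid, "count_ck": 0, "count_hypoxia": 0,
                 "n_tags": 0, "multi_match": False},
            )
            rec["count_ck"] += n_ck
            rec["count_hypoxia"] += n_hyp
            rec["n_tags"] += 1
            rec["multi_match"] |= multi
    rows = [r for r in acc.values() if r["count_ck"] + r["count_hypoxia"] > 0]
    df = pd.DataFrame(
        rows,
        columns=["mirna_id", "count_ck", "count_hypoxia", "n_tags", "multi_match"],
    )
    return df.sort_values("mirna_id").reset_index(drop=True)


def read_annotations(
    precursor_fasta: str | Path, mature_fasta: str | Path
) -> list[MiRNAAnnotation]:
    """Build annotations from miRBase-style precursor + mature FASTAs.

    Mature ids must extend their precursor id (e.g. `mir156` ->
    `mir156-5p`) or match it exactly; each mature is located at its first
    occurrence within the precursor.
    """
    from Bio import SeqIO

    precursors = {
        rec.id: canonical(str(rec.seq))
        for rec in SeqIO.parse(str(precursor_fasta), "fasta")
    }
    # miRBase capitalizes the precursor (miR156 on MIR156): compare
    # case-insensitively while walking suffixes off the mature id
    by_lower = {pid.lower(): pid for pid in precursors}
    out = []
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        mature = canonical(str(rec.seq))
        name = rec.id
        while name and name.lower() not in by_lower:
            name = name.rpartition("-")[0]
        if not name:
            raise ValueError(f"no precursor found for mature {rec.id}")
        pre_id = by_lower[name.lower()]
        pre = precursors[pre_id]
        start = pre.find(mature)
        if start < 0:
            raise ValueError(f"mature {rec.id} not found in precursor {pre_id}")
        out.append(MiRNAAnnotation(rec.id, pre_id, pre, start, mature))
    return out


def write_annotation_fastas(
    annotations: list[MiRNAAnnotation],
    precursor_fasta: str | Path,
    mature_fasta: str | Path,
) -> None:
    with open(precursor_fasta, "w") as fh:
        for a in annotations:
            fh.write(f">{a.precursor_id}\n{a.precursor_seq}\n")
    with open(mature_fasta, "w") as fh:
        for a in annotations:
            fh.write(f">{a.mirna_id}\n{a.mature_seq}\n")
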