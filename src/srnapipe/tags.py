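"""Read cleaning and tag collapsing for small-RNA libraries.

Raw reads are 3'-adapter-ligated inserts.  Cleaning trims the adapter
(located by the longest prefix of the adapter found at the read 3' end),
drops low-quality reads, reads without an adapter hit, reads with
ambiguous bases, and inserts outside the retained length window
(17-30 nt by default; shorter inserts are degradation products).
Surviving inserts are collapsed to unique tags with occurrence counts —
all downstream stages work on tags, not reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from ._util import canonical

__all__ = [
    "CleaningStats",
    "TagLibrary",
    "clean_reads",
    "clean_sequences",
    "collapse",
    "length_histogram",
    "parse_fastq",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "MIN_TAG_LEN",
    "MAX_TAG_LEN",
]

MIN_TAG_LEN = 17
MAX_TAG_LEN = 30
#: minimum adapter prefix that must be visible at the read 3' end.
MIN_ADAPTER_OVERLAP = 5


@dataclass
class CleaningStats:
    """Per-library read accounting; reasons partition the discarded reads."""

    total_reads: int = 0
    retained: int = 0
    discarded: Counter = field(default_factory=Counter)

    def check_conservation(self) -> bool:
        return self.total_reads == self.retained + sum(self.discarded.values())


@dataclass
class TagLibrary:
    """Unique tags with per-condition counts and clean-read totals.

    counts maps tag sequence -> [count_ck, count_hypoxia]; totals are the
    clean-read totals N2 (control) and N1 (hypoxia) used for TPM and the
    exact test.
    """

    counts: dict[str, list[int]]
    total_clean_ck: int
    total_clean_hypoxia: int

    @classmethod
    def from_conditions(cls, ck: Counter, hypoxia: Counter) -> "TagLibrary":
        counts: dict[str, list[int]] = {}
        for seq, n in ck.items():
            counts[seq] = [n, 0]
        for seq, n in hypoxia.items():
            counts.setdefault(seq, [0, 0])[1] = n
        return cls(counts, sum(ck.values()), sum(hypoxia.values()))

    def __len__(self) -> int:
        return len(self.counts)

    def total(self, condition: str) -> int:
        if condition == "ck":
            return self.total_clean_ck
        if condition == "hypoxia":
            return self.total_clean_hypoxia
        raise KeyError(condition)


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"FASTQ record {record_index}: {message}")


def parse_fastq(handle: TextIO | str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ stream.

    Thin wrapper over Bio.SeqIO's FastqGeneralIterator that re-raises
    parse failures as FastqParseError carrying the 1-based record index.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            yield from parse_fastq(fh)
        return
    idx = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            idx += 1
            yield title.split()[0], seq, qual
    except ValueError as exc:
        raise FastqParseError(idx + 1, str(exc)) from exc


def _locate_adapter(read: str, adapter: str) -> int:
    """Insert length, i.e. start of the adapter match, or -1 if absent.

    Looks for the full adapter anywhere, then for progressively shorter
    adapter prefixes as a read suffix (the adapter may run off the end
    of the read).
    """
    pos = read.find(adapter)
    if pos >= 0:
        return pos
    for k in range(min(len(adapter), len(read)) - 1, MIN_ADAPTER_OVERLAP - 1, -1):
        if read.endswith(adapter[:k]):
            return len(read) - k
    return -1


def clean_sequences(
    reads: Iterable[tuple[str, str]],
    adapter: str,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    min_quality: int = 20,
    require_adapter: bool = True,
) -> tuple[Counter, CleaningStats]:
    """Clean (sequence, quality) pairs; returns collapsed tag counts.

    quality may be "" to skip the quality filter (e.g. collapsed input).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = canonical(adapter)
    tags: Counter = Counter()
    stats = CleaningStats()
    qmin_char = chr(min_quality + 33)
    for seq, qual in reads:
        stats.total_reads += 1
        seq = canonical(seq)
        if qual and min(qual) < qmin_char:
            stats.discarded["low_quality"] += 1
            continue
        pos = _locate_adapter(seq, adapter)
        if pos < 0:
            if require_adapter:
                stats.discarded["no_adapter"] += 1
                continue
            insert = seq
        else:
            insert = seq[:pos]
        if len(insert) < min_len:
            stats.discarded["too_short"] += 1
            continue
        if len(insert) > max_len:
            stats.discarded["too_long"] += 1
            continue
        if any(c not in "ACGT" for c in insert):
            stats.discarded["ambiguous_base"] += 1
            continue
        tags[insert] += 1
        stats.retained += 1
    return tags, stats


def clean_counter(
    read_counts: Counter,
    adapter: str,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    require_adapter: bool = True,
) -> tuple[Counter, CleaningStats]:
    """Clean pre-collapsed reads (sequence -> multiplicity).

    Equivalent to cleaning the expanded read multiset (identical reads
    clean identically), but each unique sequence is processed once.
    Quality filtering does not apply (no per-read qualities).
    """
    tags: Counter = Counter()
    stats = CleaningStats()
    for seq, n in read_counts.items():
        unique, ustats = clean_sequences(
            [(seq, "")], adapter, min_len=min_len, max_len=max_len,
            require_adapter=require_adapter,
        )
        stats.total_reads += n
        if unique:
            ((insert, _),) = unique.items()
            tags[insert] += n
            stats.retained += n
        else:
            ((reason, _),) = ustats.discarded.items()
            stats.discarded[reason] += n
    return tags, stats


def clean_reads(
    fastq: TextIO | str | Path,
    adapter: str,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    min_quality: int = 20,
    require_adapter: bool = True,
) -> tuple[Counter, CleaningStats]:
    """Clean one condition's FASTQ into collapsed tag counts."""
    reads = ((seq, qual) for _, seq, qual in parse_fastq(fastq))
    return clean_sequences(
        reads, adapter, min_len=min_len, max_len=max_len,
        min_quality=min_quality, require_adapter=require_adapter,
    )


def collapse(ck: Counter, hypoxia: Counter) -> TagLibrary:
    return TagLibrary.from_conditions(ck, hypoxia)


def length_histogram(library: TagLibrary, condition: str) -> dict[int, int]:
    """Read-weighted tag-length distribution for one condition.

    Weights are read counts (a tag seen 500 times contributes 500), the
    quantity plotted in length-distribution summaries of sRNA libraries.
    """
    col = 0 if condition == "ck" else 1
    if condition not in ("ck", "hypoxia"):
        raise KeyError(condition)
    if library.total(condition) == 0:
        raise ValueError(f"library has no reads for condition {condition!r}")
    hist: dict[int, int] = {}
    for seq, counts in library.counts.items():
        if counts[col]:
            hist[len(seq)] = hist.get(len(seq), 0) + counts[col]
    return dict(sorted(hist.items()))


def write_collapsed_fasta(tags: Counter, path: str | Path) -> None:
    """Write tags in the `>tag<i>_x<count>` collapsed-read dialect."""
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(
            sorted(tags.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        ):
            fh.write(f">tag{i}_x{n}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> Counter:
    tags: Counter = Counter()
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:]
            else:
                if header is None:
                    raise ValueError("FASTA sequence before any header")
                count = int(header.rsplit("_x", 1)[1]) if "_x" in header else 1
                tags[canonical(line)] += count
                header = None
    return tags
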