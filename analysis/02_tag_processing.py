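#!/usr/bin/env python
"""Clean both libraries, collapse to tags, and table the length profile.

Reads the FASTQ files from step 01, trims the 3' adapter, applies the
quality/length filters (17-30 nt retained), and reports how many reads
survive and where the length distribution peaks (expected: 19-24 nt).
"""

from pathlib import Path

import pandas as pd

from srnapipe.simulate import DEFAULT_ADAPTER
from srnapipe.tags import TagLibrary, clean_reads, length_histogram, write_collapsed_fasta

BASE = Path(__file__).resolve().parent.parent / "results"
EXP = BASE / "experiment"


def main() -> None:
    out = BASE / "tags"
    out.mkdir(parents=True, exist_ok=True)
    counters = {}
    for cond in ("ck", "hypoxia"):
        tags, stats = clean_reads(EXP / f"{cond}.fastq", DEFAULT_ADAPTER)
        counters[cond] = tags
        write_collapsed_fasta(tags, out / f"{cond}_tags.fa")
        print(
            f"{cond}: {stats.retained}/{stats.total_reads} reads retained "
            f"({len(tags)} unique tags); discarded: {dict(stats.discarded)}"
        )
    library = TagLibrary.from_conditions(counters["ck"], counters["hypoxia"])
    rows = []
    for cond in ("ck", "hypoxia"):
        for length, n in length_histogram(library, cond).items():
            rows.append({"condition": cond, "length": length, "reads": n})
    hist = pd.DataFrame(rows)
    hist.to_csv(out / "length_histogram.tsv", sep="\t", index=False)
    for cond, sub in hist.groupby("condition"):
        mode = sub.loc[sub["reads"].idxmax(), "length"]
        frac = sub[sub["length"].between(19, 24)]["reads"].sum() / sub["reads"].sum()
        print(f"{cond}: modal tag length {mode} nt; {frac:.0%} of reads in 19-24 nt")


if __name__ == "__main__":
    main()
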