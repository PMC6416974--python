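#!/usr/bin/env python
"""TPM-normalize the known-miRNA counts and call differential expression.

Applies the exact two-library count test with the two-tier thresholds
(|log2 FC| >= 0.6 with 0.01 <= p < 0.05 "DE", p < 0.01 "significant"),
then checks the calls against the folds planted in step 01.
"""

import json
from pathlib import Path

import pandas as pd

from srnapipe.diffexpr import LibraryTotals, differential_expression
from srnapipe.report import ratio_report, summary_json
from srnapipe.tags import TagLibrary, read_collapsed_fasta

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = BASE / "diffexpr"
    out.mkdir(parents=True, exist_ok=True)
    library = TagLibrary.from_conditions(
        read_collapsed_fasta(BASE / "tags" / "ck_tags.fa"),
        read_collapsed_fasta(BASE / "tags" / "hypoxia_tags.fa"),
    )
    counts = pd.read_csv(BASE / "annotation" / "known_mirna_counts.tsv", sep="\t")
    totals = LibraryTotals(library.total_clean_hypoxia, library.total_clean_ck)
    de = differential_expression(counts, totals)
    de.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    ratio_report(de).to_csv(out / "abundance_ratios.tsv", sep="\t", index=False)
    summary = summary_json(de)
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    called = de[de["tier"] != "not_DE"]
    print(f"{len(de)} miRNAs tested; {len(called)} called "
          f"({summary['n_significant']} significant, {summary['n_de']} DE)")
    planted = json.loads((BASE / "experiment" / "planted_folds.json").read_text())
    for mid, fold in planted.items():
        row = de[de["mirna_id"] == mid]
        status = row.iloc[0]["tier"] if len(row) else "absent"
        fc = row.iloc[0]["fold_change"] if len(row) else float("nan")
        print(f"  planted {mid}: fold {fold} -> log2FC {fc:+.2f}, {status}")
    print(called[["mirna_id", "tpm_ck", "tpm_hypoxia", "abundance_ratio",
                  "fold_change", "p_two_sided", "tier", "direction"]]
          .head(10).to_string(index=False))


if __name__ == "__main__":
    main()
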