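#!/usr/bin/env python
"""Generate the synthetic two-condition experiment used by all later steps.

Creates two 100k-read libraries (control vs. hypoxia) over 100 known
miRNA hairpins plus two novel loci sharing one mature sequence, with
five abundant miRNAs planted at known fold-changes, and writes FASTQ,
reference FASTAs, the genome proxy and the truth table.
"""

import json
from pathlib import Path

from srnapipe.known import write_annotation_fastas
from srnapipe.simulate import SimulationConfig, generate_precursors, simulate_libraries

OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"
SEED = 20260928


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = SimulationConfig(seed=SEED)
    refs = generate_precursors(base)
    top = sorted(refs.base_weights, key=refs.base_weights.get, reverse=True)
    folds = dict(zip(top, (4.0, 2.5, 2.0, 0.5, 0.4)))
    cfg = SimulationConfig(seed=SEED, library_depth=100_000, fold_change_map=folds)
    sim = simulate_libraries(refs, cfg)

    for cond in ("ck", "hypoxia"):
        sim.write_fastq(cond, OUT / f"{cond}.fastq")
    write_annotation_fastas(refs.known, OUT / "precursors.fa", OUT / "mature.fa")
    with open(OUT / "genome.fa", "w") as fh:
        fh.write(">genome_proxy\n")
        for i in range(0, len(refs.genome), 80):
            fh.write(refs.genome[i : i + 80] + "\n")
    for cat, seqs in refs.category_seqs.items():
        with open(OUT / f"{cat}.fa", "w") as fh:
            for i, s in enumerate(seqs, 1):
                fh.write(f">{cat}_{i}\n{s}\n")
    sim.write_truth(OUT / "truth.tsv")
    cfg.to_json(OUT / "sim_config.json")
    (OUT / "planted_folds.json").write_text(json.dumps(folds, indent=2) + "\n")

    print(f"wrote {cfg.library_depth}-read libraries for 2 conditions to {OUT}")
    print(f"planted folds (control/hypoxia): {folds}")
    print(f"novel loci at {refs.novel_loci} share mature {refs.novel[0].mature_seq}")


if __name__ == "__main__":
    main()
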