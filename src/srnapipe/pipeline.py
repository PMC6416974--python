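"""End-to-end pipeline orchestration: clean -> annotate -> quantify ->
differential expression -> novel discovery, with every stage's table
written to the output directory and a deterministic JSON summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    CategoryReferences,
    GenomeIndex,
    categorize,
    category_table,
    map_to_genome,
)
from .diffexpr import LibraryTotals, differential_expression
from .known import read_annotations, quantify
from .novel import discover_novel, group_families
from .report import ratio_report, summary_json
from .tags import TagLibrary, clean_reads, length_histogram

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

#: categories removed before novel-miRNA discovery (known classes,
#: structural RNAs, repeat- and exon-derived tags).
NOVEL_EXCLUDED = {
    "miRNA", "Precursor", "rRNA", "tRNA", "snoRNA", "snRNA", "sRNA",
    "Repeat", "Exon", "un_mapped",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    fastq_ck: str
    fastq_hypoxia: str
    genome_fasta: str
    precursor_fasta: str
    mature_fasta: str
    category_fastas: dict[str, str] = field(default_factory=dict)
    outdir: str = "results"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 17
    max_len: int = 30
    min_quality: int = 20
    start_window: int = 2
    min_tpm: float = 1.0
    flank: int = 150
    min_support: int = 5
    seed: int = 0

    def validate(self) -> None:
        paths = [
            self.fastq_ck, self.fastq_hypoxia, self.genome_fasta,
            self.precursor_fasta, self.mature_fasta,
            *self.category_fastas.values(),
        ]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError("validate", f"missing input files: {missing}")
        if not (0 <= self.start_window <= 5) or self.min_len < 1 or self.flank < 0:
            raise PipelineError("validate", "parameter out of documented range")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def parameter_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units} | parameter_hash={config.parameter_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON).

    Re-running with an identical config writes byte-identical outputs:
    every stage is deterministic and no timestamps enter the tables.
    """
    from Bio import SeqIO

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    # clean
    ck_tags, ck_stats = stage(
        "clean", clean_reads, config.fastq_ck, config.adapter,
        min_len=config.min_len, max_len=config.max_len,
        min_quality=config.min_quality,
    )
    hyp_tags, hyp_stats = stage(
        "clean", clean_reads, config.fastq_hypoxia, config.adapter,
        min_len=config.min_len, max_len=config.max_len,
        min_quality=config.min_quality,
    )
    library = TagLibrary.from_conditions(ck_tags, hyp_tags)
    hist = pd.DataFrame(
        [
            {"length": l, "reads_ck": c, "reads_hypoxia": 0}
            for l, c in length_histogram(library, "ck").items()
        ]
    ).set_index("length")
    for l, c in length_histogram(library, "hypoxia").items():
        if l not in hist.index:
            hist.loc[l] = [0, 0]
        hist.loc[l, "reads_hypoxia"] = c
    _write_tsv(hist.sort_index().reset_index(), outdir / "length_histogram.tsv",
               config, "length=nt reads=count")

    # annotate
    genome = "".join(
        str(rec.seq) for rec in SeqIO.parse(config.genome_fasta, "fasta")
    )
    annotations = stage(
        "annotate", read_annotations, config.precursor_fasta, config.mature_fasta
    )
    references = stage(
        "annotate", CategoryReferences.from_fastas, config.category_fastas, annotations
    )
    genome_index = GenomeIndex(genome, config.min_len, config.max_len)
    assignment = stage(
        "annotate", categorize, library, genome_index, references, config.start_window
    )
    cat_table = category_table(library, assignment)
    _write_tsv(cat_table, outdir / "category_table.tsv", config,
               "reads=count frequency=percent_of_clean")

    # quantify known miRNAs
    counts = stage("quantify", quantify, library, annotations, config.start_window)
    _write_tsv(counts, outdir / "known_mirna_counts.tsv", config, "counts=raw_tags")

    # differential expression
    totals = LibraryTotals(n1=library.total_clean_hypoxia, n2=library.total_clean_ck)
    de = stage("diffexpr", differential_expression, counts, totals, config.min_tpm)
    _write_tsv(de, outdir / "differential_expression.tsv", config,
               "tpm=tags_per_million fold_change=log2(ck/hypoxia)")
    _write_tsv(ratio_report(de), outdir / "abundance_ratios.tsv", config,
               "ratio=linear_tpm_ratio")

    # novel discovery on unannotated mapped tags
    unannotated = {}
    for seq, cat in assignment.items():
        if cat in NOVEL_EXCLUDED:
            continue
        starts, pos = [], genome.find(seq)
        while pos >= 0:
            starts.append(pos)
            pos = genome.find(seq, pos + 1)
        if starts:
            unannotated[seq] = starts
    candidates = stage(
        "novel", discover_novel, unannotated, library, genome,
        config.flank, config.min_support,
    )
    families = group_families(candidates)
    _write_tsv(families, outdir / "novel_mirna_families.tsv", config,
               "tpm=tags_per_million loci=genome_0based")
    with open(outdir / "novel_structures.txt", "w") as fh:
        for c in candidates:
            fh.write(f">{c.family_id or 'candidate'} locus={c.locus[0]}-{c.locus[1]}\n")
            fh.write(c.structure.sequence + "\n" + c.structure.dot_bracket() + "\n")

    mapped, _ = map_to_genome(library, genome_index)
    mapped_reads_ck = sum(library.counts[s][0] for s in mapped)
    mapped_reads_hyp = sum(library.counts[s][1] for s in mapped)
    summary = {
        "version": __version__,
        "parameter_hash": config.parameter_hash(),
        "seed": config.seed,
        "clean_reads_ck": library.total_clean_ck,
        "clean_reads_hypoxia": library.total_clean_hypoxia,
        "discarded_ck": dict(ck_stats.discarded),
        "discarded_hypoxia": dict(hyp_stats.discarded),
        "mapped_reads_ck": mapped_reads_ck,
        "mapped_reads_hypoxia": mapped_reads_hyp,
        "known_mirnas_detected_ck": int((counts["count_ck"] > 0).sum()),
        "known_mirnas_detected_hypoxia": int((counts["count_hypoxia"] > 0).sum()),
        "novel_families": int(len(families)),
        "novel_loci": int(families["n_loci"].sum()) if len(families) else 0,
        **summary_json(de),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
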