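"""Ground-truthed two-condition small-RNA library simulator.

Emulates the sequencing design this pipeline analyses: two libraries
(control "ck" and treated "hypoxia"), each a multinomial sample of
`library_depth` reads over

* ~100 known miRNAs sitting on designed hairpin precursors, base
  abundance log-uniform over 10..10^4 expected TPM, with per-miRNA
  linear fold-changes (control/hypoxia) from `fold_change_map`;
* a small miRNA* fraction per expressed miRNA (maps to the precursor
  outside the mature window -> "Precursor" category);
* novel miRNA loci: `n_novel_loci` hairpins embedded in the genome at
  distinct positions but sharing one identical mature sequence (one
  family), expressed above the 100-TPM novel-acceptance threshold and
  slightly induced under hypoxia, plus sequenced star reads;
* contaminant categories (rRNA/tRNA/snoRNA/snRNA/sRNA/Repeat/Exon/
  Intron/Intergenic) as random fragments of embedded reference
  sequences, and an un_mapped class of random sequences absent from the
  genome.  Default fractions follow the proportions such libraries
  actually show (un_mapped dominating, miRNA a few percent).

Reads are the insert plus a 3' adapter, truncated to the instrument
read length, constant Phred quality.  Insert lengths concentrate on
19-24 nt.  All randomness flows from one seeded generator, so a fixed
seed gives byte-identical libraries and truth tables.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import revcomp
from .known import MiRNAAnnotation

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "generate_precursors",
    "simulate_libraries",
    "DEFAULT_ADAPTER",
]

#: documented adapter constant (Illumina TruSeq small-RNA 3' adapter).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: insert-length weights, 17..30 nt, concentrated on 19-24.
_LENGTHS = np.arange(17, 31)
_LENGTH_W = np.array(
    [0.5, 1.0, 6.0, 10.0, 22.0, 14.0, 14.0, 20.0, 4.0, 3.0, 2.0, 1.5, 1.0, 1.0]
)
_LENGTH_P = _LENGTH_W / _LENGTH_W.sum()

_DEFAULT_CONTAMINANTS = {
    "un_mapped": 0.61,
    "Repeat": 0.16,
    "Intergenic": 0.11,
    "rRNA": 0.026,
    "Exon": 0.026,
    "Intron": 0.026,
    "sRNA": 0.0013,
    "tRNA": 0.0003,
    "snoRNA": 0.0002,
    "snRNA": 0.0002,
}

_REF_PLAN = {  # category -> (n sequences, length each)
    "rRNA": (3, 400),
    "tRNA": (5, 75),
    "snoRNA": (4, 110),
    "snRNA": (3, 140),
    "sRNA": (5, 90),
    "Repeat": (3, 350),
    "Exon": (5, 400),
    # intron space is wide in real genomes; spreading the intron read
    # mass thin keeps chance loci from accumulating read support
    "Intron": (20, 500),
}


@dataclass
class SimulationConfig:
    n_known_mirnas: int = 100
    n_novel_loci: int = 2
    library_depth: int = 100_000
    #: miRNA id -> linear fold (control / hypoxia); unlisted miRNAs are 1.0.
    fold_change_map: dict[str, float] = field(default_factory=dict)
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTAMINANTS)
    )
    length_noise: float = 0.05
    seed: int = 0
    mature_len: int = 21
    flank_len: int = 8
    loop_len: int = 12
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    #: miRNA* reads as a fraction of each miRNA's mature abundance.
    star_fraction: float = 0.02
    #: novel-family expected TPM (control, hypoxia): highly expressed,
    #: mildly induced under hypoxia.
    novel_tpm: tuple[float, float] = (854.24, 1272.13)
    novel_star_tpm: float = 50.0

    def __post_init__(self) -> None:
        if self.n_known_mirnas < 1:
            raise ValueError("need at least one known miRNA")
        if self.library_depth < 0:
            raise ValueError("library_depth must be non-negative")
        if any(f <= 0 for f in self.fold_change_map.values()):
            raise ValueError("all fold changes must be positive")
        total = sum(self.contaminant_fractions.values())
        if total >= 1.0:
            raise ValueError("contaminant fractions must leave room for miRNA reads")
        if self.flank_len < 2:
            raise ValueError(
                "impossible geometry: the star 2-nt 3' overhang needs >= 2 nt "
                "of flank beyond the stem"
            )
        if self.loop_len < 3:
            raise ValueError("impossible geometry: hairpin loop must be >= 3 nt")
        if self.mature_len < 5:
            raise ValueError("impossible geometry: mature shorter than a stable stem")

    @property
    def mirna_fraction(self) -> float:
        """Read fraction left for miRNA-derived reads (mature + star + novel)."""
        return 1.0 - sum(self.contaminant_fractions.values())

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["novel_tpm"] = list(d["novel_tpm"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


@dataclass
class References:
    """Everything the downstream stages need to run on a simulation."""

    known: list[MiRNAAnnotation]
    novel: list[MiRNAAnnotation]  # ground truth only, not given to the pipeline
    genome: str
    category_seqs: dict[str, list[str]]
    novel_loci: list[tuple[int, int]]  # genome coordinates of novel precursors
    precursor_offsets: dict[str, int]  # precursor_id -> genome offset
    intergenic_regions: list[tuple[int, int]]
    #: fixed underlying expression of each known miRNA (relative weights,
    #: log-uniform over 3 decades); library draws sample around these.
    base_weights: dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _build_precursor(
    rng: np.random.Generator, mature: str, flank: int, loop_len: int
) -> tuple[str, int, int, str]:
    """Hairpin precursor: f5 + mature + loop + revcomp(mature) + revcomp(f5).

    The full 5' side (flank + mature) pairs the full 3' side, giving a
    perfect stem; the star is the 3'-arm duplex partner with the
    canonical 2-nt 3' overhang.  Returns (precursor, mature_start,
    star_start, star_seq).
    """
    f5 = _random_seq(rng, flank)
    # an A/C loop cannot pair internally or against the stem
    loop = "".join(rng.choice(["A", "C"], size=loop_len))
    pre = f5 + mature + loop + revcomp(mature) + revcomp(f5)
    mature_start = flank
    arm_start = flank + len(mature) + loop_len
    star_start = arm_start + 2
    star = pre[star_start : star_start + len(mature)]
    return pre, mature_start, star_start, star


def generate_precursors(config: SimulationConfig) -> References:
    """Designed precursors, novel loci, category references and the genome.

    Every precursor folds into a clean hairpin (checked property, not a
    runtime assertion); the `n_novel_loci` novel precursors share one
    mature sequence at distinct genome positions.
    """
    rng = np.random.default_rng(config.seed)
    L, flank, loop = config.mature_len, config.flank_len, config.loop_len
    if L < 5:
        raise ValueError("mature sequence too short for a stem")

    matures: set[str] = set()

    def fresh_mature() -> str:
        while True:
            m = _random_seq(rng, L)
            # avoid homopolymer-ish matures and duplicates
            if m not in matures and len(set(m)) >= 3:
                matures.add(m)
                return m

    known: list[MiRNAAnnotation] = []
    for i in range(1, config.n_known_mirnas + 1):
        m = fresh_mature()
        pre, ms, ss, star = _build_precursor(rng, m, flank, loop)
        known.append(
            MiRNAAnnotation(
                mirna_id=f"syn-miR{i}",
                precursor_id=f"syn-MIR{i}",
                precursor_seq=pre,
                mature_start=ms,
                mature_seq=m,
                star_start=ss,
                star_seq=star,
            )
        )

    novel_mature = fresh_mature()
    novel: list[MiRNAAnnotation] = []
    for i in range(1, config.n_novel_loci + 1):
        pre, ms, ss, star = _build_precursor(rng, novel_mature, flank, loop)
        novel.append(
            MiRNAAnnotation(
                mirna_id=f"syn-novel-miR{i}",
                precursor_id=f"syn-novel-locus{i}",
                precursor_seq=pre,
                mature_start=ms,
                mature_seq=novel_mature,
                star_start=ss,
                star_seq=star,
            )
        )

    category_seqs = {
        cat: [_random_seq(rng, length) for _ in range(n)]
        for cat, (n, length) in _REF_PLAN.items()
    }

    # genome: spacers | known precursors | category refs | novel loci
    parts: list[str] = []
    offsets: dict[str, int] = {}
    intergenic: list[tuple[int, int]] = []
    pos = 0

    def add(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    def spacer(n: int = 300) -> None:
        start = add(_random_seq(rng, n))
        intergenic.append((start, start + n))

    spacer(2000)
    for ann in known:
        offsets[ann.precursor_id] = add(ann.precursor_seq)
        spacer()
    for cat, seqs in category_seqs.items():
        for s in seqs:
            add(s)
            spacer()
    novel_loci = []
    for ann in novel:
        start = add(ann.precursor_seq)
        offsets[ann.precursor_id] = start
        novel_loci.append((start, start + len(ann.precursor_seq)))
        spacer(600)
    genome = "".join(parts)
    w = 10 ** rng.uniform(1, 4, size=config.n_known_mirnas)
    base_weights = {a.mirna_id: float(x) for a, x in zip(known, w)}
    return References(
        known=known,
        novel=novel,
        genome=genome,
        category_seqs=category_seqs,
        novel_loci=novel_loci,
        precursor_offsets=offsets,
        intergenic_regions=intergenic,
        base_weights=base_weights,
    )


def _isomir(
    rng: np.random.Generator, ann: MiRNAAnnotation, p: float
) -> str:
    """Mature sequence with probability-p 1-nt end variation (precursor
    context supplies extensions); 5' shifts stay within the ±2 window."""
    if rng.random() >= p:
        return ann.mature_seq
    pre, s, e = ann.precursor_seq, ann.mature_start, ann.mature_end
    moves = []
    if e - s > 18:
        moves += [(0, -1), (1, 0)]
    if e < len(pre):
        moves.append((0, 1))
    if s > 0:
        moves.append((-1, 0))
    ds, de = moves[rng.integers(len(moves))]
    return pre[s + ds : e + de]


class SimulatedData:
    """Reads, truth table and references for one simulated experiment."""

    def __init__(
        self,
        config: SimulationConfig,
        refs: References,
        reads: dict[str, list[str]],
        truth: pd.DataFrame,
    ):
        self.config = config
        self.refs = refs
        self.reads = reads  # condition -> list of insert sequences
        self.truth = truth

    def insert_counter(self, condition: str) -> Counter:
        """Collapsed insert counts — the fast path that bypasses FASTQ."""
        return Counter(self.reads[condition])

    def write_fastq(self, condition: str, path: str | Path) -> None:
        cfg = self.config
        with open(path, "w") as fh:
            for i, insert in enumerate(self.reads[condition], start=1):
                read = (insert + cfg.adapter)[: cfg.read_length]
                fh.write(f"@sim_{condition}_{i}\n{read}\n+\n{'I' * len(read)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_libraries(refs: References, config: SimulationConfig) -> SimulatedData:
    """Multinomial two-library sample with a complete truth table.

    Per condition, expected read fractions are assembled for every class
    (each miRNA, its star, the novel family and star, each contaminant
    category), normalized, and `library_depth` reads drawn in one
    multinomial.  Truth counts therefore sum exactly to the depth.
    """
    if config.library_depth == 0:
        raise ValueError("library_depth is zero: refusing to simulate empty libraries")
    unknown = set(config.fold_change_map) - {a.mirna_id for a in refs.known}
    if unknown:
        raise ValueError(f"fold_change_map keys not in annotations: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed + 1)
    weights = refs.base_weights
    wsum = sum(weights.values())
    mir_budget = config.mirna_fraction
    novel_ck = config.novel_tpm[0] / 1e6
    novel_hyp = config.novel_tpm[1] / 1e6
    novel_star = config.novel_star_tpm / 1e6 if config.n_novel_loci else 0.0
    known_budget = mir_budget - (max(novel_ck, novel_hyp) + novel_star) - 1e-4
    if known_budget <= 0:
        raise ValueError("contaminant fractions leave no budget for known miRNAs")

    # class list: (name, kind, frac_ck, frac_hyp)
    classes: list[tuple[str, str, float, float]] = []
    for ann in refs.known:
        base = weights[ann.mirna_id] / wsum * known_budget
        fold = config.fold_change_map.get(ann.mirna_id, 1.0)
        frac_hyp = base
        frac_ck = base * fold
        classes.append((ann.mirna_id, "miRNA", frac_ck, frac_hyp))
        if config.star_fraction > 0:
            classes.append(
                (
                    ann.mirna_id + "*",
                    "Precursor",
                    frac_ck * config.star_fraction,
                    frac_hyp * config.star_fraction,
                )
            )
    if config.n_novel_loci:
        classes.append(("novel-family", "Intergenic", novel_ck, novel_hyp))
        classes.append(("novel-family*", "Intergenic", novel_star, novel_star))
    for cat, frac in config.contaminant_fractions.items():
        classes.append((cat, cat, frac, frac))

    names = [c[0] for c in classes]
    kinds = {c[0]: c[1] for c in classes}
    frac = np.array([[c[2] for c in classes], [c[3] for c in classes]])
    frac /= frac.sum(axis=1, keepdims=True)

    counts = {
        cond: rng.multinomial(config.library_depth, frac[i])
        for i, cond in enumerate(("ck", "hypoxia"))
    }

    ann_by_id = {a.mirna_id: a for a in refs.known}
    reads: dict[str, list[str]] = {"ck": [], "hypoxia": []}
    rows = []
    for ci, name in enumerate(names):
        kind = kinds[name]
        for cond in ("ck", "hypoxia"):
            n = int(counts[cond][ci])
            if n == 0:
                continue
            reads[cond].extend(
                _emit_reads(rng, name, kind, n, refs, config, ann_by_id)
            )
        rows.append(
            {
                "class_id": name,
                "kind": kind,
                "count_ck": int(counts["ck"][ci]),
                "count_hypoxia": int(counts["hypoxia"][ci]),
                "expected_frac_ck": frac[0][ci],
                "expected_frac_hypoxia": frac[1][ci],
            }
        )
    truth = pd.DataFrame(rows)
    return SimulatedData(config, refs, reads, truth)


def _emit_reads(
    rng: np.random.Generator,
    name: str,
    kind: str,
    n: int,
    refs: References,
    config: SimulationConfig,
    ann_by_id: dict[str, MiRNAAnnotation],
) -> list[str]:
    if kind == "miRNA":
        ann = ann_by_id[name]
        return [_isomir(rng, ann, config.length_noise) for _ in range(n)]
    if name.endswith("*") and name != "novel-family*":
        return [ann_by_id[name[:-1]].star_seq] * n
    if name == "novel-family":
        # reads are split over the loci but are sequence-identical
        return [refs.novel[0].mature_seq] * n
    if name == "novel-family*":
        stars = [a.star_seq for a in refs.novel]
        picks = rng.integers(0, len(stars), size=n)
        return [stars[i] for i in picks]
    if kind == "un_mapped":
        lens = rng.choice(_LENGTHS, size=n, p=_LENGTH_P)
        return [_random_seq(rng, int(l)) for l in lens]
    if kind == "Intergenic":
        # regions weighted by length -> uniform per-position coverage
        pool = refs.intergenic_regions
        weights = np.array([e - s for s, e in pool], dtype=float)
        weights /= weights.sum()
        lens = rng.choice(_LENGTHS, size=n, p=_LENGTH_P)
        region_idx = rng.choice(len(pool), size=n, p=weights)
        out = []
        for l, ri in zip(lens, region_idx):
            s, e = pool[ri]
            off = int(rng.integers(s, e - int(l)))
            out.append(refs.genome[off : off + int(l)])
        return out
    # fragment of a category reference sequence
    seqs = refs.category_seqs[kind]
    lens = rng.choice(_LENGTHS, size=n, p=_LENGTH_P)
    idx = rng.integers(0, len(seqs), size=n)
    out = []
    for l, si in zip(lens, idx):
        ref = seqs[si]
        off = int(rng.integers(0, len(ref) - int(l)))
        out.append(ref[off : off + int(l)])
    return out
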