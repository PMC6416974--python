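"""Novel miRNA discovery from unannotated genome-mapped tags.

Tags that survive category filtering (no rRNA/tRNA/snoRNA/snRNA/sRNA
hit, not repeat- or exon-derived, not a known miRNA) and have enough
read support seed candidate loci.  For each such tag two genomic
windows are excised — one extending upstream, one downstream — so the
tag is tested as the 3p and as the 5p arm of a putative precursor.
Windows are folded by base-pair maximization and judged against
plant-miRNA annotation criteria: the mature must sit on one arm of the
hairpin without spanning the loop, pair with its star partner with at
most 4 unpaired positions and no bulge longer than 2 nt, and have at
least 75% of its bases paired.  The star sequence is the duplex partner
with the canonical 2-nt 3' overhang (mature[i] pairs star[L-3-i]).
A structurally sound candidate is accepted as a novel miRNA only if its
star is actually sequenced (±1 nt end tolerance) or its abundance
exceeds 100 TPM in at least one library.  Accepted candidates sharing
one mature sequence from different loci collapse into one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import canonical
from .fold import HairpinStructure, fold_hairpin
from .tags import TagLibrary

__all__ = [
    "CandidateWindow",
    "NovelCandidate",
    "excise_candidates",
    "evaluate_candidate",
    "discover_novel",
    "group_families",
    "DEFAULT_FLANK",
    "MIN_SUPPORT",
    "NOVEL_TPM_THRESHOLD",
]

DEFAULT_FLANK = 150
MIN_SUPPORT = 5
NOVEL_TPM_THRESHOLD = 100.0
#: structural thresholds on the mature/star duplex.
MAX_DUPLEX_MISMATCHES = 4
MAX_DUPLEX_BULGE = 2
MIN_PAIRED_FRACTION = 0.75


@dataclass(frozen=True)
class CandidateWindow:
    """An excised genomic window to be folded; coordinates 0-based half-open."""

    tag: str
    genome_start: int  # of the window
    genome_end: int
    tag_offset: int  # tag start within the window
    clipped: bool = False


@dataclass
class NovelCandidate:
    mature_seq: str
    locus: tuple[int, int]
    structure: HairpinStructure | None = None
    star_seq: str | None = None
    star_detected: bool = False
    tpm_ck: float = 0.0
    tpm_hypoxia: float = 0.0
    duplex_mismatches: int = 0
    duplex_bulge: int = 0
    paired_fraction: float = 0.0
    structural_pass: bool = False
    accepted: bool = False
    family_id: str | None = None


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos >= 0:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def excise_candidates(
    unannotated: dict[str, list[int]],
    library: TagLibrary,
    genome: str,
    flank: int = DEFAULT_FLANK,
    min_support: int = MIN_SUPPORT,
) -> list[CandidateWindow]:
    """Candidate windows around supported unannotated tags.

    Parameters
    ----------
    unannotated
        tag sequence -> genome occurrence starts (already stripped of
        known-miRNA and contaminant categories).
    library
        supplies read support (summed over both conditions).
    """
    genome = canonical(genome)
    windows = []
    for seq, starts in unannotated.items():
        n_ck, n_hyp = library.counts.get(seq, (0, 0))
        if n_ck + n_hyp < min_support:
            continue
        for s in starts:
            e = s + len(seq)
            for ws, we in ((s - flank, e), (s, e + flank)):
                clipped = ws < 0 or we > len(genome)
                cs, ce = max(ws, 0), min(we, len(genome))
                windows.append(
                    CandidateWindow(seq, cs, ce, s - cs, clipped=clipped)
                )
    return windows


def _star_from_structure(
    structure: HairpinStructure, m_start: int, m_len: int
) -> tuple[int, int] | None:
    """Star interval (half-open, window coords) from the duplex geometry.

    In the canonical duplex mature[i] pairs star[L-3-i], so a paired
    mature base k with partner q places star[0] at q - (L - 3 - k).
    Each paired mature base votes for an offset; the majority wins, so a
    stray pair into a different helix cannot hijack the duplex frame.
    Returns None when nothing pairs or the implied star falls outside
    the window — no admissible duplex exists there.
    """
    pm = structure.pair_map
    votes: dict[int, int] = {}
    for k in range(m_len):
        q = pm[m_start + k]
        if q >= 0:
            t = q - (m_len - 3 - k)
            votes[t] = votes.get(t, 0) + 1
    if not votes:
        return None
    t = max(votes, key=lambda t: (votes[t], -abs(t)))
    if 0 <= t and t + m_len <= len(structure.sequence):
        return (t, t + m_len)
    return None


def _duplex_metrics(
    structure: HairpinStructure, m_start: int, m_len: int, star: tuple[int, int] | None
) -> tuple[int, int, float]:
    """(mismatches, max bulge, paired fraction) over the mature arm.

    A mature position is a mismatch when unpaired or paired outside the
    star window; the bulge is the longest run of consecutive mismatches.
    """
    pm = structure.pair_map
    mismatches = bulge = run = 0
    paired = 0
    for k in range(m_len):
        q = pm[m_start + k]
        ok = q >= 0 and star is not None and star[0] <= q < star[1]
        if q >= 0:
            paired += 1
        # the 2-nt 3' overhang is unpaired by design; don't penalize it
        if not ok and k < m_len - 2:
            mismatches += 1
            run += 1
            bulge = max(bulge, run)
        else:
            run = 0
    return mismatches, bulge, paired / m_len


def _mature_on_one_arm(structure: HairpinStructure, m_start: int, m_len: int) -> bool:
    """True iff mature partners all sit on the same side and none is internal."""
    pm = structure.pair_map
    partners = [pm[m_start + k] for k in range(m_len) if pm[m_start + k] >= 0]
    if not partners:
        return False
    m_end = m_start + m_len
    if any(m_start <= q < m_end for q in partners):
        return False  # self-pairing: mature spans the loop
    return all(q >= m_end for q in partners) or all(q < m_start for q in partners)


def _tag_variants(seq: str, window: str, offset: int) -> set[str]:
    """The sequence ±1 nt at either end, using window context to extend."""
    variants = set()
    L = len(seq)
    for ds in (-1, 0, 1):
        for de in (-1, 0, 1):
            s, e = offset + ds, offset + L + de
            if 0 <= s < e <= len(window):
                variants.add(window[s:e])
    return variants


def evaluate_candidate(
    structure: HairpinStructure,
    window: CandidateWindow,
    library: TagLibrary,
) -> NovelCandidate:
    """Judge one folded window; returns the candidate with all evidence.

    Expression is the summed count of library tags whose start lies
    within ±2 nt of the candidate mature start in the window (the same
    5'-isomiR window used for known miRNAs).
    """
    seq = structure.sequence
    mature = canonical(window.tag)
    m_start, m_len = window.tag_offset, len(mature)
    if seq[m_start : m_start + m_len] != mature:
        raise ValueError("mature tag not found at its window offset")

    cand = NovelCandidate(
        mature_seq=mature,
        locus=(window.genome_start, window.genome_end),
        structure=structure,
    )
    star_iv = _star_from_structure(structure, m_start, m_len)
    mm, bulge, pfrac = _duplex_metrics(structure, m_start, m_len, star_iv)
    cand.duplex_mismatches, cand.duplex_bulge, cand.paired_fraction = mm, bulge, pfrac
    cand.structural_pass = (
        star_iv is not None  # an admissible duplex frame exists in-window
        and _mature_on_one_arm(structure, m_start, m_len)
        and mm <= MAX_DUPLEX_MISMATCHES
        and bulge <= MAX_DUPLEX_BULGE
        and pfrac >= MIN_PAIRED_FRACTION
    )
    if star_iv is not None:
        cand.star_seq = seq[star_iv[0] : star_iv[1]]
        star_set = _tag_variants(cand.star_seq, seq, star_iv[0])
        cand.star_detected = any(
            sum(library.counts.get(v, (0, 0))) > 0 for v in star_set
        )

    # abundance: mature plus 5' isomiRs within ±2 nt start
    n_ck = n_hyp = 0
    for ds in range(-2, 3):
        s = m_start + ds
        if s < 0:
            continue
        for e in range(s + m_len - 2, s + m_len + 3):
            if e <= s or e > len(seq):
                continue
            c = library.counts.get(seq[s:e])
            if c:
                n_ck += c[0]
                n_hyp += c[1]
    if library.total_clean_ck:
        cand.tpm_ck = n_ck / library.total_clean_ck * 1e6
    if library.total_clean_hypoxia:
        cand.tpm_hypoxia = n_hyp / library.total_clean_hypoxia * 1e6

    cand.accepted = cand.structural_pass and (
        cand.star_detected
        or max(cand.tpm_ck, cand.tpm_hypoxia) > NOVEL_TPM_THRESHOLD
    )
    return cand


def discover_novel(
    unannotated: dict[str, list[int]],
    library: TagLibrary,
    genome: str,
    flank: int = DEFAULT_FLANK,
    min_support: int = MIN_SUPPORT,
    engine=None,
) -> list[NovelCandidate]:
    """Full discovery pass: excise, fold, evaluate, keep accepted loci.

    Each supported tag is tested as a 5p and a 3p arm at three flank
    scales (flank, flank/2, flank/4): base-pair maximization can trade
    a genuine stem for scattered context pairs in a long window, and a
    tighter excision around the same tag recovers it.  The best-scoring
    window per (tag, locus) wins; one candidate is reported per locus.
    """
    genome_c = canonical(genome)
    windows: list[CandidateWindow] = []
    for f in {flank, max(flank // 2, 25), max(flank // 4, 25)}:
        windows.extend(
            excise_candidates(
                unannotated, library, genome_c, flank=f, min_support=min_support
            )
        )
    best: dict[tuple[str, int], NovelCandidate] = {}
    for w in windows:
        if w.genome_end - w.genome_start < 50:
            continue
        structure = fold_hairpin(genome_c[w.genome_start : w.genome_end], engine=engine)
        cand = evaluate_candidate(structure, w, library)
        key = (w.tag, w.genome_start + w.tag_offset)
        prev = best.get(key)
        score = (cand.accepted, cand.structural_pass, cand.paired_fraction)
        if prev is None or score > (
            prev.accepted, prev.structural_pass, prev.paired_fraction
        ):
            best[key] = cand
    accepted = [c for c in best.values() if c.accepted]
    return _collapse_overlapping_loci(accepted)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _collapse_overlapping_loci(cands: list[NovelCandidate]) -> list[NovelCandidate]:
    """One reported miRNA per hairpin locus.

    A well-expressed star strand can seed its own window and pass every
    rule (its "star" is the mature strand, which is certainly
    sequenced), so both arms of one duplex may arrive here as separate
    accepted candidates with overlapping windows.  A hairpin defines a
    single miRNA: among accepted candidates whose loci overlap, only
    the most abundant is reported.
    """
    keep: list[NovelCandidate] = []
    for c in sorted(cands, key=lambda c: -max(c.tpm_ck, c.tpm_hypoxia)):
        if not any(_overlap(c.locus, k.locus) for k in keep):
            keep.append(c)
    return keep


def group_families(candidates: list[NovelCandidate]) -> pd.DataFrame:
    """Collapse accepted candidates with identical mature sequences.

    Loci sharing one mature sequence are one miRNA family; expression is
    reported once per family since their reads are indistinguishable.
    """
    fams: dict[str, list[NovelCandidate]] = {}
    for c in candidates:
        fams.setdefault(c.mature_seq, []).append(c)
    rows = []
    for idx, (mature, members) in enumerate(
        sorted(fams.items(), key=lambda kv: kv[0]), start=1
    ):
        fam_id = f"novel-fam-{idx}"
        for m in members:
            m.family_id = fam_id
        rows.append(
            {
                "family_id": fam_id,
                "mature_seq": mature,
                "n_loci": len({m.locus for m in members}),
                "loci": ";".join(f"{s}-{e}" for s, e in sorted({m.locus for m in members})),
                "star_detected": any(m.star_detected for m in members),
                "tpm_ck": members[0].tpm_ck,
                "tpm_hypoxia": members[0].tpm_hypoxia,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "mature_seq", "n_loci", "loci",
            "star_detected", "tpm_ck", "tpm_hypoxia",
        ],
    )
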