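"""Novel-miRNA candidate excision, evaluation and family grouping."""

from __future__ import annotations

from collections import Counter

import pytest

from srnapipe._util import revcomp
from srnapipe.annotate import CategoryReferences, categorize
from srnapipe.fold import fold_hairpin
from srnapipe.novel import (
    CandidateWindow,
    discover_novel,
    evaluate_candidate,
    excise_candidates,
    group_families,
)
from srnapipe.simulate import SimulationConfig, generate_precursors
from srnapipe.tags import TagLibrary


def _lib(items: dict[str, tuple[int, int]], totals=(10_000, 10_000)) -> TagLibrary:
    lib = TagLibrary.from_conditions(
        Counter({s: c for s, (c, _) in items.items() if c}),
        Counter({s: h for s, (_, h) in items.items() if h}),
    )
    # allow fixing totals independently of the listed tags (TPM control)
    lib.total_clean_ck, lib.total_clean_hypoxia = totals
    return lib


MATURE = "TTGACAGAAGATAGAGAGCAC"  # 21 nt
HAIRPIN = "ACGTACGT" + MATURE + "AACCAACCAACC" + revcomp(MATURE) + revcomp("ACGTACGT")
STAR = HAIRPIN[(8 + 21 + 12 + 2):(8 + 21 + 12 + 2 + 21)]


def planted_genome() -> tuple[str, int]:
    """Genome with the hairpin at a known offset."""
    left = "GATTACAGATTACAGATTACA" * 10
    right = "TTAGCCTTAGCCTTAGCC" * 12
    return left + HAIRPIN + right, len(left)


class TestExcision:
    def test_window_arithmetic(self):
        genome, off = planted_genome()
        tag_start = off + 8
        lib = _lib({MATURE: (6, 2)})
        wins = excise_candidates({MATURE: [tag_start]}, lib, genome, flank=150)
        spans = {(w.genome_start, w.genome_end) for w in wins}
        assert spans == {
            (tag_start - 150, tag_start + 21),
            (tag_start, tag_start + 21 + 150),
        }
        assert all(not w.clipped for w in wins)

    def test_window_clipped_at_sequence_bounds(self):
        lib = _lib({MATURE: (9, 0)})
        genome = MATURE + "ACGT" * 30
        wins = excise_candidates({MATURE: [0]}, lib, genome, flank=150)
        assert any(w.clipped for w in wins)
        assert all(w.genome_start >= 0 and w.genome_end <= len(genome) for w in wins)

    def test_low_support_tags_skipped(self):
        lib = _lib({MATURE: (2, 2)})
        assert excise_candidates({MATURE: [0]}, lib, "A" * 500, min_support=5) == []


class TestEvaluate:
    def window(self):
        genome, off = planted_genome()
        start = off + 8
        w = CandidateWindow(MATURE, start, start + 21 + 150, 0)
        seq = genome[w.genome_start : w.genome_end]
        return fold_hairpin(seq), w

    def test_star_sequence_from_duplex_geometry(self):
        structure, w = self.window()
        cand = evaluate_candidate(structure, w, _lib({MATURE: (6, 0)}))
        assert cand.star_seq == STAR
        assert cand.structural_pass
        assert cand.paired_fraction == 1.0
        assert cand.duplex_mismatches == 0

    @pytest.mark.parametrize(
        "star_count,tpm_counts,accepted",
        [
            (1, (2, 0), True),     # star present, low abundance
            (0, (2000, 0), True),  # no star, >100 TPM in one library
            (0, (500, 500), False),  # no star, 50 TPM in both
        ],
    )
    def test_acceptance_rule(self, star_count, tpm_counts, accepted):
        structure, w = self.window()
        items = {MATURE: tpm_counts}
        if star_count:
            items[STAR] = (star_count, 0)
        cand = evaluate_candidate(
            structure, w, _lib(items, totals=(10_000_000, 10_000_000))
        )
        assert cand.structural_pass
        assert cand.star_detected is bool(star_count)
        assert cand.accepted is accepted

    def test_star_detection_tolerates_one_nt_ends(self):
        structure, w = self.window()
        seq = structure.sequence
        star_pos = seq.find(STAR)
        shifted = seq[star_pos + 1 : star_pos + 21]  # 5' trimmed by 1
        cand = evaluate_candidate(
            structure, w, _lib({MATURE: (6, 0), shifted: (1, 0)})
        )
        assert cand.star_detected

    def test_unstructured_window_fails(self):
        tag = "GATTACAGATTACAGATTACA"
        genome, _ = planted_genome()
        w = CandidateWindow(tag, 0, 171, 0)
        structure = fold_hairpin(genome[0:171])
        cand = evaluate_candidate(structure, w, _lib({tag: (50, 50)}))
        assert not cand.structural_pass
        assert not cand.accepted

    def test_mature_absent_from_window_errors(self):
        structure, w = self.window()
        bad = CandidateWindow("A" * 21, w.genome_start, w.genome_end, 0)
        with pytest.raises(ValueError):
            evaluate_candidate(structure, bad, _lib({MATURE: (1, 0)}))


class TestFamilies:
    def cand(self, mature, locus, **kw):
        from srnapipe.novel import NovelCandidate

        c = NovelCandidate(mature_seq=mature, locus=locus)
        for k, v in kw.items():
            setattr(c, k, v)
        return c

    def test_same_mature_two_loci_one_family(self):
        fams = group_families(
            [
                self.cand(MATURE, (100, 271), tpm_ck=800.0),
                self.cand(MATURE, (900, 1071), tpm_ck=800.0),
            ]
        )
        assert len(fams) == 1
        assert fams.iloc[0]["n_loci"] == 2

    def test_different_matures_two_families(self):
        fams = group_families(
            [self.cand(MATURE, (0, 171)), self.cand(revcomp(MATURE), (500, 671))]
        )
        assert len(fams) == 2

    def test_empty_input(self):
        assert group_families([]).empty


class TestPipelineOrder:
    def test_known_and_contaminant_tags_never_reach_discovery(self, sim_library, refs, genome_index, category_refs):
        """rRNA-, known-miRNA- etc. tags are excluded upstream, so no
        reported novel locus overlaps a known precursor."""
        library, _ = sim_library
        assignment = categorize(library, genome_index, category_refs)
        unannotated = {}
        for seq, cat in assignment.items():
            if cat not in ("Intergenic", "Intron"):
                continue
            pos = refs.genome.find(seq)
            if pos >= 0:
                unannotated[seq] = [pos]
        for seq in unannotated:
            assert assignment[seq] in ("Intergenic", "Intron")
        cands = discover_novel(unannotated, library, refs.genome)
        known_spans = [
            (off, off + len(a.precursor_seq))
            for a in refs.known
            for off in [refs.precursor_offsets[a.precursor_id]]
        ]
        for c in cands:
            for s, e in known_spans:
                assert not (c.locus[0] < e and s < c.locus[1])

    def test_planted_loci_recovered_as_one_family(self, sim_library, refs, genome_index, category_refs):
        library, _ = sim_library
        assignment = categorize(library, genome_index, category_refs)
        unannotated = {}
        for seq, cat in assignment.items():
            if cat not in ("Intergenic", "Intron"):
                continue
            starts, pos = [], refs.genome.find(seq)
            while pos >= 0:
                starts.append(pos)
                pos = refs.genome.find(seq, pos + 1)
            unannotated[seq] = starts
        fams = group_families(discover_novel(unannotated, library, refs.genome))
        target = fams[fams["mature_seq"] == refs.novel[0].mature_seq]
        assert len(target) == 1
        assert target.iloc[0]["n_loci"] == 2
        # the family is abundant enough to be accepted on TPM alone at
        # this shallow fixture depth; star support is checked at full
        # depth in the recovery suite
        assert target.iloc[0]["tpm_hypoxia"] > 100
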