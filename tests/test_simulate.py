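"""Synthetic-data generator: construction guarantees and sampling truth."""

from __future__ import annotations

import numpy as np
import pytest

from srnapipe.fold import fold_hairpin
from srnapipe.novel import CandidateWindow, evaluate_candidate
from srnapipe.simulate import (
    SimulationConfig,
    generate_precursors,
    simulate_libraries,
)
from srnapipe.tags import TagLibrary


class TestConfig:
    def test_fraction_budget_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(contaminant_fractions={"un_mapped": 1.2})

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fold_change_map={"syn-miR1": 0.0})

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            SimulationConfig(flank_len=1)
        with pytest.raises(ValueError, match="geometry"):
            SimulationConfig(loop_len=2)

    def test_mirna_fraction_complements_contaminants(self):
        cfg = SimulationConfig()
        assert cfg.mirna_fraction + sum(
            cfg.contaminant_fractions.values()
        ) == pytest.approx(1.0, abs=1e-9)


class TestPrecursors:
    def test_novel_loci_share_one_mature_at_distinct_positions(self, refs):
        assert len(refs.novel) == 2
        matures = {a.mature_seq for a in refs.novel}
        assert len(matures) == 1
        (s1, e1), (s2, e2) = refs.novel_loci
        assert e1 <= s2 or e2 <= s1  # distinct, non-overlapping loci
        for (s, e), ann in zip(refs.novel_loci, refs.novel):
            assert refs.genome[s:e] == ann.precursor_seq

    def test_mature_maps_at_annotated_offset(self, refs):
        for ann in refs.known:
            assert (
                ann.precursor_seq[ann.mature_start : ann.mature_end] == ann.mature_seq
            )

    def test_every_precursor_passes_the_hairpin_criteria(self, refs):
        """Generated precursors must survive the discovery-side structural
        evaluation they were designed for."""
        from collections import Counter

        for ann in refs.known[:15] + refs.novel:
            structure = fold_hairpin(ann.precursor_seq)
            w = CandidateWindow(
                ann.mature_seq, 0, len(ann.precursor_seq), ann.mature_start
            )
            lib = TagLibrary.from_conditions(
                Counter({ann.mature_seq: 1}), Counter()
            )
            cand = evaluate_candidate(structure, w, lib)
            assert cand.structural_pass
            assert cand.star_seq == ann.star_seq

    def test_star_has_canonical_two_nt_overhang(self, refs):
        ann = refs.known[0]
        # star[0] pairs mature[L-3] in the designed duplex
        L = len(ann.mature_seq)
        structure = fold_hairpin(ann.precursor_seq)
        pm = structure.pair_map
        assert pm[ann.mature_start + L - 3] == ann.star_start


class TestLibraries:
    def test_truth_counts_sum_to_depth(self, sim_library, base_config):
        _, sim = sim_library
        assert sim.truth["count_ck"].sum() == base_config.library_depth
        assert sim.truth["count_hypoxia"].sum() == base_config.library_depth

    def test_identical_seed_identical_output(self, refs, base_config):
        a = simulate_libraries(refs, base_config)
        b = simulate_libraries(refs, base_config)
        assert a.truth.equals(b.truth)
        assert a.reads == b.reads

    def test_fold_change_visible_in_truth_counts(self, refs):
        """Planted control/hypoxia ratio is recovered within 3 binomial SD
        (delta method on the count ratio, using the truth expectations)."""
        target = max(refs.base_weights, key=refs.base_weights.get)
        fold = 4.0
        cfg = SimulationConfig(
            seed=7, library_depth=100_000, fold_change_map={target: fold}
        )
        sim = simulate_libraries(refs, cfg)
        row = sim.truth.set_index("class_id").loc[target]
        n_ck, n_hyp = row["count_ck"], row["count_hypoxia"]
        e_ck = cfg.library_depth * row["expected_frac_ck"]
        e_hyp = cfg.library_depth * row["expected_frac_hypoxia"]
        assert min(e_ck, e_hyp) > 50  # abundant enough for the check
        ratio = n_ck / n_hyp
        sd = fold * np.sqrt(1 / e_ck + 1 / e_hyp)
        assert abs(ratio - fold) <= 3 * sd

    def test_depth_zero_rejected(self, refs):
        with pytest.raises(ValueError, match="empty"):
            simulate_libraries(refs, SimulationConfig(library_depth=0, seed=1))

    def test_unknown_fold_key_rejected(self, refs):
        cfg = SimulationConfig(fold_change_map={"no-such-mir": 2.0}, seed=1)
        with pytest.raises(ValueError, match="no-such-mir"):
            simulate_libraries(refs, cfg)

    def test_fastq_round_trip_preserves_tags(self, refs, tmp_path):
        from srnapipe.tags import clean_reads

        cfg = SimulationConfig(seed=9, library_depth=2000)
        sim = simulate_libraries(refs, cfg)
        path = tmp_path / "ck.fastq"
        sim.write_fastq("ck", path)
        tags, stats = clean_reads(path, cfg.adapter)
        assert stats.total_reads == 2000
        # every simulated insert within the length window comes back
        expected = sim.insert_counter("ck")
        recoverable = {s: n for s, n in expected.items() if 17 <= len(s) <= 30}
        assert sum(tags.values()) == sum(recoverable.values())

    def test_null_simulation_calls_nothing(self, refs):
        """All folds at 1.0: the DE stage calls no miRNA beyond the
        nominal false-positive allowance."""
        from srnapipe.diffexpr import LibraryTotals, differential_expression
        from srnapipe.experiments import simulate_to_library
        from srnapipe.known import quantify

        cfg = SimulationConfig(seed=77, library_depth=50_000)
        library, _ = simulate_to_library(refs, cfg)
        counts = quantify(library, refs.known)
        de = differential_expression(
            counts, LibraryTotals(library.total_clean_hypoxia, library.total_clean_ck)
        )
        called = (de["tier"] != "not_DE").sum()
        # alpha = 0.05 with ~100 tests, |FC| gate makes calls rarer still
        assert called <= np.ceil(0.06 * len(de))
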