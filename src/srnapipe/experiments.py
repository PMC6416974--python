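"""Validation experiments: calibration and recovery studies.

Self-contained, seeded experiments that measure how well the pipeline's
statistics behave: an exact-arithmetic cross-check of the count test, a
null-calibration (type-I error) simulation, and end-to-end recovery of
planted fold-changes and novel loci from synthetic libraries.  Used by
the test suite and the reproduction script; each function returns plain
numbers.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np

from .annotate import CategoryReferences, GenomeIndex, categorize
from .diffexpr import LibraryTotals, differential_expression, exact_count_pvalue
from .known import quantify
from .novel import discover_novel, group_families
from .simulate import SimulationConfig, generate_precursors, simulate_libraries
from .tags import TagLibrary, clean_counter

__all__ = [
    "exact_pvalue_fraction",
    "pvalue_engine_max_error",
    "null_type1_rate",
    "simulate_to_library",
    "de_recovery",
    "novel_family_recovery",
]


def exact_pvalue_fraction(
    x: int, y_obs: int, n1: int, n2: int
) -> tuple[Fraction, Fraction]:
    """(point, lower-tail) probability by exact rational arithmetic.

    Direct factorial evaluation of p(y|x) = r^y (x+y)!/(x! y! (1+r)^(x+y+1)),
    r = n2/n1, summed term by term — an oracle path sharing no code with
    the log-space engine.
    """
    r = Fraction(n2, n1)

    def point(y: int) -> Fraction:
        return (
            r**y
            * factorial(x + y)
            / (factorial(x) * factorial(y) * (1 + r) ** (x + y + 1))
        )

    lower = sum(point(y) for y in range(y_obs + 1))
    return point(y_obs), lower


def pvalue_engine_max_error(
    max_count: int = 50, ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
) -> float:
    """Max relative error of the log-space engine vs. the rational oracle
    over all x, y <= max_count at the given library-size ratios."""
    worst = 0.0
    for r in ratios:
        n1, n2 = 1_000_000, int(round(1_000_000 * r))  # totals at exact ratio r
        totals = LibraryTotals(n1, n2)
        for x in range(max_count + 1):
            rr = Fraction(n2, n1)
            run = Fraction(0)
            for y in range(max_count + 1):
                pt = (
                    rr**y
                    * factorial(x + y)
                    / (factorial(x) * factorial(y) * (1 + rr) ** (x + y + 1))
                )
                run += pt
                got = exact_count_pvalue(x, y, totals)
                for val, ref in ((got.p_point, pt), (got.p_lower, run)):
                    err = abs(Fraction(val) - ref) / ref
                    worst = max(worst, float(err))
    return worst


def null_type1_rate(
    n_replicates: int = 2000,
    mean_tpm: tuple[float, ...] = (5.0, 50.0, 500.0),
    depth: int = 1_000_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null miRNAs (equal true TPM in both libraries) with a
    two-sided p below alpha; calibrated tests stay near or below alpha."""
    rng = np.random.default_rng(seed)
    totals = LibraryTotals(depth, depth)
    hits = 0
    for i in range(n_replicates):
        lam = mean_tpm[i % len(mean_tpm)] * depth / 1e6
        x = int(rng.poisson(lam))
        y = int(rng.poisson(lam))
        if exact_count_pvalue(x, y, totals).p_two_sided < alpha:
            hits += 1
    return hits / n_replicates


def simulate_to_library(refs, config: SimulationConfig):
    """Simulate libraries and run the cleaning stage in memory.

    Builds the same adapter-ligated, length-truncated reads that the
    FASTQ writer emits, collapses them, and cleans each unique read once
    — byte-equivalent to the FASTQ round trip, minus the disk I/O.
    Returns (TagLibrary, SimulatedData).
    """
    from collections import Counter

    sim = simulate_libraries(refs, config)
    cleaned = {}
    for cond in ("ck", "hypoxia"):
        raw = Counter(
            (insert + config.adapter)[: config.read_length]
            for insert in sim.reads[cond]
        )
        cleaned[cond], _ = clean_counter(raw, config.adapter)
    return TagLibrary.from_conditions(cleaned["ck"], cleaned["hypoxia"]), sim


def de_recovery(
    n_replicates: int = 50,
    depth: int = 100_000,
    folds: tuple[float, ...] = (2.0, 3.0, 4.0, 0.5, 0.25),
    min_expected_count: int = 50,
    seed: int = 0,
) -> float:
    """End-to-end recovery of planted fold-changes.

    Plants the given linear folds (control/hypoxia) on the most abundant
    known miRNAs, then over seeded replicates measures the fraction of
    (replicate, planted miRNA) events — restricted to miRNAs whose
    expected count is >= min_expected_count in both libraries — that the
    pipeline calls DE or significant.
    """
    base = SimulationConfig(seed=seed, library_depth=depth)
    refs = generate_precursors(base)
    # plant the folds on the most abundant known miRNAs
    top = sorted(refs.base_weights, key=refs.base_weights.get, reverse=True)
    fold_map = dict(zip(top, folds))

    called = total = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            seed=seed + 1000 + rep, library_depth=depth, fold_change_map=fold_map
        )
        library, sim = simulate_to_library(refs, cfg)
        truth = sim.truth.set_index("class_id")
        counts = quantify(library, refs.known)
        totals = LibraryTotals(library.total_clean_hypoxia, library.total_clean_ck)
        de = differential_expression(counts, totals).set_index("mirna_id")
        for mid in fold_map:
            exp_ck = truth.loc[mid, "expected_frac_ck"] * depth
            exp_hyp = truth.loc[mid, "expected_frac_hypoxia"] * depth
            if min(exp_ck, exp_hyp) < min_expected_count:
                continue
            total += 1
            if mid in de.index and de.loc[mid, "tier"] != "not_DE":
                called += 1
    if total == 0:
        raise RuntimeError("no planted miRNA met the expected-count threshold")
    return called / total


def novel_family_recovery(
    n_replicates: int = 20, depth: int = 100_000, seed: int = 0
) -> float:
    """Fraction of seeded replicates in which the two planted novel loci
    (one shared mature sequence) are reported as exactly one family with
    two loci."""
    base = SimulationConfig(seed=seed, library_depth=depth)
    refs = generate_precursors(base)
    gindex = GenomeIndex(refs.genome)
    crefs = CategoryReferences(refs.category_seqs, refs.known)
    ok = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + 2000 + rep, library_depth=depth)
        library, _ = simulate_to_library(refs, cfg)
        assignment = categorize(library, gindex, crefs)
        unannotated = {}
        for seq, cat in assignment.items():
            if cat not in ("Intergenic", "Intron"):
                continue
            starts, pos = [], refs.genome.find(seq)
            while pos >= 0:
                starts.append(pos)
                pos = refs.genome.find(seq, pos + 1)
            if starts:
                unannotated[seq] = starts
        fams = group_families(discover_novel(unannotated, library, refs.genome))
        if len(fams) == 1 and int(fams["n_loci"].iloc[0]) == 2:
            ok += 1
    return ok / n_replicates
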