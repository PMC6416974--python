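# Methods

This note records the models, rules and numerical choices behind
`srnapipe`, and what the synthetic experiments do and do not show.

## The statistical model

With a single library per condition there is no within-condition
replication, so differential expression rests on an exact test for two
counts drawn from libraries of different sizes.  Conditional on
observing `x` tags of a miRNA in the treated library (total clean tags
`N1`), the count `y` in the control library (total `N2`) is modelled as

    p(y | x) = r^y (x + y)! / (x! y! (1 + r)^(x + y + 1)),   r = N2 / N1

a negative binomial NB(x + 1, 1/(1 + r)) over y — the Audic–Claverie
test generalized by the library-size ratio r.  The distribution sums to
one over y ≥ 0 (the r^y factor is what makes this true; dropping its
exponent breaks normalization for r ≠ 1, which is why the engine checks
itself against both exact rational arithmetic and `scipy.stats.nbinom`).

Both tails are inclusive of the observed count:

    p_lower = Σ_{y ≤ y_obs} p(y|x),    p_upper = Σ_{y ≥ y_obs} p(y|x)

so `p_lower + p_upper − p_point = 1` exactly, and the reported
two-sided value is `min(1, 2·min(p_lower, p_upper))`.  Both tails are
emitted alongside it so a one-tailed reading remains auditable.
Computation is entirely in log space via the pmf ratio
`p(y+1)/p(y) = r(x+y+1)/[(y+1)(1+r)]`, accumulated with `logsumexp`
over a grid extended ~20 standard deviations past the distribution
bulk; probabilities that underflow float64 are floored at the smallest
positive float rather than zero.  Null calibration (equal true TPM,
N1 = N2 = 10⁶, Poisson counts) keeps the empirical type-I rate at
α = 0.05 near or below nominal; the exact test is mildly conservative
at small means.

Expression is normalized as TPM = count / total clean reads × 10⁶.  A
miRNA detected in exactly one library gets TPM 0.01 in the other so the
fold-change `log2(TPM_control / TPM_treated)` is always finite; miRNAs
under 1 TPM in both libraries are removed before testing.  The p-value
always uses the raw integer counts — the 0.01 substitution affects only
the TPM/fold-change scale.  Tier thresholds are applied exactly as
stated: |FC| ≥ 0.6 (≈ 1.52-fold linear) gates both tiers,
0.01 ≤ p < 0.05 is "DE", p < 0.01 "significant".  No multiple-testing
correction is applied — the single-library design this reproduces used
none, and the synthetic null run shows what that costs (a few α-level
false calls per hundred miRNAs).

## Matching and annotation rules

A tag counts toward a known miRNA iff it occurs *exactly* (no
mismatches) within the precursor and some occurrence starts within
±2 nt of the mature 5' end.  The 5' window reflects how little Dicer
processing wobbles at the 5' end compared to the 3' end; 3' length
variation is deliberately unconstrained.  Tags matching several
precursors (families) contribute their full count to each matched
miRNA and carry a `multi_match` flag; a `unique`-only counting mode is
available since family-level double counting is a reporting convention,
not a fact about reads.

Category annotation assigns each genome-mapped tag (exact substring,
either strand) to one class by fixed priority
miRNA > rRNA > tRNA > snoRNA > snRNA > sRNA > Precursor > Repeat >
Exon > Intron > Intergenic.  The priority is a documented convention —
reference sets overlap and a read must be counted once for the
frequency table to partition the clean reads.  "Precursor" means a
perfect hit to a known hairpin outside the mature ±2 window (miRNA*
and loop fragments); "sRNA" is a miscellaneous structural-RNA set.
Frequencies are percentages of clean reads, rounded half-up to two
decimals for display only.

## Hairpin folding and novel loci

Candidate windows (default ±150 nt flank, a typical plant-precursor
scale, around unannotated mapped tags with ≥ 5 supporting reads) are
folded by nested base-pair maximization over Watson–Crick plus G·U
pairs with a minimum loop of 3 nt.  Each tag is tested as a 5p and a 3p
arm at three flank scales (flank, flank/2, flank/4) and the best-scoring
window per locus wins: maximizing pairs can trade a genuine stem for
scattered context pairs in a long window, and a tighter excision around
the same tag recovers it.  Among maximum-pair structures the
DP prefers the one with the most stacked pairs, which selects long
uninterrupted helices — on planted precursors embedded in 150 nt of
random context this reliably returns the designed stem intact.
Base-pair maximization replaces thermodynamic folding deliberately: it
is dependency-free, deterministic, and exactly checkable against
exhaustive enumeration (which the tests do for every window ≤ 30 nt);
an `engine=` hook accepts an external thermodynamic folder where free
energies matter.

A candidate passes structurally when the mature tag lies on one arm
(no self-pairing, all partners on one side), has ≤ 4 positions unpaired
or paired outside the star window, no mismatch run longer than 2 nt,
and ≥ 75 % of its bases paired — fixed defaults in the spirit of the
community criteria for plant miRNA annotation, all config-exposed.
The star is the duplex partner with the canonical 2-nt 3' overhangs
(mature[i] pairs star[L−3−i]); its last two positions are exempt from
the mismatch count since the overhang is unpaired by construction.
Acceptance then requires sequenced star support (exact or ±1 nt at
either end — a documented guess, flagged in output) or > 100 TPM in at
least one library (strictly greater).  Both arms of a well-expressed
duplex can pass independently, so accepted candidates with overlapping
loci are collapsed to the most abundant one: one hairpin, one miRNA.
Accepted candidates sharing a mature sequence from different loci form
one family and are reported once — their reads are indistinguishable.

## qPCR layer

2^−ΔΔCT assumes perfect per-cycle doubling and a stable internal
control; replicate Ct values are averaged on the Ct scale before
differencing, and a two-sided Welch t test on replicate ΔCt values
supplies the significance stars (* p < 0.05, ** p < 0.01).  The
reference gene is a per-run parameter (U6, actin, ...), not a constant.
Efficiency correction (Pfaffl) is out of scope.

## The synthetic experiment

The generator emulates the two-condition design end to end.  Each known
precursor is `f5 + mature + loop + revcomp(mature) + revcomp(f5)`
(8 nt flanks, 12 nt A/C loop that cannot pair internally), giving a
perfect stem whose star follows the canonical overhang geometry; the
novel loci repeat this construction with one shared mature sequence at
two distant genome positions, expressed around 854/1272 TPM
(control/treated) with sequenced star reads near 50 TPM.  Known-miRNA
abundances are fixed per experiment (log-uniform over 10–10⁴ expected
TPM, spanning the range such libraries show from the 0.01 substitute to
the few-hundred-TPM top miRNAs), and per-miRNA linear fold-changes
multiply the control side.  Contaminants default to the proportions
real libraries of this kind show — un_mapped dominating (61 %), repeats
16 %, intergenic 11 %, rRNA ≈ 2.6 %, the structural classes small, a
few percent miRNA — drawn as random fragments of reference sequences
embedded in a single concatenated genome proxy (0-based, half-open
coordinates throughout).  Insert lengths concentrate on 19–24 nt with a
21 nt mode; `length_noise` adds ±1 nt end variants within the known
±2 window.  Reads are insert + a fixed, documented 3' adapter
(`TGGAATTCTCGGGTGCCAAGG`), truncated to 36 nt at constant quality —
the adapter sequence, read length and quality model are config
parameters, since real protocols vary.  One seeded generator drives
all sampling; a fixed seed reproduces libraries byte for byte, and
per-condition class counts come from a single multinomial so truth
counts sum exactly to the library depth.

What passing synthetic tests shows: the rules, the statistics and the
plumbing are implemented correctly, and planted effects of realistic
size are recovered.  What it does not show: robustness to sequencing
error (no substitution errors are simulated), multi-mapping ambiguity
on a real repeat-rich genome, adapter-dimer artifacts, or quality-score
realism — cleaning's quality filter (any base < Q20 discards the read,
configurable) is exercised by unit tests, not by the simulation.

## Problem sizes and numerics

Validation experiments use 100,000-read libraries, 50 replicates for
DE recovery and 20 for novel-family recovery — deep enough that planted
two-fold changes on miRNAs with ≥ 50 expected counts are essentially
always significant, while a full run stays in the minutes range on one
CPU.  The exact-test engine is verified to 10⁻¹² relative error against
arbitrary-precision rational arithmetic for all counts ≤ 50 at library
ratios 0.5/1/2.  The folding DP is O(n³); a numba JIT accelerates it
when available and a pure-Python fallback keeps results identical.
Frequencies and ratios are rounded half-up (Decimal), never with
banker's rounding, to match how such tables are printed.  Degenerate
inputs fail loudly: empty libraries, zero totals, Ct values outside
(0, 45), precursor/mature coordinate mismatches and out-of-range
thresholds all raise with context rather than propagating NaNs.
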