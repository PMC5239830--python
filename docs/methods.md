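# Methods

This note records the models, parameter choices and numerical conventions
behind `bloodrna`, and what the synthetic data do and do not establish.

## Color-space model

SOLiD reads are di-base encoded: color `i` is the transition code of the
base pair `(b_{i-1}, b_i)`, with `b_0` the sequencing primer base.  The
transition table is the XOR of the base indices under A,C,G,T → 0,1,2,3,
which reproduces the standard ligation-chemistry table (identity → 0,
A↔C and G↔T → 1, A↔G and C↔T → 2, complementary pairs → 3).  Encoding is
a bijection for a fixed primer, and the color string of a reverse
complement is the reversed color string — the property that makes
minus-strand alignment a simple array reversal.

Missing-call characters (`.`) are rejected at parse time rather than
imputed; the simulator never emits them and no principled imputation
exists without a quality model.  Per-color qualities are carried for
format fidelity but do not influence alignment — no quality threshold is
applied anywhere in the pipeline.

The simulator's primer base defaults to `T`, the platform convention;
this is a convention choice, not a measured fact about any particular
library.

## Alignment

**Semantics.**  A placement aligns the read's colors 2..L against the
reference's color sequence (one color per adjacent base pair).  The first
color encodes the primer transition, which no reference position can
constrain, so it is excluded — the standard treatment in color-space
aligners.  Mismatches are counted in color space; the default allowance
of 2 is a configuration default, not a literature value.  Nucleotide
reads are aligned in base space with the same machinery.

**Trimming ladder.**  Reads are tried at full length, then 3′-trimmed in
steps of 4, 3 and 2 nt down to 19 nt (the library size-selection floor).
For 50 → 19 the ladder is fixed at `[4,3,3,3,3,3,3,3,2,2,2]` — eleven
steps using all three step sizes, larger trims first so adapter
read-through is shed quickly.  Several step multisets satisfy the same
constraints; the choice is config-overridable.  For other length pairs
the rule is: fewest steps with sizes in {4,3,2}, larger first.  Trimming
stops at the first ladder length that yields any placement, so a long
read is never also reported as a shorter, less specific fragment.

**Search.**  The engine is complete for the given mismatch allowance: a
pigeonhole k-mer filter (cut the query into m+1 segments; any placement
with ≤ m mismatches contains an exact segment) proposes candidates from a
12-mer or 6-mer index, and every candidate is verified by direct
comparison.  Output is therefore identical to an exhaustive scan over all
offsets, strands and ladder lengths; the test suite asserts this
equivalence against a literal brute-force oracle on hundreds of random
instances.  Queries too short for the partition fall back to a full
numpy scan.  Ranking of placements is fully deterministic:
(fewest mismatches, longest alignment, lexicographic reference id,
leftmost position, `+` before `-`); at most k ∈ {1,2} records are
reported and the k=1 output is always a prefix of the k=2 output.

Coordinates in all outputs are 1-based, fully closed.

## Classification and contribution tables

Reads pass three consecutive reference tiers; a read reaches tier t+1
only if it has no placement at any ladder length in tier t.  Tier-1
classes (adapters, mitochondrial RNA, rRNA, tRNA, Y RNA, snRNA/7SK, and
the repeat families SINE — including 7SL by class-map assignment — LINE,
LTR, DNA, other) therefore take precedence over tier-2 transcripts
(mRNA, ncRNA), which take precedence over the genome tier (non-RefSeq).
Because mitochondrial references sit in tier 1, a mitochondrial fragment
never leaks into a nuclear transcript class even when sequence is shared.

Adapter/primer matches are filtered: the contribution table lists no
adapter row, and its denominator ("total mapped") excludes them.
Percentages are computed over reportable classes only and sum to 100 by
construction.

## Quantification

Fragment counts come from k=2 classification: one placement → 1 fragment,
two placements → ½ each (a uniform split; the simplest rule that
conserves `Σ counts = placed reads`, switchable to primary-only).
`FPKM = count · 10⁹ / (length · total_mapped)`, which satisfies the
conservation identity `Σ FPKM_i · len_i / 10⁹ = Σ count_i / total`.
Eligibility for differential testing requires a summed fragment count of
at least 100 (the min-alignment-count default) across the libraries of
the specific comparison — per-test, not per-library, semantics.

## Differential distribution

Counts are scaled by upper-quartile factors (75th percentile of each
library's nonzero counts, rescaled to geometric mean 1).  The NB model
`Var = μ + αμ²` is fitted per feature by method of moments: pooling all
contrast libraries as one group ("blind") when either side has a single
library, otherwise within each group with the maximum taken
("per-condition").  Raw moment estimates at n = 3 are extremely noisy, so
usable estimates are shrunk toward a fitted mean-dispersion trend
`α(μ) = a₀ + a₁/μ` with weight 0.7 on the per-feature value; features
with undefined or non-positive moment estimates take the trend value, and
everything is floored at 10⁻⁸.  The shrinkage weight was fixed by a
calibration simulation against the nominal 5 % level across dispersion
regimes (α ∈ {0.05, 0.1, 0.5}) and is not exposed as a tuning knob.

Replicated contrasts use a two-sided Wald test on log group means with
the delta-method variance `(1/μ + α)/n`; because the trend-stabilized
dispersion is treated as known, the statistic is referred to a standard
normal.  A continuity offset of 0.5 keeps zero-mean groups testable and
makes identical groups give log2FC = 0 exactly.  Single-library-vs-
single-library contrasts instead use an exact-style conditional test:
given the total, the first count is beta-binomial(N, r, r) with r = 1/α
(binomial(N, ½) in the Poisson limit); the two-sided p sums all outcomes
no more probable than the observed one.  This test is deliberately
conservative — with no replicates the blind dispersion absorbs real
biological differences — which is the accepted price of 1-vs-1 designs.
Benjamini–Hochberg q-values are computed within each contrast over
eligible features only; the significance default is q < 0.05.

Simulation benchmarks pinned in the test suite (implementation
benchmarks, not literature claims): on an NB null with α = 0.1, 1,000
features and 3-vs-3 libraries the empirical p < 0.05 rate lies in
[0.03, 0.07]; planted 8-fold effects under the same conditions are
recovered with ≥ 80 % sensitivity at q < 0.05 (measured ≈ 100 %).

## Synthetic data

The generator emulates the study geometry: 15 libraries (fractions I–V ×
cohorts H/LSCC/LAC), 50-color reads, inserts uniform on [20, 100] nt
(strictly greater than the 19-nt size-selection floor), and adapter
read-through — an insert shorter than 50 nt is padded with a fixed 40-nt
synthetic adapter before encoding, so the trimming ladder is genuinely
exercised (~38 % of reads at the default geometry).  Class mixtures
default to the published per-library contribution columns, renormalized
to sum to 1.  Within a class, feature abundances are log-normal(0, 1)
weights drawn once per fraction and shared by its cohorts, so cohorts act
as replicates in fraction-vs-fraction contrasts; planted effects multiply
one feature's weight in chosen fractions.

Reference sequences are i.i.d. random nucleotides with class-typical
lengths (tRNA 70–90 nt, Y RNA 83–112 nt, snRNA/7SK 100–330 nt, SINE
250–320 nt, LINE up to 6 kb, rRNA 1.5–5 kb, mRNA 0.5–3 kb, genome
stand-in ≥ 50 kb over two chromosomes).  Random sequences of these sizes
share no read-sized substring across entries (audited exhaustively in
tests at small scale), so every simulated read has an unambiguous truth
class.  What the synthetic data deliberately lack: human sequence
homology and shared subsequence between tiers (real rRNA fragments *are*
genomic sequence), GC and PCR bias, a realistic error profile (default
per-color error rate 0, a uniform substitution rate is available), and
missing color calls.  Passing the end-to-end mixture-recovery test
therefore demonstrates the pipeline's bookkeeping and the hierarchy's
correctness under clean conditions, not robustness to real SOLiD noise.

Default problem sizes — 2,000 reads per library for the 15-library
fixture, 100,000 reads for the single-library mixture-recovery benchmark,
1,000 features for the calibration simulations — were chosen as the
smallest sizes at which the binomial/sampling tolerances quoted above are
meaningful.

## Degenerate inputs and tie-breaking

Reads shorter than 19 nt get a per-read `too_short` status, not an
exception.  A library with zero reportable reads yields an empty table
with a warning rather than NaN percentages silently.  Libraries with
all-zero counts make upper-quartile normalization fail loudly with the
library name.  Alignment ties at identical (mismatches, length) resolve
by reference id, then position, then strand — the external tools this
mirrors leave tie-breaking unspecified, so determinism was preferred.
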