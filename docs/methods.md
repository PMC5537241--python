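# Methods

This note documents the models and estimators implemented in `satmethyl`,
the design choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Monomer library model

A satellite family is represented as an equal-width alignment of monomer
sequences with species labels parsed from the record-ID prefix before the
first underscore (overridable via a sample-sheet TSV).  Coordinates are
1-based inclusive on the monomer throughout; BED exports convert to 0-based
half-open.  N bases are excluded from every frequency denominator.

**Alignment enforcement.**  Off-length records are pairwise-aligned to the
longest record (linear gap cost; match +1, mismatch −1, gap −2) and the
induced gap columns merged.  The gap cost deliberately exceeds the mismatch
cost so the optimizer never trades a substitution for an insertion+deletion
pair, which would inflate the alignment width.  Records deviating more than
20% from the reference length are rejected as non-members of the family.
The operation is idempotent.

**Consensus.**  Majority rule per column; a column emits `-` only when the
gap frequency is ≥ 0.5.  Ties default to first-alphabetical (deterministic);
an IUPAC mode exists because degenerate bisulfite primers imply ambiguity
codes are in practical use.

## Nucleotide diversity

Pi is the average uncorrected p-distance over all unordered pairs with
pairwise deletion (gap/N columns excluded per pair) — no multiple-hit
correction, matching the convention of the standard population-genetics
estimators for monomer libraries.  Complete deletion is intentionally not
used: a single monomer with one deletion would otherwise discard a column
for all pairs.  Sliding windows (default 10 bp, step 1 — the window is a
field convention for monomer-scale tracks; the step is our choice since
"overlapping" does not fix it) are computed on windows fully inside the
monomer, via cumulative per-pair mismatch counts (exact, vectorized).

**Segment rule.**  A window is variable above mean + k·SD and conserved
below mean − k·SD (k = 2 by default; SD is the sample SD over finite window
values).  Window labels are projected to positions; a position covered by
both an extreme-high and an extreme-low window takes *variable* (our
precedence rule; only the resulting segments are conventionally reported).
With SD = 0 everything is intermediate.

*Detectability caveat.*  For any two-level track in which a flat regime of
relative width f departs from the background, the rule can only flag it when
f < 20%: at f ≥ 0.2 the regime's own contribution to the SD pushes
mean ± 2·SD past its value identically.  Short variable regions (a few
percent of windows) are therefore detected readily, while broad conserved
domains (e.g. two domains covering ~30% of a monomer) depress the local
track without crossing the line.  Window sampling noise tightens this
further: with ~40 monomers the per-window Pi noise SD is ≈ 2·√(p/(10·n)),
large enough to mask a single 30 bp conserved block; the block-recovery
experiment in the test suite consequently uses a 200-monomer family, where
a planted block at positions 60–89 is recovered within ± one window width
on every seed tried.

## Bisulfite methylation calling

Reads are Sanger-sequenced clones: one molecule per read, no deduplication.
Each read is globally aligned (free end gaps) to the strand-appropriate
consensus — the reverse complement for complementary-strand reads — under a
substitution scheme in which read-T against reference-C scores as a match.
Identity is computed bisulfite-aware with the full read length as the
denominator (so unaligned overhangs count against it); reads under 50 bp
after primer masking or below 70% identity are rejected with a reason.
Primer-derived intervals from the sample sheet are excluded from evidence.

**Normalization.**  At each monomer position and strand with any C/T in the
native library column:

    m = (C fraction among covering reads) / (C+T fraction in the native column)

The C+T denominator removes the contribution of spontaneous C→T mutations
in the repeat pool.  It under-corrects when the native column carries A/G
alleles, so a native-C-only denominator is available
(`normalization="c_only"`); the C+T form is the default.  Estimates above 1
(sampling noise) are clamped to 1 and flagged, never silently.

**Incomplete-conversion correction.**  At efficiency e < 1 a fraction
(1 − e) of unmethylated cytosines read as C, inflating every context rate by
≈ (1 − m)(1 − e) — about 1.3 percentage points at e = 0.987, larger than
the differences between contexts.  `call_methylation` therefore accepts the
efficiency estimated from unmethylated PCR-product controls and subtracts
the background: m ← (m − (1 − e)) / e.  Small negative values are kept
uncensored so that averaging across positions stays unbiased (a zero floor
would bias low-rate contexts upward by several tenths of a point).  The
uncorrected printed-formula estimate remains the default.

**Context and aggregation.**  Context is classified once on the strand
consensus with circular wraparound (tandem organization); per-read context
is not recomputed.  Summaries are observation-weighted (methylation events
over opportunities, weights = read counts per position); a site-averaged
mode exists.  The "All C" row and "both" column are the weighted pools, so
the marginals are consistent by construction.

*Estimator property.*  Because context and opportunity are defined on the
consensus, positions where an individual molecule has mutated away from C
dilute the cell: the recovered CG rate sits ~3–5% (relative) below the
per-molecule generative rate at Pi ≈ 0.03.  This is a property of
consensus-anchored calling itself — the quantity measured is "methylation
per consensus cytosine opportunity" — and is shared by the manual-screening
procedure the pipeline reproduces.  Recovery tests therefore compare the
estimate against the realized opportunity-level truth from the generator's
methylation maps, and separately bound the absolute error against the
configured rates (< 0.01 mean absolute error at 60 reads).

**Correlation.**  Methylation and diversity window tracks are paired by
window start; Spearman's rho with average ranks, p-value from the t
approximation by default (the behavior of common statistics packages), with
a seeded permutation option for small n.  Pairs with NaN in either track
are dropped; at least 5 pairs are required.

## In-silico digestion

Enzymes are (recognition motif, cut offset, sensitivity rule).  Site search
covers both strands (palindromes counted once) and crosses the origin for
circular arrays.  Sensitivity rules for the CCGG isoschizomers: MspI is
blocked by outer-C methylation on either strand; HpaII only by full
(both-strand) internal-C methylation, so hemimethylated sites are cut by
both enzymes — the inference the restriction data themselves support, in
preference to stricter database semantics; the rule table is overridable.
Partial digestion is an independent Bernoulli cut per susceptible site
(the simplest defensible model; real partial-digest kinetics are not
specified by gel protocols), with a mandatory seed.  Fragment lengths are
conserved by construction and checked by property tests; the
monomer-multimer ladder assigns fragments to rung k when within ±2 bp of
k·unit.

## Synthetic-data generator

The generator emulates the cloned-monomer / bisulfite-clone study design:

| parameter | default | rationale |
|---|---|---|
| monomer length | 315 bp | the family's unit length |
| per-site substitution prob | 0.015 | expected pairwise divergence 2p(1−p)+⅔p² ≈ 0.030 |
| indel prob per monomer | 0.025 | ~1 single-base deletion per 39 clones |
| G+C target | 0.4405 | the family's base composition |
| methylation rates CG/CHG/CHH | 0.0565 / 0.0179 / 0.0269 | a few percent, CG > CHH > CHG |
| hot-block multiplier | ×3 | satellite methylation ≈ 3× the genomic mean |
| conversion efficiency | 0.987 | typical kit performance measured by controls |
| clone counts | 33 direct / 26 complementary | study-scale read depth |

Monomers diverge independently from a random ancestral sequence (uniform
substitution among the three alternatives; a transition-bias knob exists but
defaults to 1 since no model is implied by the data).  Indels are modelled
as at most one single-base deletion per monomer — deletions dominate the
observed length variants and keep the alignment width fixed; insertions are
out of scope.  Conserved/variable blocks scale the local substitution rate
multiplicatively.  The ancestral repeat can carry planted restriction
motifs (with chance duplicates scrubbed) and an exact-composition mode that
shuffles a fixed base multiset, used by the study emulation to pin G+C.

Methylation is assigned per molecule and per strand, independently at each
cytosine with its context rate (classified on the molecule, circularly);
`strand_symmetric` applies the same rates to both strands with independent
draws, so hemimethylated symmetric sites occur naturally.  Bisulfite
conversion turns each unmethylated C to T with probability e; methylated
Cs are protected (an over-conversion knob defaults to 0).  Complementary
reads are conversions of the reverse complement.  `make_dataset` writes
FASTA + sample sheet + a ground-truth JSON and is byte-reproducible under
its seeds.

**What the emulation does not capture.**  Real monomer variants are not
independent draws from one ancestor: concerted evolution correlates them
within and across species.  In consequence the emulated pooled
(interspecific) Pi is slightly *above* the within-species values, whereas a
shared variant library can make the pooled value marginally lower.  Clone
recovery is uniform here (no PCR/cloning bias), chimeras and sequencing
errors are absent, and fragment classes (external/internal) are labels
only.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated sampling model, not robustness to those
artefacts.

## Study emulation and problem sizes

The experiments module fixes the emulated study conditions: three species
with 39/21/11 monomers at intraspecific diversities 0.0294/0.0340/0.0290
(per-species substitution rates solved by inverting the expected-divergence
formula, averaged over block-modulated sites), conserved domains 41–89 and
199–232, four 15 bp variable regions, planted HaeIII/TaqI/PvuII/3×CCGG
sites, methylation hot blocks 60–89 and 209–221 nested inside the conserved
domains, and a 30-read unmethylated control set.  Headline quantities are
reported as Monte-Carlo means over 10 replicate libraries (20 for the
methylation table, whose per-study noise at 59 clones is ~1 percentage
point on the CG cell); the digestion experiment uses a 156-monomer tandem
array.  These sizes keep every experiment to seconds while holding the
Monte-Carlo error of reported means well below the quantities' natural
scale.

## Numerical choices and degenerate inputs

* Consensus tie-break: first-alphabetical, deterministic; IUPAC optional.
* Track SD: sample SD (ddof = 1) over finite window values; NaN windows
  (no C-capable position, or no comparable pair) are excluded from mean/SD
  and never classified.
* Pairs with zero comparable sites are dropped from Pi with a warning; an
  alignment with no comparable pair raises.
* Zero-coverage positions yield calls with `n_reads = 0` and NaN estimates
  rather than being silently dropped.
* All generators and the digestion sampler take explicit seeds; identical
  seeds give byte-identical outputs.

## Known limitations

* Consensus-anchored context classification measures methylation per
  consensus opportunity (see estimator property above); per-molecule
  context calling is not implemented.
* The mean ± 2·SD rule cannot flag broad regimes (≥ 20% of windows) as
  conserved or variable — an intrinsic property of the rule, not an
  implementation limit.
* No higher-order-repeat detection, phylogenetics, or corrected distance
  models; pre-aligned input is assumed beyond single-indel enforcement.
* Short-read bisulfite data (genome-scale mapping, deduplication) is out of
  scope; reads are clones.
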