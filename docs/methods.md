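# Methods

This note documents the models and procedures implemented in `teforge`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Pairwise alignment engine

All nucleotide homology search (genome self-alignment, library-to-genome
mapping, databank search, library comparison) goes through one
seed-and-extend engine (`teforge.pairwise`): exact k-mer seeds collected
with numpy, grouped into near-diagonal segments (diagonal band 24 bp,
seed gap ≤ 200 bp), verified by a unit-cost global alignment (edlib) of
the padded segment pair. Identity and score (number of matching columns)
come from the maximal-scoring sub-alignment of that verification
(match +1, mismatch/indel −3, Kadane's rule), which trims the random
flanks introduced by seed padding; ends are then re-extended greedily over
exact matches, because the unit-cost optimum is degenerate and can absorb
pad asymmetry as terminal mismatches.

Consequences worth knowing:

* **Boundary precision.** Match ends land within ~±3 bp of a planted
  repeat boundary; terminal homopolymers (polyA tails) allow an
  equal-cost slide of up to the homopolymer length, so individual matches
  at tail boundaries can be shifted ~10 bp. Downstream steps are designed
  to tolerate this (median locus boundaries, consensus end polishing).
* **Sensitivity.** With seed k = 15 (self-alignment) a copy pair must
  share a clean 15-mer; at ≥ 92% pairwise identity seeds are dense and the
  planted-pair recovery invariant holds with margin. Library mapping uses
  k = 11 (identity threshold 80%).
* **E-values** are not computed by default. The stringent E ≤ 1e-300
  cut-off used with the external aligner is, at these identity/length
  thresholds, dominated by the identity and length filters; the parameter
  is retained in `SelfAlignParams` and applied only when an E-value is
  present on a match.

Chunking cuts each sequence into 200 kb chunks with 10 kb overlaps
(defaults; both configurable). Matches are lifted back to genome
coordinates; mirror duplicates are removed by canonical ordering of the
two intervals; chunk-overlap duplicates are removed at ≥ 95% reciprocal
overlap (the higher-scoring match kept) and collinear boundary pieces are
merged. Chunked and unchunked runs agree on matches shorter than the
overlap — asserted in the test suite.

## Chaining and the three clustering strategies

Matches are connected into chains by dynamic programming per (query
sequence, subject sequence, strand), maximizing Σ match scores − gap
costs (gap cost = 20 + 0.02/bp). A join is allowed only when
min(query gap, subject gap) ≤ 500 bp and max gap ≤ 30 kb: fragments of
one copy split by an indel or nested insertion leave a near-zero gap on
the intact partner copy, whereas two distinct nearby copies gap on both
sides. Without the min-gap condition the DP chains unrelated neighbouring
copies into spurious mega-chains.

**GROUPER-style.** Chain sides are merged into loci at ≥ 95% reciprocal
overlap; the locus interval is the per-end *median* of its member
endpoints (endpoint aggregation — robust to one boundary-slopped match;
the union would inherit the worst overshoot). A chain links its two loci
into one cluster only when its aligned fragments cover ≥ 95% of each
locus; this is what keeps structural variants apart: a full-length copy
and a deletion variant share less than 95% of the full locus. Loci covered
≥ 95% of their own length by a larger locus are marked *included*
(the non-autonomous/MITE situation) and clusters need ≥ 2 non-included
members to survive. Chains with cumulative length > 20 kb spanning
> 30 kb (segmental duplications) are removed up front.

**RECON-style.** Phase 1 merges fragment sides at ≥ 50% coverage of the
shorter into elements (element interval = merged union span, as the
strategy defines it); a deterministic composite-split stands in for the
original endpoint-aggregation statistics: an element is split only where
≥ 3 member starts *and* ≥ 3 member ends agree within 20 bp at an interior
position. Phase 2 links elements whose connecting matches cover ≥ 90% of
each element. This strategy deliberately merges structural variants (50%
phase-1 coverage), which is the documented complementarity with the
GROUPER-style clusterer: the acceptance suite asserts that the former
merges and the latter separates the two-variant scenario.

**PILER-style.** Piles are maximal contiguous regions covered by ≥ 1
match side (they partition the covered genome — property-tested). Two
piles co-cluster when connecting matches cover ≥ 95% of both lengths and
the length ratio itself permits a 95% global alignment.

Cluster member orientation is propagated over the link graph (match
strand = flip edge); orientation conflicts (palindromic links) keep the
first assignment. Cluster ids are method-prefixed (G/R/P) ordinals by
decreasing total member length. Filters: < 3 members dropped; > 20
members truncated to the 20 longest (applied after the
segmental-duplication chain filter).

## Consensus

Star multiple alignment seeded on the longest member; every other member
is aligned to the centre by unit-cost global alignment and the pairwise
alignments are merged with once-a-gap-always-a-gap slots. The unit-cost
optimum tends to scatter a long insertion across chance matches, so each
pairwise path is canonicalized: between anchor runs (≥ 8 consecutive
matches) the length difference is re-emitted as one contiguous gap block
followed by substitution columns. `MsaParams` retains the declarative
scoring surface (gap-size cap 50, mismatch −8, gap open 16, gap
extend 4) describing the intended regime — long gaps not penalized
beyond a cap — which the unit-cost engine approximates adequately for
the > 90%-identity inputs this stage receives; the cap is inert in the
unit-cost path. A 16 × 8 kb cluster aligns in well under a second.

Consensus: per column, discard if all but one row is a gap, else emit the
most frequent non-gap residue; ties break A<C<G<T and N never wins a tie.
Two additional steps protect the termini of cluster consensuses:

1. terminal runs of low-confidence columns (majority residue supported by
   < 3 rows or < 60% of non-gap rows) are trimmed;
2. *end polishing by copy support*: members are locally re-aligned to the
   consensus and those reaching a terminus vote (median) on its position.
   Only ≤ 25 bp may be shaved, so a long 5′ head supported by only the few
   full-length copies of a heavily truncated family is never affected.

Rationale: union-style members (piles, elements) carry a few bp of
chance-matching flank and homopolymer-slide slop; a forced global star
alignment otherwise locks that slop into supported columns, and the
resulting over-long consensuses both fail full-length recovery for short
elements (a 300 bp SINE has only ±15 bp of ±5% tolerance) and, being
longest, win redundancy contests against better-bounded duplicates.

## Classification and redundancy

Feature detectors: terminal repeats by local affine alignment
(Biopython PairwiseAligner) of the two terminal windows (25% of length,
cap 2 kb) — LTR ≥ 100 bp ≥ 80% identity on the direct strand, TIR ≥ 10 bp
≥ 80% against the reverse complement — with hits required to be anchored
within 50 bp (LTR) / 20 bp (TIR) of the sequence ends, which keeps the
false-positive rate on 2 kb randoms below 5% (tested at 0/100); polyA
tail = run of ≥ 10 bases ≤ 20% non-A in the terminal 30 bp of either
end/strand; SSR tail = 1–6 bp motif ≥ 5 tandem copies in the terminal
50 bp; tandem fraction by a self-offset scan (motif 1–500 bp, ≥ 2 copies,
windowed identity ≥ 80%, array ≥ 20 bp, and the periodic run must extend
~one motif length per extra copy — a single lucky window is not a
tandem). Databank search: nucleotide (identity ≥ 70%, ≥ 100 bp) and
six-frame translated (BLOSUM62 local, identity ≥ 30%, ≥ 50 aa, with a
protein 4-mer prefilter); headers carry `id#Class/Order` labels.

Decision tree order: tandem fraction > 0.75 → SSR; host-gene hits without
TE evidence → host gene; contradictions (LTR + polyA, LTR + TIR,
conflicting hit orders, structure/homology conflict, length outside the
category range) → confused; structural + coding → complete;
coding only → incomplete of the hit's order; structural only → SINE/MITE
by length range for tails/TIRs, else incomplete; nothing → not
categorized. Default length ranges (LTR retro 1.5–25 kb, LINE 1.5–10 kb,
SINE 80–500 bp, DNA transposon 0.8–20 kb, MITE 80–800 bp) are package
defaults calibrated on the synthetic families and are configurable.

Redundancy removal (95-80-98): a record included within a retained record
over ≥ 98% of its length at > 95% identity (alignment ≥ 80 bp; the
maximal-scoring window of an infix alignment, so non-homologous overhangs
do not contribute chance matches) is dropped. Protection ranks:
complete > positively labelled > unclassifiable (NoCategory/Confused); a
record is only ever removed by one of equal or higher rank, and among
equal ranks the longer survives (ties by id). The unclassifiable rank
exists because chimeric mega-consensuses (a known clustering artifact)
otherwise swallow well-classified family records — the very failure mode
that motivates classification-aware redundancy removal. The procedure is
deterministic, idempotent and never empties a non-empty input.

## Annotation

Mapping thresholds: identity ≥ 80%, length ≥ 20 bp, both strands. Null
model: per-sequence mononucleotide shuffle (dinucleotide available),
identical mapping, threshold = 95% empirical quantile (linear
interpolation) of null scores; an empty null yields threshold 0. The 95%
quantile (rather than the legacy maximum) avoids over-filtering on the
strength of one lucky null match; quantile mode never filters more than
max mode (asserted).

Defragmentation connects fragments per (sequence, consensus, strand) by
the same DP as chaining (genome gap ≤ 5 kb, consensus gap ≤ 500 bp,
collinear), *then* resolves overlaps: chains are taken in decreasing
score order and later chains are trimmed or dropped where they overlap
kept fragments (> 20 bp tolerance) — so a fragment that would lose a
pairwise contest can survive inside a higher-scoring chain. The long-join
pass merges consecutive same-consensus copies when collinear and either
nearly adjacent (≤ 1 kb) or separated by ≤ 100 kb covered ≥ 90% by
strictly younger copies. Age score = length-weighted mean fragment
identity (higher = younger); the literal Σ identity/length variant is
available behind `age_formula="literal"`. The weighted mean was chosen
because it is scale-stable and matches the intent of an age proxy; the
literal ratio is dominated by the shortest fragment. Microsatellite
filter: tracts of 1–6 bp motifs, ≥ 5 copies, ≥ 20 bp; fragments < 150 bp
lying ≥ 95% inside tracts are removed ("short" is a package decision).

## Synthetic genomes and what the benchmark shows

The generator plants families with the structures the method must cope
with: LTR/TIR/polyA terminal architecture, per-copy divergence from the
ancestor (substitutions at the spec'd rate, indels at 2×10⁻⁴/bp with
geometric(mean 3) lengths), 5′ truncation (uniform point), structural
variants (exact spec'd deletions in a fraction of copies), explicit
nesting, target-site duplications for class II elements, plus non-TE
confounders (25 kb two-copy segmental duplications, SSR tracts).
Identities are *per-copy vs the ancestor*; two copies at identity i are
~100 − 2(100 − i) percent identical to each other, so the default means
(96–98.5%) put pairwise copy identity in the 92–98% band the
interspersed-repeat alignment step assumes. Insertion points keep ≥ 1 kb
spacing (interspersed, not tandem, regime) and never fall inside an
already-planted copy except through the explicit nesting channel — every
homology in the genome is recorded truth.

Default scenario: eight families (two LTR retrotransposon, two TIR
transposon — one of each with a 0.9–1.5 kb deletion variant in 40–50% of
copies, one MITE, one LINE at 50% 5′ truncation, one SINE, one
featureless Helitron stand-in with exactly three copies), 3–20 copies
each, on 250 kb of i.i.d. background split over two sequences (~450 kb
final genome). The whole pipeline runs in ~10 s per seed.

A family counts as *recoverable in full* when it has ≥ 3 full-length,
non-variant copies of pairwise identity ≥ 92%
(`eligible_full_length_families`, computed from the recorded truth). The
fixed-seed acceptance suite asserts, on a 5-seed panel: every eligible
family is exactly recovered (±5% mutual length) by the combined pipeline;
the combined exact-recovery set contains every single method's set on
every seed and strictly exceeds at least one method on at least one seed;
and annotation with the true ancestral library reaches nucleotide
sensitivity ≥ 95%.

What passing does **not** show about real genomes: the background is
i.i.d. (no gene content, GC structure, or low-complexity landscape beyond
the planted SSRs), divergence is uniform along each copy (no CpG
hot-spots, no lineage structure within families beyond the two-variant
scenario), family sizes and ages are modest, and the classifier is
exercised mostly on structural evidence (databank and host-gene homology
are covered by unit tests on constructed cases, not by the end-to-end
scenario). Real-genome behaviour additionally depends on alignment
sensitivity at higher divergence (< 90% pairwise identity), which is out
of range for this engine's thresholds by design.

## Degenerate inputs and tie-breaks

Single-member clusters return their sequence as the consensus; an
alignment whose columns are all discarded raises rather than emitting an
empty consensus. Empty match sets propagate as empty cluster lists.
Consensus residue ties break alphabetically (A<C<G<T, N never wins).
Cluster and copy ids are deterministic (sorted sweeps everywhere); the
same seed reproduces byte-identical generator output and pipeline
results. The shuffled-genome null uses its own seed; the CLI exposes it
(`--null-seed`) separately from the generator seed.
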