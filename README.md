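# teforge

De novo discovery, classification and genome annotation of transposable
elements (TEs), built on interspersed-repeat clustering.

Transposable elements are mobile, repetitive DNA sequences that make up a
large fraction of most eukaryotic genomes. Annotating them in a newly
sequenced genome has two phases: first build a *library* of consensus
sequences, one per TE family, from nothing but the genome itself; then use
that library to locate and reconstruct every TE copy on the chromosomes.
`teforge` implements both phases as a self-contained Python package, for
genome-annotation practitioners and for methods work on repeat discovery,
and ships a synthetic-genome generator with exact ground truth so that
every stage can be exercised and scored without external data.

## Method

The de novo phase is a three-step approach:

1. **Self-alignment** — an all-by-all comparison of the genome with itself
   (k-mer seeded, gapped local alignment; identity > 90%, length > 100 bp),
   run on 200 kb chunks with 10 kb overlaps. Matches longer than 20 kb are
   discarded as probable segmental duplications.
2. **Clustering** of the matches into putative families, with three
   complementary strategies run in parallel:
   * *GROUPER-style*: matches are chained by dynamic programming (one chain
     per fragmented copy), then single-linked under a high 95% coverage
     constraint, with chains fully included in others marked so that
     clusters need at least two non-included members. The high-coverage
     constraint keeps structural variants of one family (e.g. a lineage of
     copies sharing an internal deletion) in separate clusters.
   * *RECON-style*: fragments at each locus are merged into "elements"
     under a low 50% coverage constraint; elements are gathered into
     families at 90% reciprocal aligned coverage.
   * *PILER-style*: "piles" (maximal contiguous covered regions) that can
     be globally aligned over ≥ 95% of both lengths are gathered.
   Clusters with fewer than three members are dropped and large clusters
   keep their 20 longest members.
3. **Consensus** — a star multiple alignment per cluster and a majority
   rule that discards columns in which all but one member has a gap, with
   copy-support polishing of the termini.

Each consensus is then classified by its detected features — long terminal
repeats (LTRs), terminal inverted repeats (TIRs), polyA/SSR tails, tandem
content, and optional nucleotide/translated matches against a labelled TE
databank and host genes — through a decision tree (class I LTR
retrotransposon / LINE / SINE, class II DNA transposon / MITE, Helitron,
SSR, host gene, confused, no category), with a completeness flag:
structural *and* coding evidence → complete, one of the two → incomplete.
Redundancy between the parallel clusterings is removed afterwards with the
stringent 95-80-98 rule (a consensus included in another over 98% of its
length at > 95% identity is dropped), classification-aware: an incomplete
record can be removed by a complete one, never the reverse.

The annotation phase maps the library onto both genome strands, filters
false positives with a shuffled-genome null model (score threshold = the
95% quantile of scores on composition-preserving shuffled sequences),
connects fragments of one copy by dynamic programming before resolving
overlaps between chains ("TE defragmentation"), re-joins copies split by
younger nested insertions (age proxied by length-weighted mean fragment
identity), and removes short fragments fully covered by microsatellites.

Library quality is scored against a "knowledge-based" library — one
consensus per reference TE rebuilt from its own genomic copies (≥ 3 copies
longer than 100 bp) — using three indices: Sn\* (knowledge-based
consensuses matched by a de novo consensus), Sp\* (de novo consensuses
matching a knowledge-based one) and the recovery ratio R_CC (full-length
knowledge-based consensuses recovered *exactly*, i.e. mutually aligned
over their entire lengths ± 5%). Annotations are scored by nucleotide-level
sensitivity and specificity.

## Worked example

```python
from teforge import simulate, run_tedenovo
from teforge.evaluate import build_knowledge_based_library, library_metrics

truth = simulate(seed=42)   # 8 planted families, ~450 kb, exact ground truth
result = run_tedenovo(truth.genome)
for rec, cls in result["final"]:
    print(f"{rec.id:5s} {len(rec.sequence):6d} bp  {cls.label:13s} {cls.completeness}")

kb = build_knowledge_based_library(truth.ancestors, truth.genome)
m = library_metrics([rec for rec, _ in result["final"]], kb)
print(f"Sn* = {m.sn_star:.1f}%  Sp* = {m.sp_star:.1f}%  "
      f"R_CC = {m.r_cc:.1f}% ({m.n_exact_recoveries}/{m.denominator})")
```

prints

```
G11      301 bp  classI-SINE   not-applicable
G2      3508 bp  classI-LTR    incomplete
G3      2503 bp  classII-TIR   incomplete
G5      3500 bp  classI-LINE   incomplete
G8      3002 bp  NoCategory    not-applicable
G9       400 bp  classII-MITE  not-applicable
P1      4002 bp  classI-LTR    incomplete
P6      5003 bp  classI-LTR    incomplete
P9      2104 bp  classII-TIR   incomplete
R3      3001 bp  classII-TIR   incomplete
Sn* = 100.0%  Sp* = 100.0%  R_CC = 100.0% (8/8)
```

Ten consensus sequences survive redundancy removal for the eight planted
families (the LTR family with a structural variant yields one consensus
per variant, and the heavily truncated LINE family yields one full-length
and one truncated consensus). Labels follow each family's architecture:
the 301 bp tail-bearing consensus is a SINE, the 400 bp TIR-bearing one a
MITE, the featureless Helitron stand-in stays unclassified. All eight
knowledge-based consensuses are matched and recovered full-length
(R_CC = 100%, 8/8). With a labelled TE databank passed to `run_tedenovo`,
records with both structural and coding evidence would be upgraded to
"complete".

The same stages are available from the shell:

```sh
teforge simulate --seed 42 --out-dir sim/
teforge selfalign --genome sim/genome.fa --out sim/matches.tsv
teforge cluster --matches sim/matches.tsv --genome sim/genome.fa --out sim/clusters.json
teforge consensus --clusters sim/clusters.json --genome sim/genome.fa --out sim/library.fa
teforge classify --library sim/library.fa --out sim/classified.fa --report sim/report.tsv
teforge annotate --genome sim/genome.fa --library sim/classified.fa --out sim/te.gff3
teforge evaluate --denovo sim/classified.fa --reference sim/ancestors.fa \
    --genome sim/genome.fa --truth sim/truth.gff3 --pred sim/te.gff3 --out sim/metrics.json
```

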