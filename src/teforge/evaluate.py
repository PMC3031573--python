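"""Library- and annotation-level quality metrics.

A de novo consensus library is judged against a "knowledge-based" library:
one consensus per reference TE, rebuilt from that reference's own genomic
copies.  Three indices compare the two libraries: Sn* (proportion of
knowledge-based consensuses matched by a de novo consensus), Sp*
(proportion of de novo consensuses matching a knowledge-based one) and the
recovery ratio R_CC (proportion of full-length knowledge-based consensuses
exactly — mutually full-length, ±5% — retrieved by a de novo consensus).
Annotation-level sensitivity and specificity are computed on nucleotide
interval overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotate import AnnotateParams, map_library, matcher_defragment
from .consensus import MsaParams, build_consensus, polish_consensus_ends, progressive_msa
from .core_io import GenomeSet, revcomp
from .pairwise import cross_match

log = logging.getLogger("teforge")


@dataclass
class KnowledgeBasedRecord:
    id: str
    sequence: str
    n_copies: int
    full_length: bool  # consensus covers its reference within ±5%


@dataclass
class LibraryMetrics:
    sn_star: float
    sp_star: float
    r_cc: float
    n_exact_recoveries: int
    denominator: int


@dataclass
class AnnotationMetrics:
    sn: float
    sp: Optional[float]
    genome_coverage: float
    n_copies: int
    boundary_exact: dict = field(default_factory=dict)


def recovery_ratio(n_exact: int, denominator: int) -> float:
    """R_CC as a percentage: exactly recovered full-length knowledge-based
    consensuses over the number of reference sequences a knowledge-based
    consensus itself recovered in full (e.g. 60 of 68 -> 88%)."""
    if denominator <= 0:
        raise ValueError("R_CC denominator must be positive")
    return 100.0 * n_exact / denominator


def _best_pair_alignment(a: str, b: str, min_identity: float, min_length: int):
    """Best local alignment between two sequences over both orientations;
    returns (coverage_a, coverage_b, identity) of the best-scoring hit."""
    hits = cross_match(
        {"q": a}, {"s": b}, min_identity=min_identity, min_length=min_length,
        k=11, both_strands=True,
    )
    if not hits:
        return None
    best = max(hits, key=lambda m: m.score)
    return best.query_length / len(a), best.subject_length / len(b), best.identity


def matches_library(
    a: str, b: str, min_identity: float = 90.0, min_length: int = 100
) -> bool:
    """Whether two consensuses match (any local alignment above thresholds)."""
    return _best_pair_alignment(a, b, min_identity, min_length) is not None


def exact_recovery(
    a: str, b: str, tolerance: float = 0.05, min_identity: float = 90.0
) -> bool:
    """Mutual full-length alignment within ±5% of both lengths.

    Symmetric: a exactly recovers b iff b exactly recovers a.
    """
    res = _best_pair_alignment(a, b, min_identity, 50)
    if res is None:
        return False
    cov_a, cov_b, _ = res
    return cov_a >= 1 - tolerance and cov_b >= 1 - tolerance


def build_knowledge_based_library(
    reference_tes: dict,
    genome: GenomeSet,
    annotate_params: Optional[AnnotateParams] = None,
    msa_params: Optional[MsaParams] = None,
    min_copy_len: int = 100,
    min_copies: int = 3,
    max_copies: int = 20,
    full_length_tolerance: float = 0.05,
) -> list:
    """One consensus per reference TE, from the multiple alignment of its
    genomic copies, when at least three copies longer than 100 bp exist.

    Each record carries whether the rebuilt consensus is full-length with
    respect to its reference (mutual ±5% coverage) — those records form
    the denominator of R_CC.
    """
    if annotate_params is None:
        annotate_params = AnnotateParams()
    frags = map_library(reference_tes, genome, annotate_params)
    copies = matcher_defragment(frags, annotate_params)
    per_family: dict = {}
    for c in copies:
        if c.genome_iv.end - c.genome_iv.start > min_copy_len:
            per_family.setdefault(c.consensus_id, []).append(c)
    records = []
    for fam in sorted(per_family):
        fam_copies = per_family[fam]
        if len(fam_copies) < min_copies:
            continue
        fam_copies.sort(key=lambda c: -(c.genome_iv.end - c.genome_iv.start))
        fam_copies = fam_copies[:max_copies]
        seqs = {}
        for i, c in enumerate(fam_copies):
            iv = c.genome_iv
            s = genome[iv.seq_id][iv.start : iv.end]
            if iv.strand == "-":
                s = revcomp(s)
            seqs[f"{fam}_c{i}"] = s
        aln = progressive_msa(seqs, msa_params)
        cons = polish_consensus_ends(
            build_consensus(aln, cluster_id=fam, end_agreement=0.6), seqs
        )
        full = exact_recovery(cons.sequence, reference_tes[fam], full_length_tolerance)
        records.append(
            KnowledgeBasedRecord(
                id=fam, sequence=cons.sequence, n_copies=len(fam_copies), full_length=full
            )
        )
    return records


def library_metrics(
    denovo: list,
    knowledge_based: list,
    full_length_tolerance: float = 0.05,
    match_identity: float = 90.0,
    match_length: int = 100,
) -> LibraryMetrics:
    """Sn*, Sp* and R_CC between a de novo library and a knowledge-based
    library.

    ``denovo``: list of ConsensusRecord (or anything with .id/.sequence);
    ``knowledge_based``: list of KnowledgeBasedRecord.
    """
    if not knowledge_based:
        raise ValueError("empty knowledge-based library: Sn*/R_CC undefined")
    if not denovo:
        raise ValueError("empty de novo library")
    kb_matched = set()
    dn_matched = set()
    kb_exact = set()
    for kb in knowledge_based:
        for dn in denovo:
            if matches_library(kb.sequence, dn.sequence, match_identity, match_length):
                kb_matched.add(kb.id)
                dn_matched.add(dn.id)
                if kb.full_length and kb.id not in kb_exact and exact_recovery(
                    kb.sequence, dn.sequence, full_length_tolerance, match_identity
                ):
                    kb_exact.add(kb.id)
    denominator = sum(1 for kb in knowledge_based if kb.full_length)
    sn_star = 100.0 * len(kb_matched) / len(knowledge_based)
    sp_star = 100.0 * len(dn_matched) / len(denovo)
    r_cc = recovery_ratio(len(kb_exact), denominator) if denominator else 0.0
    return LibraryMetrics(
        sn_star=sn_star,
        sp_star=sp_star,
        r_cc=r_cc,
        n_exact_recoveries=len(kb_exact),
        denominator=denominator,
    )


def exact_recovery_set(
    denovo: list, knowledge_based: list, tolerance: float = 0.05, min_identity: float = 90.0
) -> set:
    """Ids of full-length knowledge-based records exactly recovered by at
    least one de novo consensus (the per-method sets behind the
    combination argument)."""
    out = set()
    for kb in knowledge_based:
        if not kb.full_length:
            continue
        for dn in denovo:
            if exact_recovery(kb.sequence, dn.sequence, tolerance, min_identity):
                out.add(kb.id)
                break
    return out


# ---------------------------------------------------------------------------
# annotation-level metrics


def _union(ivs):
    ivs = sorted(ivs)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def _union_bp(per_seq: dict) -> int:
    return sum(e - s for ivs in per_seq.values() for s, e in _union(ivs))


def _intersect_bp(a: dict, b: dict) -> int:
    total = 0
    for seq_id, ivs_a in a.items():
        ivs_b = b.get(seq_id)
        if not ivs_b:
            continue
        ua, ub = _union(ivs_a), _union(ivs_b)
        i = j = 0
        while i < len(ua) and j < len(ub):
            s = max(ua[i][0], ub[j][0])
            e = min(ua[i][1], ub[j][1])
            if e > s:
                total += e - s
            if ua[i][1] < ub[j][1]:
                i += 1
            else:
                j += 1
    return total


def _as_per_seq(intervals) -> dict:
    per_seq: dict = {}
    for iv in intervals:
        per_seq.setdefault(iv.seq_id, []).append([iv.start, iv.end])
    return per_seq


def annotation_metrics(predicted, reference, genome: GenomeSet) -> AnnotationMetrics:
    """Nucleotide-level Sn, Sp and genome coverage of a TE annotation.

    Sn = |pred ∩ ref| / |ref| (few TE nucleotides missed), Sp =
    |pred ∩ ref| / |pred| (few non-TE nucleotides annotated), on bp of
    interval unions.  ``predicted``/``reference`` are Interval lists.
    """
    pred = _as_per_seq(predicted)
    ref = _as_per_seq(reference)
    ref_bp = _union_bp(ref)
    if ref_bp == 0:
        raise ValueError("empty reference annotation: Sn undefined")
    pred_bp = _union_bp(pred)
    inter = _intersect_bp(pred, ref)
    sn = 100.0 * inter / ref_bp
    sp = 100.0 * inter / pred_bp if pred_bp else None
    coverage = 100.0 * pred_bp / genome.total_length if genome.total_length else 0.0
    return AnnotationMetrics(
        sn=sn, sp=sp, genome_coverage=coverage, n_copies=len(predicted)
    )


def boundary_agreement(predicted, reference, tolerance_bp: int = 5) -> dict:
    """Per-end boundary comparison of each predicted interval against its
    best-overlapping reference interval.

    Returns counts: exact / over-extended / under-extended for the 5' and
    3' ends (exact = within ±tolerance)."""
    counts = {
        "exact_5p": 0,
        "over_5p": 0,
        "under_5p": 0,
        "exact_3p": 0,
        "over_3p": 0,
        "under_3p": 0,
        "unmatched": 0,
    }
    for p in predicted:
        best, best_ov = None, 0
        for r in reference:
            ov = p.overlap(r)
            if ov > best_ov:
                best, best_ov = r, ov
        if best is None:
            counts["unmatched"] += 1
            continue
        d5 = p.start - best.start
        if abs(d5) <= tolerance_bp:
            counts["exact_5p"] += 1
        elif d5 < 0:
            counts["over_5p"] += 1
        else:
            counts["under_5p"] += 1
        d3 = p.end - best.end
        if abs(d3) <= tolerance_bp:
            counts["exact_3p"] += 1
        elif d3 > 0:
            counts["over_3p"] += 1
        else:
            counts["under_3p"] += 1
    return counts
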