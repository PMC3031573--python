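"""All-by-all genomic self-comparison producing filtered pairwise matches.

First step of the de novo approach: the genome is cut into overlapping
chunks, every chunk pair is compared on both strands with the seed-and-
extend engine, matches are lifted back to genome coordinates, duplicates
(mirror pairs and chunk-overlap re-discoveries) are removed, collinear
chunk-boundary pieces are merged, and very long matches — segmental
duplications rather than TEs — are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_io import GenomeSet, Interval, Match
from .pairwise import cross_match

log = logging.getLogger("teforge")


@dataclass
class SelfAlignParams:
    """Thresholds of the self-alignment step.

    Defaults follow the stringent repeat-discovery setting: identity above
    90%, length above 100 bp, E-value cut-off 1e-300 (only applied when an
    E-value is computed; identity/length do the work), 200 kb chunks with
    10 kb overlaps, and removal of matches longer than 20 kb.
    """

    min_identity: float = 90.0
    min_length: int = 100
    max_evalue: float = 1e-300
    chunk_length: int = 200_000
    chunk_overlap: int = 10_000
    max_match_length: int = 20_000
    seed_k: int = 15

    def __post_init__(self):
        if self.chunk_overlap >= self.chunk_length:
            raise ValueError("chunk_overlap must be smaller than chunk_length")
        if self.min_length < self.seed_k:
            raise ValueError("min_length must be >= seed_k")


def chunk_genome(genome: GenomeSet, params: SelfAlignParams):
    """Cut each sequence into overlapping chunks.

    Returns a list of (chunk_id, Interval, sequence).  Consecutive chunks
    overlap by ``chunk_overlap``; a chunk fully contained in the previous
    one is skipped, so short sequences yield a single chunk.
    """
    step = params.chunk_length - params.chunk_overlap
    chunks = []
    i = 0
    for seq_id in genome:
        seq = genome[seq_id]
        L = len(seq)
        prev_end = -1
        for start in range(0, max(L, 1), step):
            end = min(start + params.chunk_length, L)
            if end <= prev_end:
                break
            chunks.append((f"chunk{i}", Interval(seq_id, start, end, "+"), seq[start:end]))
            prev_end = end
            i += 1
            if end == L:
                break
    return chunks


def _lift(m: Match, offsets: dict) -> Match:
    q_id, q_off = offsets[m.query.seq_id]
    s_id, s_off = offsets[m.subject.seq_id]
    return Match(
        id=m.id,
        query=Interval(q_id, m.query.start + q_off, m.query.end + q_off, "+"),
        subject=Interval(s_id, m.subject.start + s_off, m.subject.end + s_off, m.subject.strand),
        identity=m.identity,
        score=m.score,
        e_value=m.e_value,
    )


def _canonicalize(m: Match) -> Match:
    """Orient a match so query <= subject (mirror-duplicate canonical form)."""
    qk = (m.query.seq_id, m.query.start, m.query.end)
    sk = (m.subject.seq_id, m.subject.start, m.subject.end)
    if qk <= sk:
        return m
    return Match(
        id=m.id,
        query=Interval(m.subject.seq_id, m.subject.start, m.subject.end, "+"),
        subject=Interval(m.query.seq_id, m.query.start, m.query.end, m.subject.strand),
        identity=m.identity,
        score=m.score,
        e_value=m.e_value,
    )


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def _dedup_and_merge(matches, merge_gap=50, dup_coverage=0.95):
    """Remove chunk-overlap duplicates and merge collinear boundary pieces.

    Two matches are duplicates if query and subject intervals each overlap
    reciprocally >= ``dup_coverage``; the higher-scoring one is kept.
    Collinear pieces on a consistent diagonal that overlap (or nearly abut)
    are merged, which reconstitutes matches split at chunk boundaries.
    """
    groups: dict = {}
    for m in matches:
        groups.setdefault((m.query.seq_id, m.subject.seq_id, m.subject.strand), []).append(m)
    out = []
    for key, group in groups.items():
        strand = key[2]
        group.sort(key=lambda m: (m.query.start, m.subject.start))
        kept: list = []
        for m in group:
            merged = False
            for other in reversed(kept):
                if m.query.start - other.query.end > merge_gap:
                    break
                if _reciprocal_overlap(m.query, other.query) >= dup_coverage and _reciprocal_overlap(
                    m.subject, other.subject
                ) >= dup_coverage:
                    if m.score > other.score:
                        kept[kept.index(other)] = m
                    merged = True
                    break
                # collinear boundary merge: consistent diagonal, touching pieces
                if strand == "+":
                    diag_m = m.query.start - m.subject.start
                    diag_o = other.query.start - other.subject.start
                else:
                    diag_m = m.query.start + m.subject.end
                    diag_o = other.query.start + other.subject.end
                q_gap = m.query.start - other.query.end
                touching = q_gap <= merge_gap and m.query.end > other.query.end
                if touching and abs(diag_m - diag_o) <= merge_gap and m.subject.overlap(other.subject) >= 0:
                    n_new = max(0, m.query.end - other.query.end)
                    frac_new = n_new / max(1, m.query_length)
                    q = Interval(m.query.seq_id, other.query.start, m.query.end, "+")
                    s = Interval(
                        m.subject.seq_id,
                        min(m.subject.start, other.subject.start),
                        max(m.subject.end, other.subject.end),
                        strand,
                    )
                    w_o, w_m = other.query_length, n_new
                    identity = (other.identity * w_o + m.identity * w_m) / max(1, w_o + w_m)
                    kept[kept.index(other)] = Match(
                        id=other.id,
                        query=q,
                        subject=s,
                        identity=identity,
                        score=other.score + m.score * frac_new,
                    )
                    merged = True
                    break
            if not merged:
                kept.append(m)
        out.extend(kept)
    return out


def self_align(genome: GenomeSet, params: SelfAlignParams | None = None) -> list:
    """All-by-all comparison of the genome with itself.

    Every reported match exceeds the identity and length thresholds, the
    trivial self-identity diagonal is excluded, both strands are searched,
    chunk coordinates are lifted to genome coordinates, and mirror and
    chunk-overlap duplicates are removed.
    """
    if params is None:
        params = SelfAlignParams()
    if not genome:
        raise ValueError("empty genome")
    chunks = chunk_genome(genome, params)
    chunk_seqs = {cid: seq for cid, _, seq in chunks}
    offsets = {cid: (iv.seq_id, iv.start) for cid, iv, _ in chunks}
    raw: list = []
    ids = list(chunk_seqs)
    for i, qid in enumerate(ids):
        sub = {sid: chunk_seqs[sid] for sid in ids[i:]}
        raw.extend(
            cross_match(
                {qid: chunk_seqs[qid]},
                sub,
                min_identity=params.min_identity,
                min_length=params.min_length,
                k=params.seed_k,
                both_strands=True,
                exclude_self=True,
                start_id=len(raw),
            )
        )
    lifted = [_canonicalize(_lift(m, offsets)) for m in raw]
    # drop residual self-identity hits (identical coordinates)
    lifted = [
        m
        for m in lifted
        if not (m.query.seq_id == m.subject.seq_id and m.query.start == m.subject.start and m.query.end == m.subject.end and m.subject.strand == "+")
    ]
    seen = set()
    unique = []
    for m in lifted:
        key = m.mirror_key()
        if key in seen:
            continue
        seen.add(key)
        unique.append(m)
    merged = _dedup_and_merge(unique)
    merged.sort(key=lambda m: (m.query.seq_id, m.query.start, m.subject.seq_id, m.subject.start))
    for i, m in enumerate(merged):
        m.id = i
    log.info("self-alignment: %d matches after filtering", len(merged))
    return merged


def filter_long_matches(matches, params: SelfAlignParams | None = None) -> list:
    """Discard matches longer than ``max_match_length`` (strictly more than).

    Such matches correspond to long segmental duplications rather than TEs.
    The filter applies when either side of the match exceeds the threshold.
    """
    if params is None:
        params = SelfAlignParams()
    return [
        m
        for m in matches
        if max(m.query_length, m.subject_length) <= params.max_match_length
    ]


def repeat_coverage(matches, genome: GenomeSet) -> float:
    """Fraction of genome bp covered by at least one match side.

    Computed on the union of query and subject intervals; a lower limit for
    the repeat content of the genome.
    """
    per_seq: dict = {}
    for m in matches:
        per_seq.setdefault(m.query.seq_id, []).append((m.query.start, m.query.end))
        per_seq.setdefault(m.subject.seq_id, []).append((m.subject.start, m.subject.end))
    covered = 0
    for seq_id, ivs in per_seq.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    total = genome.total_length
    return covered / total if total else 0.0


def merge_intervals(ivs):
    """Union of (start, end) pairs as a sorted, disjoint list."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s > out[-1][1]:
            out.append([s, e])
        else:
            out[-1][1] = max(out[-1][1], e)
    return [tuple(iv) for iv in out]
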