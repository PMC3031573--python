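"""Seed-and-extend local alignment between nucleotide sequence sets.

Exact k-mer seeds are collected with numpy, grouped into near-diagonal
segments, and each candidate segment pair is verified with a unit-cost
banded alignment (edlib) from which identity and score (number of matching
columns) are computed.  This is the engine behind genome self-alignment,
consensus-to-genome mapping and nucleotide databank searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .core_io import Interval, Match, revcomp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i


def encode(seq: str) -> np.ndarray:
    """2-bit encode A/C/G/T; N (and anything else) becomes 255."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer codes; positions whose window contains N get -1."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = arr != 255
    a = np.where(valid, arr, 0).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        codes = codes * 4 + a[j : j + n]
        ok &= valid[j : j + n]
    codes[~ok] = -1
    return codes


def seed_hits(q_codes: np.ndarray, s_codes: np.ndarray, max_per_kmer: int = 2000):
    """All (qpos, spos) pairs with identical k-mers, via sorted subject codes."""
    if q_codes.size == 0 or s_codes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(s_codes, kind="stable")
    s_sorted = s_codes[order]
    left = np.searchsorted(s_sorted, q_codes, side="left")
    right = np.searchsorted(s_sorted, q_codes, side="right")
    counts = np.minimum(right - left, max_per_kmer)
    valid = (q_codes >= 0) & (counts > 0)
    counts = np.where(valid, counts, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qpos = np.repeat(np.arange(q_codes.size), counts)
    offsets = np.concatenate([np.arange(c) for c in counts[counts > 0]])
    spos = order[np.repeat(left[counts > 0], counts[counts > 0]) + offsets]
    return qpos, spos


@dataclass
class _Segment:
    qs: int
    qe: int
    ss: int
    se: int

    @property
    def diag(self) -> float:
        return (self.qs - self.ss + self.qe - self.se) / 2


def chain_seed_hits(qpos, spos, k, band=24, max_gap=200) -> list:
    """Group seed hits into near-diagonal segments.

    Hits are first merged per exact diagonal (splitting at query gaps larger
    than ``max_gap``), then mini-segments whose diagonals differ by at most
    ``band`` and whose query extents are within ``max_gap`` are unioned.
    """
    if qpos.size == 0:
        return []
    diag = qpos - spos
    order = np.lexsort((qpos, diag))
    qd, dd = qpos[order], diag[order]
    new_seg = np.ones(qd.size, dtype=bool)
    new_seg[1:] = (dd[1:] != dd[:-1]) | (qd[1:] - qd[:-1] > max_gap)
    starts = np.flatnonzero(new_seg)
    ends = np.r_[starts[1:], qd.size]
    minis = []
    for a, b in zip(starts, ends):
        q0, q1 = int(qd[a]), int(qd[b - 1]) + k
        d = int(dd[a])
        minis.append(_Segment(q0, q1, q0 - d, q1 - d))
    return _union_minis(minis, band, max_gap)


def _union_minis(minis, band, max_gap):
    n = len(minis)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    minis = sorted(minis, key=lambda s: s.qs)
    for i in range(n):
        si = minis[i]
        for j in range(i + 1, n):
            sj = minis[j]
            if sj.qs - si.qe > max_gap:
                break
            if abs(si.diag - sj.diag) <= band and sj.ss - si.se <= max_gap and si.ss - sj.se <= max_gap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(minis[i])
    out = []
    for segs in groups.values():
        out.append(
            _Segment(
                min(s.qs for s in segs),
                max(s.qe for s in segs),
                min(s.ss for s in segs),
                max(s.se for s in segs),
            )
        )
    out.sort(key=lambda s: (s.qs, s.ss))
    return out


def _cigar_stats(cigar: str):
    matches = mismatches = gaps = 0
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            n = int(num)
            num = ""
            if c == "=":
                matches += n
            elif c == "X":
                mismatches += n
            else:
                gaps += n
    return matches, mismatches, gaps


def align_global(a: str, b: str):
    """Unit-cost global alignment; returns (identity_pct, n_match_cols, n_cols)."""
    res = edlib.align(a, b, task="path", mode="NW")
    matches, mismatches, gaps = _cigar_stats(res["cigar"])
    cols = matches + mismatches + gaps
    return (100.0 * matches / cols if cols else 0.0), matches, cols


def _polish_ends(qarr, sarr, seg: _Segment):
    """Greedy ungapped extension of segment ends while bases match."""
    qs, qe, ss, se = seg.qs, seg.qe, seg.ss, seg.se
    while qs > 0 and ss > 0 and qarr[qs - 1] == sarr[ss - 1] and qarr[qs - 1] != 255:
        qs -= 1
        ss -= 1
    nq, ns = qarr.size, sarr.size
    while qe < nq and se < ns and qarr[qe] == sarr[se] and qarr[qe] != 255:
        qe += 1
        se += 1
    seg.qs, seg.qe, seg.ss, seg.se = qs, min(qe, nq), ss, min(se, ns)


def _expand_cigar(cigar: str):
    ops = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            ops.extend(c * int(num))
            num = ""
    return ops


def _trim_segment(cigar: str, match_score=1.0, penalty=3.0):
    """Locate the maximal-scoring contiguous sub-alignment of a global
    alignment (match +1, mismatch/indel -penalty; Kadane's rule), so that
    low-identity flanks introduced by seed padding are trimmed away.

    Returns (q_trim_left, q_trim_right, s_trim_left, s_trim_right,
    n_matches, n_columns) of the retained window.
    """
    ops = _expand_cigar(cigar)
    best = cur = 0.0
    best_span = (0, 0)
    cur_start = 0
    for i, op in enumerate(ops):
        sc = match_score if op == "=" else -penalty
        if cur <= 0:
            cur = sc
            cur_start = i
        else:
            cur += sc
        if cur > best:
            best = cur
            best_span = (cur_start, i + 1)
    a, b = best_span
    q0 = sum(1 for op in ops[:a] if op in "=XI")
    s0 = sum(1 for op in ops[:a] if op in "=XD")
    q1 = sum(1 for op in ops[b:] if op in "=XI")
    s1 = sum(1 for op in ops[b:] if op in "=XD")
    window = ops[a:b]
    matches = sum(1 for op in window if op == "=")
    return q0, q1, s0, s1, matches, len(window)


def verify_segments(qseq: str, sseq: str, segments, min_identity, min_length, pad=30):
    """Verify candidate segments with edlib, returning (qs,qe,ss,se,identity,score)."""
    qarr, sarr = encode(qseq), encode(sseq)
    out = []
    for seg in segments:
        seg.qs = max(0, seg.qs - pad)
        seg.ss = max(0, seg.ss - pad)
        seg.qe = min(len(qseq), seg.qe + pad)
        seg.se = min(len(sseq), seg.se + pad)
        _polish_ends(qarr, sarr, seg)
        qsub = qseq[seg.qs : seg.qe]
        ssub = sseq[seg.ss : seg.se]
        if min(len(qsub), len(ssub)) < min_length:
            continue
        res = edlib.align(qsub, ssub, task="path", mode="NW")
        q0, q1, s0, s1, matches, cols = _trim_segment(res["cigar"])
        qs, qe = seg.qs + q0, seg.qe - q1
        ss, se = seg.ss + s0, seg.se - s1
        # the unit-cost optimum is degenerate: pad asymmetry may be absorbed
        # as leading/trailing mismatches, which the trim then removes along
        # with genuine bases — re-extend greedily over exact matches
        while qs > 0 and ss > 0 and qarr[qs - 1] == sarr[ss - 1] and qarr[qs - 1] != 255:
            qs -= 1
            ss -= 1
            matches += 1
            cols += 1
        nq, ns = qarr.size, sarr.size
        while qe < nq and se < ns and qarr[qe] == sarr[se] and qarr[qe] != 255:
            qe += 1
            se += 1
            matches += 1
            cols += 1
        if qe - qs < min_length or se - ss < min_length:
            continue
        identity = 100.0 * matches / cols if cols else 0.0
        if identity <= min_identity:
            continue
        out.append((qs, qe, ss, se, identity, float(matches)))
    return out


def cross_match(
    query_seqs: dict,
    subject_seqs: dict,
    min_identity: float = 90.0,
    min_length: int = 100,
    k: int = 15,
    both_strands: bool = True,
    exclude_self: bool = False,
    band: int = 24,
    max_gap: int = 200,
    max_per_kmer: int = 2000,
    start_id: int = 0,
) -> list:
    """All local alignments between two sequence sets above the thresholds.

    Query intervals are always on ``+``; subject intervals carry the strand.
    With ``exclude_self`` the trivial full-length self-identity diagonal of
    identical (query id == subject id) pairs is suppressed.
    """
    matches: list = []
    next_id = start_id
    sub_cache = {}
    for sid, sseq in subject_seqs.items():
        codes = kmer_codes(encode(sseq), k)
        rc = revcomp(sseq)
        codes_rc = kmer_codes(encode(rc), k) if both_strands else None
        sub_cache[sid] = (sseq, codes, rc, codes_rc)
    for qid, qseq in query_seqs.items():
        q_codes = kmer_codes(encode(qseq), k)
        for sid, (sseq, s_codes, s_rc, s_codes_rc) in sub_cache.items():
            strands = ["+", "-"] if both_strands else ["+"]
            for strand in strands:
                codes = s_codes if strand == "+" else s_codes_rc
                target = sseq if strand == "+" else s_rc
                qpos, spos = seed_hits(q_codes, codes, max_per_kmer)
                if exclude_self and qid == sid and strand == "+":
                    keep = qpos != spos
                    qpos, spos = qpos[keep], spos[keep]
                if qpos.size == 0:
                    continue
                segs = chain_seed_hits(qpos, spos, k, band=band, max_gap=max_gap)
                for qs, qe, ss, se, identity, score in verify_segments(
                    qseq, target, segs, min_identity, min_length
                ):
                    if strand == "-":
                        ss, se = len(sseq) - se, len(sseq) - ss
                    if exclude_self and qid == sid and strand == "+" and qs == ss and qe == se:
                        continue
                    matches.append(
                        Match(
                            id=next_id,
                            query=Interval(qid, qs, qe, "+"),
                            subject=Interval(sid, ss, se, strand),
                            identity=identity,
                            score=score,
                        )
                    )
                    next_id += 1
    return matches


def best_hit(query: str, subject: str, min_identity=0.0, min_length=1, k=11):
    """Best-scoring local alignment between two sequences (or None)."""
    hits = cross_match(
        {"q": query}, {"s": subject}, min_identity=min_identity, min_length=min_length, k=k
    )
    if not hits:
        return None
    return max(hits, key=lambda m: m.score)


def included_identity(query: str, subject: str):
    """Identity and coverage of ``query`` aligned as an infix of ``subject``.

    Used for the inclusion test of redundancy removal.  The query is
    aligned wholly within the subject (edlib HW); the maximal-scoring
    sub-alignment is then extracted so that a non-homologous overhang does
    not contribute its chance matches.  Returns (identity_pct,
    homologous_coverage_of_query).
    """
    if not query or not subject:
        return (0.0, 0.0)
    res = edlib.align(query, subject, task="path", mode="HW")
    if res["editDistance"] < 0:
        return (0.0, 0.0)
    q0, q1, _, _, matches, cols = _trim_segment(res["cigar"])
    q_in_window = len(query) - q0 - q1
    identity = 100.0 * matches / cols if cols else 0.0
    return (identity, q_in_window / len(query))
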