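"""Feature-based classification of TE consensus sequences.

Each consensus is searched for structural features (terminal repeats,
tails, tandem content) and homology evidence (nucleotide and translated
matches against a labelled TE databank, matches against host genes); a
decision tree then assigns a class/order label plus a completeness flag:
a consensus with both structural and coding features is "complete", with
only one of the two it is "incomplete", with contradictory features it is
"confused", and with none it is not categorized.

Redundancy introduced by combining several clustering methods is removed
afterwards with classification-aware rules (the stringent 95-80-98
setting): an "incomplete" consensus included in a "complete" one is
dropped, never the reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core_io import revcomp
from .pairwise import cross_match, encode, included_identity

log = logging.getLogger("teforge")

LABELS = (
    "classI-LTR",
    "classI-LINE",
    "classI-SINE",
    "classII-TIR",
    "classII-MITE",
    "Helitron",
    "SSR",
    "HostGene",
    "Confused",
    "NoCategory",
)


@dataclass
class TerminalRepeat:
    len_5p: int
    len_3p: int
    identity: float


@dataclass
class FeatureSet:
    ltr: Optional[TerminalRepeat] = None
    tir: Optional[TerminalRepeat] = None
    polyA_tail: bool = False
    ssr_tail: bool = False
    tandem_fraction: float = 0.0
    te_hits_nt: list = field(default_factory=list)  # (db_id, label, coverage, identity)
    te_hits_translated: list = field(default_factory=list)
    host_gene_hits: list = field(default_factory=list)

    @property
    def has_structural(self) -> bool:
        return self.ltr is not None or self.tir is not None or self.polyA_tail or self.ssr_tail

    @property
    def has_coding(self) -> bool:
        return bool(self.te_hits_translated)

    @property
    def has_te_evidence(self) -> bool:
        return bool(self.te_hits_nt or self.te_hits_translated) or self.has_structural


@dataclass
class Classification:
    label: str
    completeness: str = "not-applicable"  # complete | incomplete | not-applicable
    evidence: list = field(default_factory=list)


@dataclass
class LengthRanges:
    """Per-category plausible length ranges (bp), used for completeness
    sanity checks and for the SINE/MITE calls.  Package defaults calibrated
    on synthetic families; override for a real databank."""

    ltr_retro: tuple = (1500, 25_000)
    line: tuple = (1500, 10_000)
    sine: tuple = (80, 500)
    dna_transposon: tuple = (800, 20_000)
    mite: tuple = (80, 800)

    def in_range(self, category: str, length: int) -> bool:
        lo, hi = getattr(self, category)
        return lo <= length <= hi


# ---------------------------------------------------------------------------
# structural feature detectors


def _local_aligner(match=2, mismatch=-3, open_gap=-5, extend=-2):
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = open_gap
    a.extend_gap_score = extend
    return a


def _best_local(a_seq: str, b_seq: str):
    """Best local alignment: ((a_start, a_end), (b_start, b_end), identity, length)."""
    aligner = _local_aligner()
    if not a_seq or not b_seq:
        return None
    alns = aligner.align(a_seq, b_seq)
    if len(alns) == 0:
        return None
    aln = alns[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return None
    matches = 0
    cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            cols += 1
            if a_seq[as_ + i] == b_seq[bs + i]:
                matches += 1
    # count gap columns between blocks
    for i in range(1, len(blocks_a)):
        cols += (blocks_a[i][0] - blocks_a[i - 1][1]) + (blocks_b[i][0] - blocks_b[i - 1][1])
    identity = 100.0 * matches / cols if cols else 0.0
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    length = max(a_span[1] - a_span[0], b_span[1] - b_span[0])
    return a_span, b_span, identity, length


def detect_terminal_repeats(
    consensus: str,
    window_frac: float = 0.25,
    window_cap: int = 2000,
    ltr_min_len: int = 100,
    tir_min_len: int = 10,
    min_identity: float = 80.0,
    edge_tolerance: int = 50,
    tir_edge_tolerance: int = 20,
):
    """Detect LTRs (direct terminal repeats) and TIRs (inverted terminal
    repeats) by locally aligning the two terminal windows.

    A hit must be anchored at the sequence ends (within the edge tolerance)
    — terminal repeats are terminal — which keeps the false-positive rate
    on random sequences low.
    """
    L = len(consensus)
    if L < 100:
        return None, None
    w = min(max(int(window_frac * L), 100), window_cap, L // 2)
    head = consensus[:w]
    tail = consensus[L - w :]
    ltr = None
    res = _best_local(head, tail)
    if res is not None:
        (hs, he), (ts, te), identity, length = res
        anchored = hs <= edge_tolerance and te >= w - edge_tolerance
        if anchored and identity >= min_identity and length >= ltr_min_len:
            ltr = TerminalRepeat(len_5p=he - hs, len_3p=te - ts, identity=identity)
    tir = None
    res = _best_local(head, revcomp(tail))
    if res is not None:
        (hs, he), (ts, te), identity, length = res
        # in revcomp coordinates the 3' terminus is at position 0
        anchored = hs <= tir_edge_tolerance and ts <= tir_edge_tolerance
        if anchored and identity >= min_identity and length >= tir_min_len:
            tir = TerminalRepeat(len_5p=he - hs, len_3p=te - ts, identity=identity)
    return ltr, tir


def detect_tails(
    consensus: str,
    window: int = 30,
    ssr_window: int = 50,
    polyA_min_run: int = 10,
    polyA_max_impurity: float = 0.20,
):
    """Detect a polyA tail or an SSR-like tail at either terminus.

    polyA: a run of >= 10 bases, at most 20% non-A, within the terminal
    30 bp (an A-tail at the 3' end or its reverse complement, a T-head, at
    the 5' end).  SSR tail: a 1-6 bp motif tandemly repeated >= 5 times
    within the terminal 50 bp of either end.
    """

    def _a_rich(s: str, base: str) -> bool:
        n = len(s)
        for i in range(n):
            for j in range(i + polyA_min_run, n + 1):
                seg = s[i:j]
                if seg.count(base) >= (1 - polyA_max_impurity) * len(seg):
                    return True
        return False

    polyA = _a_rich(consensus[-window:], "A") or _a_rich(consensus[:window], "T")
    ssr = False
    for terminal in (consensus[:ssr_window], consensus[-ssr_window:]):
        sats = microsatellite_intervals(terminal, min_copies=5, min_array_len=10)
        if sats:
            ssr = True
            break
    return polyA, ssr


def _offset_runs(arr: np.ndarray, m: int, min_window_identity: float = 0.8):
    """Boolean mask of positions participating in an m-periodic repeat."""
    n = arr.size
    if n < 2 * m:
        return None
    eq = (arr[m:] == arr[:-m]) & (arr[m:] != 255)
    w = min(max(m, 5), 20)
    if eq.size < w:
        return None
    c = np.cumsum(np.r_[0, eq.astype(np.int64)])
    means = (c[w:] - c[:-w]) / w
    good = means >= min_window_identity
    return eq, good, w


def _mark_covered(covered, eq, good, w, m, min_array_len, min_copies):
    """A qualifying run of m-periodic agreement must extend roughly one
    motif length per extra copy — a single lucky window is not a tandem."""
    idx = np.flatnonzero(good)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    for s, e in zip(starts, ends):
        run = e - s + w  # extent in eq coordinates
        array_len = run + m
        if array_len >= min_array_len and run >= 0.9 * (min_copies - 1) * m:
            covered[s : min(covered.size, s + array_len)] = True


def detect_tandem(
    consensus: str,
    max_motif: int = 500,
    min_copies: float = 2.0,
    min_array_len: int = 20,
    min_identity: float = 0.8,
) -> float:
    """Fraction of positions inside tandem arrays (motif 1-500 bp, >= 2
    copies, >= 80% motif identity), found by a self-alignment-offset scan."""
    arr = encode(consensus)
    n = arr.size
    covered = np.zeros(n, dtype=bool)
    for m in range(1, min(max_motif, n // 2) + 1):
        res = _offset_runs(arr, m, min_identity)
        if res is None:
            continue
        eq, good, w = res
        _mark_covered(covered, eq, good, w, m, min_array_len, min_copies)
    return float(covered.sum()) / n if n else 0.0


def microsatellite_intervals(
    seq: str,
    max_motif: int = 6,
    min_copies: float = 5.0,
    min_array_len: int = 20,
    min_identity: float = 0.9,
) -> list:
    """Microsatellite (SSR) tracts: motif 1-6 bp repeated >= 5 times.
    Returns merged (start, end) intervals."""
    arr = encode(seq)
    n = arr.size
    covered = np.zeros(n, dtype=bool)
    for m in range(1, min(max_motif, max(1, n // 2)) + 1):
        res = _offset_runs(arr, m, min_identity)
        if res is None:
            continue
        eq, good, w = res
        _mark_covered(covered, eq, good, w, m, min_array_len, min_copies)
    idx = np.flatnonzero(covered)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# homology evidence


def parse_databank_label(header: str) -> str:
    """Extract the class/order label from a databank header of the form
    ``id#Class/Order``; unlabeled records yield "unknown" (with a warning
    issued by the caller)."""
    if "#" in header:
        return header.split("#", 1)[1]
    return "unknown"


_ORDER_KEYWORDS = {
    "LTR": "classI-LTR",
    "LINE": "classI-LINE",
    "SINE": "classI-SINE",
    "TIR": "classII-TIR",
    "DNA": "classII-TIR",
    "MITE": "classII-MITE",
    "HELITRON": "Helitron",
}


def label_to_order(label: str) -> Optional[str]:
    up = label.upper()
    for kw, order in _ORDER_KEYWORDS.items():
        if kw in up:
            return order
    return None


def _six_frames(seq: str) -> list:
    frames = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append(str(Seq(sub).translate()))
    return frames


def _protein_kmers(p: str, k: int = 4) -> set:
    return {p[i : i + k] for i in range(len(p) - k + 1)}


def _protein_local(a: str, b: str):
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    try:
        alns = aligner.align(a.replace("*", "X"), b.replace("*", "X"))
    except Exception:
        return None
    if len(alns) == 0:
        return None
    aln = alns[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return None
    matches = cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            cols += 1
            if a[as_ + i] == b[bs + i]:
                matches += 1
    length = int(blocks_a[-1][1] - blocks_a[0][0])
    identity = 100.0 * matches / cols if cols else 0.0
    return identity, length


def search_databank(
    consensus: str,
    databank: dict,
    mode: str = "nucleotide",
    nt_min_identity: float = 70.0,
    nt_min_length: int = 100,
    aa_min_identity: float = 30.0,
    aa_min_length: int = 50,
) -> list:
    """Search a labelled databank (headers ``id#Class/Order``) for local
    alignments with the consensus.

    ``nucleotide`` mode uses the seed-and-extend nucleotide engine;
    ``translated`` mode compares six-frame translations of both sequences
    (a 4-mer prefilter keeps only promising frame pairs).  Hits are
    (databank-id, label, coverage-of-consensus, identity).
    """
    hits = []
    if mode == "nucleotide":
        matches = cross_match(
            {"q": consensus},
            databank,
            min_identity=nt_min_identity,
            min_length=nt_min_length,
            k=11,
        )
        best_per_subject: dict = {}
        for m in matches:
            cur = best_per_subject.get(m.subject.seq_id)
            if cur is None or m.score > cur.score:
                best_per_subject[m.subject.seq_id] = m
        for sid, m in sorted(best_per_subject.items()):
            label = parse_databank_label(sid)
            if label == "unknown":
                log.warning("databank record %s has no class/order label", sid)
            hits.append((sid, label, m.query_length / len(consensus), m.identity))
    elif mode == "translated":
        q_frames = _six_frames(consensus)
        for sid in sorted(databank):
            label = parse_databank_label(sid)
            if label == "unknown":
                log.warning("databank record %s has no class/order label", sid)
            best = None
            s_frames = _six_frames(databank[sid])
            for qf in q_frames:
                qk = _protein_kmers(qf)
                for sf in s_frames:
                    if len(qk & _protein_kmers(sf)) < 3:
                        continue
                    res = _protein_local(qf, sf)
                    if res is None:
                        continue
                    identity, length = res
                    if identity >= aa_min_identity and length >= aa_min_length:
                        if best is None or length * identity > best[0] * best[1]:
                            best = (length, identity)
            if best is not None:
                hits.append((sid, label, 3 * best[0] / len(consensus), best[1]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return hits


def compute_features(
    consensus: str,
    te_databank: Optional[dict] = None,
    host_genes: Optional[dict] = None,
) -> FeatureSet:
    """Run all feature detectors on one consensus sequence."""
    ltr, tir = detect_terminal_repeats(consensus) if len(consensus) >= 100 else (None, None)
    polyA, ssr_tail = detect_tails(consensus)
    tandem = detect_tandem(consensus)
    fs = FeatureSet(
        ltr=ltr, tir=tir, polyA_tail=polyA, ssr_tail=ssr_tail, tandem_fraction=tandem
    )
    if te_databank:
        fs.te_hits_nt = search_databank(consensus, te_databank, "nucleotide")
        fs.te_hits_translated = search_databank(consensus, te_databank, "translated")
    if host_genes:
        matches = cross_match(
            {"q": consensus}, host_genes, min_identity=70.0, min_length=100, k=11
        )
        fs.host_gene_hits = sorted({m.subject.seq_id for m in matches})
    return fs


# ---------------------------------------------------------------------------
# decision tree


def _hit_orders(features: FeatureSet) -> set:
    orders = set()
    for hits in (features.te_hits_nt, features.te_hits_translated):
        for _, label, _, _ in hits:
            o = label_to_order(label)
            if o:
                orders.add(o)
    return orders


def _structural_order(features: FeatureSet) -> Optional[str]:
    if features.ltr is not None:
        return "classI-LTR"
    if features.tir is not None:
        return "classII-TIR"
    if features.polyA_tail or features.ssr_tail:
        return "classI-LINE"
    return None


_RANGE_OF_ORDER = {
    "classI-LTR": "ltr_retro",
    "classI-LINE": "line",
    "classII-TIR": "dna_transposon",
    "classI-SINE": "sine",
    "classII-MITE": "mite",
}


def classify_consensus(
    features: FeatureSet, length: int, ranges: Optional[LengthRanges] = None
) -> Classification:
    """Apply the decision tree to one consensus.

    Test order: SSR → host gene → contradictions → complete (structural +
    coding) → incomplete (coding only) → SINE/MITE or incomplete
    (structural only) → no category.  A pure function of its inputs.
    """
    if ranges is None:
        ranges = LengthRanges()
    ev: list = []
    # 1. tandem-repeat dominated
    if features.tandem_fraction > 0.75:
        return Classification("SSR", "not-applicable", [f"tandem fraction {features.tandem_fraction:.2f}"])
    # 2. host gene with no TE evidence
    if features.host_gene_hits and not features.has_te_evidence:
        return Classification("HostGene", "not-applicable", [f"host gene hits: {features.host_gene_hits}"])
    hit_orders = _hit_orders(features)
    struct_order = _structural_order(features)
    # 3. contradictions
    if features.ltr is not None and features.polyA_tail:
        return Classification("Confused", "not-applicable", ["LTR pair and polyA tail are contradictory"])
    if features.ltr is not None and features.tir is not None:
        return Classification("Confused", "not-applicable", ["both LTRs and TIRs detected"])
    if len(hit_orders - {"Helitron"}) > 1:
        return Classification(
            "Confused", "not-applicable", [f"databank hits of conflicting orders: {sorted(hit_orders)}"]
        )
    # 4. structural + coding -> complete
    if struct_order is not None and features.has_coding:
        if hit_orders and struct_order not in hit_orders and hit_orders != {"Helitron"}:
            return Classification(
                "Confused",
                "not-applicable",
                [f"structural order {struct_order} conflicts with hits {sorted(hit_orders)}"],
            )
        rng_key = _RANGE_OF_ORDER[struct_order]
        if not ranges.in_range(rng_key, length):
            return Classification(
                "Confused", "not-applicable", [f"length {length} outside {rng_key} range"]
            )
        ev.append(f"structural {struct_order} + coding evidence")
        return Classification(struct_order, "complete", ev)
    # 5. coding only -> incomplete of the hit's order
    if hit_orders:
        order = sorted(hit_orders)[0]
        if order == "Helitron":
            return Classification("Helitron", "not-applicable", ["databank Helitron homology"])
        if order in ("classI-SINE", "classII-MITE"):
            return Classification(order, "not-applicable", ["databank homology"])
        return Classification(order, "incomplete", ["databank homology without structural features"])
    # 6. structural only
    if struct_order is not None:
        if struct_order == "classI-LINE" and ranges.in_range("sine", length):
            return Classification("classI-SINE", "not-applicable", ["tail + SINE-range length"])
        if struct_order == "classII-TIR" and ranges.in_range("mite", length):
            return Classification("classII-MITE", "not-applicable", ["TIRs + MITE-range length"])
        rng_key = _RANGE_OF_ORDER[struct_order]
        if not ranges.in_range(rng_key, length):
            return Classification(
                "Confused", "not-applicable", [f"length {length} outside {rng_key} range"]
            )
        return Classification(struct_order, "incomplete", ["structural features without coding evidence"])
    # 7. nothing
    return Classification("NoCategory", "not-applicable", [])


# ---------------------------------------------------------------------------
# redundancy removal


def _protection_rank(cls: Classification) -> int:
    """Redundancy-removal protection: complete > any positively labelled
    record > unclassifiable (NoCategory/Confused).  A well-classified
    consensus is never removed by an unclassifiable (possibly chimeric)
    one — removing redundancy blind to classification loses well
    classified consensuses to longer, misclassified ones."""
    if cls.completeness == "complete":
        return 2
    if cls.label in ("NoCategory", "Confused"):
        return 0
    return 1


def remove_redundancy(
    records: list,
    x_identity: float = 95.0,
    min_len: int = 80,
    y_coverage: float = 98.0,
) -> list:
    """Remove consensus sequences included within another over >= 98% of
    their length with > 95% identity (alignment at least 80 bp), with
    classification-aware asymmetry: an incomplete consensus included in a
    complete one is removed, never the reverse; among equal completeness
    the shorter is removed.  Deterministic, idempotent, and never empties a
    non-empty input.

    ``records`` is a list of (ConsensusRecord, Classification) pairs.
    """
    order = sorted(
        range(len(records)),
        key=lambda i: (
            -_protection_rank(records[i][1]),
            -len(records[i][0].sequence),
            records[i][0].id,
        ),
    )
    retained: list = []
    for i in order:
        rec, cls = records[i]
        rank = _protection_rank(cls)
        redundant = False
        for rec_b, cls_b in retained:
            if len(rec.sequence) < min_len:
                break
            if _protection_rank(cls_b) < rank:
                continue  # a better-classified record is never the remover
            if len(rec_b.sequence) < len(rec.sequence):
                continue
            for query in (rec.sequence, revcomp(rec.sequence)):
                identity, coverage = included_identity(query, rec_b.sequence)
                if identity > x_identity and coverage * 100 >= y_coverage and len(rec.sequence) * coverage >= min_len:
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            retained.append((rec, cls))
    retained.sort(key=lambda rc: rc[0].id)
    return retained
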