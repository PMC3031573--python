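"""Genome annotation of TE copies from a consensus library.

The library is mapped onto both strands of the genome; false-positive
matches are filtered with a shuffled-genome null model (the score
threshold is the 95% quantile of scores obtained on composition-preserving
shuffled sequences — using the maximum instead, the legacy behaviour,
over-filters on the strength of one lucky match).  Fragments of the same
copy are then connected by dynamic programming and overlapping chains are
resolved afterwards ("TE defragmentation"); a long-join pass re-connects
copies split by younger nested insertions, using a length-weighted mean
identity as the age proxy.  Finally short fragments fully recovered by
microsatellites are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_io import Feature, GenomeSet, Interval
from .classify import microsatellite_intervals
from .pairwise import cross_match

log = logging.getLogger("teforge")


@dataclass
class AnnotateParams:
    min_identity: float = 80.0
    min_length: int = 20
    seed_k: int = 11
    null_quantile: float = 0.95
    # matcher joins: small gaps and deletions within one copy
    matcher_genome_gap: int = 5000
    matcher_cons_gap: int = 500
    overlap_tolerance: int = 20
    join_open_cost: float = 20.0
    join_per_bp_cost: float = 0.02
    # long join: bridging younger nested insertions
    longjoin_max_gap: int = 100_000
    longjoin_plain_gap: int = 1000
    longjoin_nest_coverage: float = 0.90
    age_formula: str = "weighted"  # or "literal": sum(identity/length)
    # microsatellite filter
    sat_min_coverage: float = 0.95
    sat_max_fragment: int = 150


@dataclass
class TEFragment:
    """A match between a TE consensus and the genome."""

    genome_iv: Interval
    consensus_id: str
    cons_start: int
    cons_end: int
    identity: float
    score: float

    def __len__(self):
        return len(self.genome_iv)


@dataclass
class TECopy:
    """A chain of collinear fragments reconstructing one insertion."""

    fragments: list = field(default_factory=list)
    copy_id: str = ""

    @property
    def genome_iv(self) -> Interval:
        f0, f1 = self.fragments[0], self.fragments[-1]
        return Interval(
            f0.genome_iv.seq_id,
            min(f.genome_iv.start for f in self.fragments),
            max(f.genome_iv.end for f in self.fragments),
            f0.genome_iv.strand,
        )

    @property
    def consensus_id(self) -> str:
        return self.fragments[0].consensus_id

    @property
    def score(self) -> float:
        return sum(f.score for f in self.fragments)

    @property
    def length(self) -> int:
        return sum(len(f) for f in self.fragments)

    def age_score(self, formula: str = "weighted") -> float:
        """Proxy for the age of the copy; higher = younger.

        ``weighted``: length-weighted mean identity of the fragments.
        ``literal``: Σ identity/length over the fragments.
        """
        if formula == "literal":
            return sum(f.identity / len(f) for f in self.fragments)
        total = sum(len(f) for f in self.fragments)
        return sum(f.identity * len(f) for f in self.fragments) / total if total else 0.0


@dataclass
class NullModel:
    scores: list
    threshold: float

    @classmethod
    def from_scores(cls, scores, quantile=0.95) -> "NullModel":
        scores = sorted(float(s) for s in scores)
        if not scores:
            return cls(scores=[], threshold=0.0)
        thr = float(np.quantile(scores, quantile))
        return cls(scores=scores, threshold=thr)


def map_library(library: dict, genome: GenomeSet, params: Optional[AnnotateParams] = None) -> list:
    """Local alignments of each consensus against both genome strands."""
    if params is None:
        params = AnnotateParams()
    if not library:
        raise ValueError("empty library")
    matches = cross_match(
        library,
        genome,
        min_identity=params.min_identity,
        min_length=params.min_length,
        k=params.seed_k,
        both_strands=True,
    )
    frags = [
        TEFragment(
            genome_iv=m.subject,
            consensus_id=m.query.seq_id,
            cons_start=m.query.start,
            cons_end=m.query.end,
            identity=m.identity,
            score=m.score,
        )
        for m in matches
    ]
    frags.sort(key=lambda f: (f.genome_iv.seq_id, f.genome_iv.start, f.consensus_id))
    return frags


def shuffle_genome(genome: GenomeSet, seed: int, mode: str = "mono") -> GenomeSet:
    """Composition-preserving shuffle of each sequence (mononucleotide by
    default; ``dinucleotide`` keeps the dinucleotide composition by a
    2-mer chunk permutation)."""
    rng = np.random.default_rng(seed)
    out = GenomeSet()
    for name in genome:
        seq = genome[name]
        if mode == "dinucleotide":
            chunks = [seq[i : i + 2] for i in range(0, len(seq), 2)]
            rng.shuffle(chunks)
            out[name] = "".join(chunks)
        else:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            rng.shuffle(arr)
            out[name] = arr.tobytes().decode()
    return out


def build_null(
    library: dict, genome: GenomeSet, seed: int, params: Optional[AnnotateParams] = None
) -> NullModel:
    """Map the library onto the shuffled genome with identical parameters;
    the filter threshold is the empirical 95th percentile of null scores."""
    if params is None:
        params = AnnotateParams()
    shuffled = shuffle_genome(genome, seed)
    try:
        frags = map_library(library, shuffled, params)
    except ValueError:
        frags = []
    return NullModel.from_scores([f.score for f in frags], params.null_quantile)


def filter_by_null(fragments, null: NullModel) -> list:
    return [f for f in fragments if f.score > null.threshold]


def matcher_defragment(fragments, params: Optional[AnnotateParams] = None) -> list:
    """Connect fragments into copies by dynamic programming, then resolve
    overlaps between chains.

    Joins require collinearity (genome and consensus order agree,
    strand-aware) and bounded gaps.  Connecting first means a fragment that
    would lose a pairwise overlap contest can survive inside a
    higher-scoring chain.
    """
    if params is None:
        params = AnnotateParams()
    tol = params.overlap_tolerance
    groups: dict = {}
    for f in fragments:
        groups.setdefault((f.genome_iv.seq_id, f.consensus_id, f.genome_iv.strand), []).append(f)
    chains: list = []
    for key, group in sorted(groups.items()):
        strand = key[2]
        group.sort(key=lambda f: (f.genome_iv.start, f.cons_start))
        n = len(group)
        best = [f.score for f in group]
        parent = [-1] * n
        for j in range(n):
            fj = group[j]
            for i in range(j):
                fi = group[i]
                g_gap = fj.genome_iv.start - fi.genome_iv.end
                if g_gap < -tol or g_gap > params.matcher_genome_gap:
                    continue
                if strand == "+":
                    c_gap = fj.cons_start - fi.cons_end
                else:
                    c_gap = fi.cons_start - fj.cons_end
                if c_gap < -tol or c_gap > params.matcher_cons_gap:
                    continue
                gap = max(g_gap, c_gap, 0)
                cost = params.join_open_cost + params.join_per_bp_cost * gap
                cand = best[i] + fj.score - cost
                if cand > best[j]:
                    best[j] = cand
                    parent[j] = i
        used = [False] * n
        for j in sorted(range(n), key=lambda j: -best[j]):
            if used[j]:
                continue
            path = []
            cur = j
            while cur != -1 and not used[cur]:
                path.append(cur)
                used[cur] = True
                cur = parent[cur]
            path.reverse()
            chains.append(TECopy(fragments=[group[i] for i in path]))
    # resolve overlapping chains: higher-scoring chain wins; the loser is
    # truncated (overlapping fragments trimmed or dropped)
    per_seq: dict = {}
    for c in chains:
        per_seq.setdefault(c.genome_iv.seq_id, []).append(c)
    out = []
    for seq_id in sorted(per_seq):
        kept_ivs: list = []
        for c in sorted(per_seq[seq_id], key=lambda c: (-c.score, c.genome_iv.start, c.consensus_id)):
            new_frags = []
            for f in c.fragments:
                s, e = f.genome_iv.start, f.genome_iv.end
                for ks, ke in kept_ivs:
                    ov = min(e, ke) - max(s, ks)
                    if ov <= tol:
                        continue
                    # trim the side that overlaps
                    if ks <= s:
                        s = min(e, ke)
                    else:
                        e = max(s, ks)
                if e - s >= max(params.min_length, 1):
                    frac = (e - s) / len(f)
                    nf = TEFragment(
                        genome_iv=Interval(f.genome_iv.seq_id, s, e, f.genome_iv.strand),
                        consensus_id=f.consensus_id,
                        cons_start=f.cons_start,
                        cons_end=f.cons_end,
                        identity=f.identity,
                        score=f.score * frac,
                    )
                    new_frags.append(nf)
            if new_frags:
                for f in new_frags:
                    kept_ivs.append((f.genome_iv.start, f.genome_iv.end))
                out.append(TECopy(fragments=new_frags))
    out.sort(key=lambda c: (c.genome_iv.seq_id, c.genome_iv.start, c.consensus_id))
    for i, c in enumerate(out):
        c.copy_id = f"copy{i}"
    return out


def long_join(copies, params: Optional[AnnotateParams] = None) -> list:
    """Merge same-consensus copies separated by younger nested insertions.

    Two consecutive copies of one consensus are merged when collinear and
    either nearly adjacent (gap <= 1 kb) or separated by a region mostly
    covered by strictly younger copies (higher age score) within 100 kb.
    """
    if params is None:
        params = AnnotateParams()
    per_seq: dict = {}
    for c in copies:
        per_seq.setdefault(c.genome_iv.seq_id, []).append(c)
    merged_all = []
    for seq_id in sorted(per_seq):
        seq_copies = sorted(per_seq[seq_id], key=lambda c: c.genome_iv.start)
        groups: dict = {}
        for c in seq_copies:
            groups.setdefault((c.consensus_id, c.genome_iv.strand), []).append(c)
        merged_here = []
        for (cons_id, strand), group in sorted(groups.items()):
            group.sort(key=lambda c: c.genome_iv.start)
            cur = group[0]
            for nxt in group[1:]:
                gap_s, gap_e = cur.genome_iv.end, nxt.genome_iv.start
                gap = gap_e - gap_s
                # collinearity on the consensus
                if strand == "+":
                    collinear = nxt.fragments[0].cons_start >= cur.fragments[-1].cons_end - params.overlap_tolerance
                else:
                    collinear = nxt.fragments[0].cons_end <= cur.fragments[-1].cons_start + params.overlap_tolerance
                ok = False
                if collinear and gap <= params.longjoin_plain_gap:
                    ok = True
                elif collinear and 0 < gap <= params.longjoin_max_gap:
                    age_here = max(
                        cur.age_score(params.age_formula), nxt.age_score(params.age_formula)
                    )
                    younger_ivs = [
                        (f.genome_iv.start, f.genome_iv.end)
                        for other in seq_copies
                        if other is not cur and other is not nxt
                        and other.age_score(params.age_formula) > age_here
                        for f in other.fragments
                    ]
                    cov = _interval_cover(younger_ivs, gap_s, gap_e)
                    ok = cov >= params.longjoin_nest_coverage * gap
                if ok:
                    cur = TECopy(fragments=cur.fragments + nxt.fragments, copy_id=cur.copy_id)
                else:
                    merged_here.append(cur)
                    cur = nxt
            merged_here.append(cur)
        merged_all.extend(merged_here)
    merged_all.sort(key=lambda c: (c.genome_iv.seq_id, c.genome_iv.start, c.consensus_id))
    for i, c in enumerate(merged_all):
        c.copy_id = f"copy{i}"
    return merged_all


def _interval_cover(ivs, lo, hi) -> int:
    ivs = sorted((max(s, lo), min(e, hi)) for s, e in ivs)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if e <= s:
            continue
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def detect_microsatellites(genome: GenomeSet) -> dict:
    """Microsatellite tracts per sequence: motif 1-6 bp, >= 5 copies."""
    return {name: microsatellite_intervals(genome[name]) for name in genome}


def filter_satellite_overlaps(
    copies, sat_intervals: dict, params: Optional[AnnotateParams] = None
) -> list:
    """Drop short TE fragments (< 150 bp) fully (>= 95%) recovered by
    microsatellites; copies losing all fragments are dropped."""
    if params is None:
        params = AnnotateParams()
    out = []
    for c in copies:
        sats = sat_intervals.get(c.genome_iv.seq_id, [])
        keep = []
        for f in c.fragments:
            if len(f) < params.sat_max_fragment:
                cov = _interval_cover(sats, f.genome_iv.start, f.genome_iv.end)
                if cov >= params.sat_min_coverage * len(f):
                    continue
            keep.append(f)
        if keep:
            out.append(TECopy(fragments=keep, copy_id=c.copy_id))
    return out


def annotate_genome(
    library: dict,
    genome: GenomeSet,
    seed: int = 17,
    params: Optional[AnnotateParams] = None,
    use_null: bool = True,
) -> list:
    """Full annotation: map, null-filter, defragment, long-join,
    microsatellite-filter.  Returns a list of :class:`TECopy`."""
    if params is None:
        params = AnnotateParams()
    frags = map_library(library, genome, params)
    if use_null:
        null = build_null(library, genome, seed, params)
        frags = filter_by_null(frags, null)
        log.info("null threshold %.1f; %d fragments survive", null.threshold, len(frags))
    copies = matcher_defragment(frags, params)
    copies = long_join(copies, params)
    sats = detect_microsatellites(genome)
    copies = filter_satellite_overlaps(copies, sats, params)
    return copies


def copies_to_features(copies) -> list:
    """GFF3 features: TE_fragment children of TE_copy."""
    feats = []
    for c in copies:
        feats.append(
            Feature(
                interval=c.genome_iv,
                type="TE_copy",
                attributes={
                    "ID": c.copy_id,
                    "consensus": c.consensus_id,
                    "identity": f"{c.age_score():.1f}",
                },
            )
        )
        for i, f in enumerate(c.fragments):
            feats.append(
                Feature(
                    interval=f.genome_iv,
                    type="TE_fragment",
                    attributes={
                        "ID": f"{c.copy_id}.f{i}",
                        "consensus": f.consensus_id,
                        "cons_start": f.cons_start + 1,
                        "cons_end": f.cons_end,
                        "identity": f"{f.identity:.1f}",
                    },
                    parent=c.copy_id,
                )
            )
    return feats
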