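"""Grouping of self-alignment matches into putative TE families.

Three complementary strategies are implemented:

* a GROUPER-style clusterer: matches are first connected into chains by
  dynamic programming (one chain per fragmented TE copy), chains are
  gathered by single-link clustering under a high (95%) reciprocal-coverage
  constraint, chains fully included in others are marked as such (the
  non-autonomous / MITE situation) and clusters without enough non-included
  members are dropped;
* a RECON-style clusterer: a two-phase procedure that first merges
  overlapping fragments at each locus into "elements" under a low (50%)
  coverage constraint and then gathers elements into families under a high
  (90%) constraint;
* a PILER-style clusterer: "piles" are maximal contiguous regions covered
  by at least one match side; piles alignable with each other over 95% of
  their lengths are gathered into clusters.

The high-coverage constraint of the GROUPER strategy is what separates
structural variants of one family into distinct clusters; the RECON
strategy may merge them.  The strategies are therefore run in parallel and
combined, with redundancy resolved only after classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .core_io import Chain, GenomeSet, Interval, revcomp

log = logging.getLogger("teforge")


@dataclass
class GrouperParams:
    coverage: float = 0.95
    min_nonincluded_members: int = 2
    join_open_cost: float = 20.0
    join_per_bp_cost: float = 0.02
    max_join_gap: int = 30_000
    max_small_gap: int = 500
    overlap_tolerance: int = 20
    chain_cum_len_max: int = 20_000
    chain_span_max: int = 30_000

    def __post_init__(self):
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")


@dataclass
class ReconParams:
    element_coverage: float = 0.50
    family_coverage: float = 0.90
    endpoint_agreement: int = 3
    endpoint_window: int = 20


@dataclass
class PilerParams:
    pile_gap: int = 0
    global_coverage: float = 0.95


@dataclass
class ClusterMember:
    """One family-member locus: a genomic interval plus its orientation
    relative to the cluster frame and the inclusion mark."""

    interval: Interval
    orientation: str = "+"
    included: bool = False

    def __len__(self):
        return len(self.interval)


@dataclass
class Cluster:
    id: str
    members: list = field(default_factory=list)
    method: str = ""

    @property
    def total_member_length(self) -> int:
        return sum(len(m) for m in self.members)

    def sequences(self, genome: GenomeSet) -> dict:
        """Extract member sequences, reverse-complemented when the member is
        oriented against the cluster frame."""
        seqs = {}
        for i, m in enumerate(self.members):
            s = genome[m.interval.seq_id][m.interval.start : m.interval.end]
            if m.orientation == "-":
                s = revcomp(s)
            seqs[f"{self.id}_m{i}"] = s
        return seqs


# ---------------------------------------------------------------------------
# chaining


def chain_matches(matches, params: Optional[GrouperParams] = None) -> list:
    """Connect fragments of the same TE copy into chains by dynamic
    programming over the pairwise matches.

    Matches are grouped per (query sequence, subject sequence, strand);
    within a group the chain score Σ match scores − gap costs is maximised
    over collinear successors (query and subject order agree, strand
    consistent).  Each match ends up in at most one chain.
    """
    if params is None:
        params = GrouperParams()
    tol = params.overlap_tolerance
    groups: dict = {}
    for m in matches:
        groups.setdefault((m.query.seq_id, m.subject.seq_id, m.subject.strand), []).append(m)
    chains = []
    for (qs_id, ss_id, strand), group in sorted(groups.items()):
        group.sort(key=lambda m: (m.query.start, m.subject.start))
        n = len(group)
        best = [m.score for m in group]
        parent = [-1] * n
        for j in range(n):
            mj = group[j]
            for i in range(j):
                mi = group[i]
                q_gap = mj.query.start - mi.query.end
                if q_gap < -tol:
                    continue
                if strand == "+":
                    s_gap = mj.subject.start - mi.subject.end
                else:
                    s_gap = mi.subject.start - mj.subject.end
                if s_gap < -tol or q_gap > params.max_join_gap or s_gap > params.max_join_gap:
                    continue
                # fragments of one copy split by an indel or a nested
                # insertion leave a small gap on at least one side; two
                # distinct copies leave large gaps on both sides
                if min(q_gap, s_gap) > params.max_small_gap:
                    continue
                gap = max(q_gap, s_gap, 0)
                cost = params.join_open_cost + params.join_per_bp_cost * gap
                cand = best[i] + mj.score - cost
                if cand > best[j]:
                    best[j] = cand
                    parent[j] = i
        used = [False] * n
        order = sorted(range(n), key=lambda j: -best[j])
        for j in order:
            if used[j]:
                continue
            path = []
            cur = j
            while cur != -1 and not used[cur]:
                path.append(cur)
                used[cur] = True
                cur = parent[cur]
            path.reverse()
            chains.append(Chain(members=[group[i] for i in path]))
    chains.sort(key=lambda c: (c.query_interval.seq_id, c.query_interval.start, c.subject_interval.seq_id, c.subject_interval.start))
    return chains


# ---------------------------------------------------------------------------
# shared locus machinery


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _reciprocal(a: Interval, b: Interval) -> float:
    ov = a.overlap(b)
    return 0.0 if ov == 0 else min(ov / len(a), ov / len(b))


def _shorter_coverage(a: Interval, b: Interval) -> float:
    ov = a.overlap(b)
    return 0.0 if ov == 0 else ov / min(len(a), len(b))


def _merge_sides(sides, link_fn, boundary: str = "union"):
    """Single-link merge of intervals via a sweep; ``link_fn(a, b) -> bool``.

    Returns (component index per side, merged interval per component).
    ``boundary`` chooses how the merged interval is derived: ``union``
    (min start, max end) or ``median`` (per-end median of the member
    endpoints — endpoint aggregation robust to a stray long side).
    """
    order = sorted(range(len(sides)), key=lambda i: (sides[i].seq_id, sides[i].start, sides[i].end))
    uf = _UnionFind(len(sides))
    active: list = []
    for idx in order:
        iv = sides[idx]
        active = [
            a for a in active if sides[a].seq_id == iv.seq_id and sides[a].end > iv.start
        ]
        for a in active:
            if link_fn(sides[a], iv):
                uf.union(a, idx)
        active.append(idx)
    comp_of = {}
    comp_ids = []
    for i in range(len(sides)):
        r = uf.find(i)
        if r not in comp_of:
            comp_of[r] = len(comp_ids)
            comp_ids.append(r)
    assign = [comp_of[uf.find(i)] for i in range(len(sides))]
    members: dict = {}
    for i, c in enumerate(assign):
        members.setdefault(c, []).append(sides[i])
    unions = {}
    for c, ivs in members.items():
        if boundary == "median":
            starts = sorted(iv.start for iv in ivs)
            ends = sorted(iv.end for iv in ivs)
            start = starts[(len(starts) - 1) // 2]
            end = ends[len(ends) // 2]
        else:
            start = min(iv.start for iv in ivs)
            end = max(iv.end for iv in ivs)
        unions[c] = Interval(ivs[0].seq_id, start, end, "+")
    return assign, unions


def _orient_components(n_nodes, edges):
    """Assign a consistent orientation (+/-) per node from (a, b, flip)
    edges by BFS; conflicts (palindromic links) keep the first assignment."""
    adj: dict = {}
    for a, b, flip in edges:
        adj.setdefault(a, []).append((b, flip))
        adj.setdefault(b, []).append((a, flip))
    orient = {}
    for start in range(n_nodes):
        if start in orient:
            continue
        orient[start] = "+"
        queue = [start]
        while queue:
            u = queue.pop()
            for v, flip in adj.get(u, []):
                if v in orient:
                    continue
                if flip:
                    orient[v] = "-" if orient[u] == "+" else "+"
                else:
                    orient[v] = orient[u]
                queue.append(v)
    return orient


def _mark_inclusions(all_members, coverage):
    """Mark members whose interval is covered >= ``coverage`` of their own
    length by another (larger) member interval, the non-autonomous case."""
    order = sorted(range(len(all_members)), key=lambda i: (all_members[i].interval.seq_id, all_members[i].interval.start))
    ivs = [all_members[i].interval for i in order]
    for a_pos, a_idx in enumerate(order):
        a = all_members[a_idx].interval
        for b_pos in range(a_pos + 1, len(order)):
            b = all_members[order[b_pos]].interval
            if b.seq_id != a.seq_id or b.start >= a.end:
                break
            ov = a.overlap(b)
            if ov >= coverage * len(a) and len(a) < len(b):
                all_members[a_idx].included = True
            if ov >= coverage * len(b) and len(b) < len(a):
                all_members[order[b_pos]].included = True


def _assign_ids(clusters, prefix):
    clusters.sort(key=lambda c: (-c.total_member_length, c.members[0].interval.seq_id, c.members[0].interval.start))
    for i, c in enumerate(clusters, start=1):
        c.id = f"{prefix}{i}"
    return clusters


# ---------------------------------------------------------------------------
# GROUPER-style


def grouper_cluster(chains, params: Optional[GrouperParams] = None) -> list:
    """Single-link clustering of chains under a 95% reciprocal-coverage
    constraint, with same-locus merging and inclusion marking.

    Chains whose cumulative length exceeds 20 kb while spanning more than
    30 kb — probable segmental duplications — are removed beforehand.
    Clusters keep their members' genomic loci; clusters with fewer than
    ``min_nonincluded_members`` members not included in any other are
    dropped.
    """
    if params is None:
        params = GrouperParams()
    chains = [
        c
        for c in chains
        if not (c.cumulative_length > params.chain_cum_len_max and c.span > params.chain_span_max)
    ]
    if not chains:
        return []
    sides = []
    side_chain = []  # (chain index, which side)
    for ci, c in enumerate(chains):
        sides.append(c.query_interval)
        side_chain.append((ci, 0))
        sides.append(c.subject_interval)
        side_chain.append((ci, 1))
    assign, unions = _merge_sides(
        sides, lambda a, b: _reciprocal(a, b) >= params.coverage, boundary="median"
    )
    # loci = merged components; a chain links its two loci only when its
    # aligned fragments cover >= coverage of each locus — copies of two
    # structural variants share less than that and stay in separate
    # clusters
    n_loci = len(unions)
    uf = _UnionFind(n_loci)
    edges = []
    for ci, c in enumerate(chains):
        la, lb = assign[2 * ci], assign[2 * ci + 1]
        cov_q = c.cumulative_length / len(unions[la])
        cov_s = sum(m.subject_length for m in c.members) / len(unions[lb])
        if min(cov_q, cov_s) >= params.coverage:
            uf.union(la, lb)
            edges.append((la, lb, c.strand == "-"))
    orient = _orient_components(n_loci, edges)
    comp_members: dict = {}
    for locus in range(n_loci):
        comp_members.setdefault(uf.find(locus), []).append(locus)
    all_members = {}
    clusters = []
    for root in sorted(comp_members):
        members = []
        for locus in sorted(comp_members[root], key=lambda l: (unions[l].seq_id, unions[l].start)):
            mem = ClusterMember(interval=unions[locus], orientation=orient.get(locus, "+"))
            members.append(mem)
        clusters.append(Cluster(id="", members=members, method="grouper"))
    flat = [m for c in clusters for m in c.members]
    _mark_inclusions(flat, params.coverage)
    clusters = [
        c
        for c in clusters
        if sum(not m.included for m in c.members) >= params.min_nonincluded_members
    ]
    return _assign_ids(clusters, "G")


# ---------------------------------------------------------------------------
# RECON-style


def _split_composite_elements(element_iv, member_sides, params: ReconParams):
    """Deterministic stand-in for endpoint-aggregation: split a merged
    element where at least ``endpoint_agreement`` member starts and ends
    both pile up (within ``endpoint_window``) at the same interior position,
    the signature of a composite (segmental-duplication-like) element."""
    starts = sorted(s.start for s in member_sides)
    ends = sorted(s.end for s in member_sides)
    w, need = params.endpoint_window, params.endpoint_agreement
    cut_candidates = []
    for i in range(len(starts)):
        group = [s for s in starts if abs(s - starts[i]) <= w]
        if len(group) >= need:
            pos = sorted(group)[len(group) // 2]
            if element_iv.start + 100 < pos < element_iv.end - 100:
                near_ends = [e for e in ends if abs(e - pos) <= 2 * w]
                if len(near_ends) >= need:
                    cut_candidates.append(pos)
    cuts = []
    for pos in sorted(set(cut_candidates)):
        if not cuts or pos - cuts[-1] > 100:
            cuts.append(pos)
    if not cuts:
        return [element_iv]
    bounds = [element_iv.start] + cuts + [element_iv.end]
    return [
        Interval(element_iv.seq_id, a, b, "+") for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]


def recon_like_cluster(chains, params: Optional[ReconParams] = None) -> list:
    """Two-phase clustering: fragments → elements (50% coverage of the
    shorter member, per locus) then elements → families (90% reciprocal
    aligned coverage via the connecting matches)."""
    if params is None:
        params = ReconParams()
    if not chains:
        return []
    sides = []
    for c in chains:
        sides.append(c.query_interval)
        sides.append(c.subject_interval)
    assign, unions = _merge_sides(
        sides, lambda a, b: _shorter_coverage(a, b) >= params.element_coverage
    )
    # optional composite split
    comp_sides: dict = {}
    for i, comp in enumerate(assign):
        comp_sides.setdefault(comp, []).append(sides[i])
    elements = []  # list of Interval
    elem_of_comp: dict = {}
    for comp in sorted(unions):
        pieces = _split_composite_elements(unions[comp], comp_sides[comp], params)
        elem_of_comp[comp] = list(range(len(elements), len(elements) + len(pieces)))
        elements.extend(pieces)

    def element_for(side_idx):
        comp = assign[side_idx]
        candidates = elem_of_comp[comp]
        side = sides[side_idx]
        best_e, best_ov = candidates[0], -1
        for e in candidates:
            ov = elements[e].overlap(side)
            if ov > best_ov:
                best_e, best_ov = e, ov
        return best_e

    # phase 2: aligned coverage between element pairs
    pair_cov: dict = {}
    pair_flip: dict = {}
    for ci, c in enumerate(chains):
        ea, eb = element_for(2 * ci), element_for(2 * ci + 1)
        if ea == eb:
            continue
        key = (min(ea, eb), max(ea, eb))
        a_iv = sides[2 * ci] if key[0] == ea else sides[2 * ci + 1]
        b_iv = sides[2 * ci + 1] if key[0] == ea else sides[2 * ci]
        pair_cov.setdefault(key, ([], []))
        pair_cov[key][0].append((a_iv.start, a_iv.end))
        pair_cov[key][1].append((b_iv.start, b_iv.end))
        pair_flip[key] = c.strand == "-"
    uf = _UnionFind(len(elements))
    edges = []
    for (ea, eb), (ivs_a, ivs_b) in sorted(pair_cov.items()):
        cov_a = _union_len(ivs_a, elements[ea]) / len(elements[ea])
        cov_b = _union_len(ivs_b, elements[eb]) / len(elements[eb])
        if cov_a >= params.family_coverage and cov_b >= params.family_coverage:
            uf.union(ea, eb)
            edges.append((ea, eb, pair_flip[(ea, eb)]))
    orient = _orient_components(len(elements), edges)
    fam: dict = {}
    for e in range(len(elements)):
        fam.setdefault(uf.find(e), []).append(e)
    clusters = []
    for root in sorted(fam):
        members = [
            ClusterMember(interval=elements[e], orientation=orient.get(e, "+"))
            for e in sorted(fam[root], key=lambda e: (elements[e].seq_id, elements[e].start))
        ]
        clusters.append(Cluster(id="", members=members, method="recon"))
    return _assign_ids(clusters, "R")


def _union_len(ivs, clip: Interval) -> int:
    ivs = sorted((max(s, clip.start), min(e, clip.end)) for s, e in ivs)
    total = 0
    cur_s, cur_e = None, None
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


# ---------------------------------------------------------------------------
# PILER-style


def piler_cluster(matches, params: Optional[PilerParams] = None) -> list:
    """Pile-based clustering: piles are maximal contiguous covered regions;
    piles alignable over >= 95% of both lengths are single-linked."""
    if params is None:
        params = PilerParams()
    if not matches:
        return []
    per_seq: dict = {}
    for m in matches:
        per_seq.setdefault(m.query.seq_id, []).append((m.query.start, m.query.end))
        per_seq.setdefault(m.subject.seq_id, []).append((m.subject.start, m.subject.end))
    piles = []
    for seq_id in sorted(per_seq):
        ivs = sorted(per_seq[seq_id])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e + params.pile_gap:
                piles.append(Interval(seq_id, cur_s, cur_e, "+"))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        piles.append(Interval(seq_id, cur_s, cur_e, "+"))

    def pile_for(iv: Interval):
        # binary search over piles of that sequence
        best, best_ov = None, 0
        for i, p in enumerate(piles):
            if p.seq_id != iv.seq_id:
                continue
            ov = p.overlap(iv)
            if ov > best_ov:
                best, best_ov = i, ov
        return best

    pair_cov: dict = {}
    pair_flip: dict = {}
    for m in matches:
        pa, pb = pile_for(m.query), pile_for(m.subject)
        if pa is None or pb is None or pa == pb:
            continue
        key = (min(pa, pb), max(pa, pb))
        a_iv = m.query if key[0] == pa else m.subject
        b_iv = m.subject if key[0] == pa else m.query
        pair_cov.setdefault(key, ([], []))
        pair_cov[key][0].append((a_iv.start, a_iv.end))
        pair_cov[key][1].append((b_iv.start, b_iv.end))
        pair_flip[key] = m.subject.strand == "-"
    uf = _UnionFind(len(piles))
    edges = []
    for (pa, pb), (ivs_a, ivs_b) in sorted(pair_cov.items()):
        len_a, len_b = len(piles[pa]), len(piles[pb])
        # global alignability over 95% of both lengths also bounds the
        # length ratio: a 1 kb pile cannot be globally aligned with a
        # 0.5 kb pile
        if min(len_a, len_b) / max(len_a, len_b) < params.global_coverage:
            continue
        cov_a = _union_len(ivs_a, piles[pa]) / len_a
        cov_b = _union_len(ivs_b, piles[pb]) / len_b
        if cov_a >= params.global_coverage and cov_b >= params.global_coverage:
            uf.union(pa, pb)
            edges.append((pa, pb, pair_flip[(pa, pb)]))
    orient = _orient_components(len(piles), edges)
    groups: dict = {}
    for p in range(len(piles)):
        groups.setdefault(uf.find(p), []).append(p)
    clusters = []
    for root in sorted(groups):
        members = [
            ClusterMember(interval=piles[p], orientation=orient.get(p, "+"))
            for p in sorted(groups[root], key=lambda p: (piles[p].seq_id, piles[p].start))
        ]
        clusters.append(Cluster(id="", members=members, method="piler"))
    return _assign_ids(clusters, "P")


def piles(matches, params: Optional[PilerParams] = None) -> list:
    """Expose the pile partition (used by tests of the covered-positions
    invariant)."""
    if params is None:
        params = PilerParams()
    clusters = piler_cluster(matches, params)
    return [m.interval for c in clusters for m in c.members]


# ---------------------------------------------------------------------------
# filters and combination


def filter_clusters(clusters, max_members: int = 20, min_members: int = 3) -> list:
    """Remove clusters with fewer than three members; keep only the 20
    longest members of large clusters."""
    out = []
    for c in clusters:
        if len(c.members) < min_members:
            continue
        members = sorted(c.members, key=lambda m: (-len(m), m.interval.seq_id, m.interval.start))[
            :max_members
        ]
        members.sort(key=lambda m: (m.interval.seq_id, m.interval.start))
        out.append(Cluster(id=c.id, members=members, method=c.method))
    return out


def combine_clusterings(g: list, r: list, p: list) -> list:
    """Concatenate the three clusterings, keeping method-tagged ids;
    redundancy between them is resolved later, after classification."""
    combined = list(g) + list(r) + list(p)
    seen = set()
    for c in combined:
        if c.id in seen:
            raise ValueError(f"duplicate cluster id {c.id}")
        seen.add(c.id)
    return combined
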