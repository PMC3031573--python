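import random

import numpy as np
import pytest

from teforge.clustering import (
    GrouperParams,
    PilerParams,
    ReconParams,
    chain_matches,
    combine_clusterings,
    filter_clusters,
    grouper_cluster,
    piler_cluster,
    recon_like_cluster,
    Cluster,
    ClusterMember,
)
from teforge.core_io import GenomeSet, Interval
from teforge.selfalign import self_align
from teforge.synthgenome import FamilySpec, plant_copies, random_sequence
from .conftest import make_match


class TestChainMatches:
    def test_fragments_split_by_insertion_chain_together(self):
        # one copy carries a 2 kb insertion: two collinear matches with a
        # large query gap but no subject gap
        ms = [
            make_match(0, "s", 1000, 2000, "s", 10_000, 11_000),
            make_match(1, "s", 4000, 5000, "s", 11_000, 12_000),
        ]
        chains = chain_matches(ms)
        assert len(chains) == 1
        assert len(chains[0].members) == 2
        assert chains[0].cumulative_length == 2000
        assert chains[0].span == 4000

    def test_opposite_strands_not_chained(self):
        ms = [
            make_match(0, "s", 1000, 2000, "s", 10_000, 11_000, strand="+"),
            make_match(1, "s", 2100, 3000, "s", 11_100, 12_000, strand="-"),
        ]
        assert len(chain_matches(ms)) == 2

    def test_single_match_chain(self):
        ms = [make_match(0, "s", 1000, 2000, "s", 10_000, 11_000)]
        (chain,) = chain_matches(ms)
        assert chain.span == 1000 == chain.cumulative_length

    def test_distant_copies_not_chained(self):
        # large gaps on both sides: two distinct copies, not one fragmented one
        ms = [
            make_match(0, "s", 1000, 2000, "s", 10_000, 11_000),
            make_match(1, "s", 4000, 5000, "s", 13_000, 14_000),
        ]
        assert len(chain_matches(ms)) == 2

    def test_minus_strand_collinearity(self):
        # on '-' subject, subject coordinates decrease as query increases
        ms = [
            make_match(0, "s", 1000, 2000, "s", 11_000, 12_000, strand="-"),
            make_match(1, "s", 2050, 3000, "s", 10_000, 11_000, strand="-"),
        ]
        assert len(chain_matches(ms)) == 1


def _variant_family_genome(seed, with_variant):
    """A genome with one featureless family; optionally half the copies
    carry a 1.2 kb internal deletion (two structural variants sharing
    <95% of their lengths)."""
    rng = np.random.default_rng(seed)
    variants = [((800, 2000), 0.5)] if with_variant else []
    spec = FamilySpec(
        "fam", "featureless", 3000, n_copies=10, identity_mean=98.5,
        identity_sd=0.4, variants=variants,
    )
    bg = GenomeSet({"chr": random_sequence(rng, 60_000)})
    return plant_copies(bg, [spec], rng)


class TestGrouperVariants:
    def test_two_variants_yield_separate_clusters(self):
        truth = _variant_family_genome(7, with_variant=True)
        assert {c.variant for c in truth.copies} == {0, 1}
        matches = self_align(truth.genome)
        clusters = grouper_cluster(chain_matches(matches))
        assert len(clusters) >= 2

    def test_single_variant_yields_one_cluster(self):
        truth = _variant_family_genome(7, with_variant=False)
        matches = self_align(truth.genome)
        clusters = filter_clusters(grouper_cluster(chain_matches(matches)))
        assert len(clusters) == 1
        assert len(clusters[0].members) >= 3

    def test_order_invariance(self):
        truth = _variant_family_genome(7, with_variant=True)
        chains = chain_matches(self_align(truth.genome))
        ref = grouper_cluster(chains)
        shuffled = list(chains)
        random.Random(0).shuffle(shuffled)
        alt = grouper_cluster(shuffled)
        key = lambda cs: sorted(
            tuple(sorted((m.interval.start, m.interval.end) for m in c.members)) for c in cs
        )
        assert key(ref) == key(alt)


class TestGrouperFilters:
    def test_segdup_chains_removed_before_clustering(self):
        # cumulative length > 20 kb AND span > 30 kb
        ms = [
            make_match(0, "s", 0, 15_000, "s", 100_000, 115_000),
            make_match(1, "s", 32_000, 42_000, "s", 115_100, 125_100),
        ]
        params = GrouperParams(max_join_gap=40_000, max_small_gap=40_000)
        chains = chain_matches(ms, params)
        assert len(chains) == 1 and chains[0].cumulative_length > 20_000
        assert grouper_cluster(chains, params) == []

    def test_all_included_cluster_removed(self):
        # a MITE-like pair existing only inside autonomous copies: all its
        # members are marked included, so the cluster fails the -X filter
        ms = [
            make_match(0, "s", 10_000, 15_000, "s", 50_000, 55_000),  # autonomous pair
            make_match(1, "s", 11_000, 11_400, "s", 51_000, 51_400),  # inner pair
        ]
        clusters = grouper_cluster(chain_matches(ms))
        assert not any(len(m.interval) < 1000 for c in clusters for m in c.members)

    def test_inclusion_marking_for_nested_members(self):
        # MITE loci nested in autonomous copies are marked included and do
        # not count toward the -X threshold; solo MITE loci keep the
        # cluster alive
        ms = [
            make_match(0, "s", 10_000, 15_000, "s", 50_000, 55_000),  # autonomous pair
            make_match(1, "s", 11_000, 11_400, "s", 51_000, 51_400),  # nested MITEs
            make_match(2, "s", 80_000, 80_400, "s", 90_000, 90_400),  # solo MITEs
            make_match(3, "s", 11_000, 11_400, "s", 80_000, 80_400),  # link them
        ]
        clusters = grouper_cluster(chain_matches(ms))
        mite_cluster = next(
            c for c in clusters if all(len(m.interval) < 1000 for m in c.members)
        )
        nested = [m for m in mite_cluster.members if m.interval.start < 60_000]
        solo = [m for m in mite_cluster.members if m.interval.start >= 60_000]
        assert nested and all(m.included for m in nested)
        assert solo and not any(m.included for m in solo)

    def test_isolated_reciprocal_pair_clusters_together(self):
        ms = [make_match(0, "s", 1000, 2000, "s", 5000, 6000)]
        clusters = grouper_cluster(chain_matches(ms))
        assert len(clusters) == 1
        assert len(clusters[0].members) == 2


class TestReconLike:
    def _oracle_elements(self, intervals, threshold=0.5):
        """Independent union-find oracle for phase 1 (50% of shorter)."""
        n = len(intervals)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = intervals[i], intervals[j]
                ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
                if ov >= threshold * min(a[1] - a[0], b[1] - b[0]):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(intervals[i])
        return sorted(
            (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
        )

    def test_staggered_fragments_merge_into_one_element(self):
        # three fragments at one locus overlapping ~60% pairwise, each
        # matching a distinct remote locus
        ms = [
            make_match(0, "s", 1000, 2000, "s", 50_000, 51_000),
            make_match(1, "s", 1400, 2400, "s", 60_000, 61_000),
            make_match(2, "s", 1800, 2800, "s", 70_000, 71_000),
        ]
        sides = [(1000, 2000), (1400, 2400), (1800, 2800)]
        oracle = self._oracle_elements(sides)
        assert oracle[0] == (1000, 2800)  # one merged element at the locus
        clusters = recon_like_cluster(chain_matches(ms))
        spans = sorted(
            (m.interval.start, m.interval.end) for c in clusters for m in c.members
        )
        assert (1000, 2800) in spans

    def test_low_reciprocal_coverage_elements_stay_separate_families(self):
        # 5 kb vs 2 kb elements: 40% reciprocal coverage, below the 90% bar
        ms = [
            make_match(0, "s", 0, 5000, "s", 20_000, 25_000),
            make_match(1, "s", 1000, 3000, "s", 40_000, 42_000),
        ]
        clusters = recon_like_cluster(chain_matches(ms))
        for c in clusters:
            lens = {len(m.interval) for m in c.members}
            assert not ({5000} & lens and {2000} & lens)

    def test_identical_elements_at_three_loci_one_family(self):
        ms = [
            make_match(0, "s", 0, 1000, "s", 10_000, 11_000),
            make_match(1, "s", 0, 1000, "s", 20_000, 21_000),
            make_match(2, "s", 10_000, 11_000, "s", 20_000, 21_000),
        ]
        clusters = recon_like_cluster(chain_matches(ms))
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3


class TestPiler:
    def test_three_interspersed_copies_three_piles_one_cluster(self):
        ms = [
            make_match(0, "s", 0, 1000, "s", 10_000, 11_000),
            make_match(1, "s", 0, 1000, "s", 20_000, 21_000),
            make_match(2, "s", 10_000, 11_000, "s", 20_000, 21_000),
        ]
        clusters = piler_cluster(ms)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_length_mismatched_piles_different_clusters(self):
        # a 1 kb pile and a 0.5 kb pile cannot align over 95% of both
        ms = [make_match(0, "s", 0, 1000, "s", 10_000, 10_500)]
        clusters = piler_cluster(ms)
        assert len(clusters) == 2

    def test_tandem_array_single_pile(self):
        # overlapping matches form one contiguous covered region
        ms = [
            make_match(0, "s", 0, 1000, "s", 900, 1900),
            make_match(1, "s", 900, 1900, "s", 1800, 2800),
        ]
        clusters = piler_cluster(ms)
        all_piles = [m.interval for c in clusters for m in c.members]
        assert len(all_piles) == 1
        assert (all_piles[0].start, all_piles[0].end) == (0, 2800)

    def test_piles_partition_covered_positions(self, rng):
        from .conftest import random_seq

        bg = random_seq(rng, 20_000)
        rep = random_seq(rng, 600)
        seq = bg[:3000] + rep + bg[3000:9000] + rep + bg[9000:15_000] + rep + bg[15_000:]
        matches = self_align(GenomeSet({"s": seq}))
        covered = set()
        for m in matches:
            covered.update(range(m.query.start, m.query.end))
            covered.update(range(m.subject.start, m.subject.end))
        clusters = piler_cluster(matches)
        pile_positions = []
        for c in clusters:
            for m in c.members:
                pile_positions.append(set(range(m.interval.start, m.interval.end)))
        union = set().union(*pile_positions) if pile_positions else set()
        assert union == covered
        for i in range(len(pile_positions)):
            for j in range(i + 1, len(pile_positions)):
                assert not (pile_positions[i] & pile_positions[j])


class TestFilterAndCombine:
    def _cluster(self, cid, n_members, length=1000):
        members = [
            ClusterMember(interval=Interval("s", i * 10_000, i * 10_000 + length + i))
            for i in range(n_members)
        ]
        return Cluster(id=cid, members=members, method="grouper")

    def test_small_cluster_removed(self):
        assert filter_clusters([self._cluster("G1", 2)]) == []

    def test_large_cluster_truncated_to_20_longest(self):
        (c,) = filter_clusters([self._cluster("G1", 35)])
        assert len(c.members) == 20
        # the 20 longest were kept (member lengths increase with index)
        assert min(len(m) for m in c.members) == 1000 + 15

    def test_three_member_cluster_unchanged(self):
        (c,) = filter_clusters([self._cluster("G1", 3)])
        assert len(c.members) == 3

    def test_combine_concatenates_with_method_tags(self):
        g = [self._cluster(f"G{i}", 3) for i in range(1, 6)]
        r = [self._cluster(f"R{i}", 3) for i in range(1, 4)]
        p = [self._cluster(f"P{i}", 3) for i in range(1, 3)]
        combined = combine_clusterings(g, r, p)
        assert len(combined) == 10
        assert combine_clusterings(g, [], p) == g + p

    def test_combine_rejects_id_collision(self):
        with pytest.raises(ValueError, match="duplicate"):
            combine_clusterings([self._cluster("G1", 3)], [self._cluster("G1", 3)], [])

    def test_method_prefix_naming(self):
        truth = _variant_family_genome(3, with_variant=False)
        clusters = recon_like_cluster(chain_matches(self_align(truth.genome)))
        assert all(c.id.startswith("R") for c in clusters)
        assert clusters[0].id == "R1"
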