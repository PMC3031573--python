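import numpy as np
import pytest

from teforge.annotate import (
    AnnotateParams,
    NullModel,
    TECopy,
    TEFragment,
    build_null,
    detect_microsatellites,
    filter_by_null,
    filter_satellite_overlaps,
    long_join,
    map_library,
    matcher_defragment,
    shuffle_genome,
)
from teforge.core_io import GenomeSet, Interval
from .conftest import mutate_seq, random_seq


def frag(seq_id, gs, ge, cons="c1", cs=0, ce=None, identity=95.0, score=None, strand="+"):
    if ce is None:
        ce = cs + (ge - gs)
    return TEFragment(
        genome_iv=Interval(seq_id, gs, ge, strand),
        consensus_id=cons,
        cons_start=cs,
        cons_end=ce,
        identity=identity,
        score=float(ge - gs) if score is None else score,
    )


class TestMapLibrary:
    def test_exact_copy_recovered(self, rng):
        cons = random_seq(rng, 1000)
        g = GenomeSet({"chr": random_seq(rng, 2000) + cons + random_seq(rng, 2000)})
        frags = map_library({"c1": cons}, g)
        best = max(frags, key=lambda f: f.score)
        assert best.identity == 100.0
        assert abs(best.genome_iv.start - 2000) <= 2
        assert abs(len(best.genome_iv) - 1000) <= 5

    def test_no_homology_empty(self, rng):
        g = GenomeSet({"chr": random_seq(rng, 3000)})
        assert map_library({"c1": random_seq(rng, 800)}, g) == []

    def test_internal_deletion_yields_two_fragments_with_cons_gap(self, rng):
        cons = random_seq(rng, 2000)
        copy = cons[:800] + cons[1300:]  # 500 bp deletion
        g = GenomeSet({"chr": random_seq(rng, 1000) + copy + random_seq(rng, 1000)})
        frags = sorted(map_library({"c1": cons}, g), key=lambda f: f.genome_iv.start)
        assert len(frags) == 2
        gap = frags[1].cons_start - frags[0].cons_end
        assert 450 <= gap <= 550

    def test_empty_library_error(self, rng):
        with pytest.raises(ValueError, match="empty"):
            map_library({}, GenomeSet({"chr": random_seq(rng, 100)}))


class TestNullModel:
    def test_threshold_is_95th_quantile(self):
        scores = list(range(1, 101))  # 1..100
        null = NullModel.from_scores(scores, 0.95)
        assert null.threshold == pytest.approx(np.quantile(scores, 0.95))
        assert min(scores) <= null.threshold <= max(scores)

    def test_empty_scores_threshold_zero(self):
        null = NullModel.from_scores([], 0.95)
        assert null.threshold == 0.0
        frags = [frag("chr", 0, 100)]
        assert filter_by_null(frags, null) == frags

    def test_quantile_mode_filters_no_more_than_legacy_max(self):
        scores = [10.0] * 99 + [1000.0]  # one lucky match dominates the max
        frags = [frag("chr", i * 200, i * 200 + 100, score=s) for i, s in enumerate([50.0, 500.0, 1500.0])]
        q_null = NullModel.from_scores(scores, 0.95)
        max_null = NullModel(scores=scores, threshold=max(scores))
        kept_q = filter_by_null(frags, q_null)
        kept_max = filter_by_null(frags, max_null)
        assert len(kept_max) <= len(kept_q)
        assert set(f.genome_iv.start for f in kept_max) <= set(
            f.genome_iv.start for f in kept_q
        )

    def test_shuffle_preserves_composition(self, rng):
        g = GenomeSet({"chr": random_seq(rng, 5000)})
        sh = shuffle_genome(g, seed=7)
        assert sorted(sh["chr"]) == sorted(g["chr"])
        assert sh["chr"] != g["chr"]

    def test_build_null_deterministic(self, rng):
        cons = random_seq(rng, 500)
        g = GenomeSet({"chr": random_seq(rng, 10_000) + cons + random_seq(rng, 2000)})
        n1 = build_null({"c1": cons}, g, seed=5)
        n2 = build_null({"c1": cons}, g, seed=5)
        assert n1.threshold == n2.threshold and n1.scores == n2.scores


class TestMatcherDefragment:
    def test_copy_split_by_nested_insertion_joined(self):
        # fragments of one copy around a 3 kb nest: small consensus gap
        frags = [
            frag("chr", 10_000, 11_000, cs=0, ce=1000),
            frag("chr", 14_000, 15_000, cs=1000, ce=2000),
        ]
        copies = matcher_defragment(frags)
        assert len(copies) == 1
        assert len(copies[0].fragments) == 2
        assert copies[0].genome_iv.start == 10_000 and copies[0].genome_iv.end == 15_000

    def test_overlap_contest_lower_scoring_chain_loses(self):
        frags = [
            frag("chr", 10_000, 12_000, cons="winner", score=2000.0),
            frag("chr", 10_500, 11_500, cons="loser", score=300.0),
        ]
        copies = matcher_defragment(frags)
        winner = [c for c in copies if c.consensus_id == "winner"]
        loser = [c for c in copies if c.consensus_id == "loser"]
        assert winner and len(winner[0].fragments[0]) == 2000
        assert not loser  # fully inside the winner: dropped

    def test_partial_overlap_truncated_not_dropped(self):
        frags = [
            frag("chr", 10_000, 12_000, cons="winner", score=2000.0),
            frag("chr", 11_500, 13_500, cons="loser", cs=0, ce=2000, score=1500.0),
        ]
        copies = matcher_defragment(frags)
        loser = next(c for c in copies if c.consensus_id == "loser")
        assert loser.genome_iv.start >= 12_000  # trimmed to the free region

    def test_chained_fragment_survives_contest_it_would_lose_alone(self):
        # the middle fragment alone would lose to "other", but chained with
        # its partners the chain outscores it
        frags = [
            frag("chr", 10_000, 11_000, cons="a", cs=0, ce=1000, score=1000.0),
            frag("chr", 11_050, 11_250, cons="a", cs=1050, ce=1250, score=200.0),
            frag("chr", 11_300, 12_300, cons="a", cs=1300, ce=2300, score=1000.0),
            frag("chr", 11_000, 11_300, cons="other", cs=0, ce=300, score=250.0),
        ]
        copies = matcher_defragment(frags)
        a = next(c for c in copies if c.consensus_id == "a")
        assert len(a.fragments) == 3

    def test_single_fragment_copy(self):
        copies = matcher_defragment([frag("chr", 100, 600)])
        assert len(copies) == 1 and len(copies[0].fragments) == 1

    def test_no_overlapping_fragments_within_output(self):
        frags = [
            frag("chr", 10_000, 12_000, cons="a", score=2000.0),
            frag("chr", 11_000, 13_000, cons="b", score=1500.0),
            frag("chr", 11_500, 12_500, cons="c", score=900.0),
        ]
        copies = matcher_defragment(frags)
        ivs = sorted(
            (f.genome_iv.start, f.genome_iv.end) for c in copies for f in c.fragments
        )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 >= e1 - 20  # within tolerance


class TestLongJoin:
    def test_old_copy_split_by_young_nest_merged(self):
        old1 = TECopy(fragments=[frag("chr", 10_000, 12_000, cons="old", cs=0, ce=2000, identity=85.0)])
        nest = TECopy(fragments=[frag("chr", 12_000, 17_000, cons="young", cs=0, ce=5000, identity=99.0)])
        old2 = TECopy(fragments=[frag("chr", 17_000, 19_000, cons="old", cs=2000, ce=4000, identity=85.0)])
        merged = long_join([old1, nest, old2])
        old_copies = [c for c in merged if c.consensus_id == "old"]
        assert len(old_copies) == 1
        assert len(old_copies[0].fragments) == 2

    def test_inconsistent_consensus_order_not_merged(self):
        # two adjacent same-age copies, second restarts at consensus 0
        c1 = TECopy(fragments=[frag("chr", 10_000, 12_000, cons="a", cs=0, ce=2000)])
        c2 = TECopy(fragments=[frag("chr", 12_100, 14_100, cons="a", cs=0, ce=2000)])
        merged = long_join([c1, c2])
        assert len([c for c in merged if c.consensus_id == "a"]) == 2

    def test_distant_without_young_nest_not_merged(self):
        c1 = TECopy(fragments=[frag("chr", 10_000, 12_000, cons="a", cs=0, ce=2000, identity=90.0)])
        c2 = TECopy(fragments=[frag("chr", 40_000, 42_000, cons="a", cs=2000, ce=4000, identity=90.0)])
        merged = long_join([c1, c2])
        assert len(merged) == 2

    def test_age_score_orders_by_identity(self):
        young = TECopy(fragments=[frag("chr", 0, 1000, identity=99.0)])
        old = TECopy(fragments=[frag("chr", 5000, 6000, identity=85.0)])
        assert young.age_score() > old.age_score()

    def test_age_score_weighted_vs_literal(self):
        c = TECopy(
            fragments=[
                frag("chr", 0, 1000, identity=90.0),
                frag("chr", 2000, 2100, identity=80.0),
            ]
        )
        weighted = c.age_score("weighted")
        assert weighted == pytest.approx((90 * 1000 + 80 * 100) / 1100)
        literal = c.age_score("literal")
        assert literal == pytest.approx(90 / 1000 + 80 / 100)


class TestMicrosatelliteFilter:
    def test_short_fragment_inside_tract_removed(self, rng):
        g = GenomeSet({"chr": random_seq(rng, 500) + "CA" * 100 + random_seq(rng, 500)})
        sats = detect_microsatellites(g)
        assert sats["chr"]
        copies = [TECopy(fragments=[frag("chr", 520, 560)])]
        assert filter_satellite_overlaps(copies, sats) == []

    def test_long_fragment_partially_inside_kept(self, rng):
        g = GenomeSet({"chr": random_seq(rng, 500) + "CA" * 100 + random_seq(rng, 2000)})
        sats = detect_microsatellites(g)
        copies = [TECopy(fragments=[frag("chr", 600, 2600)])]
        assert len(filter_satellite_overlaps(copies, sats)) == 1

    def test_no_satellites_identity_operation(self, rng):
        copies = [TECopy(fragments=[frag("chr", 100, 600)])]
        assert filter_satellite_overlaps(copies, {"chr": []}) == copies


class TestEndToEndInvariants:
    def test_annotated_bp_bounded_and_threshold_monotone(self, rng):
        anc = random_seq(rng, 800)
        pieces = [random_seq(rng, 1500)]
        for _ in range(4):
            pieces.append(mutate_seq(rng, anc, 0.05))
            pieces.append(random_seq(rng, 1500))
        g = GenomeSet({"chr": "".join(pieces)})
        frags = map_library({"anc": anc}, g)
        total = sum(len(f) for f in frags)
        assert 0 < total
        counts = []
        for thr in (0.0, 100.0, 500.0, 1e9):
            kept = filter_by_null(frags, NullModel(scores=[thr], threshold=thr))
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)
        copies = matcher_defragment(frags)
        annotated = sum(len(f) for c in copies for f in c.fragments)
        assert annotated <= g.total_length
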