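import itertools
import random

import pytest

from teforge.classify import (
    Classification,
    FeatureSet,
    LengthRanges,
    TerminalRepeat,
    classify_consensus,
    detect_tails,
    detect_tandem,
    detect_terminal_repeats,
    microsatellite_intervals,
    remove_redundancy,
    search_databank,
)
from teforge.consensus import ConsensusRecord
from teforge.core_io import revcomp
from .conftest import mutate_seq, random_seq


class TestTerminalRepeats:
    def test_ltr_detected(self, rng):
        ltr = random_seq(rng, 300)
        seq = ltr + random_seq(rng, 4400) + ltr
        l, t = detect_terminal_repeats(seq)
        assert l is not None
        assert abs(l.len_5p - 300) <= 20
        assert l.identity >= 95

    def test_tir_detected(self, rng):
        tir = random_seq(rng, 30)
        seq = tir + random_seq(rng, 2000) + revcomp(tir)
        l, t = detect_terminal_repeats(seq)
        assert t is not None
        assert abs(t.len_5p - 30) <= 10

    def test_diverged_ltr_still_detected(self, rng):
        ltr = random_seq(rng, 250)
        seq = ltr + random_seq(rng, 3000) + mutate_seq(rng, ltr, 0.1)
        l, _ = detect_terminal_repeats(seq)
        assert l is not None and l.identity >= 80

    def test_false_positive_rate_on_randoms(self):
        fp = 0
        for i in range(100):
            r = random.Random(2000 + i)
            s = "".join(r.choice("ACGT") for _ in range(2000))
            l, t = detect_terminal_repeats(s)
            if l is not None or t is not None:
                fp += 1
        assert fp < 5

    def test_short_sequence_no_detection(self):
        assert detect_terminal_repeats("ACGT" * 10) == (None, None)


class TestTails:
    def test_terminal_polya(self, rng):
        assert detect_tails(random_seq(rng, 500) + "A" * 12)[0] is True

    def test_terminal_ssr(self, rng):
        polyA, ssr = detect_tails(random_seq(rng, 500) + "TG" * 7)
        assert ssr is True

    def test_internal_polya_not_a_tail(self, rng):
        s = random_seq(rng, 500) + "A" * 12 + random_seq(rng, 1500)
        polyA, ssr = detect_tails(s)
        assert polyA is False and ssr is False

    def test_5p_t_run_counts_as_tail(self, rng):
        # the reverse-complement strand's polyA appears as a 5' T run
        assert detect_tails("T" * 12 + random_seq(rng, 500))[0] is True


class TestTandem:
    def test_pure_tandem_near_one(self):
        assert detect_tandem("ACG" * 100) > 0.95

    def test_random_below_ten_percent(self):
        vals = []
        for i in range(10):
            r = random.Random(i)
            vals.append(detect_tandem("".join(r.choice("ACGT") for _ in range(1000))))
        assert max(vals) < 0.1

    def test_half_ssr_half_unique(self, rng):
        frac = detect_tandem("CAG" * 167 + random_seq(rng, 500))
        assert 0.4 < frac < 0.65

    def test_long_motif_tandem(self, rng):
        motif = random_seq(rng, 200)
        assert detect_tandem(motif * 3 + random_seq(rng, 400)) > 0.5

    def test_microsatellite_intervals(self, rng):
        seq = random_seq(rng, 200) + "CA" * 20 + random_seq(rng, 200)
        (iv,) = microsatellite_intervals(seq)
        assert iv[0] >= 190 and iv[1] <= 250
        assert iv[1] - iv[0] >= 30


class TestSearchDatabank:
    def test_nucleotide_exact_copy(self, rng):
        seq = random_seq(rng, 1500)
        db = {"te1#ClassI/LTR": seq}
        hits = search_databank(seq, db, "nucleotide")
        assert hits and hits[0][1] == "ClassI/LTR"
        assert hits[0][2] > 0.95  # coverage

    def test_unlabeled_record_warns(self, rng, caplog):
        seq = random_seq(rng, 1500)
        with caplog.at_level("WARNING", logger="teforge"):
            hits = search_databank(seq, {"te1": seq}, "nucleotide")
        assert hits[0][1] == "unknown"
        assert any("label" in r.message for r in caplog.records)

    def test_translated_hit_survives_synonymous_divergence(self, rng):
        """Same protein, randomized codon choice: nucleotide identity falls
        below a stringent cut-off while the translated search still hits."""
        codons = {
            "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
            "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
            "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
            "G": ["GGT", "GGC", "GGA", "GGG"],
            "A": ["GCT", "GCC", "GCA", "GCG"],
            "V": ["GTT", "GTC", "GTA", "GTG"],
            "T": ["ACT", "ACC", "ACA", "ACG"],
            "P": ["CCT", "CCC", "CCA", "CCG"],
        }
        protein = "".join(rng.choice("LRSGAVTP") for _ in range(200))
        dna1 = "".join(rng.choice(codons[aa]) for aa in protein)
        dna2 = "".join(rng.choice(codons[aa]) for aa in protein)
        db = {"rt#ClassI/LINE": dna2}
        nt_hits = search_databank(dna1, db, "nucleotide", nt_min_identity=90.0)
        aa_hits = search_databank(dna1, db, "translated")
        assert not nt_hits
        assert aa_hits and aa_hits[0][1] == "ClassI/LINE"


class TestDecisionTree:
    def test_ltr_plus_coding_is_complete_ltr(self):
        fs = FeatureSet(
            ltr=TerminalRepeat(300, 300, 95.0),
            te_hits_translated=[("x", "ClassI/LTR", 0.5, 40.0)],
        )
        cls = classify_consensus(fs, 5000)
        assert (cls.label, cls.completeness) == ("classI-LTR", "complete")

    def test_line_hit_without_tail_is_incomplete_line(self):
        fs = FeatureSet(te_hits_translated=[("x", "ClassI/LINE", 0.5, 40.0)])
        cls = classify_consensus(fs, 3000)
        assert (cls.label, cls.completeness) == ("classI-LINE", "incomplete")

    def test_ltr_with_polya_tail_confused(self):
        fs = FeatureSet(ltr=TerminalRepeat(100, 100, 90.0), polyA_tail=True)
        assert classify_consensus(fs, 635).label == "Confused"

    def test_no_features_no_category(self):
        assert classify_consensus(FeatureSet(), 2000).label == "NoCategory"

    def test_tandem_dominated_is_ssr(self):
        assert classify_consensus(FeatureSet(tandem_fraction=0.9), 500).label == "SSR"

    def test_host_gene_without_te_evidence(self):
        fs = FeatureSet(host_gene_hits=["gene1"])
        assert classify_consensus(fs, 2000).label == "HostGene"

    def test_short_tir_only_is_mite(self):
        fs = FeatureSet(tir=TerminalRepeat(30, 30, 95.0))
        assert classify_consensus(fs, 400).label == "classII-MITE"

    def test_short_tail_only_is_sine(self):
        fs = FeatureSet(polyA_tail=True)
        assert classify_consensus(fs, 300).label == "classI-SINE"

    def test_helitron_via_homology_only(self):
        fs = FeatureSet(te_hits_translated=[("x", "Helitron", 0.5, 40.0)])
        assert classify_consensus(fs, 3000).label == "Helitron"

    def test_conflicting_hit_orders_confused(self):
        fs = FeatureSet(
            te_hits_translated=[
                ("x", "ClassI/LTR", 0.5, 40.0),
                ("y", "ClassII/TIR", 0.5, 40.0),
            ]
        )
        assert classify_consensus(fs, 3000).label == "Confused"

    def test_pure_function_over_feature_grid(self):
        """Determinism and total coverage: every leaf of the tree is
        reachable and the same FeatureSet always maps to the same label."""
        ltrs = [None, TerminalRepeat(200, 200, 90.0)]
        tirs = [None, TerminalRepeat(30, 30, 90.0)]
        tails = [False, True]
        hit_sets = [
            [],
            [("x", "ClassI/LTR", 0.5, 40.0)],
            [("x", "ClassI/LINE", 0.5, 40.0)],
            [("x", "ClassII/TIR", 0.5, 40.0)],
            [("x", "ClassI/LTR", 0.5, 40.0), ("y", "ClassII/TIR", 0.5, 40.0)],
        ]
        tandems = [0.0, 0.9]
        hosts = [[], ["g"]]
        lengths = [300, 3000]
        seen_labels = set()
        for ltr, tir, tail, hits, tf, host, L in itertools.product(
            ltrs, tirs, tails, hit_sets, tandems, hosts, lengths
        ):
            fs = FeatureSet(
                ltr=ltr, tir=tir, polyA_tail=tail, te_hits_translated=list(hits),
                tandem_fraction=tf, host_gene_hits=list(host),
            )
            c1 = classify_consensus(fs, L)
            c2 = classify_consensus(fs, L)
            assert (c1.label, c1.completeness) == (c2.label, c2.completeness)
            assert c1.label in (
                "classI-LTR", "classI-LINE", "classI-SINE", "classII-TIR",
                "classII-MITE", "Helitron", "SSR", "HostGene", "Confused",
                "NoCategory",
            )
            seen_labels.add(c1.label)
        assert {"classI-LTR", "classI-LINE", "classII-TIR", "SSR", "HostGene",
                "Confused", "NoCategory", "classII-MITE", "classI-SINE"} <= seen_labels


def _rec(rid, seq, label="classI-LTR", completeness="incomplete"):
    return (
        ConsensusRecord(id=rid, sequence=seq, n_members=3),
        Classification(label=label, completeness=completeness),
    )


class TestRemoveRedundancy:
    def test_incomplete_inside_complete_removed(self, rng):
        full = random_seq(rng, 3000)
        inner = mutate_seq(rng, full[500:1500], 0.02)  # ~98% identity, full inclusion
        records = [
            _rec("A", inner, completeness="incomplete"),
            _rec("B", full, completeness="complete"),
        ]
        kept = remove_redundancy(records)
        assert [r.id for r, _ in kept] == ["B"]

    def test_complete_inside_incomplete_kept(self, rng):
        full = random_seq(rng, 3000)
        inner = full[500:1500]
        records = [
            _rec("A", inner, completeness="complete"),
            _rec("B", full, completeness="incomplete"),
        ]
        kept = remove_redundancy(records)
        assert {r.id for r, _ in kept} == {"A", "B"}

    def test_low_coverage_inclusion_kept(self, rng):
        full = random_seq(rng, 3000)
        # only 90% of A lies inside B: below the 98% coverage bar
        inner = full[500:1400] + random_seq(rng, 100)
        records = [
            _rec("A", inner, completeness="incomplete"),
            _rec("B", full, completeness="complete"),
        ]
        kept = remove_redundancy(records)
        assert {r.id for r, _ in kept} == {"A", "B"}

    def test_low_identity_inclusion_kept(self, rng):
        full = random_seq(rng, 3000)
        inner = mutate_seq(rng, full[500:1500], 0.08)  # ~92% identity < 95
        records = [
            _rec("A", inner, completeness="incomplete"),
            _rec("B", full, completeness="complete"),
        ]
        kept = remove_redundancy(records)
        assert {r.id for r, _ in kept} == {"A", "B"}

    def test_unclassifiable_never_removes_labelled(self, rng):
        full = random_seq(rng, 3000)
        chimera = full + random_seq(rng, 5000)
        records = [
            _rec("A", full, label="classI-LTR", completeness="incomplete"),
            _rec("B", chimera, label="NoCategory", completeness="not-applicable"),
        ]
        kept = remove_redundancy(records)
        assert "A" in {r.id for r, _ in kept}

    def test_idempotent_and_never_empty(self, rng):
        full = random_seq(rng, 2000)
        records = [
            _rec("A", full),
            _rec("B", full),
            _rec("C", full[100:1900]),
        ]
        once = remove_redundancy(records)
        twice = remove_redundancy(once)
        assert [r.id for r, _ in once] == [r.id for r, _ in twice]
        assert once
        assert remove_redundancy([_rec("X", full)])
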