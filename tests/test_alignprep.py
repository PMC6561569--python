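import random
import zlib

import pytest

from duplidate.alignprep import (
    Alignment,
    TranscriptRecord,
    TranslationMismatch,
    backtranslate_alignment,
    cluster_isoforms,
    dust_score,
    filter_family_alignment,
    filter_transcripts,
)


class TestDustScore:
    def test_homopolymer_window(self):
        # 62 identical triplets in a 64-base window: 62*61/2 / 61 = 31
        assert dust_score("A" * 64, window=64) == pytest.approx(31.0)

    def test_all_distinct_triplets(self):
        # de Bruijn-ish stretch where every window triplet is unique
        bases = "ACGT"
        seq = "".join(bases[(i * 7 + j) % 4] for i in range(30) for j in range(3))
        windows_scores = dust_score(seq[:40], window=64)
        assert windows_scores < 31.0  # sanity: far below homopolymer

    def test_distinct_triplets_score_zero(self):
        # explicit sequence whose overlapping triplets never repeat
        seq = "AACAGATCCGCTGGTT"  # 14 triplets, all distinct
        triplets = {seq[i:i + 3] for i in range(len(seq) - 2)}
        assert len(triplets) == len(seq) - 2
        assert dust_score(seq, window=64) == 0.0

    def test_short_sequence_scores_zero(self):
        assert dust_score("AC", window=64) == 0.0

    def test_deterministic(self):
        seq = "ACGTACGGGGTTTACG" * 8
        assert dust_score(seq) == dust_score(seq)

    def test_window_below_four_rejected(self):
        with pytest.raises(ValueError):
            dust_score("ACGTACGT", window=3)


def _t(id_, length, tpm):
    # deterministic pseudo-random sequence: high complexity, DUST far below 7
    r = random.Random(zlib.crc32(id_.encode()))
    seq = "".join(r.choice("ACGT") for _ in range(length))
    return TranscriptRecord(id_, seq, tpm)


class TestFilterTranscripts:
    def test_boundaries_and_first_failing_rule(self, config):
        records = [
            _t("short", 499, 5.0),
            _t("ok", 500, 1.0),
            _t("lowtpm", 800, 0.5),
            TranscriptRecord("homopolymer", "A" * 600, 10.0),
        ]
        kept, rejected = filter_transcripts(records, config)
        assert [r.id for r in kept] == ["ok"]
        assert dict(rejected) == {
            "short": "length",
            "lowtpm": "expression",
            "homopolymer": "complexity",
        }

    def test_inclusive_thresholds(self, config):
        # length exactly 500, TPM exactly 1 are retained
        kept, _ = filter_transcripts([_t("edge", 500, 1.0)], config)
        assert [r.id for r in kept] == ["edge"]

    def test_idempotent(self, config):
        records = [_t(f"t{i}", 400 + 50 * i, float(i)) for i in range(8)]
        once, _ = filter_transcripts(records, config)
        twice, rejected = filter_transcripts(once, config)
        assert twice == once and not rejected


class TestClusterIsoforms:
    def _records(self):
        return [
            TranscriptRecord("t1", "ACGT" * 200, 5.0),
            TranscriptRecord("t2", "ACGT" * 200, 9.0),
            TranscriptRecord("t3", "ACGT" * 200, 1.0),
            TranscriptRecord("t4", "ACGT" * 200, 2.0),
        ]

    def test_transitive_closure(self, config):
        matches = [("t1", "t2", 150, 0.98), ("t2", "t3", 120, 0.99)]
        clusters = cluster_isoforms(self._records(), matches, config)
        assert [(rep, members) for rep, members in clusters] == [
            ("t2", ["t1", "t2", "t3"]),
            ("t4", ["t4"]),
        ]

    def test_below_threshold_not_merged(self, config):
        for match in [("t1", "t2", 99, 0.99), ("t1", "t2", 150, 0.969)]:
            clusters = cluster_isoforms(self._records(), [match], config)
            assert len(clusters) == 4

    def test_representative_is_most_expressed(self, config):
        clusters = cluster_isoforms(self._records(), [("t1", "t2", 150, 0.98)], config)
        assert clusters[0][0] == "t2"  # tpm 9 beats tpm 5

    def test_representative_tie_breaks_lexicographically(self, config):
        records = [TranscriptRecord("b", "ACGT" * 50, 3.0),
                   TranscriptRecord("a", "ACGT" * 50, 3.0)]
        clusters = cluster_isoforms(records, [("a", "b", 150, 0.99)], config)
        assert clusters[0][0] == "a"

    def test_unknown_id_rejected(self, config):
        with pytest.raises(KeyError, match="tX"):
            cluster_isoforms(self._records(), [("t1", "tX", 150, 0.99)], config)

    def test_partition_invariant_under_match_order(self, config):
        records = [TranscriptRecord(f"t{i}", "ACGT" * 50, float(i)) for i in range(12)]
        matches = [(f"t{i}", f"t{i + 1}", 150, 0.99) for i in range(0, 10, 2)]
        matches += [("t1", "t4", 200, 0.98), ("t7", "t10", 120, 0.97)]
        expected = cluster_isoforms(records, matches, config)
        r = random.Random(1)
        for _ in range(10):
            shuffled = matches[:]
            r.shuffle(shuffled)
            assert cluster_isoforms(records, shuffled, config) == expected
        # clusters partition the input set
        members = [m for _, ms in expected for m in ms]
        assert sorted(members) == sorted(r.id for r in records)


class TestFilterFamilyAlignment:
    def test_row_filters(self, config):
        # 1501-column alignment: "long" has 1501 ungapped residues (> 1500),
        # "gappy" has 41% gaps in a second, narrower family
        wide = Alignment("F1", [
            ("long", "M" * 1501),
            ("ok1", "M" * 1101 + "-" * 400),
            ("ok2", "-" * 400 + "M" * 1101),
        ])
        filtered, removals = filter_family_alignment(wide, {}, config)
        assert removals == [("long", "protein_length")]
        assert filtered.ids() == ["ok1", "ok2"]
        narrow = Alignment("F2", [
            ("gappy", "M" * 59 + "-" * 41),
            ("ok1", "M" * 100),
            ("ok2", "M" * 100),
        ])
        filtered, removals = filter_family_alignment(narrow, {}, config)
        assert removals == [("gappy", "gaps")]
        assert filtered.ids() == ["ok1", "ok2"]

    def test_gap_fraction_boundary(self, config):
        # exactly 40% gaps is kept ("more than 40%" is exclusive)
        aln = Alignment("F1", [("a", "M" * 60 + "-" * 40), ("b", "M" * 100)])
        filtered, removals = filter_family_alignment(aln, {}, config)
        assert removals == [] and filtered.ids() == ["a", "b"]

    def test_cds_complexity_filter(self, config):
        aln = Alignment("F1", [("x", "MMM"), ("y", "MMM"), ("z", "MMM")])
        cds = {"x": "A" * 600}  # homopolymer CDS, DUST 31 > 7
        filtered, removals = filter_family_alignment(aln, cds, config)
        assert dict(removals) == {"x": "complexity"}
        assert filtered.ids() == ["y", "z"]

    def test_family_discarded_below_two_rows(self, config):
        aln = Alignment("F1", [
            ("long", "M" * 1501),
            ("b", "M" * 1101 + "-" * 400),
        ])
        filtered, removals = filter_family_alignment(aln, {}, config)
        assert filtered is None and removals == [("long", "protein_length")]

    def test_all_gap_columns_dropped(self, config):
        aln = Alignment("F1", [("a", "MA-KR"), ("b", "MC-RR"), ("c", "MG-AR")])
        filtered, _ = filter_family_alignment(aln, {}, config)
        assert [s for _, s in filtered.rows] == ["MAKR", "MCRR", "MGAR"]

    def test_idempotent(self, config):
        aln = Alignment("F1", [("a", "M-K-"), ("b", "MMKR"), ("c", "M-RR")])
        once, _ = filter_family_alignment(aln, {}, config)
        twice, removals = filter_family_alignment(once, {}, config)
        assert twice.rows == once.rows and removals == []


class TestBacktranslate:
    def test_gap_columns_become_gap_codons(self):
        aln = Alignment("F1", [("g1", "M-K"), ("g2", "MEK")])
        cds = {"g1": "ATGAAA", "g2": "ATGGAAAAG"}
        codon = backtranslate_alignment(aln, cds)
        assert dict(codon.rows) == {"g1": "ATG---AAA", "g2": "ATGGAAAAG"}

    def test_gapless_alignment(self):
        aln = Alignment("F1", [("g1", "MK"), ("g2", "MK")])
        codon = backtranslate_alignment(aln, {"g1": "ATGAAG", "g2": "ATGAAA"})
        assert codon.row("g1") == "ATGAAG"

    def test_trailing_stop_tolerated(self):
        aln = Alignment("F1", [("g1", "MK"), ("g2", "MK")])
        codon = backtranslate_alignment(aln, {"g1": "ATGAAGTAA", "g2": "ATGAAA"})
        assert codon.row("g1") == "ATGAAG"

    def test_mismatch_names_gene_and_position(self):
        aln = Alignment("F1", [("g1", "MK"), ("g2", "MK")])
        with pytest.raises(TranslationMismatch, match="g1.*residue 2.*'K'.*'N'"):
            backtranslate_alignment(aln, {"g1": "ATGAAT", "g2": "ATGAAA"})

    def test_translation_roundtrip_on_simulated_families(self):
        """Back-translated codon rows re-translate to the protein rows for
        every family in a simulated batch."""
        from Bio.Seq import Seq

        from duplidate.simulate import SimulationConfig, WgdEvent, simulate_families

        cfg = SimulationConfig(
            species_newick="((A:0.5,B:0.5):0.5,C:1.0);",
            n_families=200,
            wgd_events=[WgdEvent(branch="A+B", retention=0.5, age=0.8)],
            n_sites=40,
            seed=11,
        )
        _, families = simulate_families(cfg)
        assert len(families) == 200
        for fam in families:
            prot = fam.protein_alignment()
            codon = backtranslate_alignment(prot, fam.sequences)
            for gid, row in codon.rows:
                assert str(Seq(row.replace("---", "")).translate()) == \
                    prot.row(gid).replace("-", "")
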