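import math

import pytest

from duplidate.config import PipelineConfig
from duplidate.synteny import (
    GenomeGeneOrder,
    SyntenyLabel,
    classify_pair_across_genomes,
    classify_pair_in_genome,
    neighborhood_families,
    synteny_summary,
)


def genome(scaffolds: dict[str, list[str]], family_of: dict[str, str],
           genome_id: str = "G") -> GenomeGeneOrder:
    return GenomeGeneOrder(genome_id, scaffolds, family_of)


def small_config(window=50, shared=2):
    return PipelineConfig(synteny_window=window, min_shared_families=shared)


class TestNeighborhood:
    def test_truncated_at_scaffold_end(self):
        g = genome({"s": ["q", "g1", "g2"]},
                   {"q": "Fq", "g1": "F1", "g2": "F2"})
        assert set(neighborhood_families(g, "q", 50)) == {"F1", "F2"}

    def test_unassigned_and_own_family_excluded(self):
        g = genome({"s": ["x", "q", "y", "z"]},
                   {"x": "UNASSIGNED", "q": "Fq", "y": "Fq", "z": "F1"})
        assert set(neighborhood_families(g, "q", 50)) == {"F1"}

    def test_window_limits_span(self):
        fams = {f"g{i}": f"F{i}" for i in range(10)}
        g = genome({"s": [f"g{i}" for i in range(10)]}, fams)
        assert set(neighborhood_families(g, "g5", 2)) == {"F3", "F4", "F6", "F7"}

    def test_missing_gene_raises(self):
        g = genome({"s": ["a"]}, {"a": "F1"})
        with pytest.raises(KeyError):
            neighborhood_families(g, "zz", 50)


def two_scaffold_genome():
    # scaffold1 [F1,F2,q_a,F3], scaffold2 [F1,F2,q_b,F3]: three shared fams
    fams = {
        "x1": "F1", "x2": "F2", "qa": "FQ", "x3": "F3",
        "y1": "F1", "y2": "F2", "qb": "FQ", "y3": "F3",
    }
    return genome({"s1": ["x1", "x2", "qa", "x3"],
                   "s2": ["y1", "y2", "qb", "y3"]}, fams)


class TestClassifyInGenome:
    def test_close_within_window(self):
        fams = {f"g{i}": f"F{i}" for i in range(10)}
        fams.update({"qa": "FQ", "qb": "FQ"})
        order = ["g0", "g1", "qa", "g2", "qb", "g3", "g4"]
        g = genome({"s": order}, fams)
        assert classify_pair_in_genome("qa", "qb", g, small_config()) \
            is SyntenyLabel.CLOSE

    def test_some_synteny_from_shared_families(self):
        g = two_scaffold_genome()
        assert classify_pair_in_genome("qa", "qb", g, small_config()) \
            is SyntenyLabel.SOME_SYNTENY

    def test_no_info_when_neighbourhood_sparse(self):
        fams = {"qa": "FQ", "qb": "FQ", "x1": "F1", "x2": "F2"}
        g = genome({"s1": ["x1", "x2", "qa"], "s2": ["qb"]}, fams)
        assert classify_pair_in_genome("qa", "qb", g, small_config()) \
            is SyntenyLabel.NO_INFO

    def test_no_info_when_unlocatable(self):
        g = two_scaffold_genome()
        assert classify_pair_in_genome("qa", "missing", g, small_config()) \
            is SyntenyLabel.NO_INFO

    def test_no_synteny_single_shared_family(self):
        fams = {"qa": "FQ", "qb": "FQ",
                "a1": "F1", "a2": "F9", "b1": "F1", "b2": "F7"}
        g = genome({"s1": ["a1", "qa", "a2"], "s2": ["b1", "qb", "b2"]}, fams)
        assert classify_pair_in_genome("qa", "qb", g, small_config()) \
            is SyntenyLabel.NO_SYNTENY

    def test_close_takes_precedence_over_synteny(self):
        # tandem pair embedded in a duplicated block still reports CLOSE
        fams = {f"g{i}": f"F{i}" for i in range(8)}
        fams.update({"qa": "FQ", "qb": "FQ"})
        order = ["g0", "g1", "g2", "qa", "qb", "g1b", "g2b", "g3"]
        fams.update({"g1b": "F1", "g2b": "F2"})
        g = genome({"s": order}, fams)
        assert classify_pair_in_genome("qa", "qb", g, small_config()) \
            is SyntenyLabel.CLOSE

    def test_per_side_counting_stricter_than_pooled(self):
        # one shared family on each side: pooled sees 2, per-side max is 1
        fams = {"qa": "FQ", "qb": "FQ",
                "x1": "F1", "x2": "F2", "y1": "F1", "y2": "F2"}
        g = genome({"s1": ["x1", "qa", "x2"], "s2": ["y1", "qb", "y2"]}, fams)
        pooled = PipelineConfig()
        per_side = PipelineConfig(synteny_per_side=True)
        assert classify_pair_in_genome("qa", "qb", g, pooled) \
            is SyntenyLabel.SOME_SYNTENY
        assert classify_pair_in_genome("qa", "qb", g, per_side) \
            is SyntenyLabel.NO_SYNTENY

    def test_invariance_under_scaffold_reversal_and_swap(self):
        cfg = small_config()
        g = two_scaffold_genome()
        label = classify_pair_in_genome("qa", "qb", g, cfg)
        reversed_g = genome(
            {s: list(reversed(genes)) for s, genes in g.scaffolds.items()},
            g.family_of,
        )
        assert classify_pair_in_genome("qa", "qb", reversed_g, cfg) is label
        assert classify_pair_in_genome("qb", "qa", g, cfg) is label

    def test_enlarging_window_never_degrades_some_synteny(self):
        # shared families only visible at distance >= 3
        fams = {"qa": "FQ", "qb": "FQ"}
        s1 = ["u1", "u2", "s1a", "s2a", "qa", "s3a", "s4a", "u3", "u4"]
        s2 = ["v1", "v2", "s1b", "s2b", "qb", "s3b", "s4b", "v3", "v4"]
        for i, g in enumerate(s1[:2] + s1[-2:] + s2[:2] + s2[-2:]):
            fams[g] = f"U{i}"
        for tag in ("a", "b"):
            for i in range(1, 5):
                fams[f"s{i}{tag}"] = f"S{i}"
        g = genome({"s1": s1, "s2": s2}, fams)
        labels = [
            classify_pair_in_genome("qa", "qb", g, small_config(window=w))
            for w in range(2, 9)
        ]
        seen_some = False
        for lab in labels:
            if lab is SyntenyLabel.SOME_SYNTENY:
                seen_some = True
            if seen_some:
                assert lab is SyntenyLabel.SOME_SYNTENY


class TestConsensus:
    def _genomes(self, labels: dict[str, SyntenyLabel]):
        """Mock per-genome outcomes by building tiny genomes that produce
        the requested labels for pair (qa, qb)."""
        genomes = []
        for gid, lab in labels.items():
            if lab is SyntenyLabel.CLOSE:
                fams = {"qa": "FQ", "qb": "FQ"}
                order = {"s": ["n1", "qa", "qb", "n2", "n3"]}
                fams.update({"n1": "F1", "n2": "F2", "n3": "F3"})
            elif lab is SyntenyLabel.SOME_SYNTENY:
                g = two_scaffold_genome()
                genomes.append(GenomeGeneOrder(gid, g.scaffolds, g.family_of))
                continue
            elif lab is SyntenyLabel.NO_INFO:
                fams = {"qa": "FQ"}
                order = {"s": ["qa"]}
            else:  # NO_SYNTENY
                fams = {"qa": "FQ", "qb": "FQ",
                        "a1": "F1", "a2": "F9", "b1": "F1", "b2": "F7"}
                order = {"s1": ["a1", "qa", "a2"], "s2": ["b1", "qb", "b2"]}
            genomes.append(GenomeGeneOrder(gid, order, fams))
        return genomes

    def test_unanimity(self):
        genomes = self._genomes({"G1": SyntenyLabel.CLOSE, "G2": SyntenyLabel.CLOSE})
        consensus, votes = classify_pair_across_genomes("qa", "qb", genomes, small_config())
        assert consensus is SyntenyLabel.CLOSE and len(votes) == 2

    def test_no_info_votes_dropped(self):
        genomes = self._genomes({"G1": SyntenyLabel.SOME_SYNTENY,
                                 "G2": SyntenyLabel.NO_INFO})
        consensus, _ = classify_pair_across_genomes("qa", "qb", genomes, small_config())
        assert consensus is SyntenyLabel.SOME_SYNTENY

    def test_disagreement_is_conflicting(self):
        genomes = self._genomes({"G1": SyntenyLabel.CLOSE,
                                 "G2": SyntenyLabel.SOME_SYNTENY})
        consensus, _ = classify_pair_across_genomes("qa", "qb", genomes, small_config())
        assert consensus is SyntenyLabel.CONFLICTING

    def test_all_no_info(self):
        genomes = self._genomes({"G1": SyntenyLabel.NO_INFO})
        consensus, _ = classify_pair_across_genomes("qa", "qb", genomes, small_config())
        assert consensus is SyntenyLabel.NO_INFO


class TestSummary:
    def test_percentages_over_informative_pairs(self):
        table = synteny_summary({
            "B1": [SyntenyLabel.CLOSE, SyntenyLabel.SOME_SYNTENY,
                   SyntenyLabel.SOME_SYNTENY, SyntenyLabel.NO_INFO],
        })
        row = table.iloc[0]
        assert row["n_informative"] == 3 and row["n_no_info"] == 1
        assert row["pct_close"] == pytest.approx(100 / 3)
        assert row["pct_some_synteny"] == pytest.approx(200 / 3)

    def test_all_no_info_flagged_undefined(self):
        table = synteny_summary({"B1": [SyntenyLabel.NO_INFO] * 3})
        assert math.isnan(table.iloc[0]["pct_close"])

    def test_empty_branch_zero_row(self):
        table = synteny_summary({"B1": []})
        assert table.iloc[0]["n_pairs"] == 0

    def test_conflicting_excluded_from_denominator(self):
        table = synteny_summary({
            "B1": [SyntenyLabel.CLOSE, SyntenyLabel.CONFLICTING],
        })
        row = table.iloc[0]
        assert row["n_conflicting"] == 1
        assert row["pct_close"] == pytest.approx(100.0)
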