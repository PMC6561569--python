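"""Rule-based synteny classification of paralogue pairs.

Within one genome a pair is CLOSE when the two copies sit within the
synteny window of each other on one scaffold (the tandem-duplication
signature), SOME_SYNTENY when their neighbourhoods share at least
``min_shared_families`` other gene families (the whole-genome /
block-duplication signature), NO_SYNTENY otherwise, and NO_INFO when a
copy cannot be located or a neighbourhood holds fewer than two annotated
families.  Across genomes the per-genome votes (NO_INFO dropped) are
combined: unanimity wins, disagreement is CONFLICTING.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from duplidate.config import PipelineConfig

UNASSIGNED = "UNASSIGNED"


class SyntenyLabel(str, Enum):
    CLOSE = "CLOSE"
    SOME_SYNTENY = "SOME_SYNTENY"
    NO_SYNTENY = "NO_SYNTENY"
    NO_INFO = "NO_INFO"
    CONFLICTING = "CONFLICTING"


@dataclass
class GenomeGeneOrder:
    """Ordered gene lists per scaffold with family annotations."""

    genome_id: str
    scaffolds: dict[str, list[str]]          # scaffold -> genes in order
    family_of: dict[str, str]                # gene -> family or UNASSIGNED

    def __post_init__(self) -> None:
        self._location: dict[str, tuple[str, int]] = {}
        for scaffold, genes in self.scaffolds.items():
            for i, g in enumerate(genes):
                if g in self._location:
                    raise ValueError(f"{self.genome_id}: gene {g!r} appears twice")
                self._location[g] = (scaffold, i)

    def locate(self, gene: str) -> tuple[str, int] | None:
        return self._location.get(gene)

    @classmethod
    def from_position_table(
        cls, positions: pd.DataFrame, genome_id: str, family_of: dict[str, str]
    ) -> "GenomeGeneOrder":
        sub = positions[positions["genome_id"] == genome_id]
        scaffolds: dict[str, list[str]] = {}
        for scaffold, grp in sub.groupby("scaffold_id", sort=True):
            ordered = grp.sort_values("gene_index")
            scaffolds[scaffold] = list(ordered["gene_id"])
        return cls(genome_id, scaffolds, family_of)


def _side_families(genome: GenomeGeneOrder, gene: str, window: int
                   ) -> tuple[Counter, Counter]:
    loc = genome.locate(gene)
    if loc is None:
        raise KeyError(f"{gene!r} not located in genome {genome.genome_id}")
    scaffold, idx = loc
    genes = genome.scaffolds[scaffold]
    own = genome.family_of.get(gene, UNASSIGNED)
    sides = (genes[max(0, idx - window):idx], genes[idx + 1:idx + 1 + window])
    out = []
    for side in sides:
        fams = Counter()
        for g in side:
            fam = genome.family_of.get(g, UNASSIGNED)
            if fam != UNASSIGNED and fam != own:
                fams[fam] += 1
        out.append(fams)
    return out[0], out[1]


def neighborhood_families(
    genome: GenomeGeneOrder, gene: str, window: int
) -> Counter:
    """Families of up to ``window`` genes on each side of ``gene`` on its
    scaffold, excluding the query's own family and unannotated genes.
    Truncated at scaffold ends.  Raises KeyError if the gene is absent."""
    left, right = _side_families(genome, gene, window)
    return left + right


def classify_pair_in_genome(
    gene_a: str,
    gene_b: str,
    genome: GenomeGeneOrder,
    config: PipelineConfig,
) -> SyntenyLabel:
    """Apply the classification rules in strict precedence:

    1. either copy unlocatable, or either neighbourhood has fewer than two
       annotated families -> NO_INFO;
    2. same scaffold within ``synteny_window`` genes -> CLOSE;
    3. neighbourhoods share >= ``min_shared_families`` families
       (set semantics, both sides pooled) -> SOME_SYNTENY;
    4. otherwise NO_SYNTENY.
    """
    loc_a, loc_b = genome.locate(gene_a), genome.locate(gene_b)
    if loc_a is None or loc_b is None:
        return SyntenyLabel.NO_INFO
    fams_a = neighborhood_families(genome, gene_a, config.synteny_window)
    fams_b = neighborhood_families(genome, gene_b, config.synteny_window)
    if len(fams_a) < 2 or len(fams_b) < 2:
        return SyntenyLabel.NO_INFO
    if loc_a[0] == loc_b[0] and abs(loc_a[1] - loc_b[1]) <= config.synteny_window:
        return SyntenyLabel.CLOSE
    if config.synteny_per_side:
        sides_a = _side_families(genome, gene_a, config.synteny_window)
        sides_b = _side_families(genome, gene_b, config.synteny_window)
        n_shared = max(
            len(set(sa) & set(sb)) for sa in sides_a for sb in sides_b
        )
    else:
        n_shared = len(set(fams_a) & set(fams_b))
    if n_shared >= config.min_shared_families:
        return SyntenyLabel.SOME_SYNTENY
    return SyntenyLabel.NO_SYNTENY


def classify_pair_across_genomes(
    gene_a: str,
    gene_b: str,
    genomes: list[GenomeGeneOrder],
    config: PipelineConfig,
) -> tuple[SyntenyLabel, dict[str, SyntenyLabel]]:
    """Consensus over per-genome votes: NO_INFO votes are dropped; an empty
    remainder is NO_INFO, unanimity is that label, disagreement between
    genomes is CONFLICTING."""
    votes = {
        g.genome_id: classify_pair_in_genome(gene_a, gene_b, g, config)
        for g in genomes
    }
    informative = {v for v in votes.values() if v != SyntenyLabel.NO_INFO}
    if not informative:
        return SyntenyLabel.NO_INFO, votes
    if len(informative) == 1:
        return next(iter(informative)), votes
    return SyntenyLabel.CONFLICTING, votes


def synteny_summary(labels_by_branch: dict[str, list[SyntenyLabel]]) -> pd.DataFrame:
    """Per-branch percentages of CLOSE / SOME_SYNTENY / NO_SYNTENY over the
    informative pairs (NO_INFO and CONFLICTING excluded from the
    denominator and reported as counts)."""
    rows = []
    informative_labels = (
        SyntenyLabel.CLOSE, SyntenyLabel.SOME_SYNTENY, SyntenyLabel.NO_SYNTENY
    )
    for branch in sorted(labels_by_branch):
        labels = labels_by_branch[branch]
        counts = Counter(labels)
        n_inf = sum(counts[l] for l in informative_labels)
        row = {
            "branch": branch,
            "n_pairs": len(labels),
            "n_informative": n_inf,
            "n_no_info": counts[SyntenyLabel.NO_INFO],
            "n_conflicting": counts[SyntenyLabel.CONFLICTING],
        }
        for lab in informative_labels:
            row[f"n_{lab.value.lower()}"] = counts[lab]
            row[f"pct_{lab.value.lower()}"] = (
                100.0 * counts[lab] / n_inf if n_inf else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
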