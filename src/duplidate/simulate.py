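"""Ground-truthed simulation of gene families, sequences and genomes.

The generator plants three kinds of signal with known truth:

* **WGD events** on chosen species-tree branches.  A family assigned to an
  event carries a duplication whose *divergence onset* may be delayed
  relative to the event (``onset_offset > 0``): while a duplicated region
  remains tetrasomic the two copies keep recombining and do not diverge,
  so the gene-tree bifurcation sits at ``event age - offset``.  When the
  onset postdates later speciations, each descendant lineage resolves the
  duplicates independently and LCA reconciliation assigns the duplication
  to the descendant branches — the delayed-rediploidization signature.
* **Tandem segmental duplications** on random branches at ``tandem_rate``
  per family; the copy is inserted adjacent to the original.
* **Genome structure**: each WGD event owns a disjoint set of ancestral
  scaffolds (rediploidization is regional); at the event the scaffold is
  duplicated, retained families keep a copy on both scaffold copies and
  background families keep one copy on a random side.  Gene loss and
  local order shuffling then degrade the neighbourhoods.

Third positions of fourfold-degenerate codons evolve under Jukes-Cantor
with rate ``mu``; the first two positions are drawn once per site from
the eight fourfold codon families and held fixed, so every simulated
substitution is synonymous and the expected raw 4dTv between two copies
that started diverging a time ``t`` ago is (1 - exp(-4*mu*2t/3))/2 and
the expected corrected 4dTv is 2*mu*2t/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from duplidate import io as dio
from duplidate.alignprep import Alignment
from duplidate.synteny import GenomeGeneOrder, SyntenyLabel

FOURFOLD_PREFIX_LIST = ["AC", "CC", "CG", "CT", "GC", "GG", "GT", "TC"]
_BASE = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class WgdEvent:
    """A whole-genome duplication on one species-tree branch.

    ``branch`` is the branch name (sorted leaf set joined by '+', e.g.
    ``"A+B"``); ``age`` the event age (time before present, must lie on
    the branch; default = branch midpoint); ``retention`` the probability
    that a family keeps both copies; ``onset_offset`` the delay between
    the event and the onset of sequence divergence (0 = instant
    rediploidization).
    """

    branch: str
    retention: float
    age: float | None = None
    onset_offset: float = 0.0


@dataclass
class SimulationConfig:
    species_newick: str
    n_families: int
    wgd_events: list[WgdEvent] = field(default_factory=list)
    tandem_rate: float = 0.0
    mu: float = 1.0
    n_sites: int = 300           # fourfold codons per gene
    gene_loss_frac: float = 0.0
    shuffle_frac: float = 0.0
    scaffold_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_sites < 1 or self.scaffold_size < 2:
            raise SimulationError("n_families, n_sites >= 1 and scaffold_size >= 2 required")
        for name in ("tandem_rate", "mu", "gene_loss_frac", "shuffle_frac"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for ev in self.wgd_events:
            if not 0 <= ev.retention <= 1:
                raise SimulationError("retention must be in [0, 1]")
            if ev.onset_offset < 0:
                raise SimulationError("onset_offset must be >= 0")


# ------------------------------------------------------------ species tree

@dataclass(eq=False)
class SNode:
    """Lightweight ultrametric species-tree node (ages before present)."""

    clade: frozenset[str]
    age: float
    children: list["SNode"] = field(default_factory=list)
    parent: "SNode | None" = None

    @property
    def name(self) -> str:
        return "+".join(sorted(self.clade))

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()


def species_tree_from_newick(newick: str) -> SNode:
    """Parse an ultrametric species tree with branch lengths into SNodes."""
    tree = dio.read_newick(newick)

    def convert(node) -> SNode:
        if node.is_leaf():
            return SNode(frozenset({node.taxon.label}), 0.0)
        kids = [convert(c) for c in node.child_nodes()]
        ages = [k.age + c.edge.length for k, c in zip(kids, node.child_nodes())]
        if max(ages) - min(ages) > 1e-6 * max(max(ages), 1.0):
            raise SimulationError(
                f"species tree not ultrametric at clade "
                f"{sorted(frozenset().union(*(k.clade for k in kids)))}"
            )
        sn = SNode(frozenset().union(*(k.clade for k in kids)), max(ages), kids)
        for k in kids:
            k.parent = sn
        return sn

    return convert(tree.seed_node)


def _branch_node(root: SNode, branch: str) -> SNode:
    target = frozenset(branch.split("+"))
    for node in root.preorder():
        if node.clade == target:
            return node
    raise SimulationError(f"branch {branch!r} not found in species tree")


# ------------------------------------------------------------ gene trees

@dataclass(eq=False)
class GNode:
    age: float
    children: list["GNode"] = field(default_factory=list)
    name: str | None = None       # leaves only

    def leaves(self) -> list["GNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def render(node: GNode, parent_age: float) -> str:
            length = parent_age - node.age
            if not node.children:
                return f"{node.name}:{length:.8g}"
            inner = ",".join(render(c, node.age) for c in node.children)
            return f"({inner}):{length:.8g}"

        inner = ",".join(render(c, self.age) for c in self.children)
        return f"({inner});"


@dataclass
class TruthPair:
    family_id: str
    gene_a: str
    gene_b: str
    event_type: str          # "WGD" | "SD"
    branch: str              # species-tree branch of the duplication node
    t_divergence: float      # age at which the pair started diverging
    synteny_truth: str       # planted label before degradation


@dataclass
class SimulatedFamily:
    family_id: str
    root: GNode
    gene_species: dict[str, str]          # gene id -> species
    event_kind: str                        # "WGD:<branch>" | "SD:<branch>" | "none"
    event_index: int | None                # index into config.wgd_events, or None
    truth_pairs: list[TruthPair] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)   # aligned CDS

    @property
    def newick(self) -> str:
        return self.root.newick()

    def codon_alignment(self) -> Alignment:
        rows = sorted(self.sequences.items())
        return Alignment(self.family_id, rows)

    def protein_alignment(self) -> Alignment:
        rows = [
            (gid, str(Seq(seq).translate()))
            for gid, seq in sorted(self.sequences.items())
        ]
        return Alignment(self.family_id, rows)


def _dup_edges(root: SNode, branch_node: SNode, onset_age: float) -> list[SNode]:
    """Edges (identified by their child node) at or below ``branch_node``'s
    edge that cross ``onset_age``: where the duplicates start to diverge."""
    top = branch_node.parent.age if branch_node.parent else math.inf
    if branch_node.age < onset_age <= top:
        return [branch_node]
    out = []
    for node in branch_node.preorder():
        if node is branch_node:
            continue
        if node.age < onset_age <= node.parent.age:
            out.append(node)
    if not out:
        raise SimulationError(
            f"divergence onset {onset_age} falls below every lineage of "
            f"branch {branch_node.name}"
        )
    return out


def _build_gene_tree(
    family_id: str,
    root: SNode,
    dup_edges: dict,            # SNode -> duplication age on that edge
) -> tuple[GNode, dict[str, str], dict]:
    """Clone the species tree into a gene tree, inserting one duplication
    node per entry of ``dup_edges``.  Returns (root, gene->species,
    dup GNode -> species edge)."""
    counters: dict[str, int] = {}
    gene_species: dict[str, str] = {}
    dup_nodes: dict = {}

    def new_leaf(species: str) -> GNode:
        counters[species] = counters.get(species, 0) + 1
        gid = f"{family_id}_{species}_{counters[species]}"
        gene_species[gid] = species
        return GNode(0.0, name=gid)

    def descend(sn: SNode) -> GNode:
        if sn.is_leaf():
            return new_leaf(next(iter(sn.clade)))
        return GNode(sn.age, [enter(c) for c in sn.children])

    def enter(sn: SNode) -> GNode:
        if sn in dup_edges:
            d = dup_edges[sn]
            node = GNode(d, [descend(sn), descend(sn)])
            dup_nodes[id(node)] = (node, sn)
            return node
        return descend(sn)

    return enter(root) if root in dup_edges else descend(root), gene_species, dup_nodes


def simulate_families(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SNode, list[SimulatedFamily]]:
    """Generate gene trees, sequences and truth for ``n_families`` families.

    Each family is assigned at most one event: the WGD events are tried in
    order (Bernoulli with their retention), then a tandem SD with
    probability ``tandem_rate`` on a uniformly chosen non-root branch.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    root = species_tree_from_newick(config.species_newick)
    event_nodes = []
    for ev in config.wgd_events:
        node = _branch_node(root, ev.branch)
        top = node.parent.age if node.parent else math.inf
        age = ev.age if ev.age is not None else (node.age + min(top, 2 * node.age + 1)) / 2
        if not node.age < age <= top:
            raise SimulationError(
                f"WGD age {age} not on branch {ev.branch} (span ({node.age}, {top}])"
            )
        if ev.onset_offset > age:
            raise SimulationError("onset_offset larger than the event age")
        event_nodes.append((node, age))
    all_edges = [n for n in root.preorder() if n.parent is not None]

    families = []
    for i in range(config.n_families):
        fam = f"F{i:05d}"
        event_index: int | None = None
        event_kind = "none"
        dup_edges: dict = {}
        dup_meta: tuple[str, str, float] | None = None   # (type, branch, onset)
        for j, ev in enumerate(config.wgd_events):
            if rng.random() < ev.retention:
                node, age = event_nodes[j]
                onset = age - ev.onset_offset
                edges = _dup_edges(root, node, onset)
                dup_edges = {e: onset for e in edges}
                event_index = j
                event_kind = f"WGD:{ev.branch}"
                dup_meta = ("WGD", ev.branch, onset)
                break
        if dup_meta is None and config.tandem_rate > 0:
            if rng.random() < config.tandem_rate:
                edge = all_edges[rng.integers(len(all_edges))]
                top = edge.parent.age
                age = float(edge.age + (top - edge.age) * rng.random())
                dup_edges = {edge: age}
                event_kind = f"SD:{edge.name}"
                dup_meta = ("SD", edge.name, age)

        groot, gene_species, dup_nodes = _build_gene_tree(fam, root, dup_edges)
        truth_pairs = []
        if dup_meta is not None:
            kind, _, _ = dup_meta
            planted = (
                SyntenyLabel.CLOSE.value if kind == "SD" else SyntenyLabel.SOME_SYNTENY.value
            )
            for gnode, sedge in dup_nodes.values():
                left, right = gnode.children
                for la in left.leaves():
                    for lb in right.leaves():
                        a, b = sorted((la.name, lb.name))
                        truth_pairs.append(
                            TruthPair(fam, a, b, kind, sedge.name, gnode.age, planted)
                        )
        truth_pairs.sort(key=lambda t: (t.gene_a, t.gene_b))
        sequences = evolve_fourfold_sites(groot, config.mu, config.n_sites, rng)
        families.append(
            SimulatedFamily(fam, groot, gene_species, event_kind, event_index,
                            truth_pairs, sequences)
        )
    return root, families


def evolve_fourfold_sites(
    gene_tree: GNode,
    mu: float,
    n_sites: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve ``n_sites`` fourfold-degenerate codons down the gene tree.

    The first two codon positions are drawn once per site from the eight
    fourfold-degenerate families and held fixed; third positions start
    uniform at the root and evolve under Jukes-Cantor with rate ``mu``
    (per site per unit time): along a branch of length L a site keeps its
    base with probability 1/4 + 3/4 exp(-4 mu L / 3), otherwise it takes
    one of the other three bases uniformly.
    """
    prefixes = [FOURFOLD_PREFIX_LIST[j] for j in rng.integers(0, 8, size=n_sites)]
    out: dict[str, str] = {}

    def walk(node: GNode, third: np.ndarray, parent_age: float) -> None:
        length = parent_age - node.age
        if length > 0 and mu > 0:
            p_same = 0.25 + 0.75 * math.exp(-4.0 * mu * length / 3.0)
            changed = rng.random(n_sites) >= p_same
            if changed.any():
                third = third.copy()
                shifts = rng.integers(1, 4, size=int(changed.sum()))
                third[changed] = (third[changed] + shifts) % 4
        if node.children:
            for c in node.children:
                walk(c, third, node.age)
        else:
            out[node.name] = "".join(
                p + b for p, b in zip(prefixes, _BASE[third])
            )

    root_third = rng.integers(0, 4, size=n_sites)
    for c in gene_tree.children or [gene_tree]:
        walk(c, root_third, gene_tree.age)
    if not gene_tree.children:
        out[gene_tree.name] = "".join(p + b for p, b in zip(prefixes, _BASE[root_third]))
    return out


# ------------------------------------------------------------ genomes

def _scaffold_chunks(families: list, size: int) -> list[list]:
    """Split a family list into scaffold-sized chunks; a short trailing
    chunk is merged into the previous scaffold so no region is too small
    to carry a synteny signal."""
    chunks = [families[i:i + size] for i in range(0, len(families), size)]
    if len(chunks) > 1 and len(chunks[-1]) < size // 2:
        tail = chunks.pop()
        chunks[-1].extend(tail)
    return chunks

def simulate_genomes(
    config: SimulationConfig,
    species_root: SNode,
    families: list[SimulatedFamily],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GenomeGeneOrder], pd.DataFrame]:
    """Build per-species gene orders realising the planted synteny.

    Ancestral scaffolds interleave each WGD event's families with an equal
    number of background families; remaining families fill background
    scaffolds.  In species descending from an event's branch the event's
    scaffolds are present in two copies: retained families appear on both
    (planted SOME_SYNTENY), background families on one random side.
    Tandem copies are inserted adjacent to the original (planted CLOSE).
    Gene loss (background genes only) and local shuffling then degrade
    the neighbourhoods.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    species = sorted(frozenset().union(species_root.clade))
    by_event: dict[int, list[SimulatedFamily]] = {}
    tandem: list[SimulatedFamily] = []
    background: list[SimulatedFamily] = []
    for fam in families:
        if fam.event_index is not None:
            by_event.setdefault(fam.event_index, []).append(fam)
        elif fam.event_kind.startswith("SD:"):
            tandem.append(fam)
        else:
            background.append(fam)

    # ancestral scaffold plan: (scaffold_id, ordered families, owner event)
    # background families are split between the event regions and the rest
    # proportionally, so every region keeps annotated neighbour genes
    bg_pool = list(background)
    n_bg = len(bg_pool)
    n_assigned = sum(len(v) for v in by_event.values()) + len(tandem)
    plan: list[tuple[str, list[SimulatedFamily], int | None]] = []
    serial = 0
    for j in sorted(by_event):
        fams = by_event[j]
        share = int(round(n_bg * len(fams) / n_assigned)) if n_assigned else 0
        take = min(len(bg_pool), share)
        mixed = fams + bg_pool[:take]
        del bg_pool[:take]
        order = rng.permutation(len(mixed))
        mixed = [mixed[i] for i in order]
        for chunk in _scaffold_chunks(mixed, config.scaffold_size):
            plan.append((f"anc{serial:04d}", chunk, j))
            serial += 1
    rest = bg_pool + tandem
    order = rng.permutation(len(rest)) if rest else []
    rest = [rest[i] for i in order]
    for chunk in _scaffold_chunks(rest, config.scaffold_size):
        plan.append((f"anc{serial:04d}", chunk, None))
        serial += 1

    affected = {
        j: frozenset(config.wgd_events[j].branch.split("+"))
        for j in by_event
    }

    genomes: dict[str, GenomeGeneOrder] = {}
    rows = []
    family_of: dict[str, str] = {}
    for fam in families:
        for gid in fam.gene_species:
            family_of[gid] = fam.family_id
    for sp in species:
        scaffolds: dict[str, list[str]] = {}
        for anc_id, fams, owner in plan:
            duplicated = owner is not None and sp in affected[owner]
            copies: list[list[str]] = [[], []] if duplicated else [[]]
            for fam in fams:
                genes = sorted(
                    g for g, s in fam.gene_species.items() if s == sp
                )
                if not genes:
                    continue
                if fam.event_index == owner and owner is not None and len(genes) == 2:
                    copies[0].append(genes[0])
                    copies[1].append(genes[1])
                elif fam.event_kind.startswith("SD:") and len(genes) == 2:
                    side = copies[rng.integers(len(copies))]
                    side.extend(genes)        # tandem: adjacent
                else:
                    side = copies[rng.integers(len(copies))] if duplicated else copies[0]
                    # a family with its own event elsewhere or a background
                    # family contributes its single local copy
                    side.extend(genes)
            names = [f"{sp}_{anc_id}a", f"{sp}_{anc_id}b"] if duplicated else [f"{sp}_{anc_id}"]
            for name, genes in zip(names, copies):
                if genes:
                    scaffolds[name] = genes
        # degradation: loss on genes outside truth pairs, then local shuffles
        pair_genes = {
            g for fam in families for t in fam.truth_pairs for g in (t.gene_a, t.gene_b)
        }
        if config.gene_loss_frac > 0:
            for name in sorted(scaffolds):
                kept = []
                for g in scaffolds[name]:
                    if g not in pair_genes and rng.random() < config.gene_loss_frac:
                        continue
                    kept.append(g)
                scaffolds[name] = kept
            scaffolds = {n: g for n, g in scaffolds.items() if g}
        if config.shuffle_frac > 0:
            for name in sorted(scaffolds):
                genes = scaffolds[name]
                n_swap = int(round(config.shuffle_frac * len(genes)))
                for _ in range(n_swap):
                    if len(genes) < 2:
                        break
                    i = int(rng.integers(len(genes)))
                    j = min(len(genes) - 1, max(0, i + int(rng.integers(-3, 4))))
                    genes[i], genes[j] = genes[j], genes[i]
        genomes[sp] = GenomeGeneOrder(sp, scaffolds, family_of)
        for name in sorted(scaffolds):
            for i, g in enumerate(scaffolds[name]):
                rows.append((g, sp, name, i))
    positions = pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "scaffold_id", "gene_index"]
    )
    return genomes, positions


def truth_table(families: list[SimulatedFamily]) -> pd.DataFrame:
    rows = [
        (t.family_id, t.gene_a, t.gene_b, t.event_type, t.branch,
         t.t_divergence, t.synteny_truth)
        for fam in families
        for t in fam.truth_pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["family_id", "gene_a", "gene_b", "event_type", "branch",
                 "t_divergence", "synteny_truth"],
    )


def family_table(families: list[SimulatedFamily]) -> pd.DataFrame:
    rows = [
        (gid, fam.family_id, sp)
        for fam in families
        for gid, sp in sorted(fam.gene_species.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "family_id", "species_id"])
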