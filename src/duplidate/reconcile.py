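"""Gene-tree / species-tree LCA reconciliation and duplication tagging.

Each internal gene-tree node v is mapped to the species-tree node M(v) =
LCA of its children's mappings; v is a duplication iff M(v) equals the
mapping of at least one child (the parsimony criterion).  Each duplication
is assigned to the species-tree branch above M(v), and emits the cross
pairs between its two child clades as dated paralogue pairs.

Branches are identified by their child node and named by the sorted leaf
set of that node's clade (e.g. ``"A+B"``); the root branch carries the
full leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd


class ReconciliationError(ValueError):
    pass


class SpeciesTreeIndex:
    """Rooted binary species tree with O(depth) LCA queries.

    Branch ids are assigned in preorder (0 = root branch) alongside the
    leaf-set name, mirroring cladogram-style branch numbering.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._parent: dict[dendropy.Node, dendropy.Node | None] = {}
        self._depth: dict[dendropy.Node, int] = {}
        self._clade: dict[dendropy.Node, frozenset[str]] = {}
        self.branch_order: list[str] = []
        self._by_label: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise ReconciliationError(
                    f"species tree not binary at a node with {len(kids)} children"
                )
            parent = node.parent_node
            self._parent[node] = parent
            self._depth[node] = 0 if parent is None else self._depth[parent] + 1
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                self._clade[node] = frozenset({label})
                self._by_label[label] = node
            else:
                self._clade[node] = frozenset().union(
                    *(self._clade[c] for c in node.child_nodes())
                )
        for node in tree.preorder_node_iter():
            self.branch_order.append(self.branch_name(node))

    def leaf(self, species: str) -> dendropy.Node:
        try:
            return self._by_label[species]
        except KeyError:
            raise ReconciliationError(f"species {species!r} absent from species tree")

    def branch_name(self, node: dendropy.Node) -> str:
        return "+".join(sorted(self._clade[node]))

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if self._depth[a] < self._depth[b]:
                b = self._parent[b]
            else:
                a = self._parent[a]
        return a


@dataclass
class ReconciledTree:
    gene_tree: dendropy.Tree
    mapping: dict  # gene-tree node -> species-tree node
    labels: dict   # internal gene-tree node -> "speciation" | "duplication"

    def duplication_nodes(self) -> list:
        return [n for n, lab in self.labels.items() if lab == "duplication"]


@dataclass
class DuplicationEvent:
    family_id: str
    node_id: str                 # sorted leaf labels under the duplication node
    branch: str                  # species-tree branch name
    pairs: list[tuple[str, str]]


def lca_map(
    gene_tree: dendropy.Tree,
    species_index: SpeciesTreeIndex,
    gene_to_species: dict[str, str],
) -> ReconciledTree:
    """Standard LCA reconciliation of one rooted binary gene tree."""
    mapping: dict = {}
    labels: dict = {}
    for node in gene_tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            gene = node.taxon.label
            if gene not in gene_to_species:
                raise ReconciliationError(f"gene {gene!r} has no species mapping")
            mapping[node] = species_index.leaf(gene_to_species[gene])
        else:
            if len(kids) != 2:
                raise ReconciliationError(
                    f"gene tree not binary: node with {len(kids)} children"
                )
            m = species_index.lca(mapping[kids[0]], mapping[kids[1]])
            mapping[node] = m
            is_dup = any(mapping[c] is m for c in kids)
            labels[node] = "duplication" if is_dup else "speciation"
    return ReconciledTree(gene_tree, mapping, labels)


def tag_duplications(
    family_id: str,
    reconciled: ReconciledTree,
    species_index: SpeciesTreeIndex,
    pair_selector=None,
) -> list[DuplicationEvent]:
    """One event per duplication node with its branch and paralogue pairs.

    Pairs default to all cross pairs between the two child clades; pass
    ``pair_selector(pairs) -> pairs`` to restrict (e.g. to one
    representative pair with the most qualifying 4dTv sites).
    """
    events = []
    for node in reconciled.gene_tree.postorder_node_iter():
        if reconciled.labels.get(node) != "duplication":
            continue
        left, right = node.child_nodes()
        left_leaves = sorted(l.taxon.label for l in left.leaf_iter())
        right_leaves = sorted(l.taxon.label for l in right.leaf_iter())
        pairs = [tuple(sorted((a, b))) for a in left_leaves for b in right_leaves]
        pairs.sort()
        if pair_selector is not None:
            pairs = pair_selector(pairs)
        events.append(
            DuplicationEvent(
                family_id=family_id,
                node_id="+".join(sorted(left_leaves + right_leaves)),
                branch=species_index.branch_name(reconciled.mapping[node]),
                pairs=pairs,
            )
        )
    events.sort(key=lambda e: (e.family_id, e.node_id))
    return events


def representative_pair_selector(alignment_rows: dict[str, str]):
    """Selector keeping only the cross pair with the most qualifying
    fourfold-degenerate sites (ties: lexicographically first pair)."""
    from duplidate.fourdtv import qualifying_site_count

    def select(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
        pairs = [p for p in pairs
                 if p[0] in alignment_rows and p[1] in alignment_rows]
        if not pairs:
            return pairs
        scores = {
            p: qualifying_site_count(alignment_rows[p[0]], alignment_rows[p[1]])
            for p in pairs
        }
        top = max(scores.values())
        return [next(p for p in sorted(pairs) if scores[p] == top)]

    return select


def count_duplications_per_branch(
    events: list[DuplicationEvent],
    species_index: SpeciesTreeIndex,
) -> pd.DataFrame:
    """Per-branch duplication counts over every species-tree branch
    (zero rows included), in preorder branch order."""
    counts = {name: 0 for name in species_index.branch_order}
    for ev in events:
        counts[ev.branch] += 1
    return pd.DataFrame(
        {"branch": list(counts), "n_duplications": list(counts.values())}
    )
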