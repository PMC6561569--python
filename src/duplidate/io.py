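"""Readers and writers for the pipeline's external formats.

FASTA goes through Biopython, Newick through dendropy, tables through
pandas.  All readers validate the invariants the downstream stages rely on
(unique ids, contiguous gene ordinals, required columns) and raise
:class:`FormatError` with the offending record named.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("duplidate")


class FormatError(ValueError):
    """An input file violates the format contract; message names the offender."""


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Line-oriented logging to stderr and, optionally, a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    log.setLevel(level)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as an ordered list of (id, sequence).

    The id is the first whitespace-delimited token of the header.  Raises
    :class:`FormatError` on an empty file or duplicate ids.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise FormatError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------- Newick

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a single rooted tree; topology preserved exactly.

    Accepts a path or a Newick string.  Raises :class:`FormatError` on
    malformed Newick or duplicate leaf labels.  Polytomies are preserved;
    callers that require binary trees check ``tree_is_binary``.
    """
    text = _newick_text(path_or_string)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon" in str(exc):
            raise FormatError(f"duplicate leaf labels: {exc}") from exc
        raise FormatError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def read_newick_forest(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (one tree per line/statement)."""
    trees = []
    text = Path(path).read_text()
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(read_newick(chunk + ";"))
    if not trees:
        raise FormatError(f"{path}: no trees")
    return trees


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()


def tree_is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(node.child_nodes()) in (0, 2) for node in tree.preorder_node_iter()
    )


def _newick_text(path_or_string: str | Path) -> str:
    s = str(path_or_string)
    if "(" in s and ")" in s:  # literal newick
        return s
    return Path(path_or_string).read_text()


# ---------------------------------------------------------------- tables

FAMILY_COLUMNS = ["gene_id", "family_id", "species_id"]
POSITION_COLUMNS = ["gene_id", "genome_id", "scaffold_id", "gene_index"]
ANNOTATION_COLUMNS = ["gene_id", "term_id"]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        log.warning("%s: table is empty (header only)", path)
    log.info("%s: read %d rows", path, len(df))
    return df[columns].copy()


def read_family_table(path: str | Path) -> pd.DataFrame:
    """gene_id -> (family_id, species_id); gene_id must be unique."""
    df = _read_tsv(path, FAMILY_COLUMNS)
    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"]
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene_id {dupes.iloc[0]!r}")
    return df


def read_position_table(path: str | Path) -> pd.DataFrame:
    """Gene-order ordinals per scaffold; indices must be contiguous from 0."""
    df = _read_tsv(path, POSITION_COLUMNS)
    df["gene_index"] = df["gene_index"].astype(int)
    for (genome, scaffold), grp in df.groupby(["genome_id", "scaffold_id"], sort=False):
        idx = sorted(grp["gene_index"])
        if idx != list(range(len(idx))):
            raise FormatError(
                f"{path}: gene_index not contiguous from 0 on "
                f"{genome}/{scaffold} (got {idx[:5]}...)"
            )
    return df


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ANNOTATION_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def positions_from_best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Convert tabular best-hit locations (query, genome, scaffold, start)
    to gene-order ordinals by sorting each scaffold on start coordinate."""
    required = ["gene_id", "genome_id", "scaffold_id", "start"]
    missing = [c for c in required if c not in hits.columns]
    if missing:
        raise FormatError(f"best-hit table missing column(s) {missing}")
    out = []
    for (genome, scaffold), grp in hits.groupby(["genome_id", "scaffold_id"], sort=True):
        ranked = grp.sort_values(["start", "gene_id"], kind="mergesort").reset_index(drop=True)
        for i, row in ranked.iterrows():
            out.append((row["gene_id"], genome, scaffold, i))
    return pd.DataFrame(out, columns=POSITION_COLUMNS)
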