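"""Term enrichment among duplication-derived genes.

Classic term-by-term one-sided Fisher exact tests (hypergeometric tail)
of a foreground gene set against a background, with Benjamini-Hochberg
FDR correction.  No ontology-graph decorrelation is attempted: each term
is tested independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentRow:
    term_id: str
    annotated: int     # background genes carrying the term
    significant: int   # foreground genes carrying the term
    expected: float    # foreground_size * annotated / background_size
    p_value: float
    fdr: float


def fisher_p(significant: int, foreground: int, annotated: int, background: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table
    [significant, fg - significant; annotated - significant,
    bg - fg - annotated + significant]: the upper hypergeometric tail
    P(X >= significant) with X ~ Hypergeom(bg, annotated, fg)."""
    return float(stats.hypergeom.sf(significant - 1, background, annotated, foreground))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1; input
    order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    annotation: pd.DataFrame,
    foreground: set[str] | list[str],
    background: set[str] | list[str],
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment of ``foreground`` within ``background``.

    ``annotation`` holds (gene_id, term_id) rows; genes outside the
    background are ignored.  Returns rows sorted by p value with columns
    term_id, annotated, significant, expected, p_value, fdr.
    """
    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground gene(s) absent from background: {sorted(stray)[:5]}")
    ann = annotation[annotation["gene_id"].isin(bg)]
    rows = []
    for term, grp in ann.groupby("term_id", sort=True):
        genes = set(grp["gene_id"])
        annotated = len(genes)
        significant = len(genes & fg)
        expected = len(fg) * annotated / len(bg)
        if two_sided:
            table = [
                [significant, len(fg) - significant],
                [annotated - significant, len(bg) - len(fg) - annotated + significant],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = fisher_p(significant, len(fg), annotated, len(bg))
        rows.append((term, annotated, significant, expected, p))
    df = pd.DataFrame(
        rows, columns=["term_id", "annotated", "significant", "expected", "p_value"]
    )
    df["fdr"] = bh_fdr(df["p_value"]) if len(df) else []
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df
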