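"""4dTv: transversion divergence at fourfold-degenerate codon positions.

For a pair of aligned coding sequences the 4dTv distance is the number of
third-position transversions divided by the number of fourfold-degenerate
sites, with the saturation correction -ln(1 - 2d)/2 (undefined at d >= 0.5,
where transversions have reached their equilibrium share of one half).

A site qualifies only when both codons are gap-free, unambiguous, belong
to a fourfold-degenerate codon family, and share the same first two
positions — so any third-position change is guaranteed synonymous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from duplidate.alignprep import Alignment

#: Prefixes of the eight fourfold-degenerate codon families of the standard
#: genetic code: Leu(CTN), Val(GTN), Ser(TCN), Pro(CCN), Thr(ACN), Ala(GCN),
#: Arg(CGN), Gly(GGN).
FOURFOLD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


class PairStatus(str, Enum):
    OK = "OK"
    SATURATED = "SATURATED"          # raw >= 0.5, correction undefined
    UNDEFINED = "UNDEFINED"          # too few qualifying sites


@dataclass(frozen=True)
class ParalogPairDistance:
    gene_a: str
    gene_b: str
    n_4d_sites: int
    n_transversions: int
    raw_4dtv: float | None
    corrected_4dtv: float | None
    status: PairStatus


def is_transversion(base_a: str, base_b: str) -> bool:
    """True iff one base is a purine (A, G) and the other a pyrimidine (C, T)."""
    return (base_a in _PURINES and base_b in _PYRIMIDINES) or (
        base_a in _PYRIMIDINES and base_b in _PURINES
    )


def is_fourfold_site(codon_a: str, codon_b: str) -> bool:
    """True iff the aligned codon pair is a usable fourfold-degenerate site.

    Requires both codons gap-free and unambiguous, both prefixes in a
    fourfold-degenerate family, and identical prefixes across the pair.
    """
    if len(codon_a) != 3 or len(codon_b) != 3:
        return False
    if not (_BASES.issuperset(codon_a) and _BASES.issuperset(codon_b)):
        return False
    prefix = codon_a[:2]
    return prefix == codon_b[:2] and prefix in FOURFOLD_PREFIXES


def corrected_distance(raw: float) -> float:
    """Saturation correction -ln(1 - 2d)/2; caller guarantees d < 0.5."""
    return -math.log(1.0 - 2.0 * raw) / 2.0


def four_dtv(
    gene_a: str,
    row_a: str,
    gene_b: str,
    row_b: str,
    min_sites: int = 10,
) -> ParalogPairDistance:
    """4dTv for one pair of equal-length aligned codon rows.

    Fewer than ``min_sites`` qualifying sites -> UNDEFINED; raw >= 0.5 ->
    SATURATED (raw reported, corrected None).
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"{gene_a}/{gene_b}: aligned rows differ in length")
    if len(row_a) % 3:
        raise ValueError(f"{gene_a}/{gene_b}: row length not a multiple of 3")
    sites = 0
    tv = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i:i + 3], row_b[i:i + 3]
        if is_fourfold_site(ca, cb):
            sites += 1
            if is_transversion(ca[2], cb[2]):
                tv += 1
    if sites < max(1, min_sites):
        return ParalogPairDistance(gene_a, gene_b, sites, tv, None, None, PairStatus.UNDEFINED)
    raw = tv / sites
    if raw >= 0.5:
        return ParalogPairDistance(gene_a, gene_b, sites, tv, raw, None, PairStatus.SATURATED)
    return ParalogPairDistance(
        gene_a, gene_b, sites, tv, raw, corrected_distance(raw), PairStatus.OK
    )


def family_pairwise_4dtv(
    alignment: Alignment,
    pair_list: list[tuple[str, str]],
    min_sites: int = 10,
) -> list[ParalogPairDistance]:
    """4dTv for each requested pair of alignment rows, in sorted-id order."""
    rows = dict(alignment.rows)
    out = []
    for a, b in pair_list:
        for g in (a, b):
            if g not in rows:
                raise KeyError(f"{alignment.family_id}: pair references absent gene {g!r}")
        a, b = sorted((a, b))
        out.append(four_dtv(a, rows[a], b, rows[b], min_sites=min_sites))
    out.sort(key=lambda d: (d.gene_a, d.gene_b))
    return out


def qualifying_site_count(row_a: str, row_b: str) -> int:
    """Number of fourfold-degenerate sites shared by two aligned rows."""
    return sum(
        is_fourfold_site(row_a[i:i + 3], row_b[i:i + 3])
        for i in range(0, min(len(row_a), len(row_b)), 3)
    )
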