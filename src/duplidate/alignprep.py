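"""Transcript filtering, isoform clustering and codon-alignment building.

Transcripts are filtered on low complexity (DUST), length and expression;
isoforms are merged by transitive closure of pairwise overlap matches; and
codon alignments are produced by back-translating a protein alignment with
its CDS sequences, requiring exact translation agreement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from duplidate.config import PipelineConfig

_DUST_STEP = 32


@dataclass
class TranscriptRecord:
    id: str
    sequence: str
    tpm: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """A family alignment: rows of (gene_id, aligned string), equal length.

    Used for both protein alignments (residues + '-') and codon alignments
    (nucleotides, gaps as '---' per codon column).
    """

    family_id: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"{self.family_id}: unequal row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, gene_id: str) -> str:
        for gid, seq in self.rows:
            if gid == gene_id:
                return seq
        raise KeyError(gene_id)

    def ids(self) -> list[str]:
        return [gid for gid, _ in self.rows]


class TranslationMismatch(ValueError):
    """CDS does not translate to the protein row it is claimed to encode."""


def dust_score(sequence: str, window: int = 64) -> float:
    """Low-complexity score: maximum over sliding windows (step 32) of
    sum_t c_t(c_t-1)/2 / (k-1), where c_t counts overlapping triplets of
    type t in the window and k is the number of triplets.

    A homopolymer window of 64 bases scores 62*61/2 / 61 = 31.0; a window
    whose triplets are all distinct scores 0.  Sequences shorter than 4
    bases score 0 by convention.
    """
    seq = sequence.upper()
    if len(seq) < 4:
        return 0.0
    if window < 4:
        raise ValueError("DUST window must be >= 4")
    best = 0.0
    starts = range(0, max(1, len(seq) - 3), _DUST_STEP)
    for start in starts:
        chunk = seq[start:start + window]
        k = len(chunk) - 2
        if k < 2:
            continue
        counts = Counter(chunk[i:i + 3] for i in range(k))
        score = sum(c * (c - 1) // 2 for c in counts.values()) / (k - 1)
        best = max(best, score)
    return best


def filter_transcripts(
    records: list[TranscriptRecord], config: PipelineConfig
) -> tuple[list[TranscriptRecord], list[tuple[str, str]]]:
    """Keep transcripts with length >= min_transcript_len, TPM >= min_tpm
    and DUST score <= dust_threshold.

    Returns (retained, rejections); each rejection is (id, first failing
    rule) with rules checked in order: length, expression, complexity.
    """
    kept: list[TranscriptRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        if rec.length < config.min_transcript_len:
            rejected.append((rec.id, "length"))
        elif rec.tpm < config.min_tpm:
            rejected.append((rec.id, "expression"))
        elif dust_score(rec.sequence, config.dust_window) > config.dust_threshold:
            rejected.append((rec.id, "complexity"))
        else:
            kept.append(rec)
    return kept, rejected


def cluster_isoforms(
    records: list[TranscriptRecord],
    matches: list[tuple[str, str, int, float]],
    config: PipelineConfig,
) -> list[tuple[str, list[str]]]:
    """Merge transcripts into genes by transitive closure of matches with
    overlap >= isoform_min_overlap and identity >= isoform_min_identity.

    Returns a sorted list of (representative, member ids); the
    representative is the most expressed transcript, ties broken by
    lexicographically smallest id.  The clusters partition the input.
    """
    ids = {r.id for r in records}
    parent: dict[str, str] = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, overlap, identity in matches:
        for t in (a, b):
            if t not in ids:
                raise KeyError(f"match references unknown transcript id {t!r}")
        if overlap >= config.isoform_min_overlap and identity >= config.isoform_min_identity:
            ra, rb = find(a), find(b)
            if ra != rb:
                # deterministic union: smaller id becomes the root
                lo, hi = sorted((ra, rb))
                parent[hi] = lo

    tpm = {r.id: r.tpm for r in records}
    clusters: dict[str, list[str]] = {}
    for i in sorted(ids):
        clusters.setdefault(find(i), []).append(i)
    out = []
    for members in clusters.values():
        rep = min(members, key=lambda i: (-tpm[i], i))
        out.append((rep, sorted(members)))
    out.sort(key=lambda c: c[0])
    return out


def gap_fraction(row: str) -> float:
    return row.count("-") / len(row) if row else 0.0


def filter_family_alignment(
    alignment: Alignment,
    cds: dict[str, str],
    config: PipelineConfig,
) -> tuple[Alignment | None, list[tuple[str, str]]]:
    """Drop alignment rows that look like assembly artefacts.

    A row is removed when its ungapped protein is longer than
    max_protein_len residues, its CDS has DUST score above dust_threshold,
    or it has more than max_gap_frac gaps (evaluated on the input
    alignment, single pass).  All-gap columns are dropped afterwards.
    Returns (filtered alignment or None if < 2 rows remain, removals as
    (gene_id, reason)).
    """
    removals: list[tuple[str, str]] = []
    survivors: list[tuple[str, str]] = []
    for gid, row in alignment.rows:
        ungapped = row.replace("-", "")
        if len(ungapped) > config.max_protein_len:
            removals.append((gid, "protein_length"))
        elif gid in cds and dust_score(cds[gid], config.dust_window) > config.dust_threshold:
            removals.append((gid, "complexity"))
        elif gap_fraction(row) > config.max_gap_frac:
            removals.append((gid, "gaps"))
        else:
            survivors.append((gid, row))
    if len(survivors) < 2:
        return None, removals
    keep_cols = [
        i for i in range(len(survivors[0][1]))
        if any(row[i] != "-" for _, row in survivors)
    ]
    squeezed = [(gid, "".join(row[i] for i in keep_cols)) for gid, row in survivors]
    return Alignment(alignment.family_id, squeezed), removals


def backtranslate_alignment(protein_alignment: Alignment, cds: dict[str, str]) -> Alignment:
    """Build an in-frame codon alignment from a protein alignment and the
    ungapped CDS of each row.

    Protein gap columns become '---'; residue columns take the next CDS
    codon.  Each CDS must translate exactly to the ungapped protein row
    under the standard genetic code (one trailing stop codon tolerated);
    any disagreement raises :class:`TranslationMismatch` naming the gene,
    residue position and the expected/observed residues.
    """
    codon_rows: list[tuple[str, str]] = []
    for gid, prot_row in protein_alignment.rows:
        residues = prot_row.replace("-", "")
        seq = cds[gid].upper()
        if len(seq) == 3 * len(residues) + 3 and str(Seq(seq[-3:]).translate()) == "*":
            seq = seq[:-3]
        if len(seq) != 3 * len(residues):
            raise TranslationMismatch(
                f"{gid}: CDS length {len(seq)} does not encode {len(residues)} residues"
            )
        translated = str(Seq(seq).translate())
        for pos, (exp, obs) in enumerate(zip(residues, translated), start=1):
            if exp != obs and exp != "X":
                raise TranslationMismatch(
                    f"{gid}: residue {pos} expected {exp!r}, CDS encodes {obs!r}"
                )
        codons = iter(seq[i:i + 3] for i in range(0, len(seq), 3))
        codon_rows.append(
            (gid, "".join("---" if aa == "-" else next(codons) for aa in prot_row))
        )
    return Alignment(protein_alignment.family_id, codon_rows)
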