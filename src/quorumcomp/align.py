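"""Pairwise alignment helpers shared by the screening modules.

Nucleotide comparisons use global alignment with affine gap penalties; indels
are post-processed so every gap sits at its leftmost equivalent placement
(standard normalisation, which makes homopolymer indels reproducible).
Protein identity is matches / alignment length (gap columns included) under
global alignment with BLOSUM62 scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import Align
from Bio.Align import substitution_matrices


def _nt_aligner(mode: str = "global") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = 1.0
    a.mismatch_score = -2.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -0.2
    return a


def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


@dataclass(frozen=True)
class IndelBlock:
    """One gap run. kind 'ins' = extra query sequence (gap in the reference),
    'del' = missing query sequence. Positions are 0-based offsets into the
    ungapped sequences at which the block starts."""

    kind: str
    ref_pos: int
    qry_pos: int
    length: int


def align_nt_global(ref: str, qry: str) -> tuple[str, str]:
    """Globally align two nucleotide sequences; returns the gapped rows
    (reference row, query row)."""
    aln = _nt_aligner("global").align(ref, qry)[0]
    return str(aln[0]), str(aln[1])


def indel_blocks(ref_row: str, qry_row: str) -> list[IndelBlock]:
    blocks: list[IndelBlock] = []
    rpos = qpos = 0
    i, n = 0, len(ref_row)
    while i < n:
        if ref_row[i] == "-":
            j = i
            while j < n and ref_row[j] == "-":
                j += 1
            blocks.append(IndelBlock("ins", rpos, qpos, j - i))
            qpos += j - i
            i = j
        elif qry_row[i] == "-":
            j = i
            while j < n and qry_row[j] == "-":
                j += 1
            blocks.append(IndelBlock("del", rpos, qpos, j - i))
            rpos += j - i
            i = j
        else:
            rpos += 1
            qpos += 1
            i += 1
    return blocks


def left_normalise(ref: str, qry: str,
                   blocks: list[IndelBlock]) -> list[IndelBlock]:
    """Shift each gap run to its leftmost score-equivalent position.

    An insertion can move one step left when the query base entering the run
    from the left equals the base leaving it on the right (classic homopolymer
    / tandem-repeat ambiguity); deletions analogously on the reference.
    """
    out: list[IndelBlock] = []
    for b in blocks:
        rp, qp, L = b.ref_pos, b.qry_pos, b.length
        if b.kind == "ins":
            while qp > 0 and rp > 0 and qry[qp - 1] == qry[qp + L - 1]:
                qp -= 1
                rp -= 1
        else:
            while rp > 0 and qp > 0 and ref[rp - 1] == ref[rp + L - 1]:
                rp -= 1
                qp -= 1
        out.append(replace(b, ref_pos=rp, qry_pos=qp))
    return out


def nt_alignment(ref: str, qry: str) -> tuple[float, list[IndelBlock]]:
    """Percent identity plus left-normalised indel blocks for two CDSs."""
    r, q = align_nt_global(ref, qry)
    ident = nt_identity(r, q)
    return ident, left_normalise(ref, qry, indel_blocks(r, q))


def nt_identity(ref_row: str, qry_row: str) -> float:
    """Percent identity over the alignment, gap columns included."""
    matches = sum(1 for a, b in zip(ref_row, qry_row) if a == b and a != "-")
    return 100.0 * matches / len(ref_row) if ref_row else 0.0


def protein_identity(a: str, b: str) -> float:
    """Percent identity (matches / alignment length incl. gap columns) under
    global BLOSUM62 alignment."""
    if not a or not b:
        return 0.0
    aln = _aa_aligner().align(a, b)[0]
    r, q = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(r, q) if x == y and x != "-")
    return 100.0 * matches / len(r)


def protein_align_rows(ref: str, qry: str) -> tuple[str, str]:
    aln = _aa_aligner().align(ref, qry)[0]
    return str(aln[0]), str(aln[1])


def local_align_nt(ref: str, qry: str):
    """Best local nucleotide alignment (Biopython Alignment object), or None
    when nothing aligns."""
    res = _nt_aligner("local").align(ref, qry)
    try:
        return res[0]
    except IndexError:
        return None
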