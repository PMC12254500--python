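"""Alignment masking by gap fraction and pairwise global identity.

``mask_alignment`` reproduces the trimming rule used before tree inference:
every alignment column in which 10% or more of the sequences have a gap is
removed (the boundary is inclusive removal, per the rule's wording).

``pairwise_identity`` computes percent amino acid identity from a global
affine-gap alignment (Needleman–Wunsch).  Because identity depends on the
denominator convention, it is selectable: full alignment length including
gapped columns (EMBOSS-needle style, the default), the shorter sequence, or
only the gap-free aligned columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

GAP_CHARS = ("-", ".")

__all__ = ["IdentityResult", "mask_alignment", "pairwise_identity"]


@dataclass(frozen=True)
class IdentityResult:
    percent_identity: float
    n_identical: int
    denominator: int
    alignment_length: int


def mask_alignment(
    records: list[tuple[str, str]], max_gap_fraction: float = 0.10
) -> tuple[list[tuple[str, str]], list[int]]:
    """Remove columns whose gap fraction is >= ``max_gap_fraction``.

    ``records`` are (label, aligned sequence) pairs of equal length.  Returns
    the masked records (row order preserved) and the kept 0-based column
    indices.  A column is kept iff gap_count / n_rows < max_gap_fraction.
    """
    if not records:
        raise ValueError("alignment is empty")
    n_rows = len(records)
    width = len(records[0][1])
    if any(len(seq) != width for _, seq in records):
        raise ValueError("alignment rows have unequal lengths")
    labels = [label for label, _ in records]
    if len(set(labels)) != n_rows:
        raise ValueError("alignment labels are not unique")

    kept: list[int] = []
    for j in range(width):
        gaps = sum(1 for _, seq in records if seq[j] in GAP_CHARS)
        if gaps / n_rows < max_gap_fraction:
            kept.append(j)
    masked = [(label, "".join(seq[j] for j in kept)) for label, seq in records]
    return masked, kept


def pairwise_identity(
    a: str,
    b: str,
    *,
    matrix: str | None = "BLOSUM62",
    match_score: float = 1.0,
    mismatch_score: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
) -> IdentityResult:
    """Percent identity from a global affine-gap alignment of two proteins.

    With ``matrix=None`` a simple match/mismatch scoring is used instead of a
    substitution matrix.  ``denominator`` is one of ``alignment`` (all
    columns, the default), ``shorter`` (length of the shorter sequence) or
    ``columns`` (gap-free columns only).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if denominator not in ("alignment", "shorter", "columns"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        mat = substitution_matrices.load(matrix)
        alphabet = str(mat.alphabet)
        aligner.substitution_matrix = mat
        a_s = "".join(c if c in alphabet else "X" for c in a.upper())
        b_s = "".join(c if c in alphabet else "X" for c in b.upper())
    else:
        aligner.match_score = match_score
        aligner.mismatch_score = mismatch_score
        a_s, b_s = a.upper(), b.upper()
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a_s, b_s)[0]

    row_a, row_b = str(aln[0]), str(aln[1])
    aln_len = len(row_a)
    n_identical = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x not in GAP_CHARS
    )
    n_columns = sum(
        1 for x, y in zip(row_a, row_b) if x not in GAP_CHARS and y not in GAP_CHARS
    )
    if denominator == "alignment":
        denom = aln_len
    elif denominator == "shorter":
        denom = min(len(a_s), len(b_s))
    else:
        denom = n_columns
    return IdentityResult(
        percent_identity=100.0 * n_identical / denom,
        n_identical=n_identical,
        denominator=denom,
        alignment_length=aln_len,
    )
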