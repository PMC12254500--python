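"""Catalytic-triad scoring and pseudokinase classification.

Protein kinases share three catalytic residues: the β3-strand ATP-binding
lysine (of the VAIK motif), the catalytic aspartate of the HRDxxxN catalytic
loop, and the metal-binding aspartate of the activation-loop DFG motif.  A
protein whose kinase-like domain has lost at least two of the three consensus
residues (K/D/D) is rated a pseudokinase.

The domain model here is a position-specific scoring matrix (PSSM) built from
a seed alignment of kinase domains, with the three triad columns annotated.
Query sequences are aligned to the PSSM by global affine-gap dynamic
programming, the residues at the triad columns are read off, and the 2-of-3
mismatch rule is applied.  A gapped triad column counts as a mismatch: an
absent catalytic residue cannot be functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP_CHARS = frozenset("-.")

TRIAD_NAMES = ("beta3_K", "HRD_D", "DFG_D")
TRIAD_CONSENSUS = {"beta3_K": "K", "HRD_D": "D", "DFG_D": "D"}

__all__ = [
    "ProfileModel",
    "TriadCall",
    "build_profile",
    "align_to_profile",
    "call_triad",
    "classify_pseudokinase",
    "classify_sequences",
]


@dataclass
class ProfileModel:
    """Position-specific log-odds model of the kinase domain.

    ``scores`` is an (n_columns, 20) array of log2 odds against ``background``;
    ``triad_columns`` maps the three triad names to 0-based column indices.
    Gap costs are positive: a gap run of length L costs open + (L-1)*extend.
    """

    scores: np.ndarray
    triad_columns: dict[str, int]
    gap_open: float = 4.0
    gap_extend: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    consensus: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be an (n_columns, 20) array")
        cols = [self.triad_columns[name] for name in TRIAD_NAMES]
        if not all(0 <= c < self.n_columns for c in cols):
            raise ValueError("triad columns out of range")
        if not (cols[0] < cols[1] < cols[2]):
            raise ValueError("triad columns must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]


@dataclass
class TriadCall:
    """Observed triad residues for one sequence and the pseudokinase verdict."""

    sequence_id: str
    residues: dict[str, str]  # triad name -> residue or "-"
    matches: dict[str, bool]
    n_mismatches: int
    is_pseudokinase: bool | None = None


def build_profile(
    seed_records: list[tuple[str, str]],
    triad_column_spec: tuple[int, int, int],
    pseudocount: float = 1.0,
    *,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
    max_insert_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a PSSM from an aligned seed, dropping majority-gap insert columns.

    ``seed_records`` are (id, aligned sequence) pairs of equal length;
    ``triad_column_spec`` gives the three triad columns as 0-based indices of
    the *input* alignment, remapped after insert-column removal.  Per-column
    score for residue a: log2(((count_a + pseudocount) / (n + 20*pseudocount))
    / background_a), with n the number of seed rows.
    """
    if not seed_records:
        raise ValueError("seed alignment is empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    rows = [seq.upper() for _, seq in seed_records]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("seed alignment rows have unequal lengths")
    if len(set(triad_column_spec)) != 3:
        raise ValueError("triad_column_spec must name three distinct columns")

    n = len(rows)
    background = np.full(20, 1.0 / 20)
    keep: list[int] = []
    for j in range(width):
        gaps = sum(1 for r in rows if r[j] in GAP_CHARS)
        if gaps / n <= max_insert_gap_fraction:
            keep.append(j)
    keep_index = {j: i for i, j in enumerate(keep)}

    triad_sorted = sorted(triad_column_spec)
    triad_columns: dict[str, int] = {}
    for name, j in zip(TRIAD_NAMES, triad_sorted):
        if j not in keep_index:
            raise ValueError(
                f"triad column {j} was dropped as a majority-gap insert column; "
                "seed alignment unusable"
            )
        triad_columns[name] = keep_index[j]

    scores = np.empty((len(keep), 20))
    consensus = []
    for i, j in enumerate(keep):
        counts = np.zeros(20)
        for r in rows:
            idx = _AA_INDEX.get(r[j])
            if idx is not None:
                counts[idx] += 1
        freqs = (counts + pseudocount) / (n + 20 * pseudocount)
        scores[i] = np.log2(freqs / background)
        consensus.append(AA[int(np.argmax(counts))] if counts.sum() else "X")

    return ProfileModel(
        scores=scores,
        triad_columns=triad_columns,
        gap_open=gap_open,
        gap_extend=gap_extend,
        background=background,
        consensus="".join(consensus),
    )


_NEG = -1e30


def align_to_profile(
    seq: str, profile: ProfileModel, *, return_score: bool = False
) -> list[int | None] | tuple[list[int | None], float]:
    """Globally align a sequence to the profile columns.

    Returns, for each profile column, the 0-based query residue index matched
    to it, or ``None`` for a deletion (column unmatched).  Mapped indices are
    strictly increasing.  Terminal gaps are penalized like internal ones.
    """
    if not seq:
        raise ValueError("sequence is empty")
    seq = seq.upper()
    n = len(seq)
    m = profile.n_columns
    open_, ext = profile.gap_open, profile.gap_extend
    # residue score lookup per position (unknown residues get the worst
    # column score, i.e. behave like a plain mismatch)
    res_idx = np.array([_AA_INDEX.get(c, -1) for c in seq])
    col_scores = np.empty((m, n))
    for j in range(m):
        row = profile.scores[j]
        worst = row.min()
        col_scores[j] = np.where(res_idx >= 0, row[np.clip(res_idx, 0, 19)], worst)

    # DP over (column j in 0..m, residues consumed i in 0..n); states coded
    # 0=M (column j matched to residue i), 1=I (residue i inserted after
    # column j), 2=D (column j deleted).
    M = np.full((m + 1, n + 1), _NEG)
    I = np.full((m + 1, n + 1), _NEG)
    D = np.full((m + 1, n + 1), _NEG)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrI = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrD = np.zeros((m + 1, n + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    idx = np.arange(n)
    # leading insertions: run of i residues before the first column
    I[0, 1:] = -(open_ + idx * ext)
    ptrI[0, 1] = 0
    ptrI[0, 2:] = 1

    for j in range(1, m + 1):
        diag = np.stack((M[j - 1, :-1], I[j - 1, :-1], D[j - 1, :-1]))
        ptrM[j, 1:] = np.argmax(diag, axis=0)
        M[j, 1:] = col_scores[j - 1] + diag.max(axis=0)

        cand_d = np.stack((M[j - 1] - open_, I[j - 1] - open_, D[j - 1] - ext))
        ptrD[j] = np.argmax(cand_d, axis=0)
        D[j] = cand_d.max(axis=0)

        # I[j, i] = max over k <= i-1 of (max(M, D)[j, k] - open - (i-1-k)*ext),
        # computed with a prefix-max; pointers recovered from the recurrence
        # I[j, i] = max(M[j, i-1]-open, I[j, i-1]-ext, D[j, i-1]-open)
        base = np.maximum(M[j, :-1], D[j, :-1])
        running = np.maximum.accumulate(base + idx * ext)
        I[j, 1:] = running - open_ - idx * ext
        cand_i = np.stack((M[j, :-1] - open_, I[j, :-1] - ext, D[j, :-1] - open_))
        ptrI[j, 1:] = np.argmax(cand_i, axis=0)

    # traceback from the best final state
    mapping: list[int | None] = [None] * m
    j, i = m, n
    state = int(np.argmax([M[m, n], I[m, n], D[m, n]]))
    while j > 0 or i > 0:
        if state == 0:
            mapping[j - 1] = i - 1
            state = int(ptrM[j, i])
            j, i = j - 1, i - 1
        elif state == 1:
            state = int(ptrI[j, i])
            i -= 1
        else:
            state = int(ptrD[j, i])
            j -= 1
    if return_score:
        return mapping, float(max(M[m, n], I[m, n], D[m, n]))
    return mapping


def call_triad(
    mapping: list[int | None], seq: str, profile: ProfileModel, sequence_id: str = ""
) -> TriadCall:
    """Read the triad residues from an alignment mapping and score matches.

    A match requires the consensus residue exactly (K for β3, D for HRD, D for
    DFG); a gap or any other residue is a mismatch.
    """
    seq = seq.upper()
    residues: dict[str, str] = {}
    matches: dict[str, bool] = {}
    for name in TRIAD_NAMES:
        col = profile.triad_columns[name]
        idx = mapping[col]
        residue = "-" if idx is None else seq[idx]
        residues[name] = residue
        matches[name] = residue == TRIAD_CONSENSUS[name]
    n_mismatches = sum(not v for v in matches.values())
    return TriadCall(
        sequence_id=sequence_id,
        residues=residues,
        matches=matches,
        n_mismatches=n_mismatches,
    )


def classify_pseudokinase(call: TriadCall) -> TriadCall:
    """Apply the 2-of-3 rule: pseudokinase iff at least two triad mismatches."""
    call.is_pseudokinase = call.n_mismatches >= 2
    return call


def classify_sequences(
    records: list[tuple[str, str]], profile: ProfileModel
) -> list[TriadCall]:
    """Align, read and classify each (id, sequence) record against the profile."""
    calls = []
    for seq_id, seq in records:
        mapping = align_to_profile(seq, profile)
        calls.append(classify_pseudokinase(call_triad(mapping, seq, profile, seq_id)))
    return calls
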