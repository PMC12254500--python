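"""Homolog acceptance filtering for the NRBP reciprocal-search pipeline.

The NRBP1/NRBP2 ortholog set is assembled by a chain of four rules applied to
pairwise protein-search results:

1. an E-value cutoff on the forward search (default ``1e-28``, inclusive),
2. a reciprocal top-hit rule — the candidate's best reverse hit against the
   human proteome must be one of the accepted references (NRBP1 or NRBP2),
3. reference coverage — the union of aligned reference residues must cover at
   least 80% of the reference, and
4. folded-region representation — at most ``tolerance`` residues of the
   reference's predicted folded region may be left uncovered (default 40).

Hit tables are the standard 12-column tabular format (``qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore``).  All
coordinates are 1-based inclusive; interval arithmetic internally converts to
half-open ``[start, end)`` ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "HitRecord",
    "FilterConfig",
    "ScoringConfig",
    "parse_hit_table",
    "format_hit_table",
    "apply_evalue_cutoff",
    "reciprocal_filter",
    "coverage_filter",
    "folded_region_filter",
    "local_search",
    "filter_candidates",
]

HIT_COLUMNS = (
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bit_score",
)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise local-alignment hit (one line of a 12-column hit table)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end in hit {self.query_id}/{self.subject_id}")
        if self.s_start > self.s_end:
            raise ValueError(f"s_start > s_end in hit {self.query_id}/{self.subject_id}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value in hit {self.query_id}/{self.subject_id}")

    def to_line(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.percent_identity:.2f}",
                str(self.alignment_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.evalue:.2e}",
                f"{self.bit_score:.1f}",
            ]
        )


@dataclass
class FilterConfig:
    """Thresholds of the four-rule acceptance chain.

    ``coverage_relative_to`` selects whether coverage (and the folded region)
    is measured on the reference ("subject") or on the candidate ("query")
    side of the forward hits; the reference-side reading is the default.
    """

    evalue_cutoff: float = 1e-28
    min_reference_coverage: float = 0.80
    folded_region: tuple[int, int] | None = None  # 1-based inclusive on the reference
    folded_tolerance: int = 40
    accepted_reference_ids: frozenset[str] = field(default_factory=frozenset)
    coverage_relative_to: str = "subject"
    pool_hsps: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_reference_coverage <= 1):
            raise ValueError("min_reference_coverage must be in (0, 1]")
        if self.folded_tolerance < 0:
            raise ValueError("folded_tolerance must be >= 0")
        if self.coverage_relative_to not in ("subject", "query"):
            raise ValueError("coverage_relative_to must be 'subject' or 'query'")
        self.accepted_reference_ids = frozenset(self.accepted_reference_ids)


def parse_hit_table(lines: Iterable[str]) -> list[HitRecord]:
    """Parse 12-column tabular hit lines into :class:`HitRecord` objects.

    Comment lines (``#``) and blank lines are skipped; order is preserved.
    Raises ``ValueError`` naming the 1-based line number on a malformed line.
    """
    hits: list[HitRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def format_hit_table(hits: Iterable[HitRecord]) -> str:
    """Serialize hits back to 12-column tabular text (one line per hit)."""
    return "".join(hit.to_line() + "\n" for hit in hits)


def apply_evalue_cutoff(hits: Sequence[HitRecord], cutoff: float) -> list[HitRecord]:
    """Keep hits with ``evalue <= cutoff`` (inclusive boundary), order preserved."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return [h for h in hits if h.evalue <= cutoff]


def reciprocal_filter(
    candidates: Iterable[str],
    reverse_hits: Sequence[HitRecord],
    accepted_reference_ids: Iterable[str],
) -> set[str]:
    """Reciprocal top-hit acceptance.

    A candidate is accepted iff its maximal-bit-score reverse hit's subject is
    one of the accepted references; ties at the top bit score accept if *any*
    tied subject is an accepted reference.  Candidates without reverse hits
    are rejected.
    """
    accepted_refs = set(accepted_reference_ids)
    by_query: dict[str, list[HitRecord]] = {}
    for hit in reverse_hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    accepted: set[str] = set()
    for cand in candidates:
        hits = by_query.get(cand)
        if not hits:
            continue
        top = max(h.bit_score for h in hits)
        top_subjects = {h.subject_id for h in hits if h.bit_score == top}
        if top_subjects & accepted_refs:
            accepted.add(cand)
    return accepted


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of a union of half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    total += cur_end - cur_start
    return total


def _spans(hits: Sequence[HitRecord], side: str) -> list[tuple[int, int]]:
    # 1-based inclusive -> half-open
    if side == "subject":
        return [(h.s_start, h.s_end + 1) for h in hits]
    return [(h.q_start, h.q_end + 1) for h in hits]


def _grouped(hits: Sequence[HitRecord]) -> dict[tuple[str, str], list[HitRecord]]:
    groups: dict[tuple[str, str], list[HitRecord]] = {}
    for hit in hits:
        groups.setdefault((hit.query_id, hit.subject_id), []).append(hit)
    return groups


def coverage_filter(
    hits: Sequence[HitRecord],
    reference_lengths: dict[str, int],
    min_fraction: float,
    *,
    relative_to: str = "subject",
    pool_hsps: bool = True,
) -> list[HitRecord]:
    """Keep hits whose pooled aligned span covers >= ``min_fraction`` of the reference.

    Multiple hits of the same query–subject pair pool their spans (union of
    covered reference residues) when ``pool_hsps`` is true.  The boundary is
    inclusive: exactly ``min_fraction`` coverage passes.
    """
    groups = _grouped(hits)
    passing: list[HitRecord] = []
    for hit in hits:
        ref_id = hit.subject_id if relative_to == "subject" else hit.query_id
        if ref_id not in reference_lengths:
            raise KeyError(f"no length known for reference {ref_id!r}")
        ref_len = reference_lengths[ref_id]
        pool = groups[(hit.query_id, hit.subject_id)] if pool_hsps else [hit]
        covered = _union_length(_spans(pool, relative_to))
        if covered / ref_len >= min_fraction:
            passing.append(hit)
    return passing


def folded_region_filter(
    hits: Sequence[HitRecord],
    folded_region: tuple[int, int],
    tolerance: int,
    *,
    reference_lengths: dict[str, int] | None = None,
    relative_to: str = "subject",
    pool_hsps: bool = True,
) -> list[HitRecord]:
    """Keep hits leaving at most ``tolerance`` folded-region residues uncovered.

    ``folded_region`` is a 1-based inclusive interval on the reference.  The
    tolerance is a total uncovered-residue budget over the whole region, not a
    per-terminus allowance.
    """
    lo, hi = folded_region
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid folded region {folded_region}")
    if reference_lengths is not None:
        for length in reference_lengths.values():
            if hi > length:
                raise ValueError(
                    f"folded region {folded_region} extends past reference length {length}"
                )
    region_len = hi - lo + 1
    groups = _grouped(hits)
    passing: list[HitRecord] = []
    for hit in hits:
        pool = groups[(hit.query_id, hit.subject_id)] if pool_hsps else [hit]
        clipped = [
            (max(start, lo), min(end, hi + 1))
            for start, end in _spans(pool, relative_to)
        ]
        covered = _union_length([(s, e) for s, e in clipped if s < e])
        if region_len - covered <= tolerance:
            passing.append(hit)
    return passing


# ---------------------------------------------------------------------------
# Desk-scale local search
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ScoringConfig:
    """Scoring for :func:`local_search`.

    Karlin–Altschul parameters ``lambda_`` and ``k`` are fixed constants (the
    customary gapped BLOSUM62/11,1 values); they give search-tool-like bit
    scores and E-values without any score-statistics estimation, which is all
    the desk-scale ranking needs.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k: float = 0.041
    evalue_ceiling: float = 10.0


def _sanitize(seq: str, alphabet: str) -> str:
    # residues outside the matrix alphabet are scored like an ambiguous X
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def local_search(
    query: str, subject: str, scoring: ScoringConfig | None = None,
    *, query_id: str = "query", subject_id: str = "subject",
) -> HitRecord | None:
    """Best local alignment of two protein sequences as a :class:`HitRecord`.

    Affine-gap Smith–Waterman via ``Bio.Align.PairwiseAligner``; the raw score
    S is converted to a bit score S' = (λS − ln K)/ln 2 and an expect value
    E = m·n·2^(−S').  Returns ``None`` when E exceeds the configured ceiling.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringConfig()
    matrix = substitution_matrices.load(scoring.matrix)
    alphabet = str(matrix.alphabet)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    q = _sanitize(query, alphabet)
    s = _sanitize(subject, alphabet)
    alignments = aligner.align(q, s)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    score = aln.score
    bits = (scoring.lambda_ * score - math.log(scoring.k)) / math.log(2)
    evalue = len(q) * len(s) * 2.0 ** (-bits)
    if evalue > scoring.evalue_ceiling:
        return None

    q_blocks, s_blocks = aln.aligned
    identities = mismatches = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for i in range(qe - qs):
            if q[qs + i] == s[ss + i]:
                identities += 1
            else:
                mismatches += 1
    gap_opens = (len(q_blocks) - 1)
    gap_residues = 0
    for k in range(1, len(q_blocks)):
        gap_residues += (q_blocks[k][0] - q_blocks[k - 1][1]) + (
            s_blocks[k][0] - s_blocks[k - 1][1]
        )
    aln_len = identities + mismatches + gap_residues
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * identities / max(aln_len, 1),
        alignment_length=aln_len,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
        evalue=evalue,
        bit_score=bits,
    )


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def filter_candidates(
    forward_hits: Sequence[HitRecord],
    reverse_hits: Sequence[HitRecord],
    reference_lengths: dict[str, int],
    config: FilterConfig,
) -> tuple[set[str], pd.DataFrame]:
    """Run the full acceptance chain and return (accepted ids, per-candidate report).

    Candidates are the query ids of the forward hits.  A candidate is accepted
    iff it survives all four rules; the report has one row per candidate with
    a boolean column per rule.
    """
    candidates = sorted({h.query_id for h in forward_hits})

    # each rule is evaluated on the full forward table so the report shows
    # per-rule verdicts independently; acceptance is their conjunction, which
    # equals the sequential chain result
    pass_e = {h.query_id for h in apply_evalue_cutoff(forward_hits, config.evalue_cutoff)}

    pass_recip = reciprocal_filter(candidates, reverse_hits, config.accepted_reference_ids)

    pass_cov = {
        h.query_id
        for h in coverage_filter(
            forward_hits, reference_lengths, config.min_reference_coverage,
            relative_to=config.coverage_relative_to, pool_hsps=config.pool_hsps,
        )
    }

    if config.folded_region is not None:
        pass_folded = {
            h.query_id
            for h in folded_region_filter(
                forward_hits, config.folded_region, config.folded_tolerance,
                reference_lengths=reference_lengths,
                relative_to=config.coverage_relative_to, pool_hsps=config.pool_hsps,
            )
        }
    else:
        pass_folded = set(candidates)

    rows = []
    accepted: set[str] = set()
    for cand in candidates:
        ok = (
            cand in pass_e and cand in pass_recip
            and cand in pass_cov and cand in pass_folded
        )
        if ok:
            accepted.add(cand)
        rows.append(
            {
                "candidate": cand,
                "pass_evalue": cand in pass_e,
                "pass_reciprocal": cand in pass_recip,
                "pass_coverage": cand in pass_cov,
                "pass_folded_region": cand in pass_folded,
                "accepted": ok,
            }
        )
    return accepted, pd.DataFrame(rows)
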