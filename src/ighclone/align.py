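"""Shared pairwise-alignment machinery.

One fixed scoring scheme is used throughout: match +1, mismatch −1, gap
open −4, gap extend −1 (a gap of length L costs 4 + (L−1)).  'N' never
scores as a match — it is penalised like a mismatch against every base,
including another N.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0

_ALPHABET = "ACGTN"


def _matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = MATCH if (a == b and a != "N") else MISMATCH
    return m


@lru_cache(maxsize=None)
def get_aligner(mode: str) -> Align.PairwiseAligner:
    """A cached PairwiseAligner in ``local`` or ``global`` mode."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _matrix()
    aligner.mode = mode
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


Blocks = tuple[tuple[tuple[int, int], tuple[int, int]], ...]


@dataclass(frozen=True)
class SegmentAlignment:
    """Result of aligning one germline segment to a query sequence.

    Query/germline spans are 0-based half-open; ``blocks`` pairs up the
    gap-free aligned sub-spans ((q_start, q_end), (g_start, g_end)) and is
    what downstream coordinate mapping and mutation counting walk over.
    """

    gene: str
    score: float
    identity_pct: float
    q_start: int
    q_end: int
    g_start: int
    g_end: int
    n_mismatches: int
    n_insertions: int
    n_deletions: int
    blocks: Blocks = ()

    def __post_init__(self) -> None:
        assert 0 <= self.identity_pct <= 100
        assert self.q_end > self.q_start

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    def map_to_query(self, g_pos: int) -> int | None:
        """Map a germline position onto the query through the alignment.

        Returns ``None`` when the position falls in a deletion or outside
        the aligned germline span.
        """
        for (qs, qe), (gs, ge) in self.blocks:
            if gs <= g_pos < ge:
                return qs + (g_pos - gs)
        return None


def align_segment(
    query: str, germline: str, gene: str, mode: str = "local"
) -> SegmentAlignment | None:
    """Align *germline* to *query* and summarise the best alignment.

    Biopython enumerates co-optimal alignments deterministically; the first
    one is taken.  Returns ``None`` for degenerate (empty) alignments.
    """
    aligner = get_aligner(mode)
    try:
        alignments = aligner.align(query, germline)
    except ValueError:  # e.g. empty input
        return None
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    q_blocks, g_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None

    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    matches = mismatches = insertions = deletions = 0
    prev_qe = prev_ge = None
    for (qs, qe), (gs, ge) in zip(q_blocks, g_blocks):
        qs, qe, gs, ge = int(qs), int(qe), int(gs), int(ge)
        if prev_qe is not None:
            insertions += qs - prev_qe
            deletions += gs - prev_ge
        for qb, gb in zip(query[qs:qe], germline[gs:ge]):
            if qb == gb and qb != "N":
                matches += 1
            else:
                mismatches += 1
        blocks.append(((qs, qe), (gs, ge)))
        prev_qe, prev_ge = qe, ge

    columns = matches + mismatches + insertions + deletions
    identity = 100.0 * matches / columns if columns else 0.0
    return SegmentAlignment(
        gene=gene,
        score=float(aln.score),
        identity_pct=identity,
        q_start=blocks[0][0][0],
        q_end=blocks[-1][0][1],
        g_start=blocks[0][1][0],
        g_end=blocks[-1][1][1],
        n_mismatches=mismatches,
        n_insertions=insertions,
        n_deletions=deletions,
        blocks=tuple(blocks),
    )


def score_only(query: str, germline: str, mode: str = "local") -> float:
    """Alignment score without traceback (cheap pre-screen)."""
    if not query or not germline:
        return float("-inf")
    return float(get_aligner(mode).score(query, germline))
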