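"""Per-cell annotation: V/D/J assignment, junction extraction, productivity.

Each input sequence (an FR1-to-J heavy-chain amplicon) is aligned against
every germline V gene under a fixed BLAST-like local scheme; the J gene is
then sought downstream of the V span, the junction is cut between the
mapped 2nd-CYS and J-TRP/J-PHE anchors, and the D gene is assigned inside
the CDR3 by the longest-exact-run rule (a run of at least ``d_min_run``
consecutive matching bases, 7 by default).

Tie-breaking between equal-scoring germline genes is total-ordered
(higher identity, longer aligned span, lexicographically smaller name) so
annotation is fully deterministic.  Only the plus strand is annotated; an
optional pre-step reverse-complements a record whose best V score on the
reverse complement beats the forward one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq

from .align import SegmentAlignment, align_segment, score_only
from .errors import AssignmentError, JunctionUnresolvedError
from .germline import GermlineGene, GermlineSet
from .policy import ClonePolicy, DEFAULT_POLICY

#: minimum local-alignment scores for an assignment to be accepted
V_MIN_SCORE = 40.0
J_MIN_SCORE = 15.0

#: how far left of the V span end the J search window opens
J_SEARCH_BACKTRACK = 10

#: a junction shorter than this is treated as unresolved
MIN_JUNCTION_LEN = 9

_STOPS = frozenset({"TAA", "TAG", "TGA"})


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class Junction:
    """Junction nucleotides: 2nd-CYS codon through J-TRP/J-PHE codon.

    ``q_start``/``q_end`` locate the junction on the query (half-open);
    ``cdr3_nt`` strips the two anchor codons.
    """

    nt: str
    cdr3_nt: str
    frame_offset: int
    contains_stop: bool
    q_start: int
    q_end: int

    def __post_init__(self) -> None:
        assert len(self.nt) == len(self.cdr3_nt) + 6
        assert self.cdr3_nt in self.nt


@dataclass
class Rearrangement:
    """One cell's annotated heavy-chain rearrangement."""

    cell_id: str
    sequence: str
    sample_id: str = ""
    v: Optional[SegmentAlignment] = None
    j: Optional[SegmentAlignment] = None
    d: Optional[SegmentAlignment] = None
    junction: Optional[Junction] = None
    productive: str = "unresolved"
    mutation: Optional[object] = None  # MutationProfile, filled downstream
    reverse_complemented: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def v_gene_name(self) -> str | None:
        return self.v.gene.split("*", 1)[0] if self.v else None

    @property
    def cdr3_nt(self) -> str | None:
        return self.junction.cdr3_nt if self.junction else None


def _better(a: tuple[SegmentAlignment, str], b: tuple[SegmentAlignment, str]) -> bool:
    """Total order on (alignment, gene name): score, identity, span, name."""
    aa, an = a
    bb, bn = b
    ka = (aa.score, aa.identity_pct, aa.q_span, _neg_name(an))
    kb = (bb.score, bb.identity_pct, bb.q_span, _neg_name(bn))
    return ka > kb


def _neg_name(name: str) -> tuple[int, ...]:
    # lexicographically *smaller* names win: invert for max-comparison
    return tuple(-ord(c) for c in name)


def _best_alignment(
    sequence: str, genes: list[GermlineGene], query_offset: int = 0
) -> SegmentAlignment | None:
    """Best local alignment over *genes* with deterministic tie-breaking."""
    if not genes:
        return None
    genes = sorted(genes, key=lambda g: g.name)
    scores = [score_only(sequence, g.sequence) for g in genes]
    top = max(scores)
    if top == float("-inf"):
        return None
    best: tuple[SegmentAlignment, str] | None = None
    for gene, s in zip(genes, scores):
        if s < top:
            continue
        aln = align_segment(sequence, gene.sequence, gene.name)
        if aln is None:
            continue
        if best is None or _better((aln, gene.name), best):
            best = (aln, gene.name)
    if best is None:
        return None
    aln = best[0]
    if query_offset:
        aln = replace(
            aln,
            q_start=aln.q_start + query_offset,
            q_end=aln.q_end + query_offset,
            blocks=tuple(
                ((qs + query_offset, qe + query_offset), (gs, ge))
                for (qs, qe), (gs, ge) in aln.blocks
            ),
        )
    return aln


def assign_v_gene(
    sequence: str, germlines: GermlineSet, min_score: float = V_MIN_SCORE
) -> SegmentAlignment:
    """Assign the best-scoring germline V gene to *sequence*.

    Raises :class:`AssignmentError` (carrying the best sub-threshold
    candidate) when no V gene reaches *min_score*.
    """
    best = _best_alignment(sequence, germlines.by_class("V"))
    if best is None or best.score < min_score:
        raise AssignmentError("no V assignment", best_candidate=best)
    return best


def v_anchor_on_query(v: SegmentAlignment, germlines: GermlineSet) -> int | None:
    anchor = germlines[v.gene].anchor
    if anchor is None:
        return None
    return v.map_to_query(anchor)


def assign_j_gene(
    sequence: str,
    germlines: GermlineSet,
    v: SegmentAlignment,
    min_score: float = J_MIN_SCORE,
) -> SegmentAlignment:
    """Assign the J gene in the region downstream of the V alignment.

    The search window opens ``J_SEARCH_BACKTRACK`` nt left of the V span
    end; a candidate span starting left of the mapped V 2nd-CYS anchor is
    rejected.
    """
    start = max(0, v.q_end - J_SEARCH_BACKTRACK)
    sub = sequence[start:]
    best = _best_alignment(sub, germlines.by_class("J"), query_offset=start)
    if best is not None:
        va = v_anchor_on_query(v, germlines)
        if va is not None and best.q_start < va:
            best = None
    if best is None or best.score < min_score:
        raise AssignmentError("no J assignment", best_candidate=best)
    return best


def extract_junction(
    sequence: str,
    v: SegmentAlignment,
    j: SegmentAlignment,
    germlines: GermlineSet,
) -> Junction:
    """Cut the junction between the mapped V and J anchor codons.

    Raises :class:`JunctionUnresolvedError` when either anchor cannot be
    mapped through its alignment (trimmed or heavily mutated anchor) or the
    junction is implausibly short.
    """
    v_gene = germlines[v.gene]
    j_gene = germlines[j.gene]
    if v_gene.anchor is None or j_gene.anchor is None:
        raise JunctionUnresolvedError(
            f"missing germline anchor for {v.gene} or {j.gene}"
        )
    va = v.map_to_query(v_gene.anchor)
    ja = j.map_to_query(j_gene.anchor)
    if va is None or ja is None:
        raise JunctionUnresolvedError("anchor outside aligned span")
    end = ja + 3
    if end > len(sequence) or end - va < MIN_JUNCTION_LEN:
        raise JunctionUnresolvedError("junction unresolved")
    nt = sequence[va:end]
    frame_offset = len(nt) % 3
    contains_stop = False
    if frame_offset == 0:
        for i in range(0, len(nt), 3):
            if nt[i : i + 3] in _STOPS:
                contains_stop = True
                break
    return Junction(
        nt=nt,
        cdr3_nt=nt[3:-3],
        frame_offset=frame_offset,
        contains_stop=contains_stop,
        q_start=va,
        q_end=end,
    )


def longest_common_run(a: str, b: str) -> tuple[int, int, int]:
    """Longest exact common substring of *a* and *b*.

    Returns ``(length, a_start, b_start)``; ties resolve to the leftmost
    start in *a*, then in *b*.  'N' never matches.
    """
    best_len, best_i, best_j = 0, 0, 0
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        if ai != "N":
            for jj in range(1, m + 1):
                if ai == b[jj - 1]:
                    run = prev[jj - 1] + 1
                    cur[jj] = run
                    if run > best_len:
                        best_len, best_i, best_j = run, i - run, jj - run
        prev = cur
    return best_len, best_i, best_j


def assign_d_gene(
    cdr3_nt: str, germlines: GermlineSet, policy: ClonePolicy = DEFAULT_POLICY
) -> SegmentAlignment | None:
    """Assign a D gene only if ≥ ``policy.d_min_run`` consecutive bases match.

    The longest exact common substring between the CDR3 and each D germline
    (forward orientation) is found; the gene with the longest run wins, ties
    going to the lexicographically smallest name.  Returning ``None`` ("no
    D assigned") is a legitimate outcome, not an error.
    """
    best: tuple[int, str, int, int] | None = None  # (run, name, q_start, g_start)
    for gene in sorted(germlines.by_class("D"), key=lambda g: g.name):
        run, qi, gi = longest_common_run(cdr3_nt, gene.sequence)
        if best is None or run > best[0]:
            best = (run, gene.name, qi, gi)
    if best is None or best[0] < policy.d_min_run:
        return None
    run, name, qi, gi = best
    return SegmentAlignment(
        gene=name,
        score=float(run),
        identity_pct=100.0,
        q_start=qi,
        q_end=qi + run,
        g_start=gi,
        g_end=gi + run,
        n_mismatches=0,
        n_insertions=0,
        n_deletions=0,
        blocks=(((qi, qi + run), (gi, gi + run)),),
    )


def classify_productivity(r: Rearrangement) -> str:
    """Classify a rearrangement as productive / nonproductive / unresolved.

    Productive requires a resolved in-frame junction with no stop codon and
    no stop codon in the V reading frame (anchored at the mapped 2nd-CYS
    codon) across the aligned query through the junction end.
    """
    if r.v is None or r.junction is None:
        return "unresolved"
    jn = r.junction
    if jn.frame_offset != 0 or jn.contains_stop:
        return "nonproductive"
    # scan the V reading frame from the first in-frame codon in the aligned
    # span up to the junction end
    va = jn.q_start
    start = r.v.q_start + ((va - r.v.q_start) % 3)
    for i in range(start, jn.q_end - 2, 3):
        if r.sequence[i : i + 3] in _STOPS:
            return "nonproductive"
    return "productive"


def orient_sequence(sequence: str, germlines: GermlineSet) -> tuple[str, bool]:
    """Return (sequence, was_reverse_complemented), picking the strand with
    the higher best V score."""
    fwd = max(
        (score_only(sequence, g.sequence) for g in germlines.by_class("V")),
        default=float("-inf"),
    )
    rc = str(Seq(sequence).reverse_complement())
    rev = max(
        (score_only(rc, g.sequence) for g in germlines.by_class("V")),
        default=float("-inf"),
    )
    if rev > fwd:
        return rc, True
    return sequence, False


def annotate_sequence(
    cell_id: str,
    sequence: str,
    germlines: GermlineSet,
    policy: ClonePolicy = DEFAULT_POLICY,
    sample_id: str = "",
    v_min_score: float = V_MIN_SCORE,
    j_min_score: float = J_MIN_SCORE,
    allow_revcomp: bool = True,
) -> Rearrangement:
    """Full annotation of one cell sequence.

    V assignment failure raises :class:`AssignmentError`; downstream
    failures (no J, unresolved junction) degrade gracefully to a partial
    record with ``productive='unresolved'`` and an explanatory note.
    """
    sequence = sequence.upper()
    revcomp = False
    if allow_revcomp:
        sequence, revcomp = orient_sequence(sequence, germlines)
    r = Rearrangement(
        cell_id=cell_id,
        sequence=sequence,
        sample_id=sample_id,
        reverse_complemented=revcomp,
    )
    r.v = assign_v_gene(sequence, germlines, min_score=v_min_score)
    try:
        r.j = assign_j_gene(sequence, germlines, r.v, min_score=j_min_score)
    except AssignmentError as exc:
        r.notes.append(str(exc))
        return r
    try:
        r.junction = extract_junction(sequence, r.v, r.j, germlines)
    except JunctionUnresolvedError as exc:
        r.notes.append(str(exc))
        return r
    r.d = assign_d_gene(r.junction.cdr3_nt, germlines, policy)
    r.productive = classify_productivity(r)
    return r
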