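"""Somatic-mutation profiling of the assigned germline V gene.

Differences are counted over the V-gene portion of the stored V alignment
only — germline positions left of the 2nd-CYS anchor — so the junction and
N-region never inflate the count.  Indels contribute one difference per
inserted or deleted base.  'N' bases in the query are excluded from both
numerator and denominator.  A cell is unmutated when it has at most
``policy.unmutated_max_diff`` differences (default 1, tolerating a single
polymerase error), mutated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import Rearrangement
from .errors import MutationCallError
from .germline import GermlineSet
from .policy import ClonePolicy, DEFAULT_POLICY

#: V alignments covering fewer germline positions than this cannot support
#: a mutation call
MIN_ALIGNED_LEN = 50

#: one entry per differing base: (germline 0-based position, germline base,
#: query base); '-' marks the absent side of an indel
Difference = tuple[int, str, str]


@dataclass(frozen=True)
class MutationProfile:
    n_diff: int
    aligned_len: int
    freq_pct: float
    status: str  # "mutated" | "unmutated"
    positions: tuple[Difference, ...] = ()

    def __post_init__(self) -> None:
        assert self.freq_pct >= 0
        assert self.status in ("mutated", "unmutated")


def classify_mutation_status(
    profile_or_ndiff: MutationProfile | int, policy: ClonePolicy = DEFAULT_POLICY
) -> str:
    """Unmutated iff the difference count is ≤ ``policy.unmutated_max_diff``."""
    n = (
        profile_or_ndiff.n_diff
        if isinstance(profile_or_ndiff, MutationProfile)
        else int(profile_or_ndiff)
    )
    return "unmutated" if n <= policy.unmutated_max_diff else "mutated"


def count_v_mutations(
    r: Rearrangement,
    germlines: GermlineSet,
    policy: ClonePolicy = DEFAULT_POLICY,
    leading_trim: int = 0,
) -> MutationProfile:
    """Count nucleotide differences over the aligned V-gene span.

    *leading_trim* germline positions at the 5' end (e.g. a primer-covered
    FR1 stretch) can be excluded.  Raises :class:`MutationCallError` when
    fewer than ``MIN_ALIGNED_LEN`` germline positions are covered.
    """
    if r.v is None:
        raise MutationCallError(f"{r.cell_id}: no V assignment")
    gene = germlines[r.v.gene]
    g_seq = gene.sequence
    # the V-gene portion ends at the 2nd-CYS anchor; fall back to the full
    # aligned germline span for anchorless references
    g_stop = gene.anchor if gene.anchor is not None else r.v.g_end
    g_lo = leading_trim

    diffs: list[Difference] = []
    aligned_len = 0
    prev_qe: int | None = None
    prev_ge: int | None = None
    seq = r.sequence
    for (qs, qe), (gs, ge) in r.v.blocks:
        if prev_qe is not None:
            # deletion: germline positions skipped between blocks
            for g in range(prev_ge, gs):
                if g_lo <= g < g_stop and g_seq[g] != "N":
                    diffs.append((g, g_seq[g], "-"))
                    aligned_len += 1
            # insertion: query bases between blocks, attributed to the
            # germline position at which they occur
            if g_lo <= gs <= g_stop:
                for q in range(prev_qe, qs):
                    if seq[q] != "N":
                        diffs.append((gs, "-", seq[q]))
        for q, g in zip(range(qs, qe), range(gs, ge)):
            if not (g_lo <= g < g_stop):
                continue
            qb, gb = seq[q], g_seq[g]
            if qb == "N" or gb == "N":
                continue
            aligned_len += 1
            if qb != gb:
                diffs.append((g, gb, qb))
        prev_qe, prev_ge = qe, ge

    if aligned_len < MIN_ALIGNED_LEN:
        raise MutationCallError(
            f"{r.cell_id}: V span too short for mutation call "
            f"({aligned_len} < {MIN_ALIGNED_LEN})"
        )
    n_diff = len(diffs)
    freq = 100.0 * n_diff / aligned_len
    return MutationProfile(
        n_diff=n_diff,
        aligned_len=aligned_len,
        freq_pct=freq,
        status=classify_mutation_status(n_diff, policy),
        positions=tuple(diffs),
    )


def sample_mutation_summary(
    profiles: list[MutationProfile],
) -> tuple[float, float | None]:
    """Per-sample (percent mutated, mean mutation frequency of mutated cells).

    Both are rounded to one decimal; the mean is ``None`` when no cell is
    mutated.
    """
    if not profiles:
        raise ValueError("no mutation profiles")
    mutated = [p for p in profiles if p.status == "mutated"]
    pct = round(100.0 * len(mutated) / len(profiles), 1)
    if not mutated:
        return pct, None
    mean_freq = round(sum(p.freq_pct for p in mutated) / len(mutated), 1)
    return pct, mean_freq
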