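"""Numeric parameters of the clone-calling and mutation-status rules.

All four constants of the published procedure live in one frozen dataclass
so every stage of the pipeline reads them from the same place:

* ``cdr3_max_len_diff_pct`` — two CDR3s may differ in length by at most this
  percentage (of the longer sequence) to be co-clonal; the bound is
  inclusive ("maximal 5%").
* ``cdr3_min_identity_pct`` — pairwise CDR3 nucleotide identity must be
  strictly greater than this to be co-clonal (">90%").
* ``d_min_run`` — an IGHD gene is assigned only if at least this many
  consecutive bases match the germline exactly.
* ``unmutated_max_diff`` — a rearrangement with at most this many nucleotide
  differences to its germline V gene is counted as unmutated (tolerates one
  polymerase error or rare hypermutation-independent event).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ClonePolicy:
    d_min_run: int = 7
    unmutated_max_diff: int = 1
    cdr3_max_len_diff_pct: float = 5.0
    cdr3_min_identity_pct: float = 90.0

    def __post_init__(self) -> None:
        if self.d_min_run < 0:
            raise ValueError("d_min_run must be non-negative")
        if self.unmutated_max_diff < 0:
            raise ValueError("unmutated_max_diff must be non-negative")
        if self.cdr3_max_len_diff_pct < 0:
            raise ValueError("cdr3_max_len_diff_pct must be non-negative")
        if not 0 < self.cdr3_min_identity_pct <= 100:
            raise ValueError("cdr3_min_identity_pct must be in (0, 100]")


DEFAULT_POLICY = ClonePolicy()
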