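"""Clone calling by shared V gene and near-identical CDR3, plus summaries.

A clone is a set of cells using the same (allele-stripped) V gene whose
CDR3s differ in length by at most 5% and are pairwise more than 90%
identical.  "Among all CDRIII sequences" is read as complete linkage:
EVERY pair inside an emitted clone satisfies both thresholds, which
prevents chaining of gradually diverging CDR3s.  Agglomeration is
deterministic — clusters merge best-average-identity first, ties resolved
by input order — so a given input always yields the same partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .align import align_segment
from .annotate import Rearrangement
from .policy import ClonePolicy, DEFAULT_POLICY


def cdr3_identity(a: str, b: str) -> float:
    """Percent identity of two CDR3s under global end-to-end alignment.

    Identity = matching columns / total alignment columns × 100 (gap
    columns count against identity).  The pair is canonically ordered
    before aligning so the measure is exactly symmetric.
    """
    if not a or not b:
        raise ValueError("empty CDR3 sequence")
    if b < a:
        a, b = b, a
    aln = align_segment(a, b, gene="", mode="global")
    if aln is None:
        return 0.0
    return aln.identity_pct


def length_compatible(a: str, b: str, policy: ClonePolicy = DEFAULT_POLICY) -> bool:
    """True iff the CDR3 length difference is within the policy bound.

    The difference is taken relative to the longer sequence; the bound is
    inclusive ("maximal 5%" admits exactly 5.0%).
    """
    la, lb = len(a), len(b)
    if not la or not lb:
        return False
    return 100.0 * abs(la - lb) / max(la, lb) <= policy.cdr3_max_len_diff_pct


def _compatible(a: str, b: str, policy: ClonePolicy) -> bool:
    return (
        length_compatible(a, b, policy)
        and cdr3_identity(a, b) > policy.cdr3_min_identity_pct
    )


@dataclass
class Clone:
    clone_id: str
    members: list[str]  # cell_ids, input order
    v_gene_name: str
    representative_cdr3: str
    clone_status: str = "unmutated"  # mutated iff ≥1 member is mutated
    intraclonal_diversity: bool = False
    n_variants: int = 1
    unclustered: bool = False  # record lacked a resolved CDR3

    @property
    def size(self) -> int:
        return len(self.members)


def call_clones(
    rearrangements: list[Rearrangement],
    policy: ClonePolicy = DEFAULT_POLICY,
    linkage: str = "complete",
) -> list[Clone]:
    """Partition rearrangements into clones by the CDR3 rule.

    ``linkage="complete"`` (default) requires every member pair to satisfy
    the thresholds; ``linkage="single"`` instead takes connected components
    of the pairwise-compatibility graph, which allows chaining.  Records
    without a resolved CDR3 are emitted as singletons flagged
    ``unclustered``.  Output is a partition: every input record appears in
    exactly one clone; clone ids follow first-member input order.
    """
    if linkage not in ("complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    with_cdr3 = [
        (i, r) for i, r in enumerate(rearrangements) if r.cdr3_nt
    ]
    without = [(i, r) for i, r in enumerate(rearrangements) if not r.cdr3_nt]

    # group by allele-stripped V gene: co-clonal cells must share it
    groups: dict[str, list[tuple[int, Rearrangement]]] = {}
    for i, r in with_cdr3:
        groups.setdefault(r.v_gene_name or "", []).append((i, r))

    clusters: list[list[tuple[int, Rearrangement]]] = []
    for gene in groups:
        members = groups[gene]
        n = len(members)
        ident = [[0.0] * n for _ in range(n)]
        compat = [[False] * n for _ in range(n)]
        for x in range(n):
            for y in range(x + 1, n):
                a, b = members[x][1].cdr3_nt, members[y][1].cdr3_nt
                ident[x][y] = ident[y][x] = cdr3_identity(a, b)
                compat[x][y] = compat[y][x] = (
                    length_compatible(a, b, policy)
                    and ident[x][y] > policy.cdr3_min_identity_pct
                )
        cl: list[list[int]] = [[x] for x in range(n)]
        if linkage == "single":
            # connected components of the compatibility graph
            parent = list(range(n))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for x in range(n):
                for y in range(x + 1, n):
                    if compat[x][y]:
                        rx, ry = find(x), find(y)
                        if rx != ry:
                            parent[max(rx, ry)] = min(rx, ry)
            comps: dict[int, list[int]] = {}
            for x in range(n):
                comps.setdefault(find(x), []).append(x)
            clusters.extend(
                [members[x] for x in sorted(group)] for group in comps.values()
            )
            continue
        while True:
            best: tuple[float, int, int] | None = None
            for ai in range(len(cl)):
                for bi in range(ai + 1, len(cl)):
                    pairs = [(x, y) for x in cl[ai] for y in cl[bi]]
                    if all(compat[x][y] for x, y in pairs):
                        mean_id = sum(ident[x][y] for x, y in pairs) / len(pairs)
                        if best is None or mean_id > best[0]:
                            best = (mean_id, ai, bi)
            if best is None:
                break
            _, ai, bi = best
            cl[ai] = sorted(cl[ai] + cl[bi])
            del cl[bi]
        clusters.extend([members[x] for x in group] for group in cl)

    clusters.extend([[pair] for pair in without])
    # deterministic clone ids by first-member input order
    clusters.sort(key=lambda c: min(i for i, _ in c))

    clones: list[Clone] = []
    for k, cluster in enumerate(clusters, 1):
        cluster = sorted(cluster, key=lambda p: p[0])
        recs = [r for _, r in cluster]
        statuses = {
            r.mutation.status for r in recs if r.mutation is not None
        }
        clone = Clone(
            clone_id=f"clone{k}",
            members=[r.cell_id for r in recs],
            v_gene_name=recs[0].v_gene_name or "",
            representative_cdr3=recs[0].cdr3_nt or "",
            clone_status="mutated" if "mutated" in statuses else "unmutated",
            unclustered=recs[0].cdr3_nt is None,
        )
        clones.append(assess_intraclonal_diversity(clone, recs))
    return clones


def assess_intraclonal_diversity(
    clone: Clone, rearrangements: list[Rearrangement]
) -> Clone:
    """Annotate a clone with its number of distinct sequence variants.

    A variant is a distinct (V-mutation-position-set, CDR3) pair; a clone
    shows intraclonal diversity when its members carry more than one
    variant — the footprint of ongoing or divergent hypermutation within
    one lineage.
    """
    by_id = {r.cell_id: r for r in rearrangements}
    variants = set()
    for cell_id in clone.members:
        r = by_id[cell_id]
        positions = (
            frozenset(r.mutation.positions) if r.mutation is not None else frozenset()
        )
        variants.add((positions, r.cdr3_nt))
    n = max(1, len(variants))
    return replace(clone, n_variants=n, intraclonal_diversity=n > 1)


@dataclass
class SampleSummary:
    """One per-sample row: cell counts, mutation load, clone inventory."""

    sample_id: str
    n_cells_with_ighv: int
    pct_mutated: float
    mean_freq_of_mutated: float | None
    clone_inventory: list[tuple[int, str]] = field(default_factory=list)
    n_clones_mutated: int = 0
    n_clones_unmutated: int = 0
    n_clones_with_diversity: int = 0
    v_gene_usage: dict[str, int] = field(default_factory=dict)


def summarize_sample(
    sample_id: str,
    rearrangements: list[Rearrangement],
    clones: list[Clone],
) -> SampleSummary:
    """Build the per-sample summary row from annotated records and clones.

    The clone inventory lists expanded clones only (≥2 members); V-gene
    usage counts productive rearrangements per allele-stripped gene.
    """
    if not rearrangements:
        raise ValueError(f"empty sample {sample_id!r}")
    profiles = [r.mutation for r in rearrangements if r.mutation is not None]
    mutated = [p for p in profiles if p.status == "mutated"]
    pct = round(100.0 * len(mutated) / len(profiles), 1) if profiles else 0.0
    mean_freq = (
        round(sum(p.freq_pct for p in mutated) / len(mutated), 1) if mutated else None
    )
    expanded = [c for c in clones if c.size >= 2]
    inventory = [(c.size, c.clone_status) for c in expanded]
    usage = Counter(
        r.v_gene_name
        for r in rearrangements
        if r.productive == "productive" and r.v_gene_name
    )
    return SampleSummary(
        sample_id=sample_id,
        n_cells_with_ighv=len(rearrangements),
        pct_mutated=pct,
        mean_freq_of_mutated=mean_freq,
        clone_inventory=inventory,
        n_clones_mutated=sum(1 for c in expanded if c.clone_status == "mutated"),
        n_clones_unmutated=sum(1 for c in expanded if c.clone_status == "unmutated"),
        n_clones_with_diversity=sum(1 for c in expanded if c.intraclonal_diversity),
        v_gene_usage=dict(sorted(usage.items())),
    )


def format_inventory(inventory: list[tuple[int, str]], status: str) -> str:
    """Render one status column of the clone inventory, e.g. ``2x 2 cells,1x 3 cells``."""
    sizes = Counter(size for size, st in inventory if st == status)
    if not sizes:
        return "0"
    return ",".join(f"{k}x {n} cells" for n, k in sorted(sizes.items()))
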