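"""End-to-end orchestration: load → annotate → profile → clone → summarize.

The pipeline consumes a FASTA of single-cell heavy-chain amplicons, a
germline V/D/J reference and an optional sample manifest, and produces an
AIRR-style rearrangement TSV, a per-sample summary TSV and a plain-text
summary table.  All outputs are deterministic for identical inputs (no
timestamps inside data files) and carry the germline provenance string and
the full clone policy in a header comment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .annotate import (
    J_MIN_SCORE,
    V_MIN_SCORE,
    Rearrangement,
    annotate_sequence,
)
from .clones import (
    Clone,
    SampleSummary,
    call_clones,
    format_inventory,
    summarize_sample,
)
from .errors import AssignmentError, IghcloneError, MutationCallError
from .germline import GermlineSet, load_germline_fasta, merge_sets
from .mutation import count_v_mutations
from .policy import ClonePolicy, DEFAULT_POLICY

logger = logging.getLogger("ighclone")

REARRANGEMENT_COLUMNS = [
    "sequence_id",
    "sample_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "cdr3",
    "productive",
    "v_identity",
    "v_mutation_count",
    "v_aligned_length",
    "v_mutation_freq_pct",
    "mutation_status",
    "clone_id",
    "clone_size",
    "intraclonal_diversity",
]


@dataclass
class PipelineConfig:
    input_fasta: Path
    germline_v: Path
    germline_d: Path
    germline_j: Path
    out_dir: Path
    manifest: Path | None = None
    policy: ClonePolicy = DEFAULT_POLICY
    v_min_score: float = V_MIN_SCORE
    j_min_score: float = J_MIN_SCORE
    productive_only: bool = True
    leading_trim: int = 0
    allow_revcomp: bool = True
    v_anchors: Path | None = None


@dataclass
class PipelineResult:
    rearrangements: list[Rearrangement]
    clones: dict[str, list[Clone]]
    summaries: list[SampleSummary]
    table: pd.DataFrame
    summary_table: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def read_manifest(path: str | Path) -> dict[str, str]:
    """TSV mapping record ids to sample labels (columns: sequence_id, sample_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise IghcloneError(f"manifest {path} needs ≥ 2 columns")
    return dict(zip(df[cols[0]], df[cols[1]]))


def load_reference(
    v_path: str | Path,
    d_path: str | Path,
    j_path: str | Path,
    v_anchors: str | Path | None = None,
) -> GermlineSet:
    v = load_germline_fasta(v_path, "V", anchors=v_anchors)
    d = load_germline_fasta(d_path, "D")
    j = load_germline_fasta(j_path, "J")
    return merge_sets(v, d, j)


def annotate_records(
    records: Iterable[tuple[str, str]],
    germlines: GermlineSet,
    policy: ClonePolicy = DEFAULT_POLICY,
    manifest: dict[str, str] | None = None,
    v_min_score: float = V_MIN_SCORE,
    j_min_score: float = J_MIN_SCORE,
    leading_trim: int = 0,
    allow_revcomp: bool = True,
) -> list[Rearrangement]:
    """Annotate (id, sequence) pairs and attach mutation profiles.

    Records that fail V assignment or the minimum-span mutation call are
    dropped with a log line naming the record, mirroring how uninformative
    cells attrite from a single-cell screen.
    """
    out: list[Rearrangement] = []
    n_in = n_v = n_cdr3 = 0
    for cell_id, seq in records:
        n_in += 1
        sample_id = (manifest or {}).get(cell_id, "sample1")
        try:
            r = annotate_sequence(
                cell_id,
                seq,
                germlines,
                policy,
                sample_id=sample_id,
                v_min_score=v_min_score,
                j_min_score=j_min_score,
                allow_revcomp=allow_revcomp,
            )
        except AssignmentError as exc:
            logger.info("dropping %s: %s", cell_id, exc)
            continue
        n_v += 1
        if r.junction is not None:
            n_cdr3 += 1
        try:
            r.mutation = count_v_mutations(
                r, germlines, policy, leading_trim=leading_trim
            )
        except MutationCallError as exc:
            logger.info("no mutation call for %s: %s", cell_id, exc)
        out.append(r)
    logger.info(
        "annotation: %d records in, %d V-assigned, %d with resolved CDR3",
        n_in,
        n_v,
        n_cdr3,
    )
    return out


def call_clones_per_sample(
    rearrangements: list[Rearrangement],
    policy: ClonePolicy = DEFAULT_POLICY,
    productive_only: bool = True,
) -> dict[str, list[Clone]]:
    """Clone calling, invoked independently for each sample."""
    by_sample: dict[str, list[Rearrangement]] = {}
    for r in rearrangements:
        by_sample.setdefault(r.sample_id, []).append(r)
    clones: dict[str, list[Clone]] = {}
    for sample_id in by_sample:
        recs = by_sample[sample_id]
        if productive_only:
            recs = [r for r in recs if r.productive == "productive"]
        clones[sample_id] = call_clones(recs, policy)
        logger.info(
            "sample %s: %d records -> %d clones",
            sample_id,
            len(recs),
            len(clones[sample_id]),
        )
    return clones


def rearrangement_table(
    rearrangements: list[Rearrangement], clones: dict[str, list[Clone]]
) -> pd.DataFrame:
    """AIRR-style per-record table, input order preserved."""
    clone_of: dict[tuple[str, str], Clone] = {}
    for sample_id, sample_clones in clones.items():
        for c in sample_clones:
            for cell_id in c.members:
                clone_of[(sample_id, cell_id)] = c
    rows = []
    for r in rearrangements:
        c = clone_of.get((r.sample_id, r.cell_id))
        m = r.mutation
        rows.append(
            {
                "sequence_id": r.cell_id,
                "sample_id": r.sample_id,
                "v_call": r.v.gene if r.v else "",
                "d_call": r.d.gene if r.d else "",
                "j_call": r.j.gene if r.j else "",
                "junction": r.junction.nt if r.junction else "",
                "cdr3": r.cdr3_nt or "",
                "productive": r.productive,
                "v_identity": round(r.v.identity_pct, 2) if r.v else "",
                "v_mutation_count": m.n_diff if m else "",
                "v_aligned_length": m.aligned_len if m else "",
                "v_mutation_freq_pct": round(m.freq_pct, 2) if m else "",
                "mutation_status": m.status if m else "",
                "clone_id": c.clone_id if c else "",
                "clone_size": c.size if c else "",
                "intraclonal_diversity": c.intraclonal_diversity if c else "",
            }
        )
    return pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS)


def summary_table(summaries: list[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "sample_id": s.sample_id,
                "n_cells_with_ighv": s.n_cells_with_ighv,
                "pct_mutated": s.pct_mutated,
                "mean_freq_of_mutated": (
                    "" if s.mean_freq_of_mutated is None else s.mean_freq_of_mutated
                ),
                "unmutated_clones": format_inventory(s.clone_inventory, "unmutated"),
                "mutated_clones": format_inventory(s.clone_inventory, "mutated"),
                "n_clones_with_diversity": s.n_clones_with_diversity,
                "v_gene_usage": ";".join(
                    f"{g}:{n}" for g, n in s.v_gene_usage.items()
                ),
            }
        )
    return pd.DataFrame(rows)


def render_summary_table(summaries: list[SampleSummary]) -> str:
    """Plain-text per-sample table in the style of a published clone inventory."""
    if not summaries:
        raise ValueError("no summaries to render")
    header = [
        "Sample",
        "Cells with IGHV",
        "Mutated (%)",
        "Mean mut. freq. of mutated (%)",
        "Unmutated clones",
        "Mutated clones",
    ]
    rows = [header]
    for s in summaries:
        rows.append(
            [
                s.sample_id,
                str(s.n_cells_with_ighv),
                f"{s.pct_mutated:.1f}",
                "-" if s.mean_freq_of_mutated is None else f"{s.mean_freq_of_mutated:.1f}",
                format_inventory(s.clone_inventory, "unmutated"),
                format_inventory(s.clone_inventory, "mutated"),
            ]
        )
    widths = [max(len(row[i]) for row in rows) for i in range(len(header))]
    lines = []
    for k, row in enumerate(rows):
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip())
        if k == 0:
            lines.append("-" * (sum(widths) + 2 * (len(widths) - 1)))
    return "\n".join(lines) + "\n"


def summaries_from_table(df: pd.DataFrame) -> list[SampleSummary]:
    """Re-derive per-sample summaries from the rearrangement TSV alone."""
    summaries = []
    for sample_id, g in df.groupby("sample_id", sort=False):
        with_status = g[g["mutation_status"].astype(str) != ""]
        mutated = with_status[with_status["mutation_status"] == "mutated"]
        pct = (
            round(100.0 * len(mutated) / len(with_status), 1) if len(with_status) else 0.0
        )
        mean_freq = (
            round(float(mutated["v_mutation_freq_pct"].astype(float).mean()), 1)
            if len(mutated)
            else None
        )
        inventory = []
        n_div = 0
        clonal = g[g["clone_id"].astype(str) != ""]
        for _, cg in clonal.groupby("clone_id", sort=False):
            if len(cg) < 2:
                continue
            status = (
                "mutated" if (cg["mutation_status"] == "mutated").any() else "unmutated"
            )
            inventory.append((len(cg), status))
            if cg["intraclonal_diversity"].astype(str).str.lower().eq("true").any():
                n_div += 1
        productive = g[g["productive"] == "productive"]
        usage = (
            productive["v_call"]
            .map(lambda v: str(v).split("*")[0])
            .value_counts()
            .to_dict()
        )
        summaries.append(
            SampleSummary(
                sample_id=str(sample_id),
                n_cells_with_ighv=len(g),
                pct_mutated=pct,
                mean_freq_of_mutated=mean_freq,
                clone_inventory=inventory,
                n_clones_mutated=sum(1 for _, s in inventory if s == "mutated"),
                n_clones_unmutated=sum(1 for _, s in inventory if s == "unmutated"),
                n_clones_with_diversity=n_div,
                v_gene_usage=dict(sorted(usage.items())),
            )
        )
    return summaries


def _header_comment(germlines: GermlineSet, policy: ClonePolicy) -> str:
    return (
        f"# germline_reference: {germlines.provenance}\n"
        f"# policy: d_min_run={policy.d_min_run} "
        f"unmutated_max_diff={policy.unmutated_max_diff} "
        f"cdr3_max_len_diff_pct={policy.cdr3_max_len_diff_pct} "
        f"cdr3_min_identity_pct={policy.cdr3_min_identity_pct}\n"
    )


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment)
        df.to_csv(fh, sep="\t", index=False)


def analyze(
    records: Iterable[tuple[str, str]],
    germlines: GermlineSet,
    policy: ClonePolicy = DEFAULT_POLICY,
    manifest: dict[str, str] | None = None,
    productive_only: bool = True,
    **annotate_kwargs,
) -> PipelineResult:
    """Library entry point: annotate, profile, clone-call and summarise
    in-memory records."""
    rearrangements = annotate_records(
        records, germlines, policy, manifest=manifest, **annotate_kwargs
    )
    clones = call_clones_per_sample(
        rearrangements, policy, productive_only=productive_only
    )
    summaries = []
    seen: list[str] = []
    for r in rearrangements:
        if r.sample_id not in seen:
            seen.append(r.sample_id)
    for sample_id in seen:
        sample_recs = [r for r in rearrangements if r.sample_id == sample_id]
        summaries.append(
            summarize_sample(sample_id, sample_recs, clones.get(sample_id, []))
        )
    table = rearrangement_table(rearrangements, clones)
    return PipelineResult(
        rearrangements=rearrangements,
        clones=clones,
        summaries=summaries,
        table=table,
        summary_table=summary_table(summaries),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file pipeline run; raises on empty input or missing paths."""
    germlines = load_reference(
        config.germline_v, config.germline_d, config.germline_j, config.v_anchors
    )
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(config.input_fasta), "fasta")
    ]
    if not records:
        raise IghcloneError(f"no input records in {config.input_fasta}")
    manifest = read_manifest(config.manifest) if config.manifest else None
    result = analyze(
        records,
        germlines,
        config.policy,
        manifest=manifest,
        productive_only=config.productive_only,
        v_min_score=config.v_min_score,
        j_min_score=config.j_min_score,
        leading_trim=config.leading_trim,
        allow_revcomp=config.allow_revcomp,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header_comment(germlines, config.policy)
    rearr_path = out / "rearrangements.tsv"
    summary_path = out / "summary.tsv"
    report_path = out / "report.txt"
    write_tsv(result.table, rearr_path, header)
    write_tsv(result.summary_table, summary_path, header)
    report_path.write_text(render_summary_table(result.summaries))
    result.outputs = {
        "rearrangements": rearr_path,
        "summary": summary_path,
        "report": report_path,
    }
    return result
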