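"""Loading and indexing of IMGT-style germline IGHV/IGHD/IGHJ references.

Accepts both IMGT-gapped FASTA (dots mark numbering gaps) and ungapped
FASTA, with either the IMGT pipe-delimited header dialect (gene name in the
second field) or plain ``>IGHV3-30*01`` headers.  Anchor positions — the
first base of the conserved 2nd-CYS codon on V genes and of the J-TRP /
J-PHE codon on J genes — are derived automatically where the input permits:
for IMGT-gapped V sequences the 2nd-CYS sits at gapped codon 104; for J
genes the W/F-G-x-G motif is located by scanning.  For ungapped V input the
anchor may instead be supplied through a sidecar TSV (columns ``name``,
``anchor``, 0-based).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import GermlineError

SEGMENT_CLASSES = ("V", "D", "J")
_VALID_BASES = frozenset("ACGTN")

#: IMGT unique numbering position of the conserved 2nd-CYS codon.
CYS_CODON = 104

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class GermlineGene:
    """One named germline V, D, or J gene.

    ``anchor`` is the 0-based position (on the ungapped sequence) of the
    first base of the conserved 2nd-CYS codon (V) or J-TRP/J-PHE codon (J);
    ``None`` when it could not be determined.
    """

    name: str
    segment_class: str
    sequence: str
    gapped_sequence: str | None = None
    anchor: int | None = None

    def __post_init__(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise GermlineError(f"bad segment class {self.segment_class!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise GermlineError(
                f"non-DNA characters {sorted(bad)} in germline record {self.name!r}"
            )
        if self.gapped_sequence is not None:
            if self.gapped_sequence.replace(".", "") != self.sequence:
                raise GermlineError(
                    f"gapped/ungapped mismatch for germline record {self.name!r}"
                )
        if self.anchor is not None:
            if not 0 <= self.anchor <= len(self.sequence) - 3:
                raise GermlineError(
                    f"anchor {self.anchor} outside sequence for {self.name!r}"
                )

    @property
    def gene_name(self) -> str:
        """Allele-stripped label, e.g. ``IGHV3-30`` for ``IGHV3-30*01``."""
        return self.name.split("*", 1)[0]

    @property
    def subgroup(self) -> str:
        """Leading family label, e.g. ``IGHV3``."""
        return self.gene_name.split("-", 1)[0]


@dataclass
class GermlineSet:
    """A keyed collection of germline genes with per-class indices."""

    genes: dict[str, GermlineGene] = field(default_factory=dict)
    provenance: str = ""
    #: names of genes loaded without a resolvable anchor (load report)
    missing_anchors: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GermlineGene]:
        return iter(self.genes.values())

    def __getitem__(self, name: str) -> GermlineGene:
        return self.genes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    def by_class(self, segment_class: str) -> list[GermlineGene]:
        if segment_class not in SEGMENT_CLASSES:
            raise GermlineError(f"bad segment class {segment_class!r}")
        return [g for g in self.genes.values() if g.segment_class == segment_class]

    def add(self, gene: GermlineGene) -> None:
        if gene.name in self.genes:
            raise GermlineError(f"duplicate germline gene name {gene.name!r}")
        self.genes[gene.name] = gene


def _name_from_header(record: SeqRecord) -> str:
    desc = record.description
    if "|" in desc:
        fields = desc.split("|")
        if len(fields) >= 2 and fields[1].strip():
            return fields[1].strip()
    return record.id.split()[0]


def v_anchor_from_gapped(gapped: str, cys_codon: int = CYS_CODON) -> int | None:
    """0-based ungapped position of the first base of gapped codon *cys_codon*.

    Returns ``None`` if the codon lies beyond the sequence or is itself a
    numbering gap (truncated germline).
    """
    start = 3 * (cys_codon - 1)
    if len(gapped) < start + 3:
        return None
    codon = gapped[start : start + 3]
    if "." in codon:
        return None
    return start - gapped[:start].count(".")


def j_anchor_from_motif(sequence: str) -> int | None:
    """Locate the conserved J-TRP/J-PHE codon via the W/F-G-x-G motif."""
    for i in range(len(sequence) - 11):
        if sequence[i : i + 3] not in ("TGG", "TTT", "TTC"):
            continue
        if sequence[i + 3 : i + 5] == "GG" and sequence[i + 9 : i + 11] == "GG":
            return i
    return None


def read_anchor_sidecar(path: str | Path) -> dict[str, int]:
    """Read a sidecar anchor TSV with columns ``name`` and ``anchor`` (0-based)."""
    anchors: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "name":  # header row
                continue
            if len(parts) < 2:
                raise GermlineError(f"{path}:{lineno}: expected 2 columns")
            anchors[parts[0]] = int(parts[1])
    return anchors


def load_germline_fasta(
    path: str | Path,
    segment_class: str,
    anchors: Mapping[str, int] | str | Path | None = None,
    provenance: str | None = None,
) -> GermlineSet:
    """Load one segment class of an IMGT-style germline FASTA.

    Dots in gapped records are stripped into ``sequence`` with the gapped
    form retained; V/J anchors are computed where the input permits and the
    names of genes left without one are listed in ``missing_anchors``.
    """
    if segment_class not in SEGMENT_CLASSES:
        raise GermlineError(f"bad segment class {segment_class!r}")
    if anchors is not None and not isinstance(anchors, Mapping):
        anchors = read_anchor_sidecar(anchors)
    sidecar: Mapping[str, int] = anchors or {}

    gs = GermlineSet(provenance=provenance or str(path))
    missing: list[str] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        name = _name_from_header(record)
        raw = str(record.seq).upper()
        bad = set(raw) - _VALID_BASES - {"."}
        if bad:
            raise GermlineError(
                f"non-DNA characters {sorted(bad)} in record {name!r}"
            )
        gapped = raw if "." in raw else None
        sequence = raw.replace(".", "")
        anchor: int | None = None
        if name in sidecar:
            anchor = sidecar[name]
        elif segment_class == "V" and gapped is not None:
            anchor = v_anchor_from_gapped(gapped)
        elif segment_class == "J":
            anchor = j_anchor_from_motif(sequence)
        if anchor is None and segment_class in ("V", "J"):
            missing.append(name)
        gs.add(
            GermlineGene(
                name=name,
                segment_class=segment_class,
                sequence=sequence,
                gapped_sequence=gapped,
                anchor=anchor,
            )
        )
    if n_records == 0:
        raise GermlineError(f"no FASTA records in {path}")
    gs.missing_anchors = tuple(missing)
    return gs


def merge_sets(*sets: GermlineSet) -> GermlineSet:
    """Union of germline sets; name collisions are an error."""
    merged = GermlineSet(
        provenance="; ".join(s.provenance for s in sets if s.provenance)
    )
    missing: list[str] = []
    for s in sets:
        for gene in s:
            merged.add(gene)
        missing.extend(s.missing_anchors)
    merged.missing_anchors = tuple(missing)
    return merged


def write_germline_fasta(gs: GermlineSet, path: str | Path, gapped: bool = False) -> None:
    """Write a germline set back to FASTA (optionally the gapped form)."""
    records = []
    for gene in gs:
        seq = gene.gapped_sequence if (gapped and gene.gapped_sequence) else gene.sequence
        records.append(SeqRecord(Seq(seq), id=gene.name, description=""))
    SeqIO.write(records, str(path), "fasta")
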