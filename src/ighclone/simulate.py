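"""Ground-truthed synthetic single-cell heavy-chain repertoires.

Generates FR1-to-J amplicons of V(D)J rearrangements with exonucleolytic
trimming, non-templated N-nucleotides, somatic hypermutation (SHM) of the
V segment, and clonal lineages with optional intraclonal diversity.  The
default parameters emulate the statistical structure of single-cell IGHV
studies of CD30+ B cells in reactive lymph nodes: 20–36 cells per sample,
a mutated fraction of ~45–90%, mutation frequencies of ~3–9%, and a
mostly-singleton clonal structure with a few expanded clones of 2–5
members.

Every cell carries a :class:`SimTruth` record (generating genes, clone id,
implanted mutation positions, junction), so any pipeline stage can be
scored against ground truth.  All randomness flows through one
``numpy.random.Generator``; a fixed seed reproduces the sample byte for
byte.

Because no germline reference files are bundled, the module also provides
:func:`synthetic_germline_set`, a generator of an IMGT-gapped synthetic
human-like IGHV/IGHD/IGHJ reference (2nd-CYS at gapped codon 104, W-G-x-G
motif on J genes, whole-codon numbering gaps).  Gene names follow the
standard human nomenclature; the sequences are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import longest_common_run
from .clones import SampleSummary, cdr3_identity
from .errors import SimulationError
from .germline import CYS_CODON, GermlineGene, GermlineSet
from .mutation import MutationProfile, classify_mutation_status, sample_mutation_summary
from .policy import ClonePolicy, DEFAULT_POLICY

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_BASES = "ACGT"

#: IMGT codons rendered as whole-codon gaps in the synthetic V reference
_V_GAP_CODONS = frozenset({10, 31, 32, 33, 60, 61, 73})

_V_NAMES = (
    "IGHV1-2", "IGHV1-69", "IGHV3-7", "IGHV3-23",
    "IGHV3-30", "IGHV4-34", "IGHV4-59", "IGHV5-51",
)
_D_NAMES = (
    "IGHD1-1", "IGHD2-2", "IGHD3-3", "IGHD3-10", "IGHD4-17",
    "IGHD6-19", "IGHD2-15", "IGHD5-12", "IGHD3-22", "IGHD6-13",
)
_J_NAMES = ("IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6", "IGHJ1", "IGHJ2")


def _random_codon(rng: np.random.Generator) -> str:
    return _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]


def _synthetic_v(rng: np.random.Generator) -> tuple[str, str]:
    """One gapped/ungapped synthetic V gene with 2nd-CYS at codon 104."""
    fixed = {23: "TGC", 41: "TGG", CYS_CODON: "TGT"}
    codons = []
    for c in range(1, CYS_CODON + 1):
        if c in _V_GAP_CODONS:
            codons.append("...")
        elif c in fixed:
            codons.append(fixed[c])
        else:
            codons.append(_random_codon(rng))
    # short germline-encoded CDR3 stub past the 2nd-CYS
    codons += [_random_codon(rng), _random_codon(rng)]
    gapped = "".join(codons)
    return gapped, gapped.replace(".", "")


def _synthetic_d(rng: np.random.Generator, existing: list[str]) -> str:
    for _ in range(1000):
        length = int(rng.integers(16, 32))
        seq = "".join(_BASES[rng.integers(0, 4)] for _ in range(length))
        # keep every reading frame open so productive junctions exist
        # regardless of the frame the join lands in
        if any(
            seq[i : i + 3] in _STOPS
            for off in range(3)
            for i in range(off, length - 2, 3)
        ):
            continue
        if all(longest_common_run(seq, other)[0] <= 6 for other in existing):
            return seq
    raise SimulationError("could not generate mutually distinct D genes")


def _synthetic_j(rng: np.random.Generator) -> tuple[str, int]:
    """One synthetic J gene; returns (sequence, anchor of the J-TRP codon)."""
    for _ in range(1000):
        prefix_len = int(rng.integers(4, 10))
        prefix = "".join(_BASES[rng.integers(0, 4)] for _ in range(prefix_len))
        motif = "TGG" + "GG" + _BASES[rng.integers(0, 4)]
        motif += _random_codon(rng) + "GG" + _BASES[rng.integers(0, 4)]
        tail = "".join(_random_codon(rng) for _ in range(4))
        seq = prefix + motif + tail
        # the prefix, read backwards from the anchor in codon steps, must
        # stay stop-free: an in-frame stop there would survive any trim
        if any(
            seq[k : k + 3] in _STOPS
            for k in range(prefix_len - 3, -1, -3)
        ):
            continue
        from .germline import j_anchor_from_motif

        if j_anchor_from_motif(seq) == prefix_len:
            return seq, prefix_len
    raise SimulationError("could not place J anchor motif")


def synthetic_germline_set(
    seed: int = 0, n_v: int = 8, n_d: int = 6, n_j: int = 4, extra_allele: bool = True
) -> GermlineSet:
    """A synthetic IMGT-gapped IGHV/IGHD/IGHJ reference with known anchors.

    *extra_allele* adds ``IGHV3-30*02``, two substitutions away from
    ``*01``, so allele-collapsing behaviour is exercised.
    """
    rng = np.random.default_rng(seed)
    gs = GermlineSet(provenance=f"synthetic germline set (seed={seed})")
    if not 1 <= n_v <= len(_V_NAMES):
        raise SimulationError(f"n_v must be in [1, {len(_V_NAMES)}]")
    for name in _V_NAMES[:n_v]:
        gapped, ungapped = _synthetic_v(rng)
        anchor = len(gapped[: 3 * (CYS_CODON - 1)].replace(".", ""))
        gs.add(
            GermlineGene(
                name=f"{name}*01",
                segment_class="V",
                sequence=ungapped,
                gapped_sequence=gapped,
                anchor=anchor,
            )
        )
    if extra_allele and "IGHV3-30*01" in gs:
        base = gs["IGHV3-30*01"]
        seq = list(base.sequence)
        for pos in (30, 150):  # FR substitutions, away from anchors
            codon_start = 3 * (pos // 3)
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                trial = seq[codon_start:codon_start + 3]
                trial[pos - codon_start] = alt
                if "".join(trial) not in _STOPS:  # alleles stay stop-free
                    seq[pos] = alt
                    break
        mutated = "".join(seq)
        gapped = base.gapped_sequence
        # rebuild the gapped form around the same dot layout
        it = iter(mutated)
        gapped2 = "".join("." if ch == "." else next(it) for ch in gapped)
        gs.add(
            GermlineGene(
                name="IGHV3-30*02",
                segment_class="V",
                sequence=mutated,
                gapped_sequence=gapped2,
                anchor=base.anchor,
            )
        )
    d_seqs: list[str] = []
    for name in _D_NAMES[: min(n_d, len(_D_NAMES))]:
        seq = _synthetic_d(rng, d_seqs)
        d_seqs.append(seq)
        gs.add(GermlineGene(name=f"{name}*01", segment_class="D", sequence=seq))
    for name in _J_NAMES[: min(n_j, len(_J_NAMES))]:
        seq, anchor = _synthetic_j(rng)
        gs.add(
            GermlineGene(
                name=f"{name}*01", segment_class="J", sequence=seq, anchor=anchor
            )
        )
    return gs


@dataclass(frozen=True)
class CloneSpec:
    """One planned clone: member count, mutated founder, extra per-branch rate."""

    size: int
    mutated: bool
    extra_mutations_per_branch: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise SimulationError("clone size must be ≥ 1")
        if self.extra_mutations_per_branch < 0:
            raise SimulationError("branch mutation rate must be ≥ 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults emulate a single reactive-lymph-node sample: ~30 informative
    cells, ~65% of them hypermutated at ~6% per base over the V segment,
    and a few expanded clones of 2–3 members, most of them mutated with
    modest intraclonal diversity.
    """

    n_cells: int = 30
    mutated_fraction: float = 0.65
    shm_rate: float = 0.06
    clone_spec: tuple[CloneSpec, ...] = (
        CloneSpec(2, True, 1.0),
        CloneSpec(2, True, 1.0),
        CloneSpec(3, True, 1.0),
        CloneSpec(2, False, 0.0),
    )
    trim_max: int = 5
    n_insert_max: int = 7
    productive_only: bool = True
    seed: int = 0
    #: minimum pairwise CDR3 divergence enforced between distinct founder
    #: junctions (unrelated junctions are unrelated in real repertoires)
    cdr3_separation_pct: float = 20.0
    #: optional gene-usage weights (gene or subgroup name -> weight);
    #: unlisted genes get weight 1.  None = uniform usage.
    v_weights: tuple[tuple[str, float], ...] | None = None
    #: SHM rate multiplier at WRC/GYW hotspot positions; 1.0 = uniform
    shm_hotspot_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.mutated_fraction <= 1:
            raise SimulationError("mutated_fraction must be in [0, 1]")
        if not 0 <= self.shm_rate <= 1:
            raise SimulationError("shm_rate must be in [0, 1]")
        if self.trim_max < 0 or self.n_insert_max < 0:
            raise SimulationError("trim/insert maxima must be ≥ 0")
        if sum(c.size for c in self.clone_spec) > self.n_cells:
            raise SimulationError("clone_spec sizes exceed n_cells")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Read a plain ``key = value`` config file.

        ``clone_spec`` uses the compact form ``size:m|u:rate`` with commas,
        e.g. ``clone_spec = 2:m:1.0, 3:m:1.0, 2:u:0``.
        """
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "clone_spec":
                specs = []
                for item in filter(None, (s.strip() for s in value.split(","))):
                    size, flag, rate = (item.split(":") + ["0"])[:3]
                    specs.append(
                        CloneSpec(int(size), flag.lower().startswith("m"), float(rate))
                    )
                kwargs[key] = tuple(specs)
            elif key in ("n_cells", "trim_max", "n_insert_max", "seed"):
                kwargs[key] = int(value)
            elif key == "productive_only":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    v_name: str
    d_name: str
    j_name: str
    clone_id: str
    implanted_mutations: tuple[int, ...]
    junction_nt: str
    productive: bool
    v_anchor: int
    j_anchor_on_seq: int

    @property
    def cdr3_nt(self) -> str:
        return self.junction_nt[3:-3]

    @property
    def v_gene_name(self) -> str:
        return self.v_name.split("*", 1)[0]


def _is_productive(sequence: str, v_anchor: int, j_anchor_on_seq: int) -> bool:
    junction_len = j_anchor_on_seq + 3 - v_anchor
    if junction_len % 3 != 0:
        return False
    start = v_anchor % 3
    for i in range(start, j_anchor_on_seq + 1, 3):
        if sequence[i : i + 3] in _STOPS:
            return False
    return True


def _pick(
    genes: list[GermlineGene],
    rng: np.random.Generator,
    weights: tuple[tuple[str, float], ...] | None = None,
) -> GermlineGene:
    if not weights:
        return genes[int(rng.integers(0, len(genes)))]
    table = dict(weights)
    w = np.array(
        [table.get(g.name, table.get(g.gene_name, table.get(g.subgroup, 1.0)))
         for g in genes],
        dtype=float,
    )
    return genes[int(rng.choice(len(genes), p=w / w.sum()))]


def hotspot_positions(sequence: str, span: tuple[int, int]) -> set[int]:
    """Positions inside *span* that sit in a WRC or GYW hypermutation motif
    (the mutable C/G of the motif; W=A/T, R=A/G, Y=C/T)."""
    start, end = span
    hits: set[int] = set()
    for i in range(max(0, start), min(end, len(sequence))):
        if sequence[i] == "C" and i >= 2:
            if sequence[i - 2] in "AT" and sequence[i - 1] in "AG":
                hits.add(i)
        elif sequence[i] == "G" and i + 2 < len(sequence):
            if sequence[i + 1] in "CT" and sequence[i + 2] in "AT":
                hits.add(i)
    return hits


def simulate_rearrangement(
    config: SimConfig, germlines: GermlineSet, rng: np.random.Generator
) -> tuple[str, SimTruth]:
    """One V(D)J rearrangement: uniform gene draw, uniform trims, N-insertions.

    With ``productive_only`` the junction arithmetic is redrawn (up to 100
    attempts) until the join is in frame and stop-free.
    """
    v_genes = sorted(
        (g for g in germlines.by_class("V") if g.anchor is not None),
        key=lambda g: g.name,
    )
    d_genes = sorted(germlines.by_class("D"), key=lambda g: g.name)
    j_genes = sorted(
        (g for g in germlines.by_class("J") if g.anchor is not None),
        key=lambda g: g.name,
    )
    if not (v_genes and d_genes and j_genes):
        raise SimulationError("germline set lacks anchored V/D/J genes")
    v = _pick(v_genes, rng, config.v_weights)
    d, j = _pick(d_genes, rng), _pick(j_genes, rng)

    for _ in range(100):
        v_trim = int(rng.integers(0, min(config.trim_max, len(v.sequence) - v.anchor - 3) + 1))
        d5 = int(rng.integers(0, min(config.trim_max, len(d.sequence)) + 1))
        d3 = int(rng.integers(0, min(config.trim_max, len(d.sequence) - d5) + 1))
        j_trim = int(rng.integers(0, min(config.trim_max, j.anchor) + 1))
        n1 = int(rng.integers(0, config.n_insert_max + 1))
        n2 = int(rng.integers(0, config.n_insert_max + 1))
        ins1 = "".join(_BASES[rng.integers(0, 4)] for _ in range(n1))
        ins2 = "".join(_BASES[rng.integers(0, 4)] for _ in range(n2))
        d_mid = d.sequence[d5 : len(d.sequence) - d3]
        seq = (
            v.sequence[: len(v.sequence) - v_trim]
            + ins1
            + d_mid
            + ins2
            + j.sequence[j_trim:]
        )
        j_anchor_on_seq = (
            len(v.sequence) - v_trim + n1 + len(d_mid) + n2 + (j.anchor - j_trim)
        )
        productive = _is_productive(seq, v.anchor, j_anchor_on_seq)
        if productive or not config.productive_only:
            break
    else:
        raise SimulationError(
            f"no productive junction found for {v.name}/{d.name}/{j.name}"
        )
    truth = SimTruth(
        cell_id="",
        v_name=v.name,
        d_name=d.name,
        j_name=j.name,
        clone_id="",
        implanted_mutations=(),
        junction_nt=seq[v.anchor : j_anchor_on_seq + 3],
        productive=productive,
        v_anchor=v.anchor,
        j_anchor_on_seq=j_anchor_on_seq,
    )
    return seq, truth


def apply_shm(
    sequence: str,
    v_span: tuple[int, int],
    rate: float,
    rng: np.random.Generator,
    hotspot_factor: float = 1.0,
) -> tuple[str, tuple[int, ...]]:
    """Per-base SHM over *v_span*: Bernoulli(rate) substitutions, the new
    base uniform among the three alternatives.

    With ``hotspot_factor`` > 1 the rate is multiplied at WRC/GYW motif
    positions (capped at 1), emulating AID targeting; default is uniform.
    """
    if not 0 <= rate <= 1:
        raise SimulationError("SHM rate must be in [0, 1]")
    if hotspot_factor < 0:
        raise SimulationError("hotspot factor must be ≥ 0")
    start, end = v_span
    seq = list(sequence)
    positions: list[int] = []
    rates = np.full(end - start, rate)
    if hotspot_factor != 1.0:
        for i in hotspot_positions(sequence, v_span):
            rates[i - start] = min(1.0, rate * hotspot_factor)
    hits = np.flatnonzero(rng.random(end - start) < rates)
    for off in hits:
        i = start + int(off)
        alternatives = [b for b in _BASES if b != seq[i]]
        seq[i] = alternatives[int(rng.integers(0, 3))]
        positions.append(i)
    return "".join(seq), tuple(positions)


def _finalize_truth(
    seq: str, truth: SimTruth, germlines: GermlineSet
) -> SimTruth:
    """Recompute implanted mutations and productivity from the final sequence."""
    g = germlines[truth.v_name].sequence
    muts = tuple(
        p for p in range(truth.v_anchor) if seq[p] != g[p]
    )
    return replace(
        truth,
        implanted_mutations=muts,
        productive=_is_productive(seq, truth.v_anchor, truth.j_anchor_on_seq),
    )


def simulate_clone(
    spec: CloneSpec,
    config: SimConfig,
    germlines: GermlineSet,
    rng: np.random.Generator,
    clone_id: str = "clone",
) -> list[tuple[str, SimTruth]]:
    """One clonal lineage: a founder rearrangement (plus founder SHM when
    mutated) copied to every member, each member then receiving
    Poisson(extra) additional V-segment substitutions.

    All members share ``junction_nt`` exactly; branch mutations upstream of
    the 2nd-CYS codon create intraclonal diversity when the extra rate is
    positive.
    """
    founder_seq, truth = simulate_rearrangement(config, germlines, rng)
    if spec.mutated:
        founder_seq, _ = apply_shm(
            founder_seq, (0, truth.v_anchor), config.shm_rate, rng,
            hotspot_factor=config.shm_hotspot_factor,
        )
    members: list[tuple[str, SimTruth]] = []
    for _ in range(spec.size):
        seq = list(founder_seq)
        n_extra = int(rng.poisson(spec.extra_mutations_per_branch))
        if n_extra:
            sites = rng.choice(truth.v_anchor, size=min(n_extra, truth.v_anchor), replace=False)
            for site in sorted(int(s) for s in sites):
                alternatives = [b for b in _BASES if b != seq[site]]
                seq[site] = alternatives[int(rng.integers(0, 3))]
        final = "".join(seq)
        members.append(
            (final, _finalize_truth(final, replace(truth, clone_id=clone_id), germlines))
        )
    return members


def _separated(cdr3: str, accepted: list[str], min_divergence_pct: float) -> bool:
    limit = 100.0 - min_divergence_pct
    for other in accepted:
        # identity is bounded by 100·min(len)/max(len): skip the alignment
        # when the length ratio alone already guarantees separation
        bound = 100.0 * min(len(cdr3), len(other)) / max(len(cdr3), len(other))
        if bound <= limit:
            continue
        if cdr3_identity(cdr3, other) > limit:
            return False
    return True


@dataclass
class SimSample:
    """One simulated sample with its full ground truth."""

    sample_id: str
    records: list[SeqRecord]
    truth: list[SimTruth]
    truth_summary: SampleSummary

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": t.cell_id,
                "v_name": t.v_name,
                "d_name": t.d_name,
                "j_name": t.j_name,
                "clone_id": t.clone_id,
                "n_mutations": len(t.implanted_mutations),
                "positions": ";".join(map(str, t.implanted_mutations)),
                "junction": t.junction_nt,
                "productive": t.productive,
            }
            for t in self.truth
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / f"{self.sample_id}.fasta"
        SeqIO.write(self.records, str(fasta), "fasta")
        truth = out / f"{self.sample_id}.truth.tsv"
        self.truth_frame().to_csv(truth, sep="\t", index=False)
        return {"fasta": fasta, "truth": truth}


def _truth_profile(t: SimTruth, policy: ClonePolicy) -> MutationProfile:
    n = len(t.implanted_mutations)
    return MutationProfile(
        n_diff=n,
        aligned_len=t.v_anchor,
        freq_pct=100.0 * n / t.v_anchor,
        status=classify_mutation_status(n, policy),
    )


def truth_summary(
    sample_id: str, truths: list[SimTruth], policy: ClonePolicy = DEFAULT_POLICY
) -> SampleSummary:
    """The sample summary implied by ground truth, using the same formulas
    as the analysis stage (mutated = more than one difference, clone status
    mutated iff any member is, diversity = >1 distinct variant)."""
    profiles = [_truth_profile(t, policy) for t in truths]
    pct, mean_freq = sample_mutation_summary(profiles)
    clones: dict[str, list[SimTruth]] = {}
    for t in truths:
        clones.setdefault(t.clone_id, []).append(t)
    inventory: list[tuple[int, str]] = []
    n_div = 0
    for members in clones.values():
        if len(members) < 2:
            continue
        statuses = {
            classify_mutation_status(len(m.implanted_mutations), policy)
            for m in members
        }
        status = "mutated" if "mutated" in statuses else "unmutated"
        inventory.append((len(members), status))
        variants = {
            (frozenset(m.implanted_mutations), m.cdr3_nt) for m in members
        }
        if len(variants) > 1:
            n_div += 1
    usage: dict[str, int] = {}
    for t in truths:
        if t.productive:
            usage[t.v_gene_name] = usage.get(t.v_gene_name, 0) + 1
    return SampleSummary(
        sample_id=sample_id,
        n_cells_with_ighv=len(truths),
        pct_mutated=pct,
        mean_freq_of_mutated=mean_freq,
        clone_inventory=inventory,
        n_clones_mutated=sum(1 for _, s in inventory if s == "mutated"),
        n_clones_unmutated=sum(1 for _, s in inventory if s == "unmutated"),
        n_clones_with_diversity=n_div,
        v_gene_usage=dict(sorted(usage.items())),
    )


def simulate_sample(
    config: SimConfig,
    germlines: GermlineSet,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample1",
    policy: ClonePolicy = DEFAULT_POLICY,
) -> SimSample:
    """Simulate a full sample: planned clones plus singletons up to n_cells.

    Founder junctions (of clones and singletons alike) are resampled until
    their CDR3s diverge by at least ``cdr3_separation_pct`` from every
    previously accepted one, so the truth partition is unambiguous.  Cell
    ids are assigned after shuffling and encode nothing about the truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    cells: list[tuple[str, SimTruth]] = []
    accepted_cdr3: list[str] = []

    for k, spec in enumerate(config.clone_spec, 1):
        for _ in range(200):
            members = simulate_clone(spec, config, germlines, rng, clone_id=f"C{k}")
            cdr3 = members[0][1].cdr3_nt
            if _separated(cdr3, accepted_cdr3, config.cdr3_separation_pct):
                break
        else:
            raise SimulationError("could not separate clone founder junctions")
        accepted_cdr3.append(cdr3)
        cells.extend(members)

    n_clone_cells = len(cells)
    n_singletons = config.n_cells - n_clone_cells
    n_mut_target = round(config.n_cells * config.mutated_fraction)
    n_mut_clone = sum(c.size for c in config.clone_spec if c.mutated)
    n_mut_singletons = min(max(0, n_mut_target - n_mut_clone), n_singletons)

    for s in range(n_singletons):
        for _ in range(200):
            seq, truth = simulate_rearrangement(config, germlines, rng)
            if _separated(truth.cdr3_nt, accepted_cdr3, config.cdr3_separation_pct):
                break
        else:
            raise SimulationError("could not separate singleton junctions")
        accepted_cdr3.append(truth.cdr3_nt)
        if s < n_mut_singletons:
            seq, _ = apply_shm(
                seq, (0, truth.v_anchor), config.shm_rate, rng,
                hotspot_factor=config.shm_hotspot_factor,
            )
        truth = _finalize_truth(seq, replace(truth, clone_id=f"S{s + 1}"), germlines)
        cells.append((seq, truth))

    order = rng.permutation(len(cells))
    records: list[SeqRecord] = []
    truths: list[SimTruth] = []
    for rank, idx in enumerate(order, 1):
        seq, truth = cells[int(idx)]
        cell_id = f"{sample_id}_cell{rank:04d}"
        truth = replace(truth, cell_id=cell_id)
        records.append(SeqRecord(Seq(seq), id=cell_id, description=""))
        truths.append(truth)

    return SimSample(
        sample_id=sample_id,
        records=records,
        truth=truths,
        truth_summary=truth_summary(sample_id, truths, policy),
    )
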