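"""Synthetic annotated mitogenomes with planted ground truth.

The generator emulates the structure of basidiomycete mitochondrial
genomes: a circular molecule carrying the 15 core protein genes, two rRNAs
(rns, rnl), ~25 cloverleaf tRNAs, group I/II introns inserted at named
coding positions (some carrying intronic ORFs), free-standing ORFs,
intergenic spacers, interspersed repeats, and a single 1-bp gene overlap
across neighboring genes.  ``diverge`` derives a sister genome by applying
per-site transitions/transversions (coding sites constrained to keep genes
translatable under code 4), intergenic indels, and planned gene-order or
intron edits.  Every planted event is recorded in a GroundTruth object so
downstream analyses can be verified exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .codon_usage import CODE4, START_CANDIDATES, STOP_CODONS
from .genome_model import AnnotatedGenome, Feature, reverse_complement

CORE_PCGS = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)

#: default CDS lengths (nt, incl. stop) loosely following real fungal genes
DEFAULT_PCG_LENGTHS = {
    "atp6": 780, "atp8": 159, "atp9": 225, "cob": 1164, "cox1": 1593,
    "cox2": 750, "cox3": 810, "nad1": 960, "nad2": 1488, "nad3": 360,
    "nad4": 1461, "nad4L": 270, "nad5": 1980, "nad6": 600, "rps3": 1500,
}

#: 25 tRNAs: all 20 amino acids plus extra R, S, L isoacceptors and 3x trnM
DEFAULT_TRNAS = (
    ("trnA(tgc)", 4), ("trnR(tct)", 4), ("trnR(acg)", 4), ("trnN(gtt)", 4),
    ("trnD(gtc)", 4), ("trnC(gca)", 4), ("trnQ(ttg)", 4), ("trnE(ttc)", 4),
    ("trnG(tcc)", 4), ("trnH(gtg)", 4), ("trnI(gat)", 4), ("trnL(tag)", 17),
    ("trnL(taa)", 5), ("trnK(ttt)", 4), ("trnM(cat)", 4), ("trnM(cat)", 4),
    ("trnM(cat)", 4), ("trnF(gaa)", 4), ("trnP(tgg)", 4), ("trnS(tga)", 18),
    ("trnS(gct)", 5), ("trnT(tgt)", 4), ("trnW(tca)", 4), ("trnY(gta)", 4),
    ("trnV(tac)", 4),
)

TRNA_REGION_NAMES = {
    "A": "acceptor stem", "D": "D arm", "C": "anticodon arm",
    "E": "extra arm", "T": "T arm", "L": "linker",
}


@dataclass
class IntronPlan:
    host: str
    position: int       # nt 5' of the intron in the host coding sequence
    length: int
    group: str = "I"    # {I, II, unknown}
    orf: bool = False   # embed an intronic ORF


@dataclass
class DivergenceRates:
    transition: float = 0.02
    transversion: float = 0.01
    intergenic_indel: float = 0.002

    def validate(self) -> None:
        for r in (self.transition, self.transversion, self.intergenic_indel):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.transition + self.transversion > 1.0:
            raise ValueError("transition + transversion rates exceed 1")


def _default_introns() -> list[IntronPlan]:
    return [
        IntronPlan("cox1", 209, 1400, "I"),
        IntronPlan("cox1", 612, 1250, "I", orf=True),
        IntronPlan("cox1", 706, 1300, "I"),
        IntronPlan("cox1", 821, 1200, "I"),
        IntronPlan("cob", 393, 1200, "I"),
        IntronPlan("nad1", 500, 1100, "II"),
        IntronPlan("nad5", 717, 1000, "I"),
        IntronPlan("rnl", 800, 1300, "I", orf=True),
    ]


@dataclass
class SyntheticSpec:
    seed: int = 0
    genome_length_target: int = 50_000
    core_pcgs: tuple[str, ...] = CORE_PCGS
    pcg_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_LENGTHS))
    rrnas: dict[str, int] = field(default_factory=lambda: {"rns": 1687, "rnl": 3778})
    trnas: tuple[tuple[str, int], ...] = DEFAULT_TRNAS
    n_free_orfs: int = 3
    free_orf_length: int = 600
    intron_plan: list[IntronPlan] = field(default_factory=_default_introns)
    repeat_plan: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(80, 2, 100.0), (60, 2, 95.0)]
    )
    overlap_plan: tuple[str, str, int] | None = ("nad4L", "nad5", 1)
    divergence: DivergenceRates = field(default_factory=DivergenceRates)
    rearrangement_plan: list[tuple] = field(default_factory=list)
    base_composition: float = 0.29  # target GC fraction
    start_codon_overrides: dict[str, str] = field(default_factory=dict)
    stop_codon_overrides: dict[str, str] = field(default_factory=dict)
    genome_id: str = "synthetic"

    def validate(self) -> None:
        self.divergence.validate()
        if not 0.0 < self.base_composition < 1.0:
            raise ValueError("base_composition must be in (0, 1)")
        for plan in self.intron_plan:
            host_len = self.pcg_lengths.get(plan.host) or self.rrnas.get(plan.host)
            if host_len is None:
                raise ValueError(f"intron host {plan.host} not in the gene plan")
            if not 1 <= plan.position < host_len:
                raise ValueError(
                    f"intron position {plan.position} outside host {plan.host} (len {host_len})"
                )


@dataclass
class GroundTruth:
    genome_id: str
    pcl_truth: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    repeats: list[dict] = field(default_factory=list)
    edits: list[tuple] = field(default_factory=list)
    substitutions: dict[str, dict[str, int]] = field(default_factory=dict)
    indels: list[dict] = field(default_factory=list)
    trna_structures: dict[str, str] = field(default_factory=dict)
    region_lengths: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


class PackingError(ValueError):
    """Planned features do not fit in the target genome length."""


# ---------------------------------------------------------------------------
# sequence primitives


def _random_bases(rng, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=n, p=p)) if n else ""


_SENSE_CODONS = sorted(CODE4)


def _random_cds(rng, length: int, gc: float, start: str = "ATG", stop: str = "TAA") -> str:
    """Random translatable CDS: start + sense codons + stop, no internal stop."""
    if length % 3 != 0 or length < 9:
        raise ValueError(f"CDS length {length} must be a codon multiple >= 9")
    n_body = length // 3 - 2
    body = []
    while len(body) < n_body:
        cod = _random_bases(rng, 3, gc)
        if cod not in STOP_CODONS:
            body.append(cod)
    return start + "".join(body) + stop


def _trna_sequence(rng, name: str, extra_len: int, gc: float) -> tuple[str, str]:
    """(sequence, region string) for a cloverleaf tRNA.

    Layout: acceptor 7 | linker 2 | D arm 16 | linker 1 | anticodon arm 17
    | extra arm | T arm 17 | acceptor 7; the anticodon sits at positions
    8-10 of the anticodon arm.
    """
    anticodon = name[name.index("(") + 1 : name.index(")")].upper()
    segments = [("A", 7), ("L", 2), ("D", 16), ("L", 1), ("C", 17),
                ("E", extra_len), ("T", 17), ("A", 7)]
    seq, struct = [], []
    for code, n in segments:
        part = _random_bases(rng, n, gc)
        if code == "C":
            part = part[:7] + anticodon + part[10:]
        seq.append(part)
        struct.append(code * n)
    return "".join(seq), "".join(struct)


# ---------------------------------------------------------------------------
# locus assembly


@dataclass
class _Locus:
    """A contiguous stretch of sequence owning one or more features.

    Feature intervals are 0-based offsets relative to the locus start.
    """

    seq: str
    features: list[tuple[str, str, str, list[tuple[int, int]], str | None, str | None]]
    # (name, ftype, strand, rel intervals 0-based inclusive, parent, anticodon)


def _build_gene_locus(
    rng, name: str, cds: str, introns: list[IntronPlan], gc: float
) -> tuple[_Locus, list[tuple[int, int, str]]]:
    """Locus for one (plus-strand) gene with introns inserted at coding positions."""
    plans = sorted(introns, key=lambda p: p.position)
    pcl = []
    exon_bounds = [0] + [p.position for p in plans] + [len(cds)]
    pieces = []  # (kind, seq, plan)
    for i, plan in enumerate(plans):
        pieces.append(("exon", cds[exon_bounds[i] : exon_bounds[i + 1]], None))
        pieces.append(("intron", _random_bases(rng, plan.length, gc), plan))
    pieces.append(("exon", cds[exon_bounds[len(plans)] : exon_bounds[len(plans) + 1]], None))

    seq_parts, exon_ivals, feats = [], [], []
    offset = 0
    ordinal = 0
    for kind, part, plan in pieces:
        if kind == "intron":
            ordinal += 1
            intron_seq = part
            if plan.orf and plan.length >= 400:
                orf_len = min((plan.length - 120) // 3 * 3, 900)
                orf = _random_cds(rng, orf_len, gc)
                pad = 60
                intron_seq = part[:pad] + orf + part[pad + orf_len :]
                feats.append(
                    (f"orf{orf_len // 3}-{name}.i{ordinal}", "intronic_ORF", "+",
                     [(offset + pad, offset + pad + orf_len - 1)], name, None)
                )
            feats.append(
                (f"{name}.i{ordinal}", "intron", "+",
                 [(offset, offset + len(intron_seq) - 1)], name, None)
            )
            pcl.append((ordinal, plan.position, plan.group))
            seq_parts.append(intron_seq)
            offset += len(intron_seq)
        else:
            if part:
                exon_ivals.append((offset, offset + len(part) - 1))
                seq_parts.append(part)
                offset += len(part)
    ftype = "rRNA" if name in ("rns", "rnl") else "PCG"
    feats.insert(0, (name, ftype, "+", exon_ivals, None, None))
    return _Locus("".join(seq_parts), feats), pcl


def generate_genome(spec: SyntheticSpec) -> tuple[AnnotatedGenome, GroundTruth]:
    """Emit one annotated circular genome plus its planted ground truth.

    Deterministic for a fixed seed.  Raises :class:`PackingError` when the
    planned features exceed ``genome_length_target``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gc = spec.base_composition
    truth = GroundTruth(genome_id=spec.genome_id)

    introns_by_host: dict[str, list[IntronPlan]] = {}
    for plan in spec.intron_plan:
        introns_by_host.setdefault(plan.host, []).append(plan)

    # build loci in a fixed canonical genome order, tRNAs interleaved
    loci: list[_Locus] = []
    gene_order = [g for g in (
        "cox1", "cox2", "cox3", "cob", "atp6", "atp8", "atp9", "nad1", "nad2",
        "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
    ) if g in spec.core_pcgs]
    rrna_order = [r for r in ("rns", "rnl") if r in spec.rrnas]

    trna_queue = list(spec.trnas)
    trna_ordinals: dict[str, int] = {}

    def pop_trna() -> _Locus | None:
        if not trna_queue:
            return None
        name, extra = trna_queue.pop(0)
        seq, struct = _trna_sequence(rng, name, extra, gc)
        k = trna_ordinals.get(name, 0)
        trna_ordinals[name] = k + 1
        truth.trna_structures[f"{name}#{k}"] = struct
        anticodon = name[name.index("(") + 1 : name.index(")")]
        return _Locus(seq, [(name, "tRNA", "+", [(0, len(seq) - 1)], None, anticodon)])

    big_units = gene_order + rrna_order
    orf_slots = set()
    if spec.n_free_orfs:
        step = max(1, len(big_units) // (spec.n_free_orfs + 1))
        orf_slots = {step * (i + 1) for i in range(spec.n_free_orfs)}

    overlap = spec.overlap_plan
    orf_count = 0
    for idx, gname in enumerate(big_units):
        if gname in spec.rrnas:
            cds = _random_bases(rng, spec.rrnas[gname], gc)
        else:
            length = spec.pcg_lengths[gname]
            cds = _random_cds(
                rng, length, gc,
                start=spec.start_codon_overrides.get(gname, "ATG"),
                stop=spec.stop_codon_overrides.get(gname, "TAA"),
            )
        locus, pcl = _build_gene_locus(rng, gname, cds, introns_by_host.get(gname, []), gc)
        if pcl:
            truth.pcl_truth[gname] = pcl
        loci.append(locus)
        overlap_head = overlap is not None and gname == overlap[0]
        if not overlap_head:
            t = pop_trna()
            if t:
                loci.append(t)
        if idx in orf_slots and not overlap_head:
            orf_count += 1
            orf = _random_cds(rng, spec.free_orf_length, gc)
            strand = "-" if orf_count == 2 else "+"
            seq = reverse_complement(orf) if strand == "-" else orf
            loci.append(
                _Locus(seq, [(f"orf{spec.free_orf_length // 3}_{orf_count}", "free_ORF",
                              strand, [(0, len(seq) - 1)], None, None)])
            )
    while trna_queue:
        loci.append(pop_trna())

    # assemble: gap0 locus1 gap1 locus2 ... gapN (origin sits inside gap0)
    overlap_pairs = set()
    if overlap is not None:
        ga, gb, nbp = overlap
        names = [loc.features[0][0] for loc in loci]
        ia, ib = names.index(ga), names.index(gb)
        if ib != ia + 1:
            raise ValueError(f"overlap genes {ga},{gb} must be adjacent in the layout")
        if loci[ia].seq[-nbp:] != loci[ib].seq[:nbp]:
            raise PackingError(f"overlap of {nbp} bp between {ga} and {gb} is sequence-incompatible")
        overlap_pairs.add(ia)

    total_locus = sum(len(loc.seq) for loc in loci) - sum(
        spec.overlap_plan[2] for _ in overlap_pairs
    )
    n_gaps = len(loci) + 1 - len(overlap_pairs)
    spare = spec.genome_length_target - total_locus
    if spare < n_gaps:
        raise PackingError(
            f"planned features ({total_locus} bp + {n_gaps} spacers) exceed target "
            f"{spec.genome_length_target} bp"
        )
    # random spacer lengths >= 1 summing exactly to spare
    cuts = np.sort(rng.choice(np.arange(1, spare), size=n_gaps - 1, replace=False))
    gap_lens = np.diff(np.concatenate([[0], cuts, [spare]])).astype(int).tolist()

    seq_parts: list[str] = []
    features: list[Feature] = []
    pos = 0  # 0-based length so far
    gap_iter = iter(gap_lens)
    gap_records = []  # (start0, length) for repeat planting

    def emit_gap():
        nonlocal pos
        glen = next(gap_iter)
        gap_records.append((pos, glen))
        seq_parts.append(_random_bases(rng, glen, gc))
        pos += glen

    emit_gap()
    for i, loc in enumerate(loci):
        trim = 0
        if (i - 1) in overlap_pairs:
            trim = spec.overlap_plan[2]
        start0 = pos - trim
        seq_parts.append(loc.seq[trim:])
        pos = start0 + len(loc.seq)
        for name, ftype, strand, rel, parent, anticodon in loc.features:
            ivals = [(start0 + s + 1, start0 + e + 1) for s, e in rel]
            if strand == "-":
                ivals = ivals[::-1]
            features.append(Feature(name, ftype, strand, ivals, parent=parent, anticodon=anticodon))
        if i not in overlap_pairs:
            emit_gap()

    sequence = list("".join(seq_parts))
    assert len(sequence) == spec.genome_length_target

    # plant interspersed repeats by overwriting intergenic sequence
    usable_gaps = sorted(gap_records, key=lambda g: -g[1])
    gap_idx = 0
    for length, copies, identity in spec.repeat_plan:
        unit = _random_bases(rng, length, gc)
        n_mismatch = round(length * (1.0 - identity / 100.0))
        copy_coords = []
        for c in range(copies):
            while gap_idx < len(usable_gaps) and usable_gaps[gap_idx][1] < length + 2:
                gap_idx += 1
            if gap_idx >= len(usable_gaps):
                raise PackingError(f"no intergenic gap large enough for a {length}-bp repeat copy")
            gstart, glen = usable_gaps[gap_idx]
            gap_idx += 1
            at = gstart + (glen - length) // 2
            copy = list(unit)
            if c > 0 and n_mismatch:
                # mismatches evenly spaced so exact stretches stay seedable
                sites = [
                    round((i + 1) * length / (n_mismatch + 1)) - 1 for i in range(n_mismatch)
                ]
                for s in sites:
                    copy[s] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[s]]
            sequence[at : at + length] = copy
            copy_coords.append({"start": at + 1, "end": at + length})
        truth.repeats.append(
            {"length": length, "identity": identity, "copies": copy_coords}
        )

    genome = AnnotatedGenome(spec.genome_id, "".join(sequence), "circular", features)
    genome.validate()
    from .composition import partition_regions

    truth.region_lengths = partition_regions(genome).lengths
    return genome, truth


# ---------------------------------------------------------------------------
# reusable study scenarios


def random_small_spec(seed: int) -> SyntheticSpec:
    """A randomized compact genome spec for property testing.

    Samples a subset of core genes, shorter rRNAs, a random intron plan and
    a random length target, keeping generation fast while exercising the
    same structural variety as the full-size defaults.
    """
    rng = np.random.default_rng(seed)
    genes = [str(g) for g in rng.choice(CORE_PCGS, size=rng.integers(5, 10), replace=False)]
    for required in ("cox1", "nad4L", "nad5"):
        if required not in genes:
            genes.append(required)
    lengths = {g: DEFAULT_PCG_LENGTHS[g] for g in genes}
    n_tr = int(rng.integers(5, 12))
    intron_plan = []
    for host in rng.choice(genes, size=rng.integers(0, 4), replace=False):
        pos = int(rng.integers(30, lengths[host] - 30))
        intron_plan.append(IntronPlan(str(host), pos, int(rng.integers(150, 400)),
                                      "II" if rng.random() < 0.2 else "I"))
    base = sum(lengths.values()) + 700 + 1200 + n_tr * 90 + sum(p.length for p in intron_plan)
    return SyntheticSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        genome_length_target=base + int(rng.integers(60, 4000)) + 1200,
        core_pcgs=tuple(genes),
        pcg_lengths=lengths,
        rrnas={"rns": 700, "rnl": 1200},
        trnas=DEFAULT_TRNAS[:n_tr],
        n_free_orfs=int(rng.integers(0, 3)),
        intron_plan=intron_plan,
        repeat_plan=[],
        overlap_plan=("nad4L", "nad5", 1) if rng.random() < 0.5 else None,
        base_composition=float(rng.uniform(0.2, 0.45)),
        genome_id=f"rand{seed}",
    )


#: membership design for the six-genome cox1 intron panel: 27 distinct
#: insertion positions carried by 4/3/2/1 genomes -> 49 introns total
_PANEL_POSITIONS = [
    44, 101, 209, 237, 273, 312, 369, 407, 453, 498, 551, 612, 643, 706,
    731, 767, 807, 821, 867, 912, 971, 1012, 1057, 1101, 1150, 1211, 1256,
]
_PANEL_CARRIERS = [4, 4, 4, 3, 3, 3, 3, 3, 2, 2, 2] + [1] * 16


def pcl_panel(seed: int, n_genomes: int = 6):
    """Six diverged genomes with cox1 introns planted at 27 known positions.

    Returns (genomes, truths, expected) where expected maps each planted
    insertion position to the set of genome ids carrying it (49 introns
    over 27 positions in the default design).
    """
    assert len(_PANEL_POSITIONS) == len(_PANEL_CARRIERS) == 27
    base_spec = SyntheticSpec(
        seed=seed,
        genome_length_target=32_000,
        rrnas={"rns": 700, "rnl": 1200},
        intron_plan=[],
        repeat_plan=[],
        n_free_orfs=0,
        genome_id="ancestor",
    )
    ancestor, anc_truth = generate_genome(base_spec)
    rng = np.random.default_rng([seed, 17])
    # deterministic genome assignment per position
    assignment: dict[int, list[int]] = {}
    for pos, k in zip(_PANEL_POSITIONS, _PANEL_CARRIERS):
        assignment[pos] = sorted(rng.choice(n_genomes, size=k, replace=False).tolist())
    genomes, truths = [], []
    expected: dict[int, set[str]] = {pos: set() for pos in _PANEL_POSITIONS}
    for i in range(n_genomes):
        gains = [
            ("gain_intron", "cox1", pos, int(rng.integers(180, 320)), "I")
            for pos in _PANEL_POSITIONS
            if i in assignment[pos]
        ]
        spec_i = replace(
            base_spec,
            seed=seed + 1000 + i,
            divergence=DivergenceRates(0.01, 0.005, 0.0),
            rearrangement_plan=gains,
        )
        g, t = diverge(ancestor, spec_i, new_id=f"taxon{i}", parent_truth=anc_truth)
        genomes.append(g)
        truths.append(t)
        for pos in _PANEL_POSITIONS:
            if i in assignment[pos]:
                expected[pos].add(f"taxon{i}")
    return genomes, truths, expected, ancestor


# ---------------------------------------------------------------------------
# divergence


def _coding_maps(genome: AnnotatedGenome):
    """Per-gene genomic position lists (coding order) for all ORF features."""
    maps = {}
    for f in genome.features:
        if f.ftype not in ("PCG", "free_ORF", "intronic_ORF"):
            continue
        positions: list[int] = []
        for s, e in f.intervals:
            pts = genome.interval_positions(s, e)
            if f.strand == "-":
                pts = pts[::-1]
            positions.extend(pts)
        maps[f.name] = (f.strand, positions)
    return maps


_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _codon_ok(codon: str, codon_index: int, n_codons: int, start: str) -> bool:
    if codon_index == 0:
        return codon in START_CANDIDATES
    if codon_index == n_codons - 1:
        return codon in STOP_CODONS
    return codon not in STOP_CODONS


def diverge(
    genome: AnnotatedGenome,
    spec: SyntheticSpec,
    new_id: str | None = None,
    parent_truth: GroundTruth | None = None,
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Derive a sister genome by mutation, indels and planned edits.

    Substitutions are drawn per site at the spec's transition/transversion
    rates; proposals that would break a start codon, stop codon, or create
    an internal stop in any overlapping reading frame are re-drawn among the
    remaining bases or skipped.  Indels are restricted to intergenic
    sequence.  Planned edits (move/duplicate genes, gain/lose introns) are
    applied before mutation.  Deterministic for a fixed spec seed.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 7919])
    truth = GroundTruth(genome_id=new_id or f"{genome.id}_sister")
    if parent_truth is not None:
        truth.pcl_truth = {h: list(v) for h, v in parent_truth.pcl_truth.items()}
        truth.trna_structures = dict(parent_truth.trna_structures)

    work = _apply_edits(genome, spec.rearrangement_plan, rng, spec, truth)

    seq = list(work.sequence)
    n = len(seq)
    maps = _coding_maps(work)
    pos_to_codons: dict[int, list[tuple[str, int, int]]] = {}
    for gene, (strand, positions) in maps.items():
        for i, p in enumerate(positions):
            pos_to_codons.setdefault(p - 1, []).append((gene, i // 3, i % 3))

    region_of = _position_labels(work)

    ts, tv = spec.divergence.transition, spec.divergence.transversion
    draws = rng.random(n)
    tv_choice = rng.random(n)

    def coding_base(genomic_base: str, strand: str) -> str:
        return genomic_base if strand == "+" else _COMPL[genomic_base]

    def try_substitute(p0: int, new_base: str) -> bool:
        old = seq[p0]
        if old == new_base or old not in "ACGT":
            return False
        for gene, cidx, _ in pos_to_codons.get(p0, []):
            strand, positions = maps[gene]
            n_codons = len(positions) // 3
            triple = positions[3 * cidx : 3 * cidx + 3]
            codon = "".join(
                coding_base(new_base if q - 1 == p0 else seq[q - 1], strand) for q in triple
            )
            if not _codon_ok(codon, cidx, n_codons, "ATG"):
                return False
        # accept
        label = region_of[p0]
        rec = truth.substitutions.setdefault(
            label, {"transitions": 0, "transversions": 0, "synonymous": 0, "nonsynonymous": 0}
        )
        if _TS[old] == new_base:
            rec["transitions"] += 1
        else:
            rec["transversions"] += 1
        for gene, cidx, _ in pos_to_codons.get(p0, []):
            strand, positions = maps[gene]
            triple = positions[3 * cidx : 3 * cidx + 3]
            before = "".join(coding_base(seq[q - 1], strand) for q in triple)
            after = "".join(
                coding_base(new_base if q - 1 == p0 else seq[q - 1], strand) for q in triple
            )
            grec = truth.substitutions.setdefault(
                gene, {"transitions": 0, "transversions": 0, "synonymous": 0, "nonsynonymous": 0}
            )
            if gene != label:
                if _TS[old] == new_base:
                    grec["transitions"] += 1
                else:
                    grec["transversions"] += 1
            if CODE4.get(before) == CODE4.get(after):
                grec["synonymous"] += 1
            else:
                grec["nonsynonymous"] += 1
        seq[p0] = new_base
        return True

    for p0 in range(n):
        r = draws[p0]
        old = seq[p0]
        if old not in "ACGT":
            continue
        if r < ts:
            if not try_substitute(p0, _TS[old]):
                # resample among the remaining bases that keep frames valid
                for alt in _TV[old]:
                    if try_substitute(p0, alt):
                        break
        elif r < ts + tv:
            alts = _TV[old]
            first = alts[int(tv_choice[p0] * 2) % 2]
            second = alts[1] if first == alts[0] else alts[0]
            if not try_substitute(p0, first):
                if not try_substitute(p0, second):
                    try_substitute(p0, _TS[old])

    # intergenic indels
    indel_rate = spec.divergence.intergenic_indel
    new_seq_parts: list[str] = []
    shift_points: list[tuple[int, int]] = []  # (old 0-based position, cumulative shift after)
    cum = 0
    p0 = 0
    indel_draws = rng.random(n)
    while p0 < n:
        if region_of[p0] == "intergenic" and indel_draws[p0] < indel_rate:
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                # deletion, capped at the end of the intergenic run
                run_end = p0
                while run_end < n and region_of[run_end] == "intergenic":
                    run_end += 1
                size = min(size, run_end - p0)
                truth.indels.append({"type": "del", "at": p0 + 1, "length": size})
                cum -= size
                shift_points.append((p0 + size, cum))
                p0 += size
                continue
            ins = _random_bases(rng, size, spec.base_composition)
            truth.indels.append({"type": "ins", "at": p0 + 1, "length": size})
            new_seq_parts.append(ins)
            cum += size
            shift_points.append((p0, cum))
        new_seq_parts.append(seq[p0])
        p0 += 1

    def shifted(p: int) -> int:  # p is 1-based
        s = 0
        for old0, c in shift_points:
            if p - 1 >= old0:
                s = c
            else:
                break
        return p + s

    new_features = [
        replace(f, intervals=[(shifted(s), shifted(e)) for s, e in f.intervals])
        for f in work.features
    ]
    out = AnnotatedGenome(truth.genome_id, "".join(new_seq_parts), "circular", new_features)
    out.validate()
    truth.edits = list(spec.rearrangement_plan)
    return out, truth


def _position_labels(genome: AnnotatedGenome) -> list[str]:
    """Feature-name label per 0-based position (coding > RNA/intron > intergenic)."""
    n = len(genome)
    labels = ["intergenic"] * n
    order = {"intron": 0, "intronic_ORF": 1, "rRNA": 2, "tRNA": 2, "free_ORF": 3, "PCG": 3}
    for f in sorted(genome.features, key=lambda f: order[f.ftype]):
        for s, e in f.intervals:
            for p in genome.interval_positions(s, e):
                labels[p - 1] = f.name
    return labels


# -- planned gene-order / intron edits --------------------------------------


def _apply_edits(
    genome: AnnotatedGenome, plan: list[tuple], rng, spec: SyntheticSpec, truth: GroundTruth
) -> AnnotatedGenome:
    feats = [replace(f, intervals=list(f.intervals)) for f in genome.features]
    if not plan:
        return AnnotatedGenome(genome.id, genome.sequence, genome.topology, feats)

    seq = genome.sequence

    def feature_block(name: str) -> tuple[int, int, list[Feature]]:
        """Span (1-based, inclusive) of a top-level feature plus its children."""
        top = next(f for f in feats if f.name == name and f.parent is None)
        group = [top] + [f for f in feats if f.parent == name]
        s = min(min(a for a, _ in f.intervals) for f in group)
        e = max(max(b for _, b in f.intervals) for f in group)
        return s, e, group

    def largest_gap() -> int:
        """1-based position at the middle of the largest intergenic run."""
        from .composition import _class_codes

        codes = _class_codes(AnnotatedGenome(genome.id, seq, "circular", feats))
        best_len = best_start = 0
        cur = None
        for i, c in enumerate(codes):
            if c == 0:
                if cur is None:
                    cur = i
                if i - cur + 1 > best_len:
                    best_len, best_start = i - cur + 1, cur
            else:
                cur = None
        return best_start + best_len // 2 + 1

    def insert_seq(at: int, piece: str) -> None:
        """Insert piece before 1-based position `at`, shifting downstream features."""
        nonlocal seq
        L = len(piece)
        seq = seq[: at - 1] + piece + seq[at - 1 :]
        for f in feats:
            f.intervals = [
                (s + L if s >= at else s, e + L if e >= at else e) for s, e in f.intervals
            ]

    def splice_in(at: int, piece: str, moved: list[Feature], block_start: int) -> None:
        insert_seq(at, piece)
        for f in moved:
            f.intervals = [
                (s - block_start + at, e - block_start + at) for s, e in f.intervals
            ]
            feats.append(f)

    def cut_out(s: int, e: int, group: list[Feature]) -> str:
        nonlocal seq
        piece = seq[s - 1 : e]
        L = e - s + 1
        seq = seq[: s - 1] + seq[e:]
        for f in group:
            feats.remove(f)
        for f in feats:
            f.intervals = [(a - L if a > e else a, b - L if b > e else b) for a, b in f.intervals]
        return piece

    def gain_intron(host: str, cpos: int, length: int) -> None:
        top = next(f for f in feats if f.name == host and f.parent is None)
        if top.strand != "+":
            raise ValueError("gain_intron supports plus-strand hosts only")
        acc, at = 0, None
        for a, b in sorted(top.intervals):
            exon_len = b - a + 1
            if acc < cpos <= acc + exon_len - 1:
                at = a + (cpos - acc)  # first base of the new intron
                break
            acc += exon_len
        if at is None:
            raise ValueError(
                f"coding position {cpos} does not fall strictly inside an exon of {host}"
            )
        piece = _random_bases(rng, length, spec.base_composition)
        insert_seq(at, piece)
        # the containing exon became (a, b+length); split it around the intron
        new_ivals = []
        for a, b in top.intervals:
            if a < at <= b:
                new_ivals.extend([(a, at - 1), (at + length, b)])
            else:
                new_ivals.append((a, b))
        top.intervals = new_ivals
        existing = sum(1 for f in feats if f.ftype == "intron" and f.parent == host)
        feats.append(
            Feature(f"{host}.i{existing + 1}", "intron", "+", [(at, at + length - 1)], parent=host)
        )

    def lose_intron(host: str, ordinal: int) -> None:
        name = f"{host}.i{ordinal}"
        intr = next(f for f in feats if f.name == name)
        s, e = intr.intervals[0]
        group = [intr] + [
            f for f in feats
            if f.ftype == "intronic_ORF" and f.parent == host
            and s <= f.intervals[0][0] and f.intervals[-1][1] <= e
        ]
        cut_out(s, e, group)
        top = next(f for f in feats if f.name == host and f.parent is None)
        merged: list[tuple[int, int]] = []
        for a, b in sorted(top.intervals):
            if merged and a == merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        top.intervals = merged if top.strand == "+" else merged[::-1]
        # renumber this host's remaining introns 5'->3'
        host_introns = sorted(
            (f for f in feats if f.ftype == "intron" and f.parent == host),
            key=lambda f: f.intervals[0][0],
        )
        for k, f in enumerate(host_introns, start=1):
            f.name = f"{host}.i{k}"

    for edit in plan:
        kind = edit[0]
        if kind == "duplicate":
            s, e, group = feature_block(edit[1])
            piece = seq[s - 1 : e]
            copies = [replace(f, intervals=list(f.intervals)) for f in group]
            splice_in(largest_gap(), piece, copies, s)
        elif kind == "move":
            # optional third element: name of the feature to reinsert after
            s, e, group = feature_block(edit[1])
            piece = cut_out(s, e, group)
            if len(edit) > 2:
                _, te, _ = feature_block(edit[2])
                at = min(te + 2, len(seq) + 1)
            else:
                at = largest_gap()
            splice_in(at, piece, group, s)
        elif kind == "gain_intron":
            _, host, cpos, length, label = edit
            gain_intron(host, cpos, length)
            truth.pcl_truth.setdefault(host, []).append(
                (sum(1 for f in feats if f.ftype == "intron" and f.parent == host), cpos, label)
            )
        elif kind == "lose_intron":
            lose_intron(edit[1], edit[2])
        else:
            raise ValueError(f"unknown edit {edit!r}")

    out = AnnotatedGenome(genome.id, seq, genome.topology, feats)
    out.validate()
    return out
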