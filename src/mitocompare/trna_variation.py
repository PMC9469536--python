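"""tRNA variation mapped onto cloverleaf structural regions.

Homologous tRNAs from two genomes are aligned and every differing column is
a variable site, attributed to the structural region (acceptor stem, D arm,
anticodon arm, extra arm, T arm, linker) of the structurally annotated
partner.  Structures are inputs — a per-base region code string aligned to
the tRNA sequence — not predictions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome_model import AnnotatedGenome
from .seqevol import align_pair

REGION_CODES = {
    "A": "acceptor stem",
    "D": "D arm",
    "C": "anticodon arm",
    "E": "extra arm",
    "T": "T arm",
    "L": "linker",
}


@dataclass
class TrnaStructure:
    sequence: str
    regions: str  # one region code per base

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.regions):
            raise ValueError(
                f"structure length {len(self.regions)} != sequence length {len(self.sequence)}"
            )
        bad = set(self.regions) - set(REGION_CODES)
        if bad:
            raise ValueError(f"unknown region codes: {sorted(bad)}")


@dataclass
class TrnaComparison:
    variable_sites: int
    per_region: Counter
    indel_columns: int


def compare_trnas(
    structured: TrnaStructure, other_seq: str, count_indels: bool = True
) -> TrnaComparison:
    """Per-column variation calls between a structured tRNA and a partner.

    Substitution columns attribute to the region of the structured tRNA's
    base; indel columns (counted by default) attribute to the region of the
    nearest structured base 5' of the gap (3' at the very start).
    """
    aln = align_pair(structured.sequence, other_seq)
    per_region: Counter = Counter()
    variable = indels = 0
    a_index = -1  # last consumed position in structured sequence
    for x, y in aln.columns():
        if x != "-":
            a_index += 1
        if x == y:
            continue
        if x == "-" or y == "-":
            if not count_indels:
                indels += 1
                continue
            anchor = max(a_index, 0)
            per_region[REGION_CODES[structured.regions[anchor]]] += 1
            variable += 1
            indels += 1
        else:
            per_region[REGION_CODES[structured.regions[a_index]]] += 1
            variable += 1
    return TrnaComparison(variable, per_region, indels)


@dataclass
class TrnaVariationReport:
    per_trna: dict[str, int]
    per_region_counts: Counter
    per_region_percent: dict[str, float]
    total_variable_sites: int
    n_trnas_compared: int
    n_trnas_variable: int
    unmatched: list[str] = field(default_factory=list)


def _ordered_trnas(genome: AnnotatedGenome) -> list[tuple[str, int, str]]:
    """(name, copy ordinal, sequence) for tRNAs in genome order."""
    from .genome_model import reverse_complement

    feats = [f for f in genome.features if f.ftype == "tRNA"]
    feats.sort(key=lambda f: min(s for s, _ in f.intervals))
    out = []
    seen: Counter = Counter()
    for f in feats:
        k = seen[f.name]
        seen[f.name] += 1
        parts = []
        for s, e in f.intervals:
            piece = genome.extract(s, e)
            if f.strand == "-":
                piece = reverse_complement(piece)
            parts.append(piece)
        out.append((f.name, k, "".join(parts)))
    return out


def trna_set_report(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    structures_a: dict[str, str],
    count_indels: bool = True,
) -> TrnaVariationReport:
    """Aggregate tRNA variation between two genomes.

    tRNAs are matched by name (which encodes the anticodon); multi-copy
    tRNAs are matched by genome-order ordinal, unmatched copies listed in
    ``unmatched``.  ``structures_a`` maps "name#ordinal" -> region string
    for genome A's tRNAs.
    """
    trnas_a = {(n, k): s for n, k, s in _ordered_trnas(genome_a)}
    trnas_b = {(n, k): s for n, k, s in _ordered_trnas(genome_b)}
    matched = sorted(set(trnas_a) & set(trnas_b))
    if not matched:
        raise ValueError("no tRNAs shared between the two genomes")
    unmatched = sorted(
        f"{g}:{n}#{k}"
        for g, keys in (("A", set(trnas_a) - set(trnas_b)), ("B", set(trnas_b) - set(trnas_a)))
        for n, k in keys
    )
    per_trna: dict[str, int] = {}
    per_region: Counter = Counter()
    n_variable = 0
    for name, k in matched:
        key = f"{name}#{k}"
        regions = structures_a.get(key)
        if regions is None:
            unmatched.append(f"A:{key} (no structure)")
            continue
        struct = TrnaStructure(trnas_a[(name, k)], regions)
        cmp_res = compare_trnas(struct, trnas_b[(name, k)], count_indels=count_indels)
        per_trna[key] = cmp_res.variable_sites
        per_region.update(cmp_res.per_region)
        if cmp_res.variable_sites:
            n_variable += 1
    total = sum(per_region.values())
    per_region_percent = {
        region: 100.0 * per_region[region] / total if total else 0.0
        for region in sorted(REGION_CODES.values())
    }
    return TrnaVariationReport(
        per_trna=per_trna,
        per_region_counts=per_region,
        per_region_percent=per_region_percent,
        total_variable_sites=total,
        n_trnas_compared=len(per_trna),
        n_trnas_variable=n_variable,
        unmatched=unmatched,
    )
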