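"""Base composition, strand skews, region partition, and size-variation
contribution rates.

Strand asymmetry follows the usual definitions AT skew = (A-T)/(A+T) and
GC skew = (G-C)/(G+C).  The region partition assigns every nucleotide of the
genome to exactly one of four classes — protein-coding exon, intronic, RNA
(rRNA + tRNA exons), intergenic — so class lengths always sum to the genome
length; overlapping annotation is resolved by the fixed priority
rna > protein-coding > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import AnnotatedGenome, GenomeModelError

REGION_CLASSES = ("protein_coding", "intronic", "rna", "intergenic")
_INTERGENIC, _INTRON, _PCG, _RNA = 0, 1, 2, 3
_CODE_TO_CLASS = {_PCG: "protein_coding", _INTRON: "intronic", _RNA: "rna", _INTERGENIC: "intergenic"}


@dataclass
class CompositionStats:
    a: int
    c: int
    g: int
    t: int
    gc_percent: float
    at_percent: float
    at_skew: float
    gc_skew: float
    at_skew_degenerate: bool = False
    gc_skew_degenerate: bool = False


def composition_stats(sequence: str) -> CompositionStats:
    """Counts, GC/AT content and strand skews of a sequence.

    N bases are excluded from every denominator.  A zero denominator
    (A+T = 0 or G+C = 0) yields a skew of 0 with a degenerate flag.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    known = a + c + g + t
    if known == 0:
        raise ValueError("sequence contains no unambiguous bases")
    at, gc = a + t, g + c
    return CompositionStats(
        a=a, c=c, g=g, t=t,
        gc_percent=100.0 * gc / known,
        at_percent=100.0 * at / known,
        at_skew=(a - t) / at if at else 0.0,
        gc_skew=(g - c) / gc if gc else 0.0,
        at_skew_degenerate=(at == 0),
        gc_skew_degenerate=(gc == 0),
    )


@dataclass
class RegionPartition:
    lengths: dict[str, int]
    percentages: dict[str, float]
    genome_length: int

    def __getitem__(self, cls: str) -> int:
        return self.lengths[cls]


def _class_codes(genome: AnnotatedGenome) -> np.ndarray:
    n = len(genome)
    codes = np.zeros(n, dtype=np.int8)  # intergenic

    def paint(feat, code):
        for s, e in feat.intervals:
            for p in _interval_ranges(genome, s, e):
                codes[p[0] : p[1]] = code

    # ascending priority: introns (incl. intronic ORFs), then PCG/free ORFs,
    # then RNA genes; later passes overwrite earlier ones
    for f in genome.features:
        if f.ftype in ("intron", "intronic_ORF"):
            paint(f, _INTRON)
    for f in genome.features:
        if f.ftype in ("PCG", "free_ORF"):
            paint(f, _PCG)
    for f in genome.features:
        if f.ftype in ("rRNA", "tRNA"):
            paint(f, _RNA)
    return codes


def _interval_ranges(genome: AnnotatedGenome, s: int, e: int):
    """0-based half-open slices covering a possibly wrapped interval."""
    n = len(genome)
    if not (1 <= s <= n and 1 <= e <= n):
        raise GenomeModelError(f"interval {s}-{e} outside genome of length {n}")
    if s <= e:
        return [(s - 1, e)]
    if genome.topology != "circular":
        raise GenomeModelError(f"wrapped interval {s}-{e} on linear genome")
    return [(s - 1, n), (0, e)]


def partition_regions(genome: AnnotatedGenome) -> RegionPartition:
    """Nucleotide-exact partition of the genome into the four region classes.

    Every base is counted exactly once (shared bases of overlapping genes
    included once), so the class lengths sum to the genome length.
    """
    codes = _class_codes(genome)
    n = len(genome)
    lengths = {
        cls: int(np.count_nonzero(codes == code)) for code, cls in _CODE_TO_CLASS.items()
    }
    percentages = {cls: 100.0 * lengths[cls] / n for cls in lengths}
    return RegionPartition(lengths=lengths, percentages=percentages, genome_length=n)


@dataclass
class ContributionReport:
    """Decomposition of a two-genome size difference by region class."""

    size_differences: dict[str, int]  # per class, B minus A, bp
    contribution_rates: dict[str, float] | None  # percent; None when total diff is 0
    total_difference: int


def contribution_rates(partition_a: RegionPartition, partition_b: RegionPartition) -> ContributionReport:
    """Per-class contribution (percent) to the total size difference B - A.

    rate_class = 100 * (len_class(B) - len_class(A)) / (len(B) - len(A));
    rates are signed and sum to 100% whenever the total difference is
    nonzero.  With equal genome sizes, only the per-class differences are
    reported.
    """
    diffs = {
        cls: partition_b.lengths[cls] - partition_a.lengths[cls] for cls in REGION_CLASSES
    }
    total = partition_b.genome_length - partition_a.genome_length
    rates = None
    if total != 0:
        rates = {cls: 100.0 * d / total for cls, d in diffs.items()}
    return ContributionReport(size_differences=diffs, contribution_rates=rates, total_difference=total)


def partition_from_sizes(lengths: dict[str, int]) -> RegionPartition:
    """Build a partition directly from per-class lengths (e.g. reported sizes)."""
    missing = set(REGION_CLASSES) - set(lengths)
    if missing:
        raise ValueError(f"missing region classes: {sorted(missing)}")
    n = sum(lengths[c] for c in REGION_CLASSES)
    return RegionPartition(
        lengths=dict(lengths),
        percentages={c: 100.0 * lengths[c] / n for c in REGION_CLASSES},
        genome_length=n,
    )


def compare_genome_stats(length_a: int, gc_a: float, length_b: int, gc_b: float) -> dict[str, float]:
    """Headline between-genome comparison numbers.

    Returns the total size difference (bp), the absolute GC-content gap
    (percentage points) and the mean AT content (percent) of the pair.
    """
    return {
        "size_difference_bp": abs(length_b - length_a),
        "gc_gap_percent": abs(gc_b - gc_a),
        "mean_at_percent": ((100.0 - gc_a) + (100.0 - gc_b)) / 2.0,
    }
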