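"""Core data model for annotated circular mitochondrial genomes.

A mitogenome is represented as a single DNA sequence (circular or linear)
plus an ordered list of typed features in 1-based inclusive genome
coordinates, the convention used by GenBank flat files.  Features that span
the origin of a circular molecule are stored as a single interval with
``start > end`` and are normalized internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_TYPES = ("PCG", "rRNA", "tRNA", "intron", "intronic_ORF", "free_ORF")

#: standard 3-letter amino-acid codes -> 1-letter, for tRNA naming
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeModelError(ValueError):
    """Malformed genome, feature, or serialized table."""


@dataclass
class Feature:
    """One annotated element of a mitogenome.

    ``intervals`` holds 1-based inclusive (start, end) pairs in genome
    coordinates; for multi-exon genes the exons are listed 5'->3' on the
    coding strand.  ``parent`` names the host gene and is set exactly for
    introns and intronic ORFs.
    """

    name: str
    ftype: str
    strand: str
    intervals: list[tuple[int, int]]
    parent: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeModelError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise GenomeModelError(f"feature {self.name}: empty interval list")
        needs_parent = self.ftype in ("intron", "intronic_ORF")
        if needs_parent != (self.parent is not None):
            raise GenomeModelError(
                f"feature {self.name}: parent must be set iff ftype is intron/intronic_ORF"
            )

    def span(self) -> tuple[int, int]:
        """(min start, max end) over all intervals; only valid when not wrapping."""
        return min(s for s, _ in self.intervals), max(e for _, e in self.intervals)

    def length(self) -> int:
        raise NotImplementedError  # length depends on genome length for wrapped intervals


@dataclass
class AnnotatedGenome:
    """A circular (or linear) genome plus its ordered feature annotation."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeModelError(f"genome {self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeModelError(f"topology must be circular or linear: {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate helpers -------------------------------------------------

    def interval_length(self, start: int, end: int) -> int:
        if start <= end:
            return end - start + 1
        if self.topology != "circular":
            raise GenomeModelError(f"wrapped interval {start}-{end} on linear genome {self.id}")
        return len(self) - start + 1 + end

    def interval_positions(self, start: int, end: int) -> list[int]:
        """1-based genome positions covered by an interval, in 5'->3' forward order."""
        n = len(self)
        if not (1 <= start <= n and 1 <= end <= n):
            raise GenomeModelError(
                f"genome {self.id}: interval {start}-{end} outside [1, {n}]"
            )
        if start <= end:
            return list(range(start, end + 1))
        if self.topology != "circular":
            raise GenomeModelError(f"wrapped interval {start}-{end} on linear genome {self.id}")
        return list(range(start, n + 1)) + list(range(1, end + 1))

    def extract(self, start: int, end: int) -> str:
        """Forward-strand sequence of an interval, handling origin wrap."""
        n = len(self)
        if not (1 <= start <= n and 1 <= end <= n):
            raise GenomeModelError(
                f"genome {self.id}: interval {start}-{end} outside [1, {n}]"
            )
        if start <= end:
            return self.sequence[start - 1 : end]
        if self.topology != "circular":
            raise GenomeModelError(f"wrapped interval {start}-{end} on linear genome {self.id}")
        return self.sequence[start - 1 :] + self.sequence[:end]

    # -- feature access -----------------------------------------------------

    def get_features(self, name: str | None = None, ftype: str | None = None) -> list[Feature]:
        out = self.features
        if name is not None:
            out = [f for f in out if f.name == name]
        if ftype is not None:
            out = [f for f in out if f.ftype == ftype]
        return out

    def get_feature(self, name: str) -> Feature:
        hits = self.get_features(name=name)
        if not hits:
            raise GenomeModelError(f"genome {self.id}: no feature named {name!r}")
        return hits[0]

    def validate(self) -> None:
        n = len(self)
        names = {f.name for f in self.features}
        for f in self.features:
            for s, e in f.intervals:
                if not (1 <= s <= n and 1 <= e <= n):
                    raise GenomeModelError(
                        f"genome {self.id}: feature {f.name} interval {s}-{e} outside [1, {n}]"
                    )
            if f.parent is not None and f.parent not in names:
                raise GenomeModelError(
                    f"genome {self.id}: feature {f.name} references unknown parent {f.parent!r}"
                )

    def rotated(self, offset: int) -> "AnnotatedGenome":
        """Rotate a circular genome so old position offset+1 becomes position 1."""
        if self.topology != "circular":
            raise GenomeModelError("rotation only defined for circular genomes")
        n = len(self)
        offset %= n

        def shift(p: int) -> int:
            return (p - 1 - offset) % n + 1

        feats = [
            replace(f, intervals=[(shift(s), shift(e)) for s, e in f.intervals])
            for f in self.features
        ]
        seq = self.sequence[offset:] + self.sequence[:offset]
        return AnnotatedGenome(self.id, seq, self.topology, feats)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[AnnotatedGenome]:
    """Read a (multi-)FASTA into genomes with empty feature lists.

    Sequences are uppercased; IUPAC ambiguity characters outside {A,C,G,T,N}
    are normalized to N with a warning.  Duplicate record ids and empty files
    are hard errors.
    """
    genomes: list[AnnotatedGenome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeModelError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = []
        n_fixed = 0
        for c in seq:
            if c in "ACGTN":
                cleaned.append(c)
            else:
                cleaned.append("N")
                n_fixed += 1
        if n_fixed:
            warnings.warn(
                f"{rec.id}: {n_fixed} non-ACGTN characters normalized to N", stacklevel=2
            )
        genomes.append(AnnotatedGenome(rec.id, "".join(cleaned)))
    if not genomes:
        raise GenomeModelError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes, path, width: int = 70) -> None:
    if isinstance(genomes, AnnotatedGenome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank

_GB_TYPE_MAP = {"CDS": "PCG", "rRNA": "rRNA", "tRNA": "tRNA", "intron": "intron"}


def _trna_name_from_product(product: str, anticodon: str | None) -> str:
    # "tRNA-Met" -> trnM; anticodon appended lowercased when known, e.g. trnM(cat)
    aa3 = product.replace("tRNA-", "").strip()
    one = _AA3_TO_1.get(aa3.capitalize(), "X")
    if anticodon:
        return f"trn{one}({anticodon.lower()})"
    return f"trn{one}"


def read_genbank(path) -> AnnotatedGenome:
    """Read one GenBank flat file record into an AnnotatedGenome.

    ``join(...)`` locations become interval lists, ``complement(...)`` sets
    strand '-', and circular topology is taken from the LOCUS line.  CDS
    features map to PCG; rRNA/tRNA/intron keep their type.
    """
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "linear")
    n = len(rec.seq)
    feats: list[Feature] = []
    for gbf in rec.features:
        ftype = _GB_TYPE_MAP.get(gbf.type)
        if ftype is None:
            continue
        strand = "-" if gbf.location.strand == -1 else "+"
        parts = sorted(gbf.location.parts, key=lambda p: int(p.start))
        intervals = [(int(p.start) + 1, int(p.end)) for p in parts]
        for s, e in intervals:
            if e > n or s > n:
                raise GenomeModelError(f"{path}: feature coordinates {s}-{e} beyond length {n}")
        if strand == "-":
            intervals = intervals[::-1]  # 5'->3' on coding strand
        quals = gbf.qualifiers
        name = (quals.get("gene") or quals.get("label") or [None])[0]
        anticodon = None
        if ftype == "tRNA":
            product = (quals.get("product") or [""])[0]
            ac = quals.get("anticodon")
            if ac:
                raw = ac[0]
                anticodon = raw.split("seq:")[-1].rstrip(")").lower() if "seq:" in raw else raw.lower()
            if product.startswith("tRNA-"):
                name = _trna_name_from_product(product, anticodon)
        if name is None:
            name = (quals.get("product") or [f"{ftype}_{len(feats)}"])[0]
        parent = (quals.get("note") or [None])[0] if ftype == "intron" else None
        if ftype == "intron" and parent is None:
            parent = (quals.get("gene") or ["unknown"])[0]
        feats.append(Feature(name, ftype, strand, intervals, parent=parent))
    genome = AnnotatedGenome(rec.id, str(rec.seq).upper(), topology, feats)
    return genome


# ---------------------------------------------------------------------------
# FeatureTable (tab-separated serialization)

_TABLE_COLUMNS = ("genome_id", "name", "ftype", "strand", "intervals", "parent", "anticodon")


def _format_intervals(intervals) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def _parse_intervals(text: str, lineno: int):
    out = []
    for chunk in text.split(";"):
        parts = chunk.split("-")
        if len(parts) != 2:
            raise GenomeModelError(f"line {lineno}: malformed interval {chunk!r}")
        try:
            out.append((int(parts[0]), int(parts[1])))
        except ValueError as exc:
            raise GenomeModelError(f"line {lineno}: malformed interval {chunk!r}") from exc
    return out


def write_feature_table(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        f.name,
                        f.ftype,
                        f.strand,
                        _format_intervals(f.intervals),
                        f.parent or ".",
                        f.anticodon or ".",
                    ]
                )
                + "\n"
            )


def read_feature_table(path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Attach features from a feature table to a sequence-only genome.

    Returns a new AnnotatedGenome; round-trips write_feature_table output
    field-for-field.
    """
    feats: list[Feature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_TABLE_COLUMNS):
            raise GenomeModelError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(_TABLE_COLUMNS):
                raise GenomeModelError(f"line {lineno}: expected {len(_TABLE_COLUMNS)} columns")
            gid, name, ftype, strand, ivals, parent, anticodon = cols
            if gid != genome.id:
                continue
            feats.append(
                Feature(
                    name,
                    ftype,
                    strand,
                    _parse_intervals(ivals, lineno),
                    parent=None if parent == "." else parent,
                    anticodon=None if anticodon == "." else anticodon,
                )
            )
    out = AnnotatedGenome(genome.id, genome.sequence, genome.topology, feats)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Sequence extraction


def coding_sequence(genome: AnnotatedGenome, gene_name: str) -> str:
    """Spliced coding-strand sequence of a gene (exons concatenated 5'->3').

    For minus-strand genes each exon is reverse-complemented; exons are
    assumed stored 5'->3' on the coding strand.
    """
    feat = genome.get_feature(gene_name)
    parts = []
    for s, e in feat.intervals:
        piece = genome.extract(s, e)
        if feat.strand == "-":
            piece = reverse_complement(piece)
        parts.append(piece)
    return "".join(parts)


def gene_span_sequence(genome: AnnotatedGenome, gene_name: str) -> str:
    """Unspliced genomic span of a gene on its coding strand (introns included)."""
    feat = genome.get_feature(gene_name)
    s, e = feat.span()
    seq = genome.extract(s, e)
    return reverse_complement(seq) if feat.strand == "-" else seq
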