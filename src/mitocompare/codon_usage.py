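"""Translation and codon-usage statistics under the mold mitochondrial code.

Fungal mitochondrial protein genes use NCBI translation table 4, in which
TGA encodes tryptophan and only TAA/TAG terminate.  Start codons other than
ATG (GTG, TTG) occur in real mitogenomes and are reported, not rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from .genome_model import AnnotatedGenome, coding_sequence

_TABLE4 = CodonTable.unambiguous_dna_by_id[4]

#: codon -> one-letter amino acid under translation table 4 (stops excluded)
CODE4: dict[str, str] = {c.replace("U", "T"): aa for c, aa in _TABLE4.forward_table.items()}
STOP_CODONS = frozenset(c.replace("U", "T") for c in _TABLE4.stop_codons)
START_CANDIDATES = frozenset({"ATG", "GTG", "TTG"})

#: synonymous families: amino acid -> tuple of codons, table 4
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODE4.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)


class TranslationError(ValueError):
    pass


class InternalStopError(TranslationError):
    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon {codon} at codon {codon_index + 1}")


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate(cds: str) -> str:
    """Translate a CDS under code 4; a trailing stop is dropped.

    Raises :class:`InternalStopError` (with position) on a premature stop and
    :class:`TranslationError` when the length is not a codon multiple.
    """
    cods = codons_of(cds.upper())
    if cods and cods[-1] in STOP_CODONS:
        cods = cods[:-1]
    protein = []
    for i, cod in enumerate(cods):
        if cod in STOP_CODONS:
            raise InternalStopError(i, cod)
        protein.append(CODE4.get(cod, "X"))
    return "".join(protein)


@dataclass
class StartStopRecord:
    gene: str
    start_codon: str
    stop_codon: str
    start_flagged: bool
    stop_flagged: bool


def start_stop_codons(genome: AnnotatedGenome, genes: list[str] | None = None) -> list[StartStopRecord]:
    """First and last codon of each protein gene, with plausibility flags.

    A record is flagged when the start is outside {ATG, GTG, TTG} or the
    stop outside {TAA, TAG}; flagged genes are reported, never dropped.
    """
    if genes is None:
        genes = [f.name for f in genome.get_features(ftype="PCG")]
    out = []
    for gene in genes:
        cds = coding_sequence(genome, gene)
        if len(cds) < 6:
            raise TranslationError(f"{gene}: CDS shorter than 6 nt")
        start, stop = cds[:3], cds[-3:]
        out.append(
            StartStopRecord(
                gene,
                start,
                stop,
                start not in START_CANDIDATES,
                stop not in STOP_CODONS,
            )
        )
    return out


def codon_usage(
    genome: AnnotatedGenome,
    genes: list[str] | None = None,
    include_stops: bool = False,
) -> pd.DataFrame:
    """Codon counts, frequencies and RSCU over a gene subset.

    Genes whose CDS length is not a codon multiple are excluded with a
    warning column in mind; by default stop codons do not enter the counts.
    RSCU for codon c is count(c) divided by the mean count over c's
    synonymous family.

    Returns a DataFrame with columns codon, amino_acid, count, frequency,
    rscu (empty for an empty gene subset).
    """
    if genes is None:
        genes = [f.name for f in genome.get_features(ftype="PCG")]
    counts: Counter[str] = Counter()
    for gene in genes:
        cds = coding_sequence(genome, gene)
        if len(cds) % 3 != 0:
            import warnings

            warnings.warn(f"{genome.id}:{gene} length {len(cds)} not divisible by 3; excluded")
            continue
        for cod in codons_of(cds):
            if cod in STOP_CODONS and not include_stops:
                continue
            if set(cod) <= set("ACGT"):
                counts[cod] += 1
    rows = []
    total = sum(counts.values())
    for aa, family in sorted(SYNONYMOUS_FAMILIES.items()):
        fam_counts = [counts.get(c, 0) for c in family]
        fam_mean = sum(fam_counts) / len(family)
        for cod in family:
            c = counts.get(cod, 0)
            rows.append(
                {
                    "codon": cod,
                    "amino_acid": aa,
                    "count": c,
                    "frequency": c / total if total else 0.0,
                    "rscu": c / fam_mean if fam_mean > 0 else 0.0,
                }
            )
    if include_stops:
        for cod in sorted(STOP_CODONS):
            c = counts.get(cod, 0)
            rows.append(
                {
                    "codon": cod,
                    "amino_acid": "*",
                    "count": c,
                    "frequency": c / total if total else 0.0,
                    "rscu": float("nan"),
                }
            )
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "frequency", "rscu"])
    if not genes:
        return df.iloc[0:0]
    return df
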