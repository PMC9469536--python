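"""Intron position-class (Pcl) classification.

Mitochondrial introns of a host gene are labelled by the number of coding
nucleotides 5' of their insertion point, mapped onto a common reference
coding sequence through pairwise alignment.  Introns of different genomes
mapping to the same reference position form one position class ("P<pos>"),
the standard operational definition of intron orthology in fungal
mitogenomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_model import AnnotatedGenome, GenomeModelError, coding_sequence
from .seqevol import align_pair


@dataclass
class IntronRecord:
    genome_id: str
    host: str
    ordinal: int           # 1-based, 5'->3' within the host
    position: int          # coding nt 5' of the intron, 0..len(cds)
    group: str = "unknown"
    orf: str | None = None


@dataclass
class Pcl:
    name: str
    position: int          # position in the reference coding sequence
    members: list[tuple[str, str, int]] = field(default_factory=list)  # (genome, host, ordinal)
    group: str = "unknown"
    gap_flagged: bool = False


def intron_positions(genome: AnnotatedGenome, host: str) -> list[IntronRecord]:
    """Insertion positions of a host gene's introns, 5'->3' on the coding strand.

    position_k = cumulative exon length 5' of intron k.  An intron whose
    interval is not flanked by two host exons is an error.
    """
    gene = genome.get_feature(host)
    introns = [f for f in genome.features if f.ftype == "intron" and f.parent == host]
    if not introns:
        return []
    # exon boundaries in genomic order; assume non-wrapping loci
    exons = sorted(gene.intervals)
    intr_sorted = sorted(introns, key=lambda f: f.intervals[0][0])
    # map genomic gap between consecutive exons -> cumulative coding length
    gaps = []
    for i in range(len(exons) - 1):
        gaps.append((exons[i][1], exons[i + 1][0]))  # (end of exon i, start of exon i+1)
    records = []
    for intr in intr_sorted:
        s, e = min(a for a, _ in intr.intervals), max(b for _, b in intr.intervals)
        slot = None
        for i, (ge, gs) in enumerate(gaps):
            if ge < s and e < gs:
                slot = i
                break
        if slot is None:
            raise GenomeModelError(
                f"{genome.id}: intron {intr.name} not flanked by exons of {host}"
            )
        if gene.strand == "+":
            cumulative = sum(b - a + 1 for a, b in exons[: slot + 1])
        else:
            cumulative = sum(b - a + 1 for a, b in exons[slot + 1 :])
        records.append(IntronRecord(genome.id, host, 0, cumulative, _group_label(intr)))
    if gene.strand == "-":
        records = records[::-1]
    for k, rec in enumerate(records, start=1):
        rec.ordinal = k
    return records


def _group_label(intron_feature) -> str:
    # group labels are annotation inputs; encoded in the anticodon-free slot
    # of the feature table as part of the name ("...@II") when present
    if "@" in intron_feature.name:
        return intron_feature.name.rsplit("@", 1)[1]
    return "unknown"


def map_to_reference(query_cds: str, reference_cds: str, query_position: int) -> tuple[int, bool]:
    """Map an insertion point in the query CDS onto the reference CDS.

    Returns (reference position, gap_flag): the count of reference bases
    strictly 5' of the alignment column holding the insertion point.  An
    insertion point inside a reference gap maps to the nearest reference
    position 5' of the gap, with the flag set.
    """
    if not 0 <= query_position <= len(query_cds):
        raise ValueError(f"position {query_position} outside [0, {len(query_cds)}]")
    aln = align_pair(query_cds, reference_cds)
    q_count = r_count = 0
    flagged = False
    cols = list(aln.columns())
    for idx, (qc, rc) in enumerate(cols):
        if q_count == query_position:
            # insertion point reached; flag if it sits inside a reference gap
            if rc == "-" and qc != "-":
                flagged = True
            break
        if qc != "-":
            q_count += 1
        if rc != "-":
            r_count += 1
    return r_count, flagged


def classify_pcls(
    records: dict[str, list[IntronRecord]],
    cds_by_genome: dict[str, str],
    reference_cds: str,
) -> tuple[list[Pcl], pd.DataFrame]:
    """Group intron records from several genomes into position classes.

    ``records`` maps genome id -> IntronRecords of the (homologous) host
    gene; ``cds_by_genome`` supplies each genome's host coding sequence.
    Returns the Pcl list and a presence/absence matrix (Pcls x genomes).
    """
    classes: dict[int, Pcl] = {}
    genome_ids = sorted(records)
    for gid in genome_ids:
        cds = cds_by_genome[gid]
        for rec in records[gid]:
            ref_pos, flagged = map_to_reference(cds, reference_cds, rec.position)
            pcl = classes.setdefault(ref_pos, Pcl(f"P{ref_pos}", ref_pos))
            pcl.members.append((gid, rec.host, rec.ordinal))
            pcl.gap_flagged |= flagged
            if pcl.group == "unknown" and rec.group != "unknown":
                pcl.group = rec.group
    pcls = [classes[p] for p in sorted(classes)]
    matrix = pd.DataFrame(
        {
            gid: [any(m[0] == gid for m in pcl.members) for pcl in pcls]
            for gid in genome_ids
        },
        index=[pcl.name for pcl in pcls],
    )
    return pcls, matrix


def classify_host_gene(
    genomes: list[AnnotatedGenome], host: str, reference_cds: str
) -> tuple[list[Pcl], pd.DataFrame]:
    """Convenience wrapper: collect records and CDSs, then classify."""
    records = {}
    cds_by_genome = {}
    for g in genomes:
        if not g.get_features(name=host):
            continue
        records[g.id] = intron_positions(g, host)
        cds_by_genome[g.id] = coding_sequence(g, host)
    return classify_pcls(records, cds_by_genome, reference_cds)


def pcl_sharing_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-Pcl genome counts plus the private (single-genome) flag.

    Returns a DataFrame indexed by Pcl with columns n_genomes, private,
    private_to (genome id or None).
    """
    if matrix.empty:
        return pd.DataFrame(columns=["n_genomes", "private", "private_to"])
    counts = matrix.sum(axis=1).astype(int)
    private = counts == 1
    private_to = [
        matrix.columns[matrix.loc[idx].values.argmax()] if private[idx] else None
        for idx in matrix.index
    ]
    return pd.DataFrame(
        {"n_genomes": counts, "private": private, "private_to": private_to},
        index=matrix.index,
    )
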