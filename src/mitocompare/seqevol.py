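"""Pairwise alignment, K2P distances, Nei-Gojobori Ka/Ks, neighbor joining.

The K2P model separates transition (P) and transversion (Q) proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Ka/Ks follows the NG86 counting approach under translation table 4: per-codon
synonymous/nonsynonymous site fractions from the three single-nucleotide
neighbors of each position (changes creating a stop codon are inadmissible),
observed differences averaged uniformly over all stop-free minimal mutational
pathways, and a Jukes-Cantor correction applied to pN and pS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio import Align

from .codon_usage import CODE4, STOP_CODONS, codons_of, translate
from .genome_model import AnnotatedGenome, coding_sequence

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = "ACGT"


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


# ---------------------------------------------------------------------------
# Pairwise global alignment


@dataclass
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0   # cost of the first base of a gap
    gap_extend: float = -0.5


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


def align_pair(seq_a: str, seq_b: str, scoring: Scoring | None = None) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (deterministic traceback)."""
    if not seq_a or not seq_b:
        raise ValueError("align_pair requires non-empty sequences")
    scoring = scoring or Scoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return PairwiseAlignment(a, b, float(aln.score), scoring)


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance


@dataclass
class K2PResult:
    P: float
    Q: float
    d: float
    sites_used: int
    undefined: bool = False


def k2p(alignment: PairwiseAlignment) -> K2PResult:
    """K2P distance from an alignment; gap and N columns are excluded."""
    ts = tv = sites = 0
    for x, y in alignment.columns():
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if sites == 0:
        return K2PResult(0.0, 0.0, float("nan"), 0, undefined=True)
    P, Q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P, Q, float("nan"), sites, undefined=True)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P, Q, d, sites)


def k2p_from_counts(transitions: int, transversions: int, sites: int) -> K2PResult:
    """K2P directly from substitution counts (convenience for simulations)."""
    fake_a = "A" * sites
    # build a minimal alignment with the requested difference counts
    b = ["A"] * sites
    for i in range(transitions):
        b[i] = "G"
    for i in range(transitions, transitions + transversions):
        b[i] = "C"
    return k2p(PairwiseAlignment(fake_a, "".join(b), 0.0))


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@dataclass
class KaKsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    ratio: float
    codons_compared: int
    undefined: bool = False  # Ks == 0 or a JC correction out of range


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes 1 site split by the fraction of synonymous
    changes among its admissible (non-stop-creating) single-nt neighbors.
    """
    if codon in STOP_CODONS or "N" in codon:
        return 0.0, 0.0
    aa = CODE4[codon]
    s = 0.0
    for i in range(3):
        syn = admissible = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            admissible += 1
            if CODE4[alt] == aa:
                syn += 1
        s += syn / admissible if admissible else 0.0
    return s, 3.0 - s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    excluded the average falls back to all pathways.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = non = 0
        cur = codon_a
        hit_stop = False
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
                syn_step = CODE4.get(cur, "?") == CODE4.get(nxt, "!")
            else:
                syn_step = CODE4[cur] == CODE4[nxt] if cur not in STOP_CODONS else False
            if syn_step:
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non, hit_stop

    clean, dirty = [], []
    for order in permutations(diff_pos):
        syn, non, hit_stop = walk(order)
        (dirty if hit_stop else clean).append((syn, non))
    pool = clean if clean else dirty
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def _jc_correct(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * math.log(arg)


def nei_gojobori(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks for an aligned CDS pair (gapped codons excluded).

    Inputs are the two rows of a codon-aware alignment (equal length,
    divisible by 3, '-' for gaps).  Internal stop codons raise ValueError.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    cod_a, cod_b = codons_of(cds_a.upper()), codons_of(cds_b.upper())
    N = S = Nd = Sd = 0.0
    compared = 0
    for ca, cb in zip(cod_a, cod_b):
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in compared region: {ca}/{cb}")
        compared += 1
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    Ka, Ks = _jc_correct(pN), _jc_correct(pS)
    undefined = math.isnan(Ka) or math.isnan(Ks) or Ks == 0
    ratio = Ka / Ks if (not undefined and Ks > 0) else float("nan")
    return KaKsResult(N, S, Nd, Sd, pN, pS, Ka, Ks, ratio, compared, undefined)


def codon_align(cds_a: str, cds_b: str, scoring: Scoring | None = None) -> tuple[str, str]:
    """Codon-aware alignment of two CDSs via their protein alignment.

    Trailing stop codons are removed before translating; the returned rows
    have equal length divisible by 3 with '---' gaps.
    """
    def strip_stop(cds):
        return cds[:-3] if len(cds) >= 3 and cds[-3:] in STOP_CODONS else cds

    a, b = strip_stop(cds_a.upper()), strip_stop(cds_b.upper())
    prot_a, prot_b = translate(a + "TAA"), translate(b + "TAA")
    aln = align_pair(prot_a, prot_b, scoring)
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in aln.columns():
        if x == "-":
            out_a.append("---")
        else:
            out_a.append(a[3 * ia : 3 * ia + 3])
            ia += 1
        if y == "-":
            out_b.append("---")
        else:
            out_b.append(b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Per-gene statistics across a genome set


def per_gene_stats(genomes: list[AnnotatedGenome], genes: list[str]) -> "pd.DataFrame":
    """Per-gene length/composition plus mean pairwise K2P, Ka, Ks, Ka/Ks.

    Means are unweighted over all genome pairs sharing the gene; genes absent
    from every genome are omitted with a warning.  Undefined pairs flag the
    gene but do not enter the mean.
    """
    import warnings

    import pandas as pd

    from .composition import composition_stats

    rows = []
    for gene in genes:
        carriers = [g for g in genomes if g.get_features(name=gene)]
        if not carriers:
            warnings.warn(f"gene {gene} absent from all genomes; omitted")
            continue
        cdss = {g.id: coding_sequence(g, gene) for g in carriers}
        lengths = [len(c) for c in cdss.values()]
        stats = [composition_stats(c) for c in cdss.values()]
        k2ps, kas, kss, ratios = [], [], [], []
        flagged = False
        ids = sorted(cdss)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                aln_a, aln_b = codon_align(cdss[ids[i]], cdss[ids[j]])
                res_k = k2p(PairwiseAlignment(aln_a, aln_b, 0.0))
                res_ng = nei_gojobori(aln_a, aln_b)
                if res_k.undefined or res_ng.undefined:
                    flagged = True
                if not res_k.undefined:
                    k2ps.append(res_k.d)
                if not math.isnan(res_ng.Ka):
                    kas.append(res_ng.Ka)
                if not math.isnan(res_ng.Ks):
                    kss.append(res_ng.Ks)
                if not math.isnan(res_ng.ratio):
                    ratios.append(res_ng.ratio)
        rows.append(
            {
                "gene": gene,
                "n_genomes": len(carriers),
                "mean_length": float(np.mean(lengths)),
                "mean_gc_percent": float(np.mean([s.gc_percent for s in stats])),
                "mean_at_skew": float(np.mean([s.at_skew for s in stats])),
                "mean_gc_skew": float(np.mean([s.gc_skew for s in stats])),
                "mean_k2p": float(np.mean(k2ps)) if k2ps else 0.0,
                "mean_ka": float(np.mean(kas)) if kas else 0.0,
                "mean_ks": float(np.mean(kss)) if kss else 0.0,
                "mean_ka_ks": float(np.mean(ratios)) if ratios else float("nan"),
                "any_pair_undefined": flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance matrix + neighbor joining


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        self.matrix = m

    def to_phylip(self) -> str:
        lines = [f"{len(self.ids)}"]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{self.matrix[i, j]:.6f}" for j in range(len(self.ids)))
            lines.append(f"{name}  {row}")
        return "\n".join(lines) + "\n"


def concatenated_distance_matrix(genomes: list[AnnotatedGenome], genes: list[str]) -> DistanceMatrix:
    """K2P distance matrix on the concatenation of genes present in all genomes.

    Genes missing from any genome are excluded; gene order is the sorted gene
    list, fixed for reproducibility.
    """
    shared = [
        g for g in sorted(genes) if all(gen.get_features(name=g) for gen in genomes)
    ]
    if not shared:
        raise ValueError("no gene shared by all genomes")
    ids = [g.id for g in genomes]
    n = len(ids)
    mat = np.zeros((n, n))
    undefined_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            total_ts = total_tv = total_sites = 0
            for gene in shared:
                aln = align_pair(
                    coding_sequence(genomes[i], gene), coding_sequence(genomes[j], gene)
                )
                for x, y in aln.columns():
                    if x in "-N" or y in "-N":
                        continue
                    total_sites += 1
                    if x != y:
                        if is_transition(x, y):
                            total_ts += 1
                        else:
                            total_tv += 1
            res = k2p_from_counts(total_ts, total_tv, total_sites)
            if res.undefined:
                undefined_pairs.append((ids[i], ids[j]))
            mat[i, j] = mat[j, i] = res.d
    if undefined_pairs:
        raise ValueError(f"undefined distances for pairs: {undefined_pairs}")
    return DistanceMatrix(ids, mat)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Ties in the Q criterion are broken by taxon id order; negative branch
    lengths are clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.isnan(dm.matrix).any() or np.isinf(dm.matrix).any():
        bad = [
            (dm.ids[i], dm.ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not np.isfinite(dm.matrix[i, j])
        ]
        raise ValueError(f"undefined distances for pairs: {bad}")

    labels = list(dm.ids)
    d = {
        (a, b): dm.matrix[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    newick = {name: name for name in labels}
    active = sorted(labels)

    def dist(a, b):
        return d[(a, b)]

    node_counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ia in range(m):
            for ib in range(ia + 1, m):
                a, b = active[ia], active[ib]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        da = 0.5 * dist(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        db = dist(a, b) - da
        da, db = max(da, 0.0), max(db, 0.0)
        node_counter += 1
        new = f"__node{node_counter}"
        newick[new] = f"({newick[a]}:{da:.6f},{newick[b]}:{db:.6f})"
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
            d[(new, c)] = d[(c, new)] = max(dn, 0.0)
        d[(new, new)] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [new])
    # final trifurcating join of the last three nodes (unrooted convention)
    a, b, c = active
    la = max(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)), 0.0)
    lb = max(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)), 0.0)
    lc = max(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)), 0.0)
    return f"({newick[a]}:{la:.6f},{newick[b]}:{lb:.6f},{newick[c]}:{lc:.6f});"
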