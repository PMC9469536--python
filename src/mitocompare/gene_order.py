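"""Circular gene-arrangement comparison.

Gene orders are circular, stranded lists; two orders compare equal under
rotation, and reflection (reading the other strand) is considered when
searching for the conserved backbone.  The backbone is the longest common
circular subsequence of the shared single-copy genes, computed exactly by
linearizing one order at every rotation — cheap at mitogenome scale
(<= ~60 genes).  Genes outside the backbone are displaced; genes with a
higher copy number in one genome are doubling events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome_model import AnnotatedGenome

DEFAULT_INCLUDE = ("PCG", "rRNA", "tRNA")


@dataclass
class GeneOrder:
    genome_id: str
    entries: list[tuple[str, str]]  # (gene name, strand) in circular order

    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def copy_numbers(self) -> Counter:
        return Counter(self.names())

    def single_copy(self) -> set[str]:
        return {n for n, c in self.copy_numbers().items() if c == 1}

    def restricted(self, keep: set[str]) -> list[tuple[str, str]]:
        return [(n, s) for n, s in self.entries if n in keep]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return circular_equal(self.entries, other.entries)


def circular_equal(a: list[tuple[str, str]], b: list[tuple[str, str]]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    for r in range(len(b)):
        if a == b[r:] + b[:r]:
            return True
    return False


def extract_order(genome: AnnotatedGenome, include: tuple[str, ...] = DEFAULT_INCLUDE) -> GeneOrder:
    """Genes of the included types in circular genome order.

    Features are sorted by the start of their span; duplicates are retained
    (copy numbers are visible through :meth:`GeneOrder.copy_numbers`).
    """
    feats = [f for f in genome.features if f.ftype in include]
    feats.sort(key=lambda f: min(s for s, _ in f.intervals))
    return GeneOrder(genome.id, [(f.name, f.strand) for f in feats])


@dataclass
class RearrangementReport:
    backbone: list[tuple[str, str]]
    displaced: set[str]
    doubled_in_a: set[str]
    doubled_in_b: set[str]
    private_to_a: set[str]
    private_to_b: set[str]
    reflected: bool = False


def _lcs(a: list, b: list) -> list:
    """Classic O(nm) longest common subsequence of two element lists."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    out = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            out.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def _strand_flips(entries: list[tuple[str, str]]) -> int:
    return sum(1 for i in range(1, len(entries)) if entries[i][1] != entries[i - 1][1])


def _reflect(entries: list[tuple[str, str]]) -> list[tuple[str, str]]:
    flip = {"+": "-", "-": "+"}
    return [(n, flip[s]) for n, s in reversed(entries)]


def compare_orders(order_a: GeneOrder, order_b: GeneOrder) -> RearrangementReport:
    """Backbone, displaced, doubled and private genes between two orders.

    The backbone is the longest common circular subsequence over shared
    single-copy genes, considering every rotation and the reflection of B;
    ties are broken by fewer strand flips, then lexicographically.
    """
    names_a, names_b = set(order_a.names()), set(order_b.names())
    shared = names_a & names_b
    if not shared:
        raise ValueError(f"no shared genes between {order_a.genome_id} and {order_b.genome_id}")
    shared_single = order_a.single_copy() & order_b.single_copy() & shared

    a = order_a.restricted(shared_single)
    best: tuple[int, int, tuple, bool, list] | None = None
    for reflected in (False, True):
        b_full = _reflect(order_b.restricted(shared_single)) if reflected else order_b.restricted(shared_single)
        for r in range(max(len(b_full), 1)):
            b = b_full[r:] + b_full[:r]
            cand = _lcs(a, b)
            key = (-len(cand), _strand_flips(cand), tuple(cand), reflected)
            if best is None or key < (best[0], best[1], best[2], best[3]):
                best = (-len(cand), _strand_flips(cand), tuple(cand), reflected, cand)
    backbone = best[4] if best else []
    backbone_names = {n for n, _ in backbone}
    cn_a, cn_b = order_a.copy_numbers(), order_b.copy_numbers()
    return RearrangementReport(
        backbone=backbone,
        displaced=shared_single - backbone_names,
        doubled_in_a={n for n in shared | names_a if cn_a[n] >= 2 and cn_a[n] > cn_b[n]},
        doubled_in_b={n for n in shared | names_b if cn_b[n] >= 2 and cn_b[n] > cn_a[n]},
        private_to_a=names_a - names_b,
        private_to_b=names_b - names_a,
        reflected=best[3] if best else False,
    )


def multi_order_summary(orders: list[GeneOrder]) -> dict[str, str]:
    """Per-gene conservation class across several genomes.

    Classes: ``identical-in-all`` (every order circularly identical over the
    shared single-copy genes), ``identical-in-majority`` (gene in place in
    more than half the genomes), ``displaced``, ``doubled``.
    """
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    all_names = set().union(*(set(o.names()) for o in orders))
    shared_single = set.intersection(*(o.single_copy() for o in orders)) & set.intersection(
        *(set(o.names()) for o in orders)
    )
    # consensus = most common circular arrangement of shared single-copy genes
    groups: list[list[GeneOrder]] = []
    for o in orders:
        for grp in groups:
            if circular_equal(o.restricted(shared_single), grp[0].restricted(shared_single)):
                grp.append(o)
                break
        else:
            groups.append([o])
    groups.sort(key=lambda grp: (-len(grp), grp[0].genome_id))
    consensus = groups[0][0]
    all_identical = len(groups) == 1

    classes: dict[str, str] = {}
    in_place_counts: dict[str, int] = {g: 0 for g in shared_single}
    for o in orders:
        if o is consensus or circular_equal(o.restricted(shared_single), consensus.restricted(shared_single)):
            for g in shared_single:
                in_place_counts[g] += 1
            continue
        rep = compare_orders(consensus, o)
        placed = {n for n, _ in rep.backbone}
        for g in shared_single:
            if g in placed:
                in_place_counts[g] += 1
    for gene in sorted(all_names):
        if any(o.copy_numbers()[gene] >= 2 for o in orders):
            classes[gene] = "doubled"
        elif gene not in shared_single:
            classes[gene] = "displaced" if all(gene in o.names() for o in orders) else "private"
        elif all_identical:
            classes[gene] = "identical-in-all"
        elif in_place_counts[gene] == len(orders):
            classes[gene] = "identical-in-majority"
        else:
            classes[gene] = "displaced"
    return classes
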