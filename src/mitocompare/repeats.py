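"""Repeat and shared-fragment detection.

Interspersed repeats are found by comparing a genome against itself with an
exact k-mer seed, diagonal chaining, and ungapped X-drop extension — a
desk-scale analogue of a self-BLASTN search.  The tandem detector scans
period offsets directly.  The same seed-and-extend engine drives the search
for fragments shared between a mitochondrial and a nuclear sequence set
(NUMT-like transfers).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import reverse_complement


@dataclass
class RepeatHit:
    start_a: int  # 1-based inclusive
    end_a: int
    start_b: int
    end_b: int
    strand: str   # '+' direct, '-' inverted copy
    length: int
    identity: float  # percent

    def intervals(self):
        return (self.start_a, self.end_a), (self.start_b, self.end_b)


@dataclass
class TandemRepeat:
    start: int       # 1-based
    period: int
    copies: float
    span: int
    consensus: str
    match_fraction: float


@dataclass
class SharedFragment:
    mito_start: int
    mito_end: int
    target_id: str
    target_start: int
    target_end: int
    length: int
    identity: float


# ---------------------------------------------------------------------------
# seed-and-extend engine (ungapped)


def _seeds(seq_a: str, seq_b: str, k: int):
    """Diagonal-keyed exact k-mer seed positions between two sequences."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        index.setdefault(seq_a[i : i + k], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        for i in index.get(seq_b[j : j + k], ()):
            diagonals.setdefault(i - j, []).append(i)
    return diagonals


def _extend_on_diagonal(seq_a: str, seq_b: str, diag: int, seed_i: int, k: int, xdrop: float):
    """Ungapped X-drop extension around one seed; returns (ia, ja, length, matches)."""
    j0 = seed_i - diag
    # extend right
    score = best = k
    i, best_end = seed_i + k, seed_i + k
    while i < len(seq_a) and i - diag < len(seq_b):
        score += 1.0 if seq_a[i] == seq_b[i - diag] else -2.0
        if score > best:
            best, best_end = score, i + 1
        if best - score > xdrop:
            break
        i += 1
    # extend left
    score = best
    i, best_start = seed_i - 1, seed_i
    local_best = score
    while i >= 0 and i - diag >= 0:
        score += 1.0 if seq_a[i] == seq_b[i - diag] else -2.0
        if score > local_best:
            local_best, best_start = score, i
        if local_best - score > xdrop:
            break
        i -= 1
    length = best_end - best_start
    matches = sum(
        1 for p in range(best_start, best_end) if seq_a[p] == seq_b[p - diag]
    )
    return best_start, best_start - diag, length, matches


def _window_hits(seq_a: str, seq_b: str, ia: int, ja: int, length: int, min_len: int, min_identity: float):
    """Qualify an extended window, or fall back to its maximal exact runs.

    The fallback keeps hits whose exact core passes both thresholds even
    when mismatches elsewhere in the window dilute its overall identity.
    """
    win = [seq_a[ia + t] == seq_b[ja + t] for t in range(length)]
    matches = sum(win)
    if length >= min_len and 100.0 * matches / length >= min_identity:
        return [(ia, ja, length, 100.0 * matches / length)]
    runs = []
    t = 0
    while t < length:
        if win[t]:
            u = t
            while u < length and win[u]:
                u += 1
            if u - t >= min_len:
                runs.append((ia + t, ja + t, u - t, 100.0))
            t = u
        else:
            t += 1
    return runs


def _ungapped_hits(seq_a: str, seq_b: str, k: int, min_len: int, min_identity: float, xdrop: float = 20.0):
    """Maximal ungapped local matches between two sequences (forward strands)."""
    hits = {}
    for diag, seed_list in _seeds(seq_a, seq_b, k).items():
        covered_until = -1
        for seed_i in sorted(seed_list):
            if seed_i < covered_until:
                continue
            ia, ja, length, _ = _extend_on_diagonal(seq_a, seq_b, diag, seed_i, k, xdrop)
            covered_until = ia + length
            for hi, hj, hlen, hident in _window_hits(seq_a, seq_b, ia, ja, length, min_len, min_identity):
                key = (diag, hi)
                if key not in hits or hits[key][2] < hlen:
                    hits[key] = (hi, hj, hlen, hident)
    return list(hits.values())


# ---------------------------------------------------------------------------
# interspersed repeats (self-comparison)


def find_interspersed_repeats(
    sequence: str, min_len: int = 50, min_identity: float = 75.0, k: int = 12
) -> list[RepeatHit]:
    """Intra-genomic duplications of at least ``min_len`` bp.

    Both strands are searched; the trivial full-length self-match and
    symmetric (A,B)/(B,A) duplicates are removed.  Hits are sorted by
    position, deterministically.
    """
    seq = sequence.upper()
    out: list[RepeatHit] = []
    # direct repeats: self comparison, skip the main diagonal
    direct = {}
    for diag, seed_list in _seeds(seq, seq, k).items():
        if diag <= 0:
            continue  # keep one triangle; diag>0 means A downstream of B
        covered_until = -1
        for seed_i in sorted(seed_list):
            if seed_i < covered_until:
                continue
            ia, ja, length, _ = _extend_on_diagonal(seq, seq, diag, seed_i, k, 20.0)
            covered_until = ia + length
            for hi, hj, hlen, hident in _window_hits(seq, seq, ia, ja, length, min_len, min_identity):
                key = (diag, hi)
                if key not in direct or direct[key][2] < hlen:
                    direct[key] = (hi, hj, hlen, hident)
    for hi, hj, hlen, hident in direct.values():
        out.append(RepeatHit(hj + 1, hj + hlen, hi + 1, hi + hlen, "+", hlen, hident))
    # inverted repeats: genome vs its reverse complement
    rc = reverse_complement(seq)
    n = len(seq)
    seen_inverted = set()
    for ia, jb, length, identity in _ungapped_hits(seq, rc, k, min_len, min_identity):
        # map rc coordinates back to forward coordinates
        b_start = n - (jb + length) + 1  # 1-based
        b_end = n - jb
        a_start, a_end = ia + 1, ia + length
        if (b_start, b_end) == (a_start, a_end):
            continue  # palindromic self-hit
        key = tuple(sorted([(a_start, a_end), (b_start, b_end)]))
        if key in seen_inverted:
            continue
        seen_inverted.add(key)
        first, second = sorted([(a_start, a_end), (b_start, b_end)])
        out.append(RepeatHit(*first, *second, "-", length, identity))
    out.sort(key=lambda h: (h.start_a, h.start_b, h.strand))
    return out


def repeat_fraction(hits: list[RepeatHit], genome_length: int) -> float:
    """Percent of the genome covered by the union of all repeat intervals."""
    covered = set()
    for h in hits:
        for s, e in h.intervals():
            covered.update(range(s, e + 1))
    return 100.0 * len(covered) / genome_length


# ---------------------------------------------------------------------------
# tandem repeats


def find_tandem_repeats(
    sequence: str,
    max_period: int = 200,
    min_copies: float = 2.0,
    min_match: float = 0.8,
    min_score: int = 40,
) -> list[TandemRepeat]:
    """Simplified tandem-array detection by period-offset self-matching.

    For each period p the sequence is compared with itself shifted by p and
    maximal runs of agreement (merging near-adjacent match runs while the
    overall match fraction stays above ``min_match``) define candidate
    arrays.  A TRF-style alignment score (+2 per match, -7 per mismatch)
    must reach ``min_score``, which suppresses the short chance
    self-similarities a bare match-fraction criterion would report.
    Overlapping reports of different periods are deduplicated keeping the
    highest match fraction, then the longest span.
    """
    import numpy as np

    seq = sequence.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[TandemRepeat] = []
    core = 8  # minimum seed run of exact period-matches worth examining
    for p in range(1, min(max_period, n // 2) + 1):
        m = arr[: n - p] == arr[p:]
        if not m.any():
            continue
        # exact-match run boundaries
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]  # half-open runs of True
        run_lens = ends - starts
        keep = np.flatnonzero(run_lens >= core)
        used_until = -1
        for idx in keep:
            if starts[idx] < used_until:
                continue
            # merge following runs only when the merge raises the score and
            # keeps the overall match fraction above threshold
            s = starts[idx]
            e = ends[idx]
            matches = run_lens[idx]
            j = idx + 1
            while j < len(starts):
                gap = starts[j] - e
                if 2 * run_lens[j] - 7 * gap <= 0:
                    break
                new_e, new_matches = ends[j], matches + run_lens[j]
                if new_matches / (new_e - s) < min_match:
                    break
                e, matches = new_e, new_matches
                j += 1
            used_until = e
            run_len = e - s
            span = run_len + p
            copies = span / p
            mismatches = run_len - matches
            score = 2 * matches - 7 * mismatches
            frac = matches / run_len
            if copies >= min_copies and frac >= min_match and score >= min_score:
                unit = _consensus_unit(seq, int(s), p, span)
                candidates.append(
                    TandemRepeat(int(s) + 1, p, round(copies, 2), span, unit, round(frac, 4))
                )
    return _dedupe_tandem(candidates)


def _consensus_unit(seq: str, start0: int, period: int, span: int) -> str:
    from collections import Counter

    unit = []
    for off in range(period):
        col = [seq[start0 + off + c * period] for c in range(span // period) if start0 + off + c * period < start0 + span]
        unit.append(Counter(col).most_common(1)[0][0])
    return "".join(unit)


def _dedupe_tandem(candidates: list[TandemRepeat]) -> list[TandemRepeat]:
    chosen: list[TandemRepeat] = []
    for cand in sorted(candidates, key=lambda t: (-t.match_fraction, -t.span, t.period, t.start)):
        s, e = cand.start, cand.start + cand.span - 1
        redundant = False
        for kept in chosen:
            ks, ke = kept.start, kept.start + kept.span - 1
            overlap = min(e, ke) - max(s, ks) + 1
            if overlap > 0.5 * cand.span:
                redundant = True
                break
        if not redundant:
            chosen.append(cand)
    chosen.sort(key=lambda t: t.start)
    return chosen


def tandem_fraction(tandems: list[TandemRepeat], genome_length: int) -> float:
    covered = set()
    for t in tandems:
        covered.update(range(t.start, t.start + t.span))
    return 100.0 * len(covered) / genome_length


# ---------------------------------------------------------------------------
# mito vs nuclear shared fragments


def find_shared_fragments(
    mito_sequence: str,
    nuclear: dict[str, str],
    min_len: int = 100,
    min_identity: float = 75.0,
    k: int = 12,
) -> list[SharedFragment]:
    """Fragments shared between a mitogenome and a nuclear sequence set."""
    if not nuclear:
        raise ValueError("nuclear sequence set is empty")
    mito = mito_sequence.upper()
    out: list[SharedFragment] = []
    for target_id in sorted(nuclear):
        tseq = nuclear[target_id].upper()
        for ia, jb, length, identity in _ungapped_hits(mito, tseq, k, min_len, min_identity):
            out.append(
                SharedFragment(
                    ia + 1, ia + length, target_id, jb + 1, jb + length, length, round(identity, 2)
                )
            )
        rc = reverse_complement(tseq)
        nt = len(tseq)
        for ia, jb, length, identity in _ungapped_hits(mito, rc, k, min_len, min_identity):
            out.append(
                SharedFragment(
                    ia + 1, ia + length, target_id,
                    nt - (jb + length) + 1, nt - jb, length, round(identity, 2),
                )
            )
    out.sort(key=lambda f: (f.mito_start, f.target_id, f.target_start))
    return out


def total_shared_length(fragments: list[SharedFragment]) -> int:
    return sum(f.length for f in fragments)
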