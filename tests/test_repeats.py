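import numpy as np
import pytest

from mitocompare.genome_model import reverse_complement
from mitocompare.repeats import (
    find_interspersed_repeats,
    find_shared_fragments,
    find_tandem_repeats,
    repeat_fraction,
    total_shared_length,
)


def random_seq(seed, n, p=(0.3, 0.2, 0.2, 0.3)):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n, p=list(p)))


def exact_repeat_oracle(seq, min_len=50):
    """Exhaustive maximal exact repeated-substring pairs (forward strand).

    Independent of the seed-and-extend engine: collects occurrences of every
    repeated min_len-mer, extends each occurrence pair maximally, dedupes.
    """
    occ = {}
    for i in range(len(seq) - min_len + 1):
        occ.setdefault(seq[i : i + min_len], []).append(i)
    pairs = set()
    for positions in occ.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                i, j = positions[x], positions[y]
                # maximal extension
                while i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                    i, j = i - 1, j - 1
                length = min_len + (positions[y] - j)
                while i + length < len(seq) and j + length < len(seq) and seq[i + length] == seq[j + length]:
                    length += 1
                # recompute true maximal length from scratch
                L = 0
                while j + L < len(seq) and seq[i + L] == seq[j + L]:
                    L += 1
                if i != j and L >= min_len:
                    pairs.add((i + 1, i + L, j + 1, j + L))
    return pairs


class TestInterspersedRepeats:
    def test_planted_exact_duplication(self):
        # guard bases stop extension into coincidentally matching flanks
        base = random_seq(0, 10_000)
        unit = random_seq(99, 80)
        seq = base[:3000] + "A" + unit + "A" + base[3000:7000] + "C" + unit + "G" + base[7000:]
        hits = [h for h in find_interspersed_repeats(seq) if h.strand == "+"]
        assert len(hits) == 1
        h = hits[0]
        assert (h.start_a, h.end_a, h.start_b, h.end_b) == (3002, 3081, 7084, 7163)
        assert h.identity == 100.0

    def test_planted_mismatched_duplication_identity(self):
        base = random_seq(1, 8_000)
        unit = list(random_seq(98, 60))
        copy = unit.copy()
        for i in (10, 30, 50):
            copy[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[i]]
        seq = base[:2000] + "A" + "".join(unit) + "A" + base[2000:5000] + "C" + "".join(copy) + "G" + base[5000:]
        hits = find_interspersed_repeats(seq, min_len=50, min_identity=75)
        best = max(hits, key=lambda h: h.length)
        assert best.length == 60
        assert best.identity == pytest.approx(95.0)

    def test_no_duplication_empty(self):
        seq = random_seq(2, 2_000)
        assert exact_repeat_oracle(seq) == set()
        assert find_interspersed_repeats(seq, min_identity=100.0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_exact_mode(self, seed):
        base = random_seq(seed + 10, 2_000)
        u1, u2 = random_seq(seed + 50, 70), random_seq(seed + 60, 55)
        seq = base[:400] + u1 + base[400:900] + u2 + base[900:1400] + u1 + base[1400:1700] + u2 + base[1700:]
        expected = exact_repeat_oracle(seq, min_len=50)
        got = {
            (h.start_a, h.end_a, h.start_b, h.end_b)
            for h in find_interspersed_repeats(seq, min_len=50, min_identity=100.0)
            if h.strand == "+"
        }
        assert got == expected

    def test_strand_symmetry(self):
        base = random_seq(7, 5_000)
        unit = random_seq(77, 64)
        seq = base[:1000] + unit + base[1000:3000] + reverse_complement(unit) + base[3000:]
        hits = find_interspersed_repeats(seq)
        inverted = [h for h in hits if h.strand == "-"]
        assert len(inverted) == 1
        # reverse-complementing the genome maps the hit onto itself
        n = len(seq)
        rc_hits = find_interspersed_repeats(reverse_complement(seq))
        mapped = {
            (n - h.end_b + 1, n - h.start_b + 1, n - h.end_a + 1, n - h.start_a + 1, h.strand)
            for h in rc_hits
        }
        assert {(h.start_a, h.end_a, h.start_b, h.end_b, h.strand) for h in hits} == mapped

    def test_determinism(self):
        g = random_seq(3, 4_000)
        unit = random_seq(31, 90)
        seq = g[:500] + unit + g[500:2000] + unit + g[2000:]
        assert find_interspersed_repeats(seq) == find_interspersed_repeats(seq)

    def test_generator_planted_repeats_recovered(self, synthetic_genome):
        genome, truth = synthetic_genome
        hits = find_interspersed_repeats(genome.sequence)
        for plant in truth.repeats:
            c1, c2 = sorted(plant["copies"], key=lambda c: c["start"])
            found = any(
                h.start_a <= c1["start"] and h.end_a >= c1["end"] - 3
                and h.start_b <= c2["start"] + 3 and h.end_b >= c2["end"] - 3
                for h in hits
            )
            assert found, plant


class TestRepeatFraction:
    def test_single_duplication_fraction(self):
        base = random_seq(5, 10_000)
        unit = random_seq(55, 100)
        seq = base[:2000] + unit + base[2000:6000] + unit + base[6000:]
        hits = [h for h in find_interspersed_repeats(seq) if h.strand == "+"]
        assert repeat_fraction(hits, len(seq)) == pytest.approx(2.0, abs=0.1)

    def test_no_hits_zero(self):
        assert repeat_fraction([], 1000) == 0.0

    def test_union_bounded(self, synthetic_genome):
        genome, _ = synthetic_genome
        hits = find_interspersed_repeats(genome.sequence)
        assert 0.0 <= repeat_fraction(hits, len(genome)) <= 100.0


class TestTandemRepeats:
    def test_short_unit_array(self):
        base = random_seq(6, 3_000)
        seq = base[:1500] + "ACGT" * 12 + base[1500:]
        hits = find_tandem_repeats(seq)
        assert any(t.period == 4 and t.copies == pytest.approx(12.0) and t.span == 48 for t in hits)

    def test_two_copy_24bp_unit_spans_48(self):
        base = random_seq(8, 3_000)
        unit = random_seq(88, 24)
        # guards break the period-24 match just outside the planted array
        guard_l = "A" if unit[-1] != "A" else "C"
        guard_r = "A" if unit[0] != "A" else "C"
        seq = base[:1000] + guard_l + unit * 2 + guard_r + base[1000:]
        hits = find_tandem_repeats(seq)
        assert any(t.span == 48 and t.period == 24 for t in hits)

    def test_random_sequence_empty(self):
        assert find_tandem_repeats(random_seq(9, 2_000)) == []

    def test_consensus_unit_matches_plant(self):
        base = random_seq(10, 2_000)
        unit = "ACGTTGGACA"
        seq = base[:700] + unit * 5 + base[700:]
        hits = [t for t in find_tandem_repeats(seq) if t.period == 10]
        assert hits and hits[0].consensus in unit * 2  # rotation of the unit


class TestSharedFragments:
    def test_planted_numt_recovered(self):
        mito = random_seq(11, 20_000)
        nuc_bg = random_seq(12, 30_000)
        segment = mito[5000:5500]
        nuclear = {"contig1": nuc_bg[:9000] + segment + nuc_bg[9000:]}
        frags = find_shared_fragments(mito, nuclear, min_len=100)
        assert frags
        best = max(frags, key=lambda f: f.length)
        assert best.length >= 475  # >=95% of the planted 500 bp
        assert best.mito_start <= 5026 and best.mito_end >= 5475

    def test_no_shared_kmers_empty(self):
        assert find_shared_fragments("ACGT" * 100, {"c": "TTTT" * 100}) == []

    def test_total_is_additive(self):
        mito = random_seq(13, 15_000)
        nuc = random_seq(14, 15_000)
        s1, s2 = mito[1000:1300], mito[8000:8200]
        nuclear = {"c1": nuc[:5000] + s1 + nuc[5000:10000] + s2 + nuc[10000:]}
        frags = find_shared_fragments(mito, nuclear, min_len=100)
        assert total_shared_length(frags) == sum(f.length for f in frags)
        assert total_shared_length(frags) >= 300 + 200 - 10

    def test_empty_nuclear_set_error(self):
        with pytest.raises(ValueError):
            find_shared_fragments("ACGT" * 100, {})
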