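import math
from itertools import permutations

import numpy as np
import pytest

from mitocompare.codon_usage import CODE4, STOP_CODONS
from mitocompare.genome_model import AnnotatedGenome
from mitocompare.seqevol import (
    DistanceMatrix,
    PairwiseAlignment,
    align_pair,
    codon_align,
    k2p,
    nei_gojobori,
    nj_tree,
    per_gene_stats,
)
from mitocompare.synthetic_data import DivergenceRates, SyntheticSpec, diverge

from conftest import feat, make_genome


class TestAlignPair:
    def test_identity_alignment(self):
        aln = align_pair("ACGT", "ACGT")
        assert aln.score == 4 and aln.aligned_a == aln.aligned_b == "ACGT"

    def test_single_gap_score(self):
        # brute-force over all alignments of length <= 5 confirms optimum 1
        aln = align_pair("ACGT", "ACT")
        assert aln.score == pytest.approx(1.0)
        assert aln.aligned_a.replace("-", "") == "ACGT"
        assert aln.aligned_b.replace("-", "") == "ACT"
        assert aln.aligned_b.count("-") == 1

    def test_single_mismatch_column(self):
        aln = align_pair("A", "T")
        assert (aln.aligned_a, aln.aligned_b) == ("A", "T")

    def test_degapped_rows_equal_inputs(self):
        a, b = "ACGTACGTTT", "ACGACGTT"
        aln = align_pair(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b


class TestK2P:
    def test_identical_pair(self):
        res = k2p(PairwiseAlignment("A" * 100, "A" * 100, 0))
        assert (res.P, res.Q, res.d) == (0.0, 0.0, 0.0)

    def test_transitions_only_closed_form(self):
        b = "G" * 10 + "A" * 90
        res = k2p(PairwiseAlignment("A" * 100, b, 0))
        assert res.d == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)

    def test_jc_style_form_when_q_zero(self):
        for n_ts in (5, 20, 35):
            b = "G" * n_ts + "A" * (100 - n_ts)
            res = k2p(PairwiseAlignment("A" * 100, b, 0))
            assert res.d == pytest.approx(-0.5 * math.log(1 - 2 * res.P), abs=1e-12)

    def test_saturation_flags(self):
        # P=0.25, Q=0.25 -> defined; P=0.4, Q=0.2 -> undefined
        ok = "G" * 25 + "C" * 25 + "A" * 50
        res = k2p(PairwiseAlignment("A" * 100, ok, 0))
        assert not res.undefined and res.d > 0
        bad = "G" * 40 + "C" * 20 + "A" * 40
        res = k2p(PairwiseAlignment("A" * 100, bad, 0))
        assert res.undefined

    def test_gap_and_n_columns_excluded(self):
        res = k2p(PairwiseAlignment("ACGT-N", "ACGAAN", 0))
        assert res.sites_used == 4 and res.Q == pytest.approx(0.25)


# --- independent exhaustive-pathway NG86 oracle ----------------------------


def _oracle_sites(codon):
    aa = CODE4[codon]
    s = 0.0
    for pos in range(3):
        changes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS:
                changes.append(CODE4[alt] == aa)
        if changes:
            s += sum(changes) / len(changes)
    return s, 3.0 - s


def _oracle_pathways(ca, cb):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        cur, syn, non, stop = ca, 0, 0, False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                stop = stop or nxt in STOP_CODONS
                non += 1
            elif CODE4[cur] == CODE4[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        (dirty if stop else clean).append((syn, non))
    pool = clean or dirty
    return (sum(x for x, _ in pool) / len(pool), sum(y for _, y in pool) / len(pool))


def oracle_ng86(cds_a, cds_b):
    N = S = Nd = Sd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, na = _oracle_sites(ca)
        sb, nb = _oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _oracle_pathways(ca, cb)
        Sd += sd
        Nd += nd
    return N, S, Nd, Sd


def _random_codon_pair_cds(rng, n_codons):
    sense = [c for c in sorted(CODE4)]
    a = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
    b = []
    for cod in a:
        if rng.random() < 0.4:
            mutated = cod
            for _ in range(rng.integers(1, 4)):
                pos = rng.integers(0, 3)
                base = "ACGT"[rng.integers(0, 4)]
                trial = mutated[:pos] + base + mutated[pos + 1 :]
                if trial not in STOP_CODONS:
                    mutated = trial
            b.append(mutated)
        else:
            b.append(cod)
    return "".join(a), "".join(b)


class TestNeiGojobori:
    def test_identical_pair(self):
        res = nei_gojobori("ATGAAATTT", "ATGAAATTT")
        assert res.Ka == 0.0 and res.Ks == 0.0 and res.undefined

    def test_single_synonymous_codon(self):
        res = nei_gojobori("TTT", "TTC")
        assert (res.Sd, res.Nd) == (1.0, 0.0)

    def test_site_counts_sum(self):
        rng = np.random.default_rng(0)
        a, b = _random_codon_pair_cds(rng, 30)
        res = nei_gojobori(a, b)
        assert res.N + res.S == pytest.approx(3 * 30, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_pathway_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_codon_pair_cds(rng, int(rng.integers(5, 31)))
        res = nei_gojobori(a, b)
        N, S, Nd, Sd = oracle_ng86(a, b)
        assert res.N == pytest.approx(N, abs=1e-9)
        assert res.S == pytest.approx(S, abs=1e-9)
        assert res.Nd == pytest.approx(Nd, abs=1e-9)
        assert res.Sd == pytest.approx(Sd, abs=1e-9)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori("ATGTAAAAA", "ATGAAAAAA")

    def test_gapped_codons_excluded(self):
        a, b = codon_align("ATGAAATTTCCC", "ATGTTTCCC")
        res = nei_gojobori(a, b)
        assert res.codons_compared == 3


class TestPerGeneStats:
    def _pair(self, cds_a, cds_b, gene="g1"):
        ga = make_genome("C" * 5 + cds_a + "G" * 5, [feat(gene, "PCG", "+", [(6, 5 + len(cds_a))])], gid="A")
        gb = make_genome("C" * 5 + cds_b + "G" * 5, [feat(gene, "PCG", "+", [(6, 5 + len(cds_b))])], gid="B")
        return ga, gb

    def test_identical_genomes_zero_distances(self, synthetic_genome):
        genome, _ = synthetic_genome
        twin = AnnotatedGenome("twin", genome.sequence, "circular", genome.features)
        df = per_gene_stats([genome, twin], ["cox1", "nad4L"]).set_index("gene")
        assert (df.mean_k2p == 0).all() and (df.mean_ka == 0).all()

    def test_substitutions_only_in_one_gene_rank(self):
        cds = "ATG" + "AAA" * 40 + "TAA"
        mutated = "ATG" + "AAA" * 10 + "AGA" + "AAA" * 29 + "TAA"  # one nonsyn change
        ga1, gb1 = self._pair(cds, mutated, "rps3")
        ga2, gb2 = self._pair(cds, cds, "nad4L")
        for g_from, g_extra in ((ga1, ga2), (gb1, gb2)):
            g_from.features.extend(g_extra.features)
        a = make_genome(ga1.sequence + ga2.sequence,
                        ga1.features[:1] + [feat("nad4L", "PCG", "+",
                                                 [(len(ga1.sequence) + 6, len(ga1.sequence) + 5 + len(cds))])],
                        gid="A")
        b = make_genome(gb1.sequence + gb2.sequence,
                        gb1.features[:1] + [feat("nad4L", "PCG", "+",
                                                 [(len(gb1.sequence) + 6, len(gb1.sequence) + 5 + len(cds))])],
                        gid="B")
        df = per_gene_stats([a, b], ["rps3", "nad4L"]).set_index("gene")
        assert df.loc["rps3", "mean_k2p"] > df.loc["nad4L", "mean_k2p"] == 0.0

    def test_purifying_regime_ratio_below_one(self):
        # all planted changes synonymous: three TTT -> TTC swaps
        cds = "ATG" + "TTT" * 20 + "TAA"
        syn = "ATG" + "TTC" * 3 + "TTT" * 17 + "TAA"
        a, b = self._pair(cds, syn)
        df = per_gene_stats([a, b], ["g1"]).set_index("gene")
        assert df.loc["g1", "mean_ka"] == 0.0
        assert df.loc["g1", "mean_ks"] > 0.0

    def test_absent_gene_warns_and_omits(self, synthetic_genome):
        genome, _ = synthetic_genome
        twin = AnnotatedGenome("twin", genome.sequence, "circular", genome.features)
        with pytest.warns(UserWarning, match="absent"):
            df = per_gene_stats([genome, twin], ["nad4L", "nope"])
        assert list(df.gene) == ["nad4L"]


class TestK2PParameterRecovery:
    def test_neutral_divergence_within_three_se(self):
        # 50 replicate neutral 2-kb regions at ts=0.05, tv=0.02
        ts_rate, tv_rate = 0.05, 0.02
        expected = -0.5 * math.log((1 - 2 * ts_rate - tv_rate) * math.sqrt(1 - 2 * tv_rate))
        rng = np.random.default_rng(12)
        estimates = []
        for rep in range(50):
            seq = "".join(rng.choice(list("ACGT"), 2000))
            g = AnnotatedGenome(f"r{rep}", seq, "circular", [])
            spec = SyntheticSpec(seed=1000 + rep, divergence=DivergenceRates(ts_rate, tv_rate, 0.0))
            sis, _ = diverge(g, spec)
            res = k2p(PairwiseAlignment(seq, sis.sequence, 0))
            estimates.append(res.d)
        mean = float(np.mean(estimates))
        se = float(np.std(estimates, ddof=1) / math.sqrt(len(estimates)))
        assert abs(mean - expected) <= 3 * se


class TestNJTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        newick = nj_tree(dm)
        assert "a:1.000000" in newick and "b:1.000000" in newick and "c:3.000000" in newick

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }
        ids = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    mat[i, j] = mat[j, i] = d[(x, y)]
        newick = nj_tree(DistanceMatrix(ids, mat))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (x, y), dist in d.items():
            assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(dist, abs=1e-6)

    def test_zero_matrix_star_tree(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        newick = nj_tree(dm)
        assert ":0.000000" in newick and "(" in newick

    def test_undefined_distances_listed(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = float("nan")
        with pytest.raises(ValueError, match="a.*b"):
            nj_tree(DistanceMatrix(["a", "b", "c"], mat))

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_random_additive_topologies(self, seed):
        import dendropy

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa = [f"t{i}" for i in range(n)]
        ns = dendropy.TaxonNamespace(taxa)
        source = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            taxon_namespace=ns, rng=__import__("random").Random(seed),
        )
        for edge in source.preorder_edge_iter():
            edge.length = float(rng.uniform(0.2, 2.0))
        pdm = source.phylogenetic_distance_matrix()
        labels = [t.label for t in source.taxon_namespace]
        mat = np.zeros((n, n))
        tx = {t.label: t for t in source.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = pdm.distance(tx[labels[i]], tx[labels[j]])
        newick = nj_tree(DistanceMatrix(labels, mat))
        recovered = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=source.taxon_namespace)
        source.is_rooted = False
        recovered.is_rooted = False
        source.encode_bipartitions()
        recovered.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(source, recovered)
        assert rf == 0
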