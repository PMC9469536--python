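import numpy as np
import pytest

from mitocompare.genome_model import GenomeModelError, coding_sequence
from mitocompare.intron_pcl import (
    classify_host_gene,
    intron_positions,
    map_to_reference,
    pcl_sharing_summary,
)
from mitocompare.synthetic_data import IntronPlan, SyntheticSpec, generate_genome, pcl_panel

from conftest import feat, make_genome


class TestIntronPositions:
    def test_two_exons_one_intron(self):
        g = make_genome(
            "A" * 2000,
            [
                feat("g1", "PCG", "+", [(1, 300), (801, 1400)]),
                feat("g1.i1", "intron", "+", [(301, 800)], parent="g1"),
            ],
        )
        (rec,) = intron_positions(g, "g1")
        assert rec.position == 300 and rec.ordinal == 1

    def test_three_exons_two_introns(self):
        g = make_genome(
            "A" * 2000,
            [
                feat("g1", "PCG", "+", [(1, 100), (201, 400), (501, 800)]),
                feat("g1.i1", "intron", "+", [(101, 200)], parent="g1"),
                feat("g1.i2", "intron", "+", [(401, 500)], parent="g1"),
            ],
        )
        recs = intron_positions(g, "g1")
        assert [r.position for r in recs] == [100, 300]

    def test_minus_strand_positions(self):
        # coding 5' end is at the high-coordinate exon
        g = make_genome(
            "A" * 2000,
            [
                feat("g1", "PCG", "-", [(801, 1400), (1, 300)]),
                feat("g1.i1", "intron", "-", [(301, 800)], parent="g1"),
            ],
        )
        (rec,) = intron_positions(g, "g1")
        assert rec.position == 600

    def test_intron_free_gene(self, simple_gene_genome):
        assert intron_positions(simple_gene_genome, "pcg1") == []

    def test_unflanked_intron_error(self):
        g = make_genome(
            "A" * 2000,
            [
                feat("g1", "PCG", "+", [(1, 300)]),
                feat("g1.i1", "intron", "+", [(500, 600)], parent="g1"),
            ],
        )
        with pytest.raises(GenomeModelError, match="not flanked"):
            intron_positions(g, "g1")

    def test_positions_match_generator_plan(self):
        spec = SyntheticSpec(seed=8, genome_id="x")
        g, truth = generate_genome(spec)
        for host, planted in truth.pcl_truth.items():
            recs = intron_positions(g, host)
            assert [(r.ordinal, r.position) for r in recs] == [(o, p) for o, p, _ in planted]


class TestMapToReference:
    def test_identity_mapping(self):
        cds = "ATGAAATTTGGG" * 60
        pos, flag = map_to_reference(cds, cds, 612)
        assert (pos, flag) == (612, False)

    def test_reference_deletion_shifts_position(self):
        query = "ATGAAACCCGGGTTTAAACCCGGG" * 10
        ref = query[:60] + query[63:]  # 3-nt deletion 5' of any site > 63
        pos, flag = map_to_reference(query, ref, 120)
        assert pos == 117 and not flag

    def test_insertion_point_inside_reference_gap(self):
        ref = "ATGAAACCCGGGTTTAAACCCGGG" * 5
        query = ref[:60] + "CACTGC" + ref[60:]  # query-only insertion
        pos, flag = map_to_reference(query, ref, 63)  # lands mid-insertion
        assert pos == 60 and flag

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            map_to_reference("ATG", "ATG", 7)

    def test_monotone_in_query_position(self):
        rng = np.random.default_rng(4)
        query = "".join(rng.choice(list("ACGT"), 300))
        ref = "".join(rng.choice(list("ACGT"), 280))
        last = -1
        for p in range(0, 301, 10):
            pos, _ = map_to_reference(query, ref, p)
            assert pos >= last
            last = pos


@pytest.fixture(scope="module")
def panel():
    return pcl_panel(21)


class TestClassifyPcls:
    def test_recovers_planted_panel_exactly(self, panel):
        genomes, _, expected, ancestor = panel
        ref = coding_sequence(ancestor, "cox1")
        pcls, matrix = classify_host_gene(genomes, "cox1", ref)
        assert len(pcls) == 27
        assert sum(len(p.members) for p in pcls) == 49
        got = {p.position: {m[0] for m in p.members} for p in pcls}
        assert got == {pos: carriers for pos, carriers in expected.items() if carriers}

    def test_pcl_names_derived_from_position(self, panel):
        genomes, _, _, ancestor = panel
        ref = coding_sequence(ancestor, "cox1")
        pcls, _ = classify_host_gene(genomes, "cox1", ref)
        assert all(p.name == f"P{p.position}" for p in pcls)

    def test_reference_self_consistency(self):
        spec = SyntheticSpec(
            seed=14,
            intron_plan=[IntronPlan("cox1", 209, 300, "I"), IntronPlan("cox1", 612, 300, "I")],
            genome_id="selfref",
        )
        g, _ = generate_genome(spec)
        ref = coding_sequence(g, "cox1")
        pcls, _ = classify_host_gene([g], "cox1", ref)
        assert [p.position for p in pcls] == [209, 612]

    def test_intronless_genome_all_absent_column(self, panel):
        genomes, _, _, ancestor = panel
        ref = coding_sequence(ancestor, "cox1")
        _, matrix = classify_host_gene(genomes + [ancestor], "cox1", ref)
        assert not matrix["ancestor"].any()


class TestSharingSummary:
    def test_counts_and_private_flags(self, panel):
        genomes, _, expected, ancestor = panel
        ref = coding_sequence(ancestor, "cox1")
        _, matrix = classify_host_gene(genomes, "cox1", ref)
        summary = pcl_sharing_summary(matrix)
        for pos, carriers in expected.items():
            if not carriers:
                continue
            row = summary.loc[f"P{pos}"]
            assert row.n_genomes == len(carriers)
            if len(carriers) == 1:
                assert row.private and row.private_to == next(iter(carriers))

    def test_empty_matrix(self):
        import pandas as pd

        assert pcl_sharing_summary(pd.DataFrame()).empty
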