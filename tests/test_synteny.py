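import numpy as np
import pytest

from famscan.msa import InputError
from famscan.simulate import SyntheticSpec, make_genomes
from famscan.synteny import (
    GeneRecord,
    GeneTable,
    genome_fraction,
    read_gene_table_tsv,
    read_gff3_genes,
    synteny_scan,
    write_gene_table_tsv,
)


def table(label_positions, genome="g", contig="chr1", size=30):
    """Genome of ``size`` filler genes with labels planted at given ordinals."""
    return GeneTable(
        genome_id=genome,
        records=[
            GeneRecord(
                gene_id=f"{genome}_{i}",
                contig=contig,
                ordinal=i,
                label=label_positions.get(i),
            )
            for i in range(1, size + 1)
        ],
    )


class TestSyntenyScan:
    def test_adjacent_pair(self):
        calls = synteny_scan(table({5: "B", 6: "C"}))
        assert len(calls) == 1
        assert calls[0].span == 2 and calls[0].n_distinct == 2

    def test_window_boundary_span_seven(self):
        assert synteny_scan(table({3: "B", 9: "C"}))  # span 7 == window
        assert not synteny_scan(table({3: "B", 10: "C"}))  # span 8

    def test_same_label_twice_not_called(self):
        assert not synteny_scan(table({5: "B", 6: "B"}))

    def test_three_distinct_labels(self):
        calls = synteny_scan(table({4: "B", 6: "C", 8: "D"}), min_distinct=3)
        assert len(calls) == 1 and calls[0].n_distinct == 3

    def test_calls_do_not_cross_contigs(self):
        t = GeneTable(
            genome_id="g",
            records=[
                GeneRecord("g1", "chr1", 1, label="B"),
                GeneRecord("g2", "chr2", 1, label="C"),
            ],
        )
        assert synteny_scan(t) == []

    def test_unsorted_table_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            GeneTable(
                genome_id="g",
                records=[
                    GeneRecord("g1", "chr1", 5),
                    GeneRecord("g2", "chr1", 3),
                ],
            )

    def test_span_invariant(self):
        for calls in (synteny_scan(table({2: "B", 5: "C", 8: "D"}), 7, 2),):
            for c in calls:
                assert c.span <= 7 and c.n_distinct >= 2

    def test_shrinking_window_never_adds_calls(self, rng):
        for _ in range(20):
            positions = sorted(rng.choice(30, size=4, replace=False) + 1)
            labels = {int(p): lbl for p, lbl in zip(positions, "BCDB")}
            t = table(labels)
            wide = {(c.contig, c.start, c.end) for c in synteny_scan(t, 9, 2)}
            for span in (7, 5, 3, 2):
                narrow = synteny_scan(t, span, 2)
                for c in narrow:
                    # every narrow call lies within some wide call region
                    assert any(
                        ws <= c.start and c.end <= we for (_, ws, we) in wide
                    )

    def test_bad_parameters_rejected(self):
        with pytest.raises(InputError):
            synteny_scan(table({}), window_span=1)
        with pytest.raises(InputError):
            synteny_scan(table({}), min_distinct=1)


class TestGenomeFraction:
    def test_planted_two_of_three(self):
        yes1 = table({5: "B", 6: "C"}, genome="g1")
        yes2 = table({10: "B", 12: "C"}, genome="g2")
        no = table({1: "B", 20: "C"}, genome="g3")
        n_with, n_total, frac = genome_fraction([yes1, yes2, no])
        assert (n_with, n_total) == (2, 3)
        assert frac == pytest.approx(2 / 3)

    def test_all_planted(self):
        tables = [table({5: "B", 6: "C"}, genome=f"g{i}") for i in range(4)]
        assert genome_fraction(tables)[2] == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            genome_fraction([])

    def test_random_placement_null_rate(self, rng):
        # exact enumeration: P(two uniform labeled genes within span<=7 of a
        # 100-gene genome) = 579/4950
        n_sim = 1000
        hits = 0
        for i in range(n_sim):
            a, b = rng.choice(100, size=2, replace=False) + 1
            t = GeneTable(
                genome_id=f"g{i}",
                records=[
                    GeneRecord("x", "chr1", int(min(a, b)), label="B"),
                    GeneRecord("y", "chr1", int(max(a, b)), label="C"),
                ],
            )
            hits += bool(synteny_scan(t, 7, 2))
        p = 579 / 4950
        se = (p * (1 - p) / n_sim) ** 0.5
        assert abs(hits / n_sim - p) <= 3 * se


class TestPlantedGenomes:
    def test_planted_recall_is_total(self):
        for seed in range(20):
            spec = SyntheticSpec(
                seed=seed, n_genomes=5, genome_size=60, planted_fraction=1.0, planted_span=5
            )
            tables, truth = make_genomes(spec)
            assert all(truth.planted)
            for t in tables:
                assert synteny_scan(t, window_span=7, min_distinct=2)


class TestIO:
    def test_gene_table_tsv_round_trip(self, tmp_path):
        t = table({3: "B", 5: "C"}, size=8)
        path = tmp_path / "genes.tsv"
        write_gene_table_tsv([t], path)
        [again] = read_gene_table_tsv(path)
        assert again.genome_id == t.genome_id
        assert [(r.ordinal, r.label) for r in again.records] == [
            (r.ordinal, r.label) for r in t.records
        ]

    def test_gff3_reader_orders_by_start(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t500\t900\t.\t+\t.\tID=g2;family=epimerase_35\n"
            "chr1\tsrc\tgene\t100\t400\t.\t-\t.\tID=g1;family=dehydratase_46\n"
            "chr1\tsrc\tmRNA\t100\t400\t.\t-\t.\tID=m1\n"
            "chr2\tsrc\tgene\t10\t50\t.\t+\t.\tID=g3\n"
        )
        t = read_gff3_genes(gff, genome_id="G")
        assert [(r.gene_id, r.contig, r.ordinal, r.label) for r in t.records] == [
            ("g1", "chr1", 1, "dehydratase_46"),
            ("g2", "chr1", 2, "epimerase_35"),
            ("g3", "chr2", 1, None),
        ]
        assert synteny_scan(t)[0].n_distinct == 2
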