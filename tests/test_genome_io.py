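import numpy as np
import pandas as pd
import pytest

from neighborgo import genome_io
from neighborgo.genome_io import (
    Gene,
    GenomeCollection,
    GOAnnotationTable,
    ParseError,
    SimilarityHit,
    ValidationError,
    best_hits,
)


def make_gene(pid="p1", start=0, end=900, strand="+", genome="g1", contig="c1"):
    return Gene(pid, pid, genome, contig, start, end, strand)


class TestGeneModel:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValidationError):
            make_gene(start=100, end=100)
        with pytest.raises(ValidationError):
            make_gene(start=-5, end=100)

    def test_protein_unique_across_genomes(self):
        coll = GenomeCollection()
        coll.add_gene(make_gene(genome="g1"))
        with pytest.raises(ValidationError):
            coll.add_gene(make_gene(genome="g2"))

    def test_sort_tie_break_by_end_then_gene_id(self):
        genes = [
            make_gene("b", start=0, end=500),
            make_gene("a", start=0, end=500),
            make_gene("c", start=0, end=400),
        ]
        coll = GenomeCollection.from_genes(genes)
        ordered = [g.gene_id for g in coll.genomes["g1"]["c1"]]
        assert ordered == ["c", "a", "b"]


class TestGeneTable:
    def test_gff3_converts_one_based_inclusive(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tCDS\t1\t900\t.\t+\t0\tID=p1;genome_id=g1\n"
        )
        coll = genome_io.read_gene_table(path, dialect="gff3")
        gene = coll.gene_for_protein("p1")
        assert (gene.start, gene.end, gene.strand) == (0, 900, "+")

    def test_tsv_dialect_passes_through(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("g1\tc1\tp1\t0\t900\t+\n")
        gene = genome_io.read_gene_table(path, dialect="tsv").gene_for_protein("p1")
        assert (gene.start, gene.end) == (0, 900)

    def test_dialect_flag_is_mandatory(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("g1\tc1\tp1\t0\t900\t+\n")
        with pytest.raises(ValidationError):
            genome_io.read_gene_table(path, dialect="auto")

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("g1\tc1\tp1\t0\t900\t+\ng1\tc1\tp2\tzero\t900\t+\n")
        with pytest.raises(ParseError, match=":2"):
            genome_io.read_gene_table(path, dialect="tsv")

    def test_inverted_after_conversion_rejected(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text("c1\tsrc\tCDS\t900\t10\t.\t+\t0\tID=p1\n")
        with pytest.raises(ValidationError):
            genome_io.read_gene_table(path, dialect="gff3")

    def test_empty_file_gives_empty_collection(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with caplog.at_level("WARNING", logger="neighborgo"):
            coll = genome_io.read_gene_table(path, dialect="tsv")
        assert coll.n_genes() == 0
        assert any("empty" in rec.message for rec in caplog.records)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(30):
            start = int(rng.integers(0, 10000))
            genes.append(
                make_gene(
                    f"p{i}", start=start, end=start + int(rng.integers(1, 2000)),
                    strand="+-"[int(rng.integers(2))],
                    genome=f"g{i % 3}", contig=f"c{i % 2}",
                )
            )
        coll = GenomeCollection.from_genes(genes)
        path = tmp_path / "rt.tsv"
        genome_io.write_gene_table(coll, path)
        again = genome_io.read_gene_table(path, dialect="tsv")
        for g in genes:
            h = again.gene_for_protein(g.protein_id)
            assert (h.start, h.end, h.strand, h.genome_id) == (
                g.start, g.end, g.strand, g.genome_id,
            )


class TestSimilarityHits:
    def test_reads_outfmt6_row(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("A\tB\t80.0\t0\t0\t0\t0\t0\t0\t0\t1e-40\t200\n")
        (hit,) = genome_io.read_similarity_hits(path)
        assert hit == SimilarityHit("A", "B", 80.0, 1e-40, 200.0)

    def test_duplicates_kept_then_best_by_min_evalue(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "A\tB\t80.0\t0\t0\t0\t0\t0\t0\t0\t1e-10\t100\n"
            "A\tB\t85.0\t0\t0\t0\t0\t0\t0\t0\t1e-40\t200\n"
        )
        hits = genome_io.read_similarity_hits(path)
        assert len(hits) == 2  # file order, duplicates retained
        assert best_hits(hits)[("A", "B")].e_value == 1e-40

    def test_evalue_tie_broken_by_max_bitscore(self):
        hits = [
            SimilarityHit("A", "B", 80.0, 1e-40, 150.0),
            SimilarityHit("A", "B", 82.0, 1e-40, 250.0),
        ]
        assert best_hits(hits)[("A", "B")].bitscore == 250.0

    def test_non_numeric_evalue_is_parse_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("A\tB\t80.0\t0\t0\t0\t0\t0\t0\t0\tnotanumber\t200\n")
        with pytest.raises(ParseError):
            genome_io.read_similarity_hits(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert genome_io.read_similarity_hits(path) == []

    def test_round_trip(self, tmp_path):
        hits = [
            SimilarityHit("A", "B", 80.0, 1e-40, 200.0),
            SimilarityHit("B", "C", 55.5, 2e-07, 88.0),
        ]
        path = tmp_path / "hits.tsv"
        genome_io.write_similarity_hits(hits, path)
        again = genome_io.read_similarity_hits(path)
        assert [(h.query_id, h.subject_id) for h in again] == [
            ("A", "B"), ("B", "C"),
        ]
        assert again[0].e_value == pytest.approx(1e-40)


class TestGOAnnotations:
    def test_in_vocabulary_term_retained(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("P1\tGO:0030089\n")
        table = genome_io.read_go_annotations(path)
        assert table.annotations["P1"] == {"GO:0030089"}

    def test_out_of_vocabulary_dropped_and_counted(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("P1\tGO:0030089\nP2\tGO:0008150\n")
        table = genome_io.read_go_annotations(path)
        assert table.n_dropped == 1
        # protein with only dropped terms is not an instance
        assert "P2" not in table.annotations
        assert table.annotated_proteins == ["P1"]

    def test_malformed_go_id_rejected(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("P1\tGO:123\n")
        with pytest.raises(ValidationError):
            genome_io.read_go_annotations(path)

    def test_default_vocabulary_has_24_terms(self):
        assert len(genome_io.default_vocabulary()) == 24

    def test_round_trip(self, tmp_path):
        table = GOAnnotationTable(
            annotations={"P1": {"GO:0030089", "GO:0009523"}},
            vocabulary=genome_io.default_vocabulary(),
        )
        path = tmp_path / "go.tsv"
        genome_io.write_go_annotations(table, path)
        again = genome_io.read_go_annotations(path)
        assert again.annotations == table.annotations


class TestARFF:
    @staticmethod
    def matrices(n=2):
        feats = pd.DataFrame(
            [[2, 0], [1, 3]][:n], index=[f"i{k}" for k in range(n)],
            columns=["fA", "fB"], dtype="int8",
        )
        labels = pd.DataFrame(
            [[1, 0], [0, 1]][:n], index=[f"i{k}" for k in range(n)],
            columns=["GO:0009523", "GO:0030089"], dtype="int8",
        )
        return feats, labels

    def test_structure(self, tmp_path):
        feats, labels = self.matrices()
        path = tmp_path / "m.arff"
        genome_io.write_arff(feats, labels, path)
        text = path.read_text()
        assert text.count("@ATTRIBUTE") == 5  # instance_id + 2 feats + 2 labels
        assert len(text.split("@DATA\n")[1].strip().splitlines()) == 2

    def test_round_trip_lossless(self, tmp_path):
        feats, labels = self.matrices()
        path = tmp_path / "m.arff"
        genome_io.write_arff(feats, labels, path)
        feats2, labels2 = genome_io.read_arff(path)
        pd.testing.assert_frame_equal(feats, feats2)
        pd.testing.assert_frame_equal(labels, labels2)

    def test_feature_value_out_of_range_rejected(self, tmp_path):
        feats, labels = self.matrices()
        feats.iloc[0, 0] = 4
        with pytest.raises(ValidationError):
            genome_io.write_arff(feats, labels, tmp_path / "m.arff")

    def test_zero_instances_writes_header_only(self, tmp_path):
        feats, labels = self.matrices()
        path = tmp_path / "m.arff"
        with pytest.warns(UserWarning, match="header-only"):
            genome_io.write_arff(feats.iloc[:0], labels.iloc[:0], path)
        feats2, labels2 = genome_io.read_arff(path)
        assert len(feats2) == 0 and list(feats2.columns) == ["fA", "fB"]
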