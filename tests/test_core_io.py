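"""Readers/writers: strict validation, positional diagnostics, round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from rumenmt.core_io import (
    AlignmentHit,
    DomainHit,
    ParseError,
    RunConfig,
    SequenceRecord,
    Taxonomy,
    TaxonomyNode,
    read_fasta,
    read_hit_table,
    read_taxonomy,
    write_fasta,
    write_hit_table,
    write_taxonomy,
)


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "c1" and recs[0].sequence == "ACGT"

    def test_case_normalized_and_description(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1 a contig\nacgtn\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "ACGTNACGT"
        assert rec.description == "a contig"

    def test_duplicate_id_is_error_naming_id(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(ParseError, match="c1"):
            read_fasta(p)

    def test_empty_sequence_is_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\n>c2\nACGT\n")
        with pytest.raises(ParseError, match="empty sequence"):
            read_fasta(p)

    def test_non_iupac_character_reports_line_number(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGT\nACXT\n")
        with pytest.raises(ParseError, match="a.fa:3"):
            read_fasta(p)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGTN", min_size=1, max_size=200),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip_is_identity_on_sequences(self, tmp_path_factory, seqs):
        recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        p = tmp_path_factory.mktemp("fa") / "rt.fa"
        write_fasta(recs, p, width=60)
        back = read_fasta(p)
        assert [r.sequence for r in back] == [r.sequence for r in recs]
        assert [r.id for r in back] == [r.id for r in recs]


class TestHitTables:
    def test_parse_scientific_notation_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "r1\ts1\t88.6\t300\t34\t0\t1\t300\t1\t300\t1e-110\t400\tPiromyces\tbeta-glucosidase Cel1C\n"
        )
        (hit,) = read_hit_table(p, "alignment")
        assert hit.percent_identity == 88.6
        assert hit.e_value == 1e-110
        assert hit.subject_taxon == "Piromyces"

    def test_twelve_column_row_fills_empty_extras(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("r1\ts1\t90\t100\t10\t0\t1\t100\t1\t100\t1e-20\t80\n")
        (hit,) = read_hit_table(p, "alignment")
        assert hit.subject_taxon == "" and hit.subject_annotation == ""

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("# just a comment\n")
        assert read_hit_table(p, "alignment") == []
        assert read_hit_table(p, "domain") == []

    def test_inverted_coordinates_error_names_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("r1\ts1\t90\t100\t0\t0\t200\t100\t1\t100\t1e-20\t80\n")
        with pytest.raises(ParseError, match="h.tsv:1"):
            read_hit_table(p, "alignment")

    def test_unparsable_numeric_error_names_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("# header\nq\tm\tfifty\t1e-9\t1\t50\thmm\n")
        with pytest.raises(ParseError, match="h.tsv:2"):
            read_hit_table(p, "domain")

    @pytest.mark.parametrize("kind", ["alignment", "domain"])
    def test_write_read_round_trip(self, tmp_path, kind):
        if kind == "alignment":
            hits = [
                AlignmentHit("r1", "s1", 88.6, 300, 34, 0, 1, 300, 1, 300,
                             1e-110, 400.0, "Piromyces", "cellulase Cel48A precursor"),
                AlignmentHit("r2", "rrna_SSU_1", 99.0, 108, 1, 0, 1, 108, 3, 110,
                             2.5e-40, 95.5),
            ]
        else:
            hits = [
                DomainHit("c1", "PF_GH48", 120.5, 1e-30, 10, 900, "hmm"),
                DomainHit("c1", "PF_CBM10", 52.0, 1e-8, 950, 1050, "blast"),
            ]
        p = tmp_path / "rt.tsv"
        write_hit_table(hits, p, kind)
        assert read_hit_table(p, kind) == hits

    def test_overlap_is_inclusive_span_length(self):
        hit = AlignmentHit("r", "s", 90, 51, 0, 0, 50, 100, 1, 51, 1e-9, 60.0)
        assert hit.query_overlap == 100 - 50 + 1


class TestTaxonomy:
    def test_three_level_chain(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "root\t\troot\troot\n"
            "Eukaryota\troot\tkingdom\tEukaryota\n"
            "Neocallimastigomycota\tEukaryota\tphylum\tNeocallimastigomycota\n"
        )
        tax = read_taxonomy(p)
        assert tax.lineage("Neocallimastigomycota") == (
            "root", "Eukaryota", "Neocallimastigomycota")

    def test_dangling_parent_is_error(self):
        with pytest.raises(ValueError, match="missing parent"):
            Taxonomy([
                TaxonomyNode("root", "", "root", "root"),
                TaxonomyNode("x", "ghost", "kingdom", "x"),
            ])

    def test_multiple_roots_is_error(self):
        with pytest.raises(ValueError, match="exactly one root"):
            Taxonomy([
                TaxonomyNode("r1", "", "root", "r1"),
                TaxonomyNode("r2", "", "root", "r2"),
            ])

    def test_cycle_is_error(self):
        with pytest.raises(ValueError, match="cycle"):
            Taxonomy([
                TaxonomyNode("root", "", "root", "root"),
                TaxonomyNode("a", "b", "phylum", "a"),
                TaxonomyNode("b", "a", "class", "b"),
            ])

    def test_round_trip_preserves_structure(self, tmp_path, taxonomy):
        p = tmp_path / "tax.tsv"
        write_taxonomy(taxonomy, p)
        back = read_taxonomy(p)
        assert back.nodes == taxonomy.nodes
        assert back.root_id == taxonomy.root_id

    def test_ancestor_at_rank(self, taxonomy):
        assert taxonomy.ancestor_at_rank("Piromyces", "phylum") == "Neocallimastigomycota"
        assert taxonomy.ancestor_at_rank("Piromyces", "species") is None


class TestRunConfig:
    def test_yaml_round_trip_unchanged(self, tmp_path):
        cfg = RunConfig(seed=11, n_reads=1234, rank="phylum")
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert RunConfig.from_yaml(p) == cfg
        assert RunConfig.from_yaml(p).config_hash == cfg.config_hash

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="min_overlap"):
            RunConfig(min_overlap=0)
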