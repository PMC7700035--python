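"""Table readers/writers: normalization, aliasing, errors, round trips."""

import numpy as np
import pytest

from netpharm.ingest import (
    AffinityMatrix,
    CompoundRecord,
    GeneSetCollection,
    normalize_numeric_text,
    normalize_symbol,
    read_affinity_table,
    read_compound_table,
    read_gene_list,
    read_gmt,
    read_target_map,
    write_affinity_table,
    write_gene_list,
    write_gmt,
    write_target_map,
)


class TestCompoundTable:
    def test_direct_field_mapping(self, tmp_path):
        path = tmp_path / "yyh.csv"
        path.write_text("name,ob,dl\nquercetin,46.43,0.28\n")
        (rec,) = read_compound_table(path, herb="YYH")
        assert rec == CompoundRecord("quercetin", "quercetin", "YYH", 46.43, 0.28)

    def test_unparseable_numeric_row_skipped_and_logged(self, tmp_path, caplog):
        path = tmp_path / "t.csv"
        path.write_text("name,ob,dl\ngood,35,0.2\nbad,abc,0.3\n")
        with caplog.at_level("WARNING", logger="netpharm.ingest"):
            records = read_compound_table(path, herb="FZ")
        assert [r.name for r in records] == ["good"]
        assert "skipped 1 row" in caplog.text

    def test_alias_resolution(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Molecule,ob%,drug_likeness\na,31,0.2\nb,29,0.4\n")
        records = read_compound_table(path, herb="HB")
        assert [(r.name, r.ob, r.dl) for r in records] == [("a", 31.0, 0.2), ("b", 29.0, 0.4)]

    def test_custom_alias_config(self, tmp_path):
        cfg = tmp_path / "aliases.yaml"
        cfg.write_text("ob: [bioavail]\n")
        path = tmp_path / "t.csv"
        path.write_text("name,bioavail,dl\nx,40,0.3\n")
        from netpharm.ingest import load_alias_config

        (rec,) = read_compound_table(path, herb="FZ", aliases=load_alias_config(cfg))
        assert rec.ob == 40.0

    def test_unicode_minus_and_fullwidth_digits(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("name,ob,dl\nx,３５.5,0.2\n")
        (rec,) = read_compound_table(path, herb="FZ")
        assert rec.ob == 35.5

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("name,ob\nx,40\n")
        with pytest.raises(ValueError, match="'dl'"):
            read_compound_table(path, herb="FZ")

    def test_empty_file_is_hard_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("name,ob,dl\n")
        with pytest.raises(ValueError, match="no data rows"):
            read_compound_table(path, herb="FZ")

    def test_registry_id_preferred_over_name(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("MOL_ID,Molecule,OB,DL\nMOL0007,Quercetin,46.43,0.28\n")
        (rec,) = read_compound_table(path, herb="YYH")
        assert rec.compound_id == "MOL0007"

    def test_negative_ob_rejected_by_record(self):
        with pytest.raises(ValueError, match="ob"):
            CompoundRecord("x", "x", "FZ", -1.0, 0.2)


class TestGeneList:
    def test_normalization_and_dedup(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("tnf\nTNF\n vegfa \n\n")
        assert read_gene_list(path) == {"TNF", "VEGFA"}

    def test_empty_is_hard_error(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("\n\n")
        with pytest.raises(ValueError, match="empty"):
            read_gene_list(path)

    def test_round_trip(self, tmp_path, synth):
        symbols = sorted(synth.disease_genes)[:10]
        path = tmp_path / "g.txt"
        write_gene_list(symbols, path)
        assert read_gene_list(path) == set(symbols)


class TestGmt:
    def test_basic_line(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("hsa04010\tMAPK signaling pathway\tMAPK1\tTNF\n")
        coll = read_gmt(path)
        assert coll.genes("hsa04010") == {"MAPK1", "TNF"}
        assert coll.description("hsa04010") == "MAPK signaling pathway"

    def test_universe_is_union(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("a\td\tG1\tG2\nb\td\tG3\n")
        coll = read_gmt(path)
        assert coll.universe == {"G1", "G2", "G3"}
        assert len(coll.universe) == 3

    def test_short_line_is_hard_error(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("a\tdesc-only\n")
        with pytest.raises(ValueError, match=":1:"):
            read_gmt(path)

    def test_duplicate_id_last_wins_with_warning(self, tmp_path, caplog):
        path = tmp_path / "p.gmt"
        path.write_text("a\td\tG1\na\td\tG2\tG3\n")
        with caplog.at_level("WARNING", logger="netpharm.ingest"):
            coll = read_gmt(path)
        assert coll.genes("a") == {"G2", "G3"}
        assert "duplicate pathway id" in caplog.text

    def test_round_trip(self, tmp_path, synth):
        path = tmp_path / "p.gmt"
        write_gmt(synth.collection, path)
        back = read_gmt(path)
        assert back.sets == synth.collection.sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection(sets={"a": ("d", frozenset())})


class TestTargetMap:
    def test_round_trip_and_normalization(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_target_map({("c1", "tnf"), ("c1", "TNF"), ("c2", "VEGFA")}, path)
        assert read_target_map(path) == {("c1", "TNF"), ("c2", "VEGFA")}

    def test_bad_symbol_is_hard_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("compound_id\tgene_symbol\nc1\t-BAD\n")
        with pytest.raises(ValueError, match="invalid gene symbol"):
            read_target_map(path)


class TestAffinityTable:
    def test_published_fixture_shape_and_value(self, fxhj_affinity):
        assert len(fxhj_affinity.compounds) == 16
        assert len(fxhj_affinity.targets) == 5
        assert fxhj_affinity.value("Protopine", "VEGFA") == -7.8

    def test_positive_value_kept_as_printed(self, fxhj_affinity):
        assert fxhj_affinity.value("Anhydroicaritin", "PTGS2") == 6.6

    def test_pdb_codes_split_from_labels(self, fxhj_affinity):
        assert fxhj_affinity.pdb_codes["VEGFA"] == "1VPF"
        assert "(" not in "".join(fxhj_affinity.targets)

    def test_one_by_one_table(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("Compound,TNF\nx,-5.0\n")
        m = read_affinity_table(path)
        assert m.values.shape == (1, 1) and m.value("x", "TNF") == -5.0

    def test_blank_cell_is_missing(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("Compound,TNF,VEGFA\nx,-5.0,\n")
        m = read_affinity_table(path)
        assert np.isnan(m.value("x", "VEGFA"))

    def test_non_numeric_cell_is_hard_error_with_coordinates(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("Compound,TNF\nx,oops\n")
        with pytest.raises(ValueError, match="'x'.*'TNF'"):
            read_affinity_table(path)

    def test_round_trip(self, tmp_path, fxhj_affinity):
        path = tmp_path / "a.csv"
        write_affinity_table(fxhj_affinity, path)
        back = read_affinity_table(path)
        assert back.compounds == fxhj_affinity.compounds
        assert back.targets == fxhj_affinity.targets
        assert back.pdb_codes == fxhj_affinity.pdb_codes
        np.testing.assert_array_equal(back.values, fxhj_affinity.values)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            AffinityMatrix(compounds=["a"], targets=["T1", "T2"],
                           values=np.zeros((1, 1)))


class TestNormalization:
    def test_idempotent_on_ascii(self):
        for text in ("-7.8", "12.5", "TNF", "a b"):
            assert normalize_numeric_text(text) == text

    def test_unicode_minus_and_nbsp(self):
        assert normalize_numeric_text("−7.8") == "-7.8"
        assert normalize_numeric_text(" x ") == "x"

    def test_reader_outputs_are_normalized(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("tnf\nIl-6\n")
        for sym in read_gene_list(path):
            assert sym == sym.upper()
            assert "−" not in sym

    def test_symbol_uppercasing(self):
        assert normalize_symbol(" vegfa ") == "VEGFA"
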