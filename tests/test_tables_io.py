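"""I/O and validation of catalogs, communities, class grids, FASTA, newick."""

import textwrap

import dendropy
import pytest
from hypothesis import given, settings, strategies as st

from barcodegap import errors, tables_io
from barcodegap.tables_io import (
    AlignedSequences,
    load_folmer_primers,
    load_published_eqs_grid,
    normalize_taxon,
    read_catalog,
    read_community,
    read_fasta,
    read_newick,
    wide_to_long,
    write_fasta,
    write_newick,
)


def write(tmp_path, name, content):
    path = tmp_path / name
    path.write_text(textwrap.dedent(content))
    return path


class TestNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("Nereis falsa", "Nereis falsa"),
        ("nereis  falsa", "Nereis falsa"),
        ("  NEREIS FALSA  ", "Nereis falsa"),
        ("hediste\tdiversicolor", "Hediste diversicolor"),
    ])
    def test_binomial_folding(self, raw, expected):
        assert normalize_taxon(raw) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet=st.characters(codec="ascii"), max_size=40))
    def test_idempotent(self, s):
        once = normalize_taxon(s)
        assert normalize_taxon(once) == once


class TestCatalog:
    def test_basic_parse(self, tmp_path):
        path = write(tmp_path, "cat.csv", """\
            taxon_name,phylum,ecological_group,barcoded_bold,barcoded_genbank
            Nereis falsa,Annelida,I,true,false
            Abra alba,Mollusca,III,false,true
            Capitella capitata,Annelida,V,true,true
        """)
        cat = read_catalog(path)
        assert len(cat) == 3
        assert cat.group_of()["Capitella capitata"] == "V"

    def test_duplicate_after_normalization(self, tmp_path):
        path = write(tmp_path, "cat.csv", """\
            taxon_name,phylum,ecological_group,barcoded_bold,barcoded_genbank
            Nereis falsa,Annelida,I,true,false
            nereis  falsa,Annelida,I,true,false
        """)
        with pytest.raises(errors.DuplicateError, match="nereis  falsa"):
            read_catalog(path)

    def test_illegal_group_label(self, tmp_path):
        path = write(tmp_path, "cat.csv", """\
            taxon_name,phylum,ecological_group,barcoded_bold,barcoded_genbank
            Nereis falsa,Annelida,I,true,false
            Abra alba,Mollusca,VI,false,true
        """)
        with pytest.raises(errors.ValidationError, match="row 1"):
            read_catalog(path)

    def test_missing_column_named(self, tmp_path):
        path = write(tmp_path, "cat.csv", """\
            taxon_name,phylum,barcoded_bold,barcoded_genbank
            Nereis falsa,Annelida,true,false
        """)
        with pytest.raises(errors.SchemaError, match="ecological_group"):
            read_catalog(path)


class TestCommunity:
    def test_full_grid(self, tmp_path):
        lines = ["site_id\tseason\ttaxon_name\tabundance"]
        for site in ("a", "b"):
            for season in ("fall", "spring"):
                for taxon in ("T one", "T two", "T three"):
                    lines.append(f"{site}\t{season}\t{taxon}\t3")
        path = tmp_path / "com.tsv"
        path.write_text("\n".join(lines))
        com = read_community(path)
        assert len(com) == 12
        assert len(com.sample_keys) == 4

    def test_negative_abundance(self, tmp_path):
        path = write(tmp_path, "com.csv", """\
            site_id,season,taxon_name,abundance
            a,fall,T one,-1
        """)
        with pytest.raises(errors.ValidationError, match="negative"):
            read_community(path)

    def test_unknown_season(self, tmp_path):
        path = write(tmp_path, "com.csv", """\
            site_id,season,taxon_name,abundance
            a,winter,T one,4
        """)
        with pytest.raises(errors.ValidationError, match="winter"):
            read_community(path)

    def test_duplicate_triple(self, tmp_path):
        path = write(tmp_path, "com.csv", """\
            site_id,season,taxon_name,abundance
            a,fall,T one,4
            a,fall,T one,5
        """)
        with pytest.raises(errors.DuplicateError):
            read_community(path)

    def test_unknown_taxon_vs_catalog(self, tmp_path, small_catalog):
        path = write(tmp_path, "com.csv", """\
            site_id,season,taxon_name,abundance
            a,fall,Not a species,4
        """)
        with pytest.raises(errors.TaxonLookupError, match="Not a species"):
            read_community(path, catalog=small_catalog)

    def test_wide_reader_matches_long(self):
        import pandas as pd
        wide = pd.DataFrame({"Sp one": [1, 0], "Sp two": [2, 3]},
                            index=["a", "b"])
        long = wide_to_long(wide, "fall")
        assert set(long.columns) == {"site_id", "season", "taxon_name",
                                     "abundance"}
        assert long.loc[(long.site_id == "b")
                        & (long.taxon_name == "Sp two"),
                        "abundance"].item() == 3


class TestRoundTrips:
    def test_catalog_round_trip(self, tmp_path, small_catalog):
        path = tmp_path / "cat.tsv"
        tables_io.write_catalog(small_catalog, path)
        back = read_catalog(path)
        assert back.df[["taxon_name", "phylum", "ecological_group",
                        "barcoded_bold", "barcoded_genbank"]].equals(
            small_catalog.df[["taxon_name", "phylum", "ecological_group",
                              "barcoded_bold", "barcoded_genbank"]])

    def test_community_round_trip(self, tmp_path, small_community):
        path = tmp_path / "com.tsv"
        tables_io.write_community(small_community, path)
        back = read_community(path)
        assert back.df.equals(small_community.df)
        assert back.sample_keys == small_community.sample_keys

    def test_fasta_round_trip(self, tmp_path):
        aln = AlignedSequences(["a1", "a2"], ["Sp one", "Sp two"],
                               ["ACGT-RYSWK", "ACGTTACGTA"])
        path = tmp_path / "aln.fasta"
        write_fasta(aln, path)
        back = read_fasta(path)
        assert back.accessions == aln.accessions
        assert back.species == aln.species
        assert back.sequences == aln.sequences
        assert back.alignment_length == 10

    def test_newick_round_trip(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:2):1,C:3);\n")
        tree = read_newick(path)
        out = tmp_path / "out.nwk"
        write_newick(tree, out)
        again = read_newick(out)
        d1 = {t.label: tree.seed_node.distance_from_tip()
              for t in tree.taxon_namespace}
        pdm1 = tree.phylogenetic_distance_matrix()
        pdm2 = again.phylogenetic_distance_matrix()
        for ta in tree.taxon_namespace:
            for tb in tree.taxon_namespace:
                if ta.label < tb.label:
                    a2 = again.taxon_namespace.get_taxon(ta.label)
                    b2 = again.taxon_namespace.get_taxon(tb.label)
                    assert abs(pdm1.patristic_distance(ta, tb)
                               - pdm2.patristic_distance(a2, b2)) < 1e-9


class TestFastaValidation:
    def test_ragged_alignment_rejected(self):
        with pytest.raises(errors.ValidationError, match="ragged"):
            AlignedSequences(["a", "b"], ["", ""], ["ACGTACGTAC",
                                                    "ACGTACGTA"])

    def test_illegal_characters_rejected(self):
        with pytest.raises(errors.ValidationError, match="illegal"):
            AlignedSequences(["a"], [""], ["ACGU"])

    def test_malformed_newick_raises(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:2:1,C:3);")
        with pytest.raises(errors.ValidationError, match="malformed"):
            read_newick(path)


class TestPackagedFixtures:
    def test_published_grid_shape(self):
        grid = load_published_eqs_grid()
        assert len(grid.df) == 60  # 15 sites x 2 seasons x 2 databases
        assert set(grid.df["database"]) == {"morphological", "reduced"}

    def test_folmer_primers_valid_iupac(self):
        from barcodegap.seqdelim import PrimerPair
        table = load_folmer_primers()
        assert "folmer" in set(table["name"])
        for _, row in table.iterrows():
            PrimerPair(row["forward"], row["reverse"], row["name"])
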