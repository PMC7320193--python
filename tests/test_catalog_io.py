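"""Parsing and round-trip behaviour of every input dialect."""
import pytest

from lhpc import catalog_io
from lhpc.types import (
    GeneCatalogRow,
    MorbidMapRow,
    OrthologPhenotypeRow,
    ParseError,
    PhenotypeMatchRow,
)


def _write(tmp_path, text, name="morbid_map.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestMorbidMap:
    def test_plain_key3_row(self, tmp_path):
        p = _write(tmp_path, "Tuberous sclerosis-1, 191100 (3)\tTSC1\t605284\t9q34.13\n")
        (row,) = catalog_io.read_morbid_map(p)
        assert row.phenotype_label == "Tuberous sclerosis-1"
        assert row.phenotype_mim == "191100"
        assert row.mapping_key == 3
        assert row.gene_mim == "605284"
        assert row.gene_symbols == ("TSC1",)
        assert row.marker is None

    @pytest.mark.parametrize(
        "label,marker",
        [
            ("{Asthma}, 600807 (3)", "susceptibility"),
            ("[Blood group variant], 600807 (3)", "non_disease"),
            ("?Uncertain disease, 600807 (3)", "unconfirmed"),
        ],
    )
    def test_markers_detected_not_stripped(self, tmp_path, label, marker):
        p = _write(tmp_path, f"{label}\tGENE\t600001\t\n")
        (row,) = catalog_io.read_morbid_map(p)
        assert row.marker == marker
        # label retains the marker characters for the audit trail
        assert row.phenotype_label[0] in "{[?"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "")
        assert catalog_io.read_morbid_map(p) == []

    def test_missing_key_is_parse_error_with_line(self, tmp_path):
        p = _write(tmp_path, "Good, 100001 (3)\tG\t600001\t\nBad phenotype\tG\t600001\t\n")
        with pytest.raises(ParseError, match=":2"):
            catalog_io.read_morbid_map(p)

    def test_non_integer_key_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "Odd, 100001 (x)\tG\t600001\t\n")
        with pytest.raises(ParseError, match="not an integer"):
            catalog_io.read_morbid_map(p)

    def test_no_line_silently_dropped(self, tmp_path):
        text = (
            "# comment\n"
            "Good, 100001 (3)\tG\t600001\t\n"
            "Bad line without key\tG\t600001\t\n"
            "Also good (2)\tG\t600002\t\n"
        )
        p = _write(tmp_path, text)
        rows, rejects = catalog_io.scan_morbid_map(p)
        assert len(rows) + len(rejects) == 3
        assert rejects[0][0] == 3

    def test_round_trip(self, tmp_path):
        rows = [
            MorbidMapRow("Tuberous sclerosis-1", "191100", 3, ("TSC1",), "605284", "9q34"),
            MorbidMapRow("{Asthma}", "600807", 3, ("A", "B"), "600002", ""),
            MorbidMapRow("No-mim phenotype", None, 2, ("C",), "600003", "1p36"),
        ]
        p = tmp_path / "mm.tsv"
        catalog_io.write_morbid_map(rows, p)
        back = catalog_io.read_morbid_map(p)
        assert [
            (r.phenotype_label, r.phenotype_mim, r.mapping_key, r.gene_symbols,
             r.gene_mim, r.cyto_location)
            for r in back
        ] == [
            (r.phenotype_label, r.phenotype_mim, r.mapping_key, r.gene_symbols,
             r.gene_mim, r.cyto_location)
            for r in rows
        ]


OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: TAP complex
namespace: cellular_component
is_a: GO:0043234

[Term]
id: GO:0000002
name: inner complex
namespace: cellular_component
is_a: GO:0000001
relationship: part_of GO:0043234

[Term]
id: GO:0000003
name: retired complex
namespace: cellular_component
is_obsolete: true

[Term]
id: GO:0000004
name: dangling child complex
namespace: cellular_component
is_a: GO:9999999

[Term]
id: GO:0043234
name: protein complex
namespace: cellular_component
"""


class TestOntology:
    @pytest.fixture()
    def terms(self, tmp_path):
        p = _write(tmp_path, OBO, "t.obo")
        return {t.term_id: t for t in catalog_io.read_ontology(p)}

    def test_single_parent(self, terms):
        assert terms["GO:0000001"].parents == (("is_a", "GO:0043234"),)

    def test_generic_term_parsed_not_removed_here(self, terms):
        assert terms["GO:0043234"].name == "protein complex"

    def test_both_relation_kinds_captured(self, terms):
        assert set(terms["GO:0000002"].parents) == {
            ("is_a", "GO:0000001"),
            ("part_of", "GO:0043234"),
        }

    def test_obsolete_flagged(self, terms):
        assert terms["GO:0000003"].obsolete
        assert not terms["GO:0000001"].obsolete

    def test_dangling_parent_kept_and_flagged(self, terms):
        t = terms["GO:0000004"]
        assert ("is_a", "GO:9999999") in t.parents
        assert t.unresolved_parents == {"GO:9999999"}

    def test_round_trip(self, tmp_path, terms):
        out = tmp_path / "rt.obo"
        originals = sorted(terms.values(), key=lambda t: t.term_id)
        catalog_io.write_ontology(originals, out)
        back = sorted(catalog_io.read_ontology(out), key=lambda t: t.term_id)
        assert back == originals


class TestAuxTables:
    def test_ortholog_row(self, tmp_path):
        p = _write(
            tmp_path,
            "human_entrez_id\tmouse_gene_id\tmp_terms\tlethality_stage\n"
            "4688\tNcf4\tMP:0002412\t\n",
            "orthologs.tsv",
        )
        aux = catalog_io.read_aux_tables({"orthologs": p})
        assert aux.orthologs == [
            OrthologPhenotypeRow("4688", "Ncf4", frozenset({"MP:0002412"}), None)
        ]

    def test_removed_gene_retained_at_parse_time(self, tmp_path):
        p = _write(
            tmp_path,
            "gene_mim\tentrez_id\tstatus\tprotein_coding\n600001\t\tremoved\t1\n",
            "genes.tsv",
        )
        aux = catalog_io.read_aux_tables({"genes": p})
        assert aux.genes == [GeneCatalogRow("600001", None, "removed", True)]

    def test_empty_ortholog_file(self, tmp_path):
        p = _write(tmp_path, "human_entrez_id\tmouse_gene_id\tmp_terms\tlethality_stage\n",
                   "orthologs.tsv")
        aux = catalog_io.read_aux_tables({"orthologs": p})
        assert aux.orthologs == []

    def test_unknown_column_is_error_naming_it(self, tmp_path):
        p = _write(tmp_path, "mp_term\thp_term\tbogus\na\tb\tc\n", "pm.tsv")
        with pytest.raises(ParseError, match="bogus"):
            catalog_io.read_aux_tables({"phenotype_matches": p})

    def test_duplicate_phenotype_matches_deduplicated(self, tmp_path):
        p = _write(tmp_path, "mp_term\thp_term\nMP:1\tHP:1\nMP:1\tHP:1\nMP:1\tHP:2\n",
                   "pm.tsv")
        aux = catalog_io.read_aux_tables({"phenotype_matches": p})
        assert aux.phenotype_matches == [
            PhenotypeMatchRow("MP:1", "HP:1"),
            PhenotypeMatchRow("MP:1", "HP:2"),
        ]

    def test_round_trip_all_tables(self, world, tmp_path):
        aux = catalog_io.read_aux_tables(
            {k: v for k, v in world["paths"].items()
             if k not in ("morbid_map", "ontology")}
        )
        out = {
            "genes": tmp_path / "g.tsv",
            "ps_memberships": tmp_path / "p.tsv",
            "annotations": tmp_path / "a.tsv",
            "orthologs": tmp_path / "o.tsv",
            "phenotype_matches": tmp_path / "m.tsv",
            "disease_phenotypes": tmp_path / "d.tsv",
            "gof": tmp_path / "f.tsv",
        }
        catalog_io.write_gene_catalog(aux.genes, out["genes"])
        catalog_io.write_ps_memberships(aux.ps_memberships, out["ps_memberships"])
        catalog_io.write_annotations(aux.annotations, out["annotations"])
        catalog_io.write_orthologs(aux.orthologs, out["orthologs"])
        catalog_io.write_phenotype_matches(aux.phenotype_matches, out["phenotype_matches"])
        catalog_io.write_disease_phenotypes(aux.disease_phenotypes, out["disease_phenotypes"])
        catalog_io.write_gof_proteins(aux.gof_proteins, out["gof"])
        back = catalog_io.read_aux_tables(out)
        assert back.genes == aux.genes
        assert back.ps_memberships == aux.ps_memberships
        assert back.annotations == aux.annotations
        assert back.orthologs == aux.orthologs
        assert back.phenotype_matches == aux.phenotype_matches
        assert back.disease_phenotypes == aux.disease_phenotypes
        assert back.gof_proteins == aux.gof_proteins
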