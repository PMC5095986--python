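"""TSV/JSON round-trips, ClinVar-style export, and ontology lookup."""

import io
import json

import pytest

from mvld.fixtures import generate_records
from mvld.interop import (
    CLINVAR_COLUMNS,
    MVLD_COLUMNS,
    ConversionError,
    MvldReadError,
    UnknownCancerTermError,
    from_clinvar_row,
    lookup_cancer_term,
    mvld_table_str,
    ncit_code_for,
    oncotree_entries,
    read_mvld_json,
    read_mvld_table,
    to_clinvar_row,
    write_clinvar_table,
    write_mvld_json,
)
from mvld.model import evolve
from mvld.tiering import TIER_SENTENCES


@pytest.fixture(scope="module")
def corpus():
    records, _ = generate_records(40, seed=11)
    return records


class TestTable:
    def test_header_is_the_canonical_column_order(self, corpus):
        header = mvld_table_str(corpus).splitlines()[0]
        assert tuple(header.split("\t")) == MVLD_COLUMNS

    def test_roundtrip_equality(self, corpus):
        text = mvld_table_str(corpus)
        back, report = read_mvld_table(io.StringIO(text))
        assert back == corpus
        assert report.error_count == 0

    def test_byte_identical_output_across_runs(self, corpus):
        assert mvld_table_str(corpus) == mvld_table_str(list(corpus))

    def test_list_cells_use_semicolons(self, record):
        r = evolve(
            record,
            interpretation=evolve(record.interpretation, pmids=(12345678, 23456789)),
        )
        row = mvld_table_str([r]).splitlines()[1].split("\t")
        assert row[MVLD_COLUMNS.index("pmids")] == "12345678;23456789"

    def test_empty_corpus_writes_header_only(self):
        assert mvld_table_str([]) == "\t".join(MVLD_COLUMNS) + "\n"

    def test_unknown_column_preserved_with_warning(self, record):
        text = mvld_table_str([record]).splitlines()
        text[0] += "\tmy_note"
        text[1] += "\tcheck me"
        back, report = read_mvld_table(io.StringIO("\n".join(text) + "\n"))
        assert back[0].extensions == {"my_note": "check me"}
        assert any(f.rule_id == "IO.UNKNOWN_COLUMN" for f in report.findings)

    def test_unknown_columns_survive_a_full_cycle_byte_identically(self, record):
        r = evolve(record, extensions={"my_note": "check me", "site_id": "42"})
        text = mvld_table_str([r])
        back, _ = read_mvld_table(io.StringIO(text))
        assert mvld_table_str(back) == text

    def test_missing_header_is_a_hard_error(self):
        with pytest.raises(MvldReadError):
            read_mvld_table(io.StringIO(""))
        with pytest.raises(MvldReadError):
            read_mvld_table(io.StringIO("gene_name\tchromosome\nBRAF\t7\n"))

    def test_duplicate_columns_are_a_hard_error(self):
        header = "\t".join(MVLD_COLUMNS) + "\tgene_name"
        with pytest.raises(MvldReadError):
            read_mvld_table(io.StringIO(header + "\n"))

    def test_unstructurable_row_is_skipped_with_finding(self, record):
        lines = mvld_table_str([record]).splitlines()
        bad = lines[1].split("\t")
        bad[MVLD_COLUMNS.index("dna_position")] = "not-a-number"
        text = "\n".join([lines[0], "\t".join(bad), lines[1]]) + "\n"
        back, report = read_mvld_table(io.StringIO(text))
        assert len(back) == 1
        skipped = [f for f in report.findings if f.rule_id == "IO.ROW_SKIPPED"]
        assert len(skipped) == 1 and "row 2" in skipped[0].message


class TestJson:
    def test_roundtrip_equality(self, corpus):
        buf = io.StringIO()
        write_mvld_json(corpus, buf)
        back, report = read_mvld_json(io.StringIO(buf.getvalue()))
        assert back == corpus and report.error_count == 0

    def test_document_carries_version(self, corpus):
        buf = io.StringIO()
        write_mvld_json(corpus[:1], buf)
        doc = json.loads(buf.getvalue())
        assert doc["mvld_version"] == "1.0"
        assert len(doc["records"]) == 1

    def test_garbage_is_a_hard_error(self):
        with pytest.raises(MvldReadError):
            read_mvld_json(io.StringIO("not json"))


class TestClinVarExport:
    def test_row_renders_schema_and_tier_sentence(self, record):
        row = to_clinvar_row(record)
        assert "CanDL" in row["assertion_method"]
        assert TIER_SENTENCES[1] in row["assertion_method"]

    def test_condition_renders_source_code_label(self, record):
        r = evolve(
            record,
            cancer=evolve(record.cancer, cancer_type=lookup_cancer_term("RGNT", "Oncotree")),
        )
        assert to_clinvar_row(r)["condition"] == "Oncotree:RGNT (rosette-forming glioneuronal tumor)"

    def test_refuses_records_with_validation_errors(self, record):
        broken = evolve(record, descriptor=evolve(record.descriptor, gene_symbol=None))
        with pytest.raises(ConversionError) as exc:
            to_clinvar_row(broken)
        assert any(f.rule_id == "REQ.GENE_NAME" for f in exc.value.findings)

    def test_export_is_lossless_for_required_fields(self, corpus):
        for original in corpus:
            back = from_clinvar_row(to_clinvar_row(original))
            assert back.descriptor == original.descriptor
            assert back.interpretation == original.interpretation
            assert back.cancer.cancer_type == original.cancer.cancer_type
            assert back.cancer.biomarker_class == original.cancer.biomarker_class
            assert back.cancer.level_of_evidence == original.cancer.level_of_evidence

    def test_table_has_one_row_per_record(self, corpus):
        buf = io.StringIO()
        write_clinvar_table(corpus, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "\t".join(CLINVAR_COLUMNS)
        assert len(lines) == len(corpus) + 1


class TestOntologyLookup:
    def test_code_lookup(self):
        term = lookup_cancer_term("RGNT", "Oncotree")
        assert term.label == "rosette-forming glioneuronal tumor"
        assert term.source == "Oncotree"

    def test_label_lookup_is_case_insensitive(self):
        assert lookup_cancer_term("melanoma", "Oncotree").code == "MEL"
        assert lookup_cancer_term("MELANOMA", "NCIt").code == "C3224"

    def test_oncotree_entries_carry_paired_ncit_codes(self):
        assert ncit_code_for("MEL") == "C3224"
        for row in oncotree_entries():
            assert row["ncit_code"].startswith("C")

    def test_unknown_term_suggests_neighbours(self):
        with pytest.raises(UnknownCancerTermError):
            lookup_cancer_term("XYZQ", "Oncotree")
        with pytest.raises(UnknownCancerTermError) as exc:
            lookup_cancer_term("melanomaa", "Oncotree")
        assert "Melanoma" in exc.value.suggestions

    def test_fixture_has_desk_scale_coverage(self):
        assert len(oncotree_entries()) == 50
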