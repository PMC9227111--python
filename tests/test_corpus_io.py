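import csv

import pandas as pd
import pytest

from cryogap.corpus_io import (
    ArticleRecord,
    DEFAULT_EXCLUDED_NAMES,
    ExceptionalSpeciesRecord,
    TreeCountRow,
    deduplicate_articles,
    packaged_data,
    packaged_exceptional_list,
    read_article_export,
    read_backbone,
    read_exceptional_list,
    read_lexicon,
    read_tree_counts,
    write_article_export,
    write_backbone,
    write_exceptional_list,
    write_lexicon,
    write_tree_counts,
)
from cryogap.errors import ConfigurationError, ValidationError

from conftest import article


def _write_csv(path, header, rows):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# article exports
# ---------------------------------------------------------------------------


class TestReadArticleExport:
    def test_empty_file_yields_no_records(self, tmp_path):
        path = tmp_path / "empty.csv"
        _write_csv(path, ["UT", "TI", "AB"], [])
        report = read_article_export(path)
        assert report.records == [] and report.skipped == []

    def test_blank_title_rows_are_skipped_and_reported(self, tmp_path):
        path = tmp_path / "corpus.csv"
        _write_csv(
            path,
            ["UT", "TI", "AB"],
            [["A", "Title one", "x"], ["B", "   ", "y"], ["C", "Title three", ""]],
        )
        report = read_article_export(path)
        assert [r.article_id for r in report.records] == ["A", "C"]
        assert report.skipped == [(2, "empty title")]

    def test_two_exports_concatenate_before_dedup(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        _write_csv(p1, ["UT", "TI", "AB"], [["A", "t", ""], ["B", "t", ""]])
        _write_csv(p2, ["UT", "TI", "AB"], [["B", "t", ""], ["C", "t", ""]])
        merged = read_article_export(p1).records + read_article_export(p2).records
        assert len(merged) == 4  # dedup happens later

    def test_missing_mapped_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        _write_csv(path, ["ID", "TI", "AB"], [["A", "t", ""]])
        with pytest.raises(ConfigurationError, match="UT"):
            read_article_export(path)

    def test_custom_column_map_and_passthrough_fields(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        with open(path, "w") as fh:
            fh.write("id\ttitle\tsummary\tyear\n1\tA title\tabs\t1999\n")
        report = read_article_export(
            path, {"article_id": "id", "title": "title", "abstract": "summary"}
        )
        (rec,) = report.records
        assert rec.abstract == "abs" and rec.source_fields == {"year": "1999"}

    def test_xlsx_export_is_supported(self, tmp_path):
        path = tmp_path / "corpus.xlsx"
        pd.DataFrame(
            {"UT": ["X"], "TI": ["An xlsx title"], "AB": ["body"]}
        ).to_excel(path, index=False)
        assert read_article_export(path).records[0].article_id == "X"

    def test_whitespace_is_normalized(self, tmp_path):
        path = tmp_path / "ws.csv"
        _write_csv(path, ["UT", "TI", "AB"], [["A", "  Two   words ", "a\n b"]])
        rec = read_article_export(path).records[0]
        assert rec.title == "Two words" and rec.abstract == "a b"


class TestDeduplicate:
    @pytest.mark.parametrize(
        "ids, n_unique, n_dup",
        [([], 0, 0), (["A", "B", "A", "C", "B"], 3, 2), (["A", "B", "C"], 3, 0)],
    )
    def test_counts(self, ids, n_unique, n_dup):
        records = [article(i, "t") for i in ids]
        unique, dups = deduplicate_articles(records)
        assert len(unique) == n_unique and dups == n_dup
        assert len(unique) + dups == len(records)

    def test_first_occurrence_kept_in_order(self):
        records = [article("A", "first"), article("B", "b"), article("A", "second")]
        unique, _ = deduplicate_articles(records)
        assert [r.title for r in unique] == ["first", "b"]

    def test_idempotent(self):
        records = [article(i, "t") for i in ["A", "B", "A"]]
        once, _ = deduplicate_articles(records)
        twice, dups = deduplicate_articles(once)
        assert twice == once and dups == 0


def test_article_record_rejects_empty_id_and_title():
    with pytest.raises(ValidationError):
        ArticleRecord("", "title")
    with pytest.raises(ValidationError):
        ArticleRecord("A", "   ")


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

BACKBONE_HEADER = ["taxonID", "scientificName", "taxonRank", "family", "taxonomicStatus"]


class TestReadBackbone:
    def test_genera_and_families_collected(self, tmp_path):
        path = tmp_path / "bb.csv"
        _write_csv(
            path,
            BACKBONE_HEADER,
            [
                ["1", "Rosaceae", "family", "Rosaceae", "Accepted"],
                ["2", "Malus", "genus", "Rosaceae", "Accepted"],
                ["3", "Pyrus", "genus", "Rosaceae", "Accepted"],
                ["4", "Malus domestica", "species", "Rosaceae", "Accepted"],
            ],
        )
        bb = read_backbone(path)
        assert bb.genera == {"Malus", "Pyrus"}
        assert bb.families == {"Rosaceae"}
        assert bb.genus_to_family["Pyrus"] == "Rosaceae"

    def test_homograph_genus_is_both_listed_and_excluded(self, tmp_path):
        path = tmp_path / "bb.csv"
        _write_csv(path, BACKBONE_HEADER, [["1", "Aa", "genus", "Orchidaceae", "Accepted"]])
        bb = read_backbone(path)  # default packaged exclusion sidecar
        assert "Aa" in bb.genera and "Aa" in bb.excluded_names
        assert set(DEFAULT_EXCLUDED_NAMES) <= bb.excluded_names

    def test_duplicate_genus_same_family_collapses(self, tmp_path):
        path = tmp_path / "bb.csv"
        _write_csv(
            path,
            BACKBONE_HEADER,
            [
                ["1", "Malus", "genus", "Rosaceae", "Accepted"],
                ["2", "Malus", "genus", "Rosaceae", "Synonym"],
            ],
        )
        assert read_backbone(path).genera == {"Malus"}

    def test_conflicting_family_assignment_is_an_error(self, tmp_path):
        path = tmp_path / "bb.csv"
        _write_csv(
            path,
            BACKBONE_HEADER,
            [
                ["1", "Malus", "genus", "Rosaceae", "Accepted"],
                ["2", "Malus", "genus", "Orchidaceae", "Accepted"],
            ],
        )
        with pytest.raises(ValidationError, match="Malus"):
            read_backbone(path)

    def test_common_name_aliases_resolve_through_backbone(self, tmp_path):
        path = tmp_path / "bb.csv"
        _write_csv(path, BACKBONE_HEADER, [["1", "Malus", "genus", "Rosaceae", "Accepted"]])
        bb = read_backbone(path, common_names={"apple": "Malus", "oak": "Quercus"})
        assert bb.common_names == {"apple": ("Malus", "Rosaceae")}  # oak unresolvable

    def test_round_trip(self, tmp_path, backbone):
        path = tmp_path / "bb.csv"
        excl = tmp_path / "excl.txt"
        excl.write_text("Medium\n")
        write_backbone(backbone, path)
        again = read_backbone(
            path, excl, common_names={a: gf[0] for a, gf in backbone.common_names.items()}
        )
        assert again == backbone


# ---------------------------------------------------------------------------
# exceptional list
# ---------------------------------------------------------------------------


class TestExceptionalList:
    def test_genus_is_first_token(self, tmp_path):
        path = tmp_path / "exc.csv"
        _write_csv(
            path,
            ["species", "family", "exceptionality_factor"],
            [["Shorea acuminata", "Dipterocarpaceae", "EF2"]],
        )
        (rec,) = read_exceptional_list(path)
        assert rec.genus == "Shorea" and rec.efs == ("EF2",)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "exc.csv"
        _write_csv(path, ["species", "family", "exceptionality_factor"], [])
        assert read_exceptional_list(path) == []

    def test_unknown_ef_token_reports_row(self, tmp_path):
        path = tmp_path / "exc.csv"
        _write_csv(
            path,
            ["species", "family", "exceptionality_factor"],
            [["Good species", "Fam", "EF1"], ["Bad species", "Fam", "EF9"]],
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_exceptional_list(path)

    def test_multiple_ef_flags_parse(self, tmp_path):
        path = tmp_path / "exc.csv"
        _write_csv(
            path,
            ["species", "family", "exceptionality_factor"],
            [["Carex alpha", "Cyperaceae", "EF3;EF4"]],
        )
        assert read_exceptional_list(path)[0].efs == ("EF3", "EF4")

    def test_packaged_fixture_has_775_species(self):
        records = packaged_exceptional_list()
        assert len(records) == 775
        assert len({r.family for r in records}) == 111

    def test_round_trip(self, tmp_path):
        records = [
            ExceptionalSpeciesRecord("Shorea acuminata", "Dipterocarpaceae", ("EF2",)),
            ExceptionalSpeciesRecord("Carex alpha", "Cyperaceae", ("EF3", "EF4")),
        ]
        path = tmp_path / "exc.csv"
        write_exceptional_list(records, path)
        assert read_exceptional_list(path) == records


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


class TestLexicon:
    def test_packaged_default_loads(self, default_lexicon):
        assert "cryopreserv*" in default_lexicon.positive
        assert "liquid nitrogen" in default_lexicon.positive
        assert "sperm" in default_lexicon.negative
        assert "human" in default_lexicon.review_triggers
        assert default_lexicon.common_names["apple"] == "Malus"
        assert "Medium" in default_lexicon.excluded_names

    def test_duplicate_keyword_in_one_section_collapses(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text("[positive]\nsperm\nsperm\n[negative]\nmammal\n")
        lex = read_lexicon(path)
        assert lex.positive == {"sperm"}

    def test_keyword_in_positive_and_negative_is_an_error(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text("[positive]\ncryogenic\n[negative]\ncryogenic\n")
        with pytest.raises(ValidationError, match="cryogenic"):
            read_lexicon(path)

    def test_unknown_section_is_an_error(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text("[bogus]\nword\n")
        with pytest.raises(ValidationError, match="bogus"):
            read_lexicon(path)

    def test_round_trip(self, tmp_path, default_lexicon):
        path = tmp_path / "lex.txt"
        write_lexicon(default_lexicon, path)
        assert read_lexicon(path) == default_lexicon


# ---------------------------------------------------------------------------
# tree counts
# ---------------------------------------------------------------------------


def test_tree_counts_na_means_missing(tmp_path):
    rows = read_tree_counts(packaged_data("table_tree_counts.csv"))
    by_genus = {r.genus: r for r in rows}
    assert by_genus["Kanaloa"].wfo_synonym is None
    assert by_genus["Inga"].wfo_accepted == 279
    path = tmp_path / "trees.csv"
    write_tree_counts(rows, path)
    assert read_tree_counts(path) == rows
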