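import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from cryogap.corpus_io import TaxonBackbone
from cryogap.synthetic_data import (
    generate_corpus,
    truth_intended_families,
    truth_intended_genera,
)
from cryogap.taxonomy_matching import (
    MatchResult,
    Provenance,
    batch_match,
    find_names,
    infer_families,
    iterative_match,
)
from cryogap.errors import ValidationError

from conftest import article


def brute_force_find(text, names, excluded=()):
    """Independent oracle: substring scan with letter-boundary checks."""
    def is_letter(ch):
        return ch is not None and ch.isalpha()

    found = set()
    for name in set(names) - set(excluded):
        start = 0
        while True:
            i = text.find(name, start)
            if i < 0:
                break
            before = text[i - 1] if i > 0 else None
            j = i + len(name)
            after = text[j] if j < len(text) else None
            if not is_letter(before) and not is_letter(after):
                found.add(name)
                break
            start = i + 1
    return frozenset(found)


class TestFindNames:
    def test_whole_word_match(self):
        assert find_names(
            "Cryopreservation of Malus shoot tips", {"Malus", "Pyrus"}
        ) == {"Malus"}

    def test_excluded_homograph_never_matches(self):
        assert (
            find_names("A new cryopreservation medium", {"Medium", "Malus"}, {"Medium"})
            == frozenset()
        )
        # even capitalized uses are suppressed once excluded
        assert (
            find_names("Medium composition effects", {"Medium"}, {"Medium"})
            == frozenset()
        )

    def test_empty_text(self):
        assert find_names("", {"Malus"}, set()) == frozenset()

    def test_case_sensitive(self):
        assert find_names("malus grown in vitro", {"Malus"}) == frozenset()
        assert find_names("malus grown in vitro", {"Malus"}) == brute_force_find(
            "malus grown in vitro", {"Malus"}
        )

    def test_boundaries_are_non_letters(self):
        assert find_names("Malus-derived lines", {"Malus"}) == {"Malus"}
        assert find_names("Malus' seeds; (Malus)", {"Malus"}) == {"Malus"}
        assert find_names("Malusx hybrids", {"Malus"}) == frozenset()

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.sampled_from(
                ["Malus", "Pyrus", "Medium", "malus", "storage", "of", "x9",
                 "Malusoid", "-", "(Pyrus)", "Shorea,"]
            ),
            max_size=8,
        )
    )
    def test_matches_brute_force_oracle(self, words):
        text = " ".join(words)
        names = {"Malus", "Pyrus", "Medium", "Shorea"}
        assert find_names(text, names, {"Medium"}) == brute_force_find(
            text, names, {"Medium"}
        )


class TestIterativeMatch:
    def test_title_genus_shadows_abstract_genus(self, backbone):
        rec = article("A", "Cryopreservation of Malus shoot tips",
                      "Comparison with Pyrus material")
        result = iterative_match(rec, backbone)
        assert result.matched_genera == {"Malus"}
        assert result.pass_no == 1
        assert "Pyrus" not in result.matched_genera

    def test_common_name_resolves_in_pass_2(self, backbone):
        rec = article("A", "Cryopreservation of apple shoot tips", "no names here")
        result = iterative_match(rec, backbone)
        assert result.matched_genera == {"Malus"} and result.pass_no == 2

    def test_abstract_passes_run_when_title_is_empty_of_names(self, backbone):
        by_name = iterative_match(
            article("A", "Shoot tip storage", "Pyrus scions were frozen"), backbone
        )
        assert by_name.pass_no == 3 and by_name.matched_genera == {"Pyrus"}
        by_alias = iterative_match(
            article("B", "Shoot tip storage", "frozen apple scions"), backbone
        )
        assert by_alias.pass_no == 4 and by_alias.matched_genera == {"Malus"}

    def test_no_names_anywhere(self, backbone):
        result = iterative_match(article("A", "Shoot tip storage", "nothing"), backbone)
        assert result == MatchResult("A")

    def test_family_name_matches_directly(self, backbone):
        result = iterative_match(
            article("A", "Cryopreservation in the Orchidaceae", ""), backbone
        )
        assert result.matched_families == {"Orchidaceae"}
        assert result.matched_genera == frozenset()
        assert not result.family_inferred

    def test_provenance_records_winning_pass_only(self, backbone):
        result = iterative_match(
            article("A", "Malus and Pyrus storage", "Shorea too"), backbone
        )
        assert {p.pass_no for p in result.provenance} == {1}
        assert {p.name for p in result.provenance} == {"Malus", "Pyrus"}


class TestInferFamilies:
    def test_families_filled_from_genera(self, backbone):
        result = infer_families(
            MatchResult("A", matched_genera=frozenset({"Malus"})), backbone
        )
        assert result.matched_families == {"Rosaceae"} and result.family_inferred

    def test_no_genera_is_a_noop(self, backbone):
        start = MatchResult("A")
        assert infer_families(start, backbone) == start

    def test_existing_families_not_overwritten(self, backbone):
        start = MatchResult(
            "A",
            matched_genera=frozenset({"Malus"}),
            matched_families=frozenset({"Rosaceae"}),
        )
        out = infer_families(start, backbone)
        assert out == start and not out.family_inferred


class TestBatchMatch:
    def test_empty_corpus(self, backbone):
        results, summary = batch_match([], backbone)
        assert results == [] and summary.n_articles == 0
        assert summary.n_no_genus == 0 == summary.n_no_family_after_inference

    def test_summary_matches_planted_truth(self, synth_backbone, synth_corpus):
        records, truth = synth_corpus
        from cryogap.corpus_io import deduplicate_articles

        unique, _ = deduplicate_articles(records)
        results, summary = batch_match(unique, synth_backbone)
        tmap = {t.article_id: t for t in truth.articles if not t.is_duplicate}
        expected_no_genus = sum(
            1 for t in tmap.values() if not truth_intended_genera(t, synth_backbone)
        )
        assert summary.n_no_genus == expected_no_genus
        expected_no_family = sum(
            1 for t in tmap.values() if not truth_intended_families(t, synth_backbone)
        )
        assert summary.n_no_family_after_inference == expected_no_family
        assert (
            summary.n_no_family_after_inference
            <= summary.n_no_family_before_inference
            <= summary.n_articles
        )

    def test_all_title_genera_means_no_unmatched_family(self, synth_backbone):
        from cryogap.synthetic_data import CorpusConfig

        config = CorpusConfig(
            p_title_family=0.0, p_title_genus=1.0, p_common_name=0.0,
            p_abstract_genus=0.0, p_abstract_common=0.0, duplicate_rate=0.0,
        )
        records, _ = generate_corpus(synth_backbone, 100, config, seed=5)
        results, summary = batch_match(records, synth_backbone)
        assert summary.n_no_genus == 0
        assert summary.n_no_family_after_inference == 0
        assert all(r.pass_no == 1 for r in results)


class TestMatchingProperties:
    def test_abstract_mutation_cannot_change_title_pass_results(
        self, synth_backbone, synth_corpus
    ):
        records, _ = synth_corpus
        for rec in records[:200]:
            base = iterative_match(rec, synth_backbone)
            if base.pass_no in (1, 2):
                mutated = dataclasses.replace(
                    rec, abstract="Pyrus Malus apple totally different"
                )
                assert iterative_match(mutated, synth_backbone) == base

    def test_exclusion_never_increases_matches(self, backbone):
        texts = [
            "Cryopreservation of Malus and Pyrus",
            "Medium effects on Shorea",
            "nothing at all",
        ]
        names = backbone.genera | backbone.families
        for text in texts:
            before = find_names(text, names, backbone.excluded_names)
            for extra in names:
                after = find_names(
                    text, names, backbone.excluded_names | {extra}
                )
                assert after <= before

    def test_backbone_growth_is_monotone_in_genus_matches(
        self, synth_backbone, synth_corpus
    ):
        records, _ = synth_corpus
        records = records[:150]
        shrunk_map = {
            g: f
            for g, f in synth_backbone.genus_to_family.items()
            if g <= "M"  # drop roughly half the genera
        }
        shrunk = TaxonBackbone(
            genera=frozenset(shrunk_map),
            families=synth_backbone.families,
            genus_to_family=shrunk_map,
            excluded_names=synth_backbone.excluded_names,
            common_names={
                a: gf
                for a, gf in synth_backbone.common_names.items()
                if gf[0] in shrunk_map
            },
        )
        def n_with_genus(bb):
            results, _ = batch_match(records, bb)
            return sum(1 for r in results if r.matched_genera)

        assert n_with_genus(shrunk) <= n_with_genus(synth_backbone)

    def test_provenance_consistency_is_enforced(self):
        with pytest.raises(ValidationError):
            MatchResult(
                "A",
                matched_genera=frozenset({"Malus"}),
                provenance=(Provenance("Pyrus", "title", 1, "scientific"),),
            )
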