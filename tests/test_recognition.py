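import pytest

from habminer.analysis import extract_noun_phrases
from habminer.fixtures import (
    ANIMAL,
    BODY_FLUID,
    CHEESE,
    DIGESTIVE_TRACT,
    GUT_MUCOSA,
    HUMAN,
    INFANT,
    IRON_RICH_ENV,
    MOUSE,
    MUMMY_TISSUE,
    PHARYNGEAL_MUCOSA,
    PLANT,
    WET_ENV,
)
from habminer.recognition import (
    RecognitionConfig,
    apply_boundary_rules,
    attach_modifiers,
    detect_entities,
    match_ontology,
    resolve_coordination,
    simplify_noun_phrase,
    split_coordination,
)


def candidates_of(analyzed, text, sentence_index=0):
    sentence = analyzed(text).sentences[sentence_index]
    return [
        simplify_noun_phrase(np, sentence)
        for np in extract_noun_phrases(sentence)
    ], sentence


def candidate_named(analyzed, text, surface):
    cands, _ = candidates_of(analyzed, text)
    for cand in cands:
        if cand.surface_form == surface:
            return cand
    raise AssertionError(f"no candidate {surface!r} in {[c.surface_form for c in cands]}")


class TestSimplification:
    @pytest.mark.parametrize(
        "text,simplified",
        [
            ("the mummy tissue", "mummy tissue"),  # determiner dropped
            ("its small intestine", "small intestine"),  # possessive dropped
            ("water", "water"),  # nothing removable
        ],
    )
    def test_non_informative_words_removed(self, analyzed, text, simplified):
        cands, _ = candidates_of(analyzed, text)
        assert [c.surface_form for c in cands] == [simplified]

    def test_all_tokens_removed_gives_empty_candidate(self, analyzed):
        sentence = analyzed("the").sentences[0]
        nps = extract_noun_phrases(sentence)
        assert len(simplify_noun_phrase(nps[0], sentence)) == 0


class TestCoordinationSplit:
    @pytest.mark.parametrize(
        "phrase,sub1,sub2",
        [
            ("pharyngeal and gut mucosa", "pharyngeal mucosa", "gut mucosa"),
            ("iron-rich and wet environment", "iron-rich environment", "wet environment"),
            ("plants and animals", "plants", "animals"),
            ("ground and surface water", "ground water", "surface water"),
        ],
    )
    def test_shared_head_completion(self, analyzed, phrase, sub1, sub2):
        candidate = candidate_named(analyzed, phrase, phrase)
        split = split_coordination(candidate)
        assert split is not None
        assert split[0].surface_form == sub1
        assert split[1].surface_form == sub2

    def test_no_conjunction_returns_none(self, analyzed):
        candidate = candidate_named(analyzed, "the mummy tissue", "mummy tissue")
        assert split_coordination(candidate) is None

    def test_discontinuous_fragments_for_first_subphrase(self, analyzed):
        text = "the pharyngeal and gut mucosa"
        candidate = candidate_named(analyzed, text, "pharyngeal and gut mucosa")
        sub1, _sub2 = split_coordination(candidate)
        assert len(sub1.fragments) == 2  # "pharyngeal" ... "mucosa"
        start1, end1 = sub1.fragments[0]
        assert text[start1:end1] == "pharyngeal"


class TestCoordinationResolution:
    def run(self, analyzed, ontology, phrase):
        candidate = candidate_named(analyzed, phrase, phrase)
        sub1, sub2 = split_coordination(candidate)
        return resolve_coordination(sub1, sub2, candidate, ontology)

    def test_no_common_parent_gives_two_entities(self, analyzed, ontology):
        mentions = self.run(analyzed, ontology, "pharyngeal and gut mucosa")
        assert len(mentions) == 2
        discontinuous = mentions[0]
        assert len(discontinuous.fragments) == 2
        assert discontinuous.concept_ids == (PHARYNGEAL_MUCOSA,)
        assert mentions[1].concept_ids == (GUT_MUCOSA,)

    def test_common_parent_merges_into_one_entity(self, analyzed, ontology):
        mentions = self.run(analyzed, ontology, "iron-rich and wet environment")
        assert len(mentions) == 1
        assert mentions[0].text == "iron-rich and wet environment"
        assert set(mentions[0].concept_ids) == {IRON_RICH_ENV, WET_ENV}

    def test_single_noun_subphrases_stay_separate(self, analyzed, ontology):
        mentions = self.run(analyzed, ontology, "plants and animals")
        assert len(mentions) == 2
        assert {m.concept_ids[0] for m in mentions} == {PLANT, ANIMAL}

    def test_disjoint_parents_stay_separate(self, analyzed, ontology):
        mentions = self.run(analyzed, ontology, "mouse and cheese")
        assert len(mentions) == 2
        assert {m.concept_ids[0] for m in mentions} == {MOUSE, CHEESE}


class TestOntologyMatching:
    def test_bodily_fluid_two_matches(self, analyzed, ontology):
        candidate = candidate_named(
            analyzed, "the animal bodily fluid", "animal bodily fluid"
        )
        matches = match_ontology(candidate, ontology)
        by_concept = {m.concept_id: m for m in matches}
        assert set(by_concept) == {ANIMAL, BODY_FLUID}
        assert by_concept[ANIMAL].kind == "prefix_partial"
        assert by_concept[ANIMAL].token_range == (0, 1)
        assert by_concept[BODY_FLUID].kind == "internal_partial"
        assert by_concept[BODY_FLUID].token_range == (1, 3)
        assert by_concept[BODY_FLUID].label == "bodily fluid"

    def test_exact_match_covers_candidate(self, analyzed, ontology):
        candidate = candidate_named(analyzed, "the mummy tissue", "mummy tissue")
        matches = match_ontology(candidate, ontology)
        assert [(m.concept_id, m.kind) for m in matches] == [(MUMMY_TISSUE, "exact")]

    def test_plural_matches_via_lemma(self, analyzed, ontology):
        candidate = candidate_named(analyzed, "animals", "animals")
        matches = match_ontology(candidate, ontology)
        assert [(m.concept_id, m.via) for m in matches] == [(ANIMAL, "lemma")]

    def test_lemma_matching_can_be_disabled(self, analyzed, ontology):
        candidate = candidate_named(analyzed, "animals", "animals")
        config = RecognitionConfig(lemma_matching=False)
        assert match_ontology(candidate, ontology, config) == []

    def test_no_match_gives_empty_list(self, analyzed, ontology):
        candidate = candidate_named(analyzed, "severe diseases", "severe diseases")
        assert match_ontology(candidate, ontology) == []


class TestBoundaryRules:
    def test_fig_style_prefix_and_internal(self, analyzed, ontology):
        """Prefix match keeps the sub-phrase, internal match the whole
        candidate — both from the same phrase."""
        text = "the animal bodily fluid"
        candidate = candidate_named(analyzed, text, "animal bodily fluid")
        mentions = apply_boundary_rules(
            candidate, match_ontology(candidate, ontology)
        )
        by_text = {m.text: m for m in mentions}
        assert set(by_text) == {"animal", "animal bodily fluid"}
        assert by_text["animal"].concept_ids == (ANIMAL,)
        assert by_text["animal bodily fluid"].concept_ids == (BODY_FLUID,)

    def test_exact_match_spans_whole_candidate(self, analyzed, ontology):
        candidate = candidate_named(analyzed, "the mummy tissue", "mummy tissue")
        mentions = apply_boundary_rules(candidate, match_ontology(candidate, ontology))
        assert len(mentions) == 1
        assert mentions[0].text == "mummy tissue"
        assert mentions[0].concept_ids == (MUMMY_TISSUE,)

    def test_same_span_mentions_merge_concept_ids(self, analyzed, ontology):
        from habminer.recognition import OntologyMatch

        candidate = candidate_named(analyzed, "the mummy tissue", "mummy tissue")
        matches = [
            OntologyMatch("MBTO:09900001", (1, 2), "internal_partial", "surface", "x"),
            OntologyMatch("MBTO:09900002", (1, 2), "internal_partial", "surface", "y"),
        ]
        mentions = apply_boundary_rules(candidate, matches)
        assert len(mentions) == 1
        assert mentions[0].concept_ids == ("MBTO:09900001", "MBTO:09900002")


class TestModifierAttachment:
    def test_merged_candidate_added_and_originals_kept(self, analyzed):
        text = "The infected infant in Germany was examined."
        cands, sentence = candidates_of(analyzed, text)
        merged = attach_modifiers(cands, sentence, {"in"})
        forms = [c.surface_form for c in merged]
        assert forms[: len(cands)] == [c.surface_form for c in cands]
        assert "infected infant in Germany" in forms

    def test_full_phrase_normalized_to_infant(self, analyzed, ontology):
        text = "The infected infant in Germany was examined."
        config = RecognitionConfig(modifier_preps=frozenset({"in"}))
        mentions = detect_entities(analyzed(text), ontology, config)
        texts = {m.text: m.concept_ids for m in mentions}
        assert texts["infected infant in Germany"] == (INFANT,)

    def test_respiratory_tract_of_animals_boundary(self, analyzed, ontology):
        text = "This group of organisms is capable of invading the respiratory tract of animals.\n"
        config = RecognitionConfig(modifier_preps=frozenset({"of"}))
        mentions = detect_entities(analyzed(text), ontology, config)
        assert "respiratory tract of animals" in {m.text for m in mentions}

    def test_no_preposition_between_nps_is_identity(self, analyzed):
        cands, sentence = candidates_of(analyzed, "The mummy tissue was analyzed.")
        assert attach_modifiers(cands, sentence, {"in", "of", "with"}) == cands


class TestDetectEntities:
    def test_gastrointestinal_worked_example(self, analyzed, ontology):
        text = (
            "Bifidobacterium\n\n"
            "Bifidobacterium longum is found in the human gastrointestinal tract.\n"
        )
        mentions = detect_entities(analyzed(text), ontology)
        by_text = {m.text: m.concept_ids for m in mentions}
        assert by_text["human"] == (HUMAN,)
        assert by_text["human gastrointestinal tract"] == (DIGESTIVE_TRACT,)

    def test_document_without_matches_is_empty(self, analyzed, ontology):
        assert detect_entities(analyzed("It was isolated in 1982.\n"), ontology) == []

    def test_bodily_fluid_sentence_yields_two_mentions(self, analyzed, ontology):
        mentions = detect_entities(
            analyzed("The animal bodily fluid was infected.\n"), ontology
        )
        assert len(mentions) == 2

    def test_concept_ids_exist_and_fragments_in_bounds(self, analyzed, ontology, fixture_docs):
        for doc in fixture_docs.values():
            for mention in detect_entities(analyzed(doc.text), ontology):
                assert all(cid in ontology for cid in mention.concept_ids)
                for start, end in mention.fragments:
                    assert 0 <= start < end <= len(doc.text)

    def test_coordination_toggle_is_noop_without_and(self, analyzed, ontology):
        text = "The mummy tissue was analyzed.\nThe animal bodily fluid was infected.\n"
        with_coord = detect_entities(analyzed(text), ontology)
        without = detect_entities(
            analyzed(text), ontology, RecognitionConfig(coordination=False)
        )
        assert with_coord == without

    def test_mentions_never_cross_prepositions_by_default(self, analyzed, ontology, fixture_docs):
        for doc in fixture_docs.values():
            analyzed_doc = analyzed(doc.text)
            preps = {
                (t.start, t.end)
                for s in analyzed_doc.sentences
                for t in s.tokens
                if t.pos == "IN"
            }
            for mention in detect_entities(analyzed_doc, ontology):
                covered = {
                    pos for s, e in mention.fragments for pos in range(s, e)
                }
                for p_start, p_end in preps:
                    assert not set(range(p_start, p_end)) <= covered
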