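import pytest

from habminer.relations import (
    AnaphoraConfig,
    EntityRef,
    Relation,
    assign_positions,
    default_anaphora_config,
    extract_paragraph_based,
    extract_partof,
    extract_sentence_based,
    is_specific_bacteria,
    load_anaphora_keywords,
    resolve_anaphora,
)


def entity(tid, etype, text, doc_text, occurrence=0):
    start = -1
    for _ in range(occurrence + 1):
        start = doc_text.index(text, start + 1)
    return EntityRef(tid, etype, ((start, start + len(text)),), text)


class TestSpecificity:
    def test_taxon_name_is_specific(self):
        ent = EntityRef("T1", "Bacteria", ((0, 26),), "Bordetella petrii DSM12804")
        assert is_specific_bacteria(ent)

    @pytest.mark.parametrize("text", ["bacteria", "bacterium", "Bacteria"])
    def test_generic_terms_are_not_specific(self, text):
        ent = EntityRef("T1", "Bacteria", ((0, len(text)),), text)
        assert not is_specific_bacteria(ent)

    def test_non_bacteria_entity_rejected(self):
        ent = EntityRef("T1", "Habitat", ((0, 4),), "soil")
        with pytest.raises(ValueError):
            is_specific_bacteria(ent)


class TestParagraphBased:
    def test_strain_rule_reanchors_to_earlier_mention(self, analyzed, fixture_docs):
        doc = fixture_docs["bordetella-strain"]
        rels = extract_paragraph_based(analyzed(doc.text), list(doc.entities))
        assert [(r.arg1.text, r.arg2.text) for r in rels] == [
            ("Bordetella petrii DSM12804", "river sediment")
        ]

    def test_one_bacterium_two_habitats_gives_two_relations(self, analyzed):
        text = "Brucella canis was isolated from animal products and from air.\n"
        ents = [
            entity("T1", "Bacteria", "Brucella canis", text),
            entity("T2", "Habitat", "animal products", text),
            entity("T3", "Habitat", "air", text),
        ]
        rels = extract_paragraph_based(analyzed(text), ents)
        assert {(r.arg1.id, r.arg2.id) for r in rels} == {("T1", "T2"), ("T1", "T3")}

    def test_habitats_without_any_bacteria_give_nothing(self, analyzed):
        text = "The rhizosphere of plants is a habitat.\n"
        ents = [
            entity("T1", "Habitat", "rhizosphere of plants", text),
            entity("T2", "Habitat", "plants", text),
        ]
        assert extract_paragraph_based(analyzed(text), ents) == []

    def test_repeated_name_anchors_to_first_document_occurrence(self, analyzed):
        text = "Brucella canis is a bacterium.\n\nBrucella canis lives in air.\n"
        ents = [
            entity("T1", "Bacteria", "Brucella canis", text, occurrence=0),
            entity("T2", "Bacteria", "Brucella canis", text, occurrence=1),
            entity("T3", "Habitat", "air", text),
        ]
        rels = extract_paragraph_based(analyzed(text), ents)
        assert [(r.arg1.id, r.arg2.id) for r in rels] == [("T1", "T3")]


class TestAnaphora:
    def test_type1_previous_sentence_antecedent(self, analyzed, fixture_docs):
        doc = fixture_docs["brucella"]
        adoc = analyzed(doc.text)
        ents = assign_positions(doc.entities, adoc)
        antecedent = resolve_anaphora(
            adoc.sentences[1], adoc, ents, default_anaphora_config()
        )
        assert antecedent is not None and antecedent.text == "Brucella canis"

    def test_type1_falls_back_to_first_in_document(self, analyzed):
        text = (
            "Borrelia burgdorferi lives in ticks.\n"
            "The disease spreads quickly.\n"
            "This organism is found in air.\n"
        )
        adoc = analyzed(text)
        ents = assign_positions(
            [entity("T1", "Bacteria", "Borrelia burgdorferi", text)], adoc
        )
        antecedent = resolve_anaphora(
            adoc.sentences[2], adoc, ents, default_anaphora_config()
        )
        assert antecedent is not None and antecedent.text == "Borrelia burgdorferi"

    def test_type2_sentence_initial_it(self, analyzed, fixture_docs):
        doc = fixture_docs["borrelia"]
        adoc = analyzed(doc.text)
        ents = assign_positions(doc.entities, adoc)
        antecedent = resolve_anaphora(
            adoc.sentences[1], adoc, ents, default_anaphora_config()
        )
        assert antecedent is not None and antecedent.text == "Borrelia burgdorferi"

    def test_type2_on_first_sentence_gives_none(self, analyzed):
        text = "It was isolated from soil.\n"
        adoc = analyzed(text)
        assert (
            resolve_anaphora(adoc.sentences[0], adoc, [], default_anaphora_config())
            is None
        )

    def test_type3_this_strain_uses_first_in_document(self, analyzed, fixture_docs):
        doc = fixture_docs["this-strain"]
        adoc = analyzed(doc.text)
        ents = assign_positions(doc.entities, adoc)
        antecedent = resolve_anaphora(
            adoc.sentences[1], adoc, ents, default_anaphora_config()
        )
        assert antecedent is not None and antecedent.text == "Lactobacillus casei"

    def test_no_anaphor_gives_none(self, analyzed):
        text = "Sediment was analyzed.\n"
        adoc = analyzed(text)
        assert (
            resolve_anaphora(adoc.sentences[0], adoc, [], default_anaphora_config())
            is None
        )

    def test_default_keyword_list_has_23_lowercase_expressions(self):
        config = default_anaphora_config()
        assert len(config.type1_expressions) == 23
        assert all(e == e.lower() for e in config.type1_expressions)

    def test_keyword_file_loading(self):
        config = load_anaphora_keywords(["# comment", "This Organism", "", "the microbe"])
        assert config.type1_expressions == ("this organism", "the microbe")

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError):
            AnaphoraConfig(type1_expressions=())


class TestSentenceBased:
    def test_brucella_worked_example(self, analyzed, fixture_docs):
        doc = fixture_docs["brucella"]
        rels = extract_sentence_based(
            analyzed(doc.text), list(doc.entities), default_anaphora_config()
        )
        assert {(r.arg1.text, r.arg2.text) for r in rels} == {
            ("Brucella canis", "animal products"),
            ("Brucella canis", "air"),
        }

    def test_bordetella_group_worked_example(self, analyzed, fixture_docs):
        doc = fixture_docs["bordetella-group"]
        rels = extract_sentence_based(
            analyzed(doc.text), list(doc.entities), default_anaphora_config()
        )
        assert {(r.arg1.text, r.arg2.text) for r in rels} == {
            ("Bordetella", "respiratory tract of animals"),
            ("Bordetella", "animals"),
        }

    def test_without_anaphora_is_pure_cooccurrence(self, analyzed, fixture_docs):
        doc = fixture_docs["brucella"]
        assert extract_sentence_based(analyzed(doc.text), list(doc.entities), None) == []

    def test_generic_bacteria_do_not_anchor(self, analyzed):
        text = "The bacterium lives in soil.\n"
        ents = [
            entity("T1", "Bacteria", "bacterium", text),
            entity("T2", "Habitat", "soil", text),
        ]
        assert extract_sentence_based(analyzed(text), ents, None) == []

    def test_every_specific_bacterium_pairs_with_every_habitat(self, analyzed):
        text = "Brucella canis and Borrelia burgdorferi live in soil and in air.\n"
        ents = [
            entity("T1", "Bacteria", "Brucella canis", text),
            entity("T2", "Bacteria", "Borrelia burgdorferi", text),
            entity("T3", "Habitat", "soil", text),
            entity("T4", "Habitat", "air", text),
        ]
        rels = extract_sentence_based(analyzed(text), ents, None)
        assert len(rels) == 4

    def test_agrees_with_paragraph_based_on_single_sentence_doc(self, analyzed):
        text = "Brucella canis was isolated from animal products.\n"
        ents = [
            entity("T1", "Bacteria", "Brucella canis", text),
            entity("T2", "Habitat", "animal products", text),
        ]
        adoc = analyzed(text)
        sentence_rels = {r.key for r in extract_sentence_based(adoc, ents, None)}
        paragraph_rels = {r.key for r in extract_paragraph_based(adoc, ents)}
        assert sentence_rels == paragraph_rels == {("Localization", "T1", "T2")}


class TestPartOf:
    @pytest.mark.parametrize(
        "part_text,host_text",
        [
            ("rhizosphere of plants", "plants"),
            ("oral cavity in humans", "humans"),
            (
                "skin lesion from a Lyme disease patient in Europe",
                "Lyme disease patient in Europe",
            ),
            ("Aeschynomene stem nodule", "Aeschynomene"),
        ],
    )
    def test_printed_examples(self, analyzed, fixture_docs, part_text, host_text):
        doc = fixture_docs["partof"]
        rels = extract_partof(list(doc.entities), analyzed(doc.text))
        assert (part_text, host_text) in {(r.arg1.text, r.arg2.text) for r in rels}

    def test_exactly_the_four_expected_relations(self, analyzed, fixture_docs):
        doc = fixture_docs["partof"]
        rels = extract_partof(list(doc.entities), analyzed(doc.text))
        assert len(rels) == 4

    def test_disjoint_habitats_give_nothing(self, analyzed):
        text = "Fresh water and soil are habitats.\n"
        ents = [
            entity("T1", "Habitat", "water", text),
            entity("T2", "Habitat", "soil", text),
        ]
        assert extract_partof(ents, analyzed(text)) == []

    def test_prefix_rule_fires_only_for_proper_prefixes(self, analyzed):
        text = "The infant feces were analyzed.\n"
        ents = [
            entity("T1", "Habitat", "infant feces", text),
            entity("T2", "Habitat", "infant", text),
        ]
        rels = extract_partof(ents, analyzed(text))
        assert [(r.arg1.id, r.arg2.id) for r in rels] == [("T1", "T2")]


class TestRelationInvariants:
    def test_localization_type_constraints(self):
        bact = EntityRef("T1", "Bacteria", ((0, 3),), "Foo")
        hab = EntityRef("T2", "Habitat", ((4, 8),), "soil")
        with pytest.raises(ValueError):
            Relation("Localization", hab, bact)
        with pytest.raises(ValueError):
            Relation("PartOf", bact, hab)
        assert Relation("Localization", bact, hab).key == ("Localization", "T1", "T2")

    def test_extractors_respect_type_constraints(self, analyzed, fixture_docs):
        for doc in fixture_docs.values():
            adoc = analyzed(doc.text)
            ents = list(doc.entities)
            for rel in extract_sentence_based(adoc, ents, default_anaphora_config()):
                assert rel.arg1.etype == "Bacteria"
                assert rel.arg2.etype in ("Habitat", "Geographical")
            for rel in extract_partof(ents, adoc):
                assert rel.arg1.etype == rel.arg2.etype == "Habitat"
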