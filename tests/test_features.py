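"""Feature families, presets and assembly."""

import dataclasses
import logging

import numpy as np
import pytest

import ebmtag as et
from ebmtag.corpus import Label, Token
from ebmtag.features import (
    FeatureConfig,
    MissingAnnotationError,
    ConceptAnnotations,
    Resources,
    Thesaurus,
    assemble_sequence,
    available_presets,
    build_preset,
    direct_sequential_features,
    indirect_sequential_features,
    lexical_features,
    load_heading_map,
    normalize_heading,
    semantic_features,
    structural_features,
    windowed_features,
)

from conftest import make_abstract, make_sentence


@pytest.fixture()
def toy_thesaurus():
    return Thesaurus(
        token_to_cuis={
            "disease": frozenset({"C0012634"}),
            "disorder": frozenset({"C0012634"}),
            "infarction": frozenset({"C1", "C2"}),
        },
        cui_to_synonyms={
            "C0012634": frozenset({"illness"}),
            "C1": frozenset({"heart attack"}),
            "C2": frozenset(),
        },
    )


class TestLexical:
    def test_unigram_features(self):
        s = make_sentence("Mortality fell", ["Outcome"])
        s.tokens = [Token("Mortality", "NN"), Token("fell", "VBD")]
        assert lexical_features(s, build_preset("1.P")) == {
            "U=mortality_NN",
            "U=fell_VBD",
        }

    def test_bigram_features_add_consecutive_pairs(self):
        s = make_sentence("Mortality fell", ["Outcome"])
        s.tokens = [Token("Mortality", "NN"), Token("fell", "VBD")]
        feats = lexical_features(s, build_preset("1.P+2.P"))
        assert "B=mortality_NN__fell_VBD" in feats
        assert feats >= {"U=mortality_NN", "U=fell_VBD"}

    def test_empty_sentence_yields_empty_vector(self):
        s = make_sentence("", ["Other"])
        assert lexical_features(s, build_preset("1.P+2.P")) == frozenset()

    def test_feature_counts_match_token_counts(self):
        # brute-force count oracle on random token lists
        rng = np.random.default_rng(7)
        vocab = ["alpha", "beta", "gamma", "delta"]
        for _ in range(25):
            n = int(rng.integers(1, 10))
            toks = [Token(vocab[int(rng.integers(4))], "NN") for _ in range(n)]
            s = make_sentence("x", ["Other"])
            s.tokens = toks
            uni = lexical_features(s, build_preset("1.P"))
            bi = lexical_features(s, FeatureConfig(use_bigram_pos=True))
            assert len(uni) == len({t.surface for t in toks})
            expected_bi = {
                (a.surface, b.surface) for a, b in zip(toks, toks[1:])
            }
            assert len(bi) == len(expected_bi)


class TestSemantic:
    def test_synonymous_tokens_share_cui(self, toy_thesaurus):
        cfg = FeatureConfig(use_token_cui=True)
        for word in ("disease", "disorder"):
            s = make_sentence(word, ["Background"])
            feats = semantic_features(s, toy_thesaurus, cfg)
            assert feats == {"CUI=C0012634"}

    def test_synonym_breakdown_into_single_words(self, toy_thesaurus):
        s = make_sentence("infarction", ["Outcome"])
        whole = semantic_features(s, toy_thesaurus, FeatureConfig(use_token_syn=True))
        broken = semantic_features(
            s, toy_thesaurus, FeatureConfig(use_token_syn_b=True)
        )
        assert whole == {"SYN=heart attack"}
        assert broken == {"SYNB=heart", "SYNB=attack"}

    def test_unknown_token_contributes_nothing(self, toy_thesaurus):
        s = make_sentence("zebra", ["Other"])
        cfg = FeatureConfig(use_token_cui=True, use_token_syn=True, use_token_syn_b=True)
        assert semantic_features(s, toy_thesaurus, cfg) == frozenset()

    def test_missing_annotation_record_is_an_error(self, toy_thesaurus):
        s = make_sentence("anything", ["Other"])
        cfg = FeatureConfig(use_metamap_cui=True)
        empty = ConceptAnnotations()
        with pytest.raises(MissingAnnotationError):
            semantic_features(
                s, toy_thesaurus, cfg, annotations=empty, abstract_id="a1"
            )

    def test_annotation_table_emits_mm_features(self, toy_thesaurus):
        s = make_sentence("anything", ["Other"])
        anns = ConceptAnnotations({("a1", 0): frozenset({"C9"})})
        feats = semantic_features(
            s,
            toy_thesaurus,
            FeatureConfig(use_metamap_cui=True),
            annotations=anns,
            abstract_id="a1",
        )
        assert feats == {"MM=C9"}

    def test_thesaurus_tsv_round_trip(self, tmp_path, toy_thesaurus):
        path = tmp_path / "thes.tsv"
        path.write_text(
            "disease\tC0012634\tillness\n"
            "disorder\tC0012634\t\n"
            "infarction\tC1\theart attack\n"
            "infarction\tC2\t\n",
            encoding="utf-8",
        )
        loaded = Thesaurus.from_tsv(path)
        assert loaded.cuis_for("Disease") == {"C0012634"}
        assert loaded.cuis_for("infarction") == {"C1", "C2"}
        assert "heart attack" in loaded.cui_to_synonyms["C1"]


class TestStructural:
    def test_first_sentence_of_ten(self):
        abstract = make_abstract([("w", ["Other"])] * 10)
        feats = structural_features(
            abstract.sentences[0], abstract, FeatureConfig(use_position=True)
        )
        assert feats == {"POSN=1", "RELPOS=0"}

    def test_absolute_position_caps_at_ten(self):
        abstract = make_abstract([("w", ["Other"])] * 14)
        feats = structural_features(
            abstract.sentences[13], abstract, FeatureConfig(use_position=True)
        )
        assert "POSN=10" in feats and "RELPOS=9" in feats

    def test_mapped_heading_roles(self):
        abstract = make_abstract(
            [("Mortality fell", ["Outcome"], "CONCLUSIONS")]
        )
        cfg = FeatureConfig(heading_mode="mapped")
        assert structural_features(abstract.sentences[0], abstract, cfg) == {
            "SECM=Conclusions"
        }

    def test_patients_and_methods_maps_to_method(self):
        abstract = make_abstract(
            [("Adults were enrolled", ["Population"], "PATIENTS AND METHODS")]
        )
        cfg = FeatureConfig(heading_mode="mapped")
        assert structural_features(abstract.sentences[0], abstract, cfg) == {
            "SECM=Method"
        }

    def test_unmapped_heading_falls_back_with_warning(self, caplog):
        abstract = make_abstract([("w", ["Other"], "EXOTIC SECTION")])
        cfg = FeatureConfig(heading_mode="mapped")
        with caplog.at_level(logging.WARNING, logger="ebmtag.features"):
            feats = structural_features(abstract.sentences[0], abstract, cfg)
        assert feats == {"SECM=Other"}
        assert any("EXOTIC SECTION" in r.message for r in caplog.records)

    def test_raw_heading_is_normalized(self):
        abstract = make_abstract([("w", ["Other"], "Patients  and Methods:")])
        cfg = FeatureConfig(heading_mode="raw")
        assert structural_features(abstract.sentences[0], abstract, cfg) == {
            "SEC=PATIENTS AND METHODS"
        }

    def test_heading_mode_inert_without_headings(self):
        abstract = make_abstract([("w", ["Other"])])
        cfg = FeatureConfig(heading_mode="raw")
        assert structural_features(abstract.sentences[0], abstract, cfg) == frozenset()


class TestSequential:
    def test_indirect_boundary_sentinel(self):
        abstract = make_abstract([("mortality fell", ["Outcome"])])
        assert indirect_sequential_features(abstract, 0, 1) == {"P1_<BOS>"}

    def test_indirect_prefixes_previous_unigrams(self):
        abstract = make_abstract(
            [("mortality fell", ["Outcome"]), ("more needed", ["Other"])]
        )
        feats = indirect_sequential_features(abstract, 1, 1)
        assert any(f.startswith("P1_U=mortality") for f in feats)

    def test_indirect_window_three_equals_direct_recomputation(self):
        texts = [
            "prevalence was high",
            "patients were enrolled",
            "dose was given",
            "mortality fell",
            "survival improved",
            "further work needed",
        ]
        abstract = make_abstract([(t, ["Other"]) for t in texts])
        got = indirect_sequential_features(abstract, 5, 3)
        expected = set()
        for j in (1, 2, 3):
            uni = lexical_features(abstract.sentences[5 - j], build_preset("1.P"))
            expected |= {f"P{j}_{f}" for f in uni}
        assert got == expected

    def test_windowed_middle_last_and_single(self):
        abstract = make_abstract(
            [("a b", ["Other"]), ("c d", ["Other"]), ("e f", ["Other"])]
        )
        mid = windowed_features(abstract, 1)
        assert any(f.startswith("P1_U=") for f in mid)
        assert any(f.startswith("NX_U=") for f in mid)
        last = windowed_features(abstract, 2)
        assert "NX_<EOS>" in last and any(f.startswith("P1_U=") for f in last)
        single = make_abstract([("a", ["Other"])])
        assert windowed_features(single, 0) == {"P1_<BOS>", "NX_<EOS>"}

    def test_direct_window_three(self):
        pred = [Label.BACKGROUND, Label.POPULATION]
        feats = direct_sequential_features(pred, 2, 3)
        assert feats == {
            "PLAB1=Population",
            "PLAB2=Background",
            "PLAB3=<BOS>",
        }

    def test_direct_at_start_is_all_sentinel(self):
        for window in (1, 3, "all"):
            feats = direct_sequential_features([], 0, window)
            assert feats and all("<BOS>" in f for f in feats)

    def test_direct_all_has_bag_semantics(self):
        pred = [Label.BACKGROUND, Label.BACKGROUND, Label.OUTCOME, Label.OUTCOME]
        feats = direct_sequential_features(pred, 4, "all")
        assert {"PLABANY=Background", "PLABANY=Outcome"} <= feats
        assert "PLAB1=Outcome" in feats and "PLAB4=Background" in feats


class TestPresets:
    def test_unigram_position_preset(self):
        cfg = build_preset("1.P+Pst")
        assert cfg.use_unigram_pos and cfg.use_position
        assert cfg.heading_mode == "none" and not cfg.use_windowed
        assert cfg.direct_window == 0 and cfg.indirect_window == 0

    def test_basic_set_switches(self):
        cfg = build_preset("B")
        assert cfg.use_unigram_pos and cfg.use_position
        assert cfg.heading_mode == "raw"

    def test_direct_preset(self):
        assert build_preset("B+3 Prev Labels").direct_window == 3
        assert build_preset("B+All Prev Labels").direct_window == "all"

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="1.P"):
            build_preset("bogus")

    def test_all_documented_presets_build(self):
        for name in available_presets():
            assert build_preset(name).preset_name == name


class TestAssembly:
    def test_single_family_equals_lexical(self, paperlike_corpus):
        corpus, _ = paperlike_corpus
        abstract = corpus.abstracts[0]
        cfg = build_preset("1.P")
        vectors = assemble_sequence(abstract, cfg)
        assert vectors == [lexical_features(s, cfg) for s in abstract.sentences]

    def test_enabling_family_never_removes_features(self, paperlike_corpus):
        corpus, _ = paperlike_corpus
        abstract = corpus.abstracts[1]
        base_fields = {
            "use_bigram_pos": True,
            "use_position": True,
            "use_windowed": True,
        }
        rng = np.random.default_rng(0)
        for _ in range(10):
            on = {
                k: bool(rng.integers(2)) for k in base_fields
            }
            cfg = FeatureConfig(use_unigram_pos=True, **{k: v for k, v in on.items()})
            base_vecs = assemble_sequence(abstract, cfg)
            extra = [k for k, v in on.items() if not v]
            if not extra:
                continue
            k = extra[int(rng.integers(len(extra)))]
            bigger = dataclasses.replace(cfg, **{k: True})
            big_vecs = assemble_sequence(abstract, bigger)
            assert all(b >= a for a, b in zip(base_vecs, big_vecs))

    def test_empty_sentence_under_position_preset(self):
        abstract = make_abstract([("", ["Other"]), ("words here", ["Other"])])
        vectors = assemble_sequence(abstract, build_preset("1.P+Pst"))
        assert vectors[0] == {"POSN=1", "RELPOS=0"}

    def test_direct_without_base_predictions_is_error(self, paperlike_corpus):
        corpus, _ = paperlike_corpus
        with pytest.raises(ValueError, match="base predictions"):
            assemble_sequence(corpus.abstracts[0], build_preset("B+1 Prev. Label"))

    def test_thesaurus_demanded_but_absent_is_error(self, paperlike_corpus):
        corpus, _ = paperlike_corpus
        with pytest.raises(ValueError, match="thesaurus"):
            assemble_sequence(corpus.abstracts[0], build_preset("Token-CUI"))

    def test_extraction_is_pure(self, paperlike_corpus):
        corpus, _ = paperlike_corpus
        abstract = corpus.abstracts[2]
        cfg = build_preset("B+2 Prev. Sen.")
        assert assemble_sequence(abstract, cfg) == assemble_sequence(abstract, cfg)

    def test_family_prefixes_are_disjoint(self, paperlike_corpus, toy_thesaurus):
        corpus, _ = paperlike_corpus
        abstract = corpus.abstracts[3]
        cfg = FeatureConfig(
            use_unigram_pos=True,
            use_bigram_pos=True,
            use_token_cui=True,
            use_token_syn=True,
            use_token_syn_b=True,
            use_position=True,
            heading_mode="raw",
            indirect_window=3,
            use_windowed=True,
            direct_window=3,
        )
        vectors = assemble_sequence(
            abstract,
            cfg,
            Resources(thesaurus=toy_thesaurus),
            base_predictions=[s.primary_gold for s in abstract.sentences],
        )
        prefixes = (
            "U=", "B=", "CUI=", "SYN=", "SYNB=", "MM=", "POSN=", "RELPOS=",
            "SEC=", "SECM=", "P1_", "P2_", "P3_", "NX_", "PLAB1=", "PLAB2=",
            "PLAB3=", "PLABANY=",
        )
        for vec in vectors:
            for feat in vec:
                assert sum(feat.startswith(p) for p in prefixes) == 1, feat


def test_heading_map_covers_roles_only():
    mapping = load_heading_map()
    assert set(mapping.values()) <= {"Aim", "Method", "Results", "Conclusions"}
    assert mapping[normalize_heading("Conclusions:")] == "Conclusions"
    assert len(mapping) >= 40
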