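"""Word-class assignment, hapax detection, positional class profiles."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_turn
from turnload.corpus import TaggedToken, build_frequency_table, select_turns
from turnload.wordclass import (
    ClassMap,
    classify_token,
    class_position_profile,
    find_hapaxes,
    hapax_noun_profile,
    noun_function_insert_profile,
    proform_early_share,
    token_table,
)


class TestClassifyToken:
    @pytest.mark.parametrize("form,tag,expected", [
        ("well", "RR", ("insert", "none")),       # mis-tagged adverb override
        ("so", "RR", ("insert", "none")),
        ("oh", "UH", ("insert", "none")),
        ("house", "NN1", ("content", "noun")),
        ("is", "VBZ", ("function", "none")),      # auxiliary, not content
        ("can", "VM", ("function", "none")),      # modal, not content
        ("run", "VV0", ("content", "lexical_verb")),
        ("quick", "JJ", ("content", "adjective")),
        ("quickly", "RR", ("content", "adverb")),
        ("so", "CS", ("function", "none")),       # conjunction keeps its class
        ("i", "PPIS1", ("function", "none")),
    ])
    def test_c7_assignments(self, form, tag, expected):
        cmap = ClassMap.default("c7")
        assert classify_token(TaggedToken(form, tag), cmap) == expected

    @pytest.mark.parametrize("form,tag,expected", [
        ("well", "AV0", ("insert", "none")),
        ("oh", "ITJ", ("insert", "none")),
        ("house", "NN1", ("content", "noun")),
        ("is", "VBZ", ("function", "none")),
        ("walked", "VVD", ("content", "lexical_verb")),
    ])
    def test_c5_assignments(self, form, tag, expected):
        cmap = ClassMap.default("c5")
        assert classify_token(TaggedToken(form, tag), cmap) == expected

    def test_unknown_tag_falls_back_to_function(self):
        cmap = ClassMap.default("c7")
        assert classify_token(TaggedToken("blargh", "QQQ"), cmap) == (
            "function", "none")

    def test_yaml_round_trip_preserves_rules(self, tmp_path):
        cmap = ClassMap.default("c5")
        path = tmp_path / "classmap.yaml"
        cmap.to_yaml(path)
        loaded = ClassMap.from_yaml(path)
        assert loaded.tagset == cmap.tagset
        assert loaded.rules == cmap.rules
        assert loaded.overrides == cmap.overrides


class TestFindHapaxes:
    def test_toy_counts(self):
        turn = make_turn("c", "t", "s", [("a", "AT"), ("a", "AT"),
                                         ("b", "NN1"), ("c", "NN1")])
        table = build_frequency_table(select_turns([turn], 3, 25))
        assert find_hapaxes(table) == {("b", "NN1"), ("c", "NN1")}

    def test_no_singletons_gives_empty_set(self):
        turn = make_turn("c", "t", "s", [("a", "AT")] * 2 + [("b", "NN1")] * 2)
        table = build_frequency_table(select_turns([turn], 3, 25))
        assert find_hapaxes(table) == set()

    def test_matches_brute_force_scan(self, rng):
        forms = [f"w{i}" for i in rng.integers(0, 200, size=600)]
        turns = [
            make_turn("c", f"t{j}", "s",
                      [(forms[j * 6 + k], "NN1") for k in range(6)])
            for j in range(100)
        ]
        table = build_frequency_table(select_turns(turns, 3, 25))
        brute = {k for k, v in table.counts.items() if v == 1}
        assert find_hapaxes(table) == brute

    def test_second_occurrence_removes_hapax(self):
        t1 = make_turn("c", "t1", "s", [("x", "NN1"), ("a", "AT"), ("b", "AT")])
        t2 = make_turn("c", "t2", "s", [("x", "NN1"), ("a", "AT"), ("b", "AT")])
        small = build_frequency_table(select_turns([t1], 3, 25))
        grown = build_frequency_table(select_turns([t1, t2], 3, 25))
        assert ("x", "NN1") in find_hapaxes(small)
        assert ("x", "NN1") not in find_hapaxes(grown)


class TestClassPositionProfile:
    def test_always_insert_initial_position(self):
        turns = [
            make_turn("c", f"t{i}", "s",
                      [("oh", "UH"), ("i", "PPIS1"), ("ran", "VVD")])
            for i in range(5)
        ]
        prof = class_position_profile(select_turns(turns, 3, 25),
                                      ClassMap.default("c7"), sizes=[3])
        w1 = prof[(prof["index"] == 1) & (prof["word_class"] == "insert")]
        assert w1["percentage"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_100_per_cell(self, tiny_subset):
        prof = class_position_profile(tiny_subset, ClassMap.default("c7"))
        sums = prof.groupby(["size", "index"])["percentage"].sum()
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_hand_tallied_fixture(self):
        # 10 turns of size 3: 4 start with an insert, 6 with a pronoun
        turns = [
            make_turn("c", f"t{i}", "s",
                      [("oh", "UH") if i < 4 else ("i", "PPIS1"),
                       ("is", "VBZ"), ("dog", "NN1")])
            for i in range(10)
        ]
        prof = class_position_profile(select_turns(turns, 3, 25),
                                      ClassMap.default("c7"), sizes=[3])
        cell = lambda idx, wc: prof[
            (prof["index"] == idx) & (prof["word_class"] == wc)
        ]["percentage"].iloc[0]
        assert cell(1, "insert") == pytest.approx(40.0)
        assert cell(1, "function") == pytest.approx(60.0)
        assert cell(2, "function") == pytest.approx(100.0)
        assert cell(3, "content") == pytest.approx(100.0)

    def test_absent_size_flagged_with_empty_cells(self, tiny_subset):
        prof = class_position_profile(tiny_subset, ClassMap.default("c7"),
                                      sizes=[7])
        assert (prof["n"] == 0).all()

    def test_model_profile_reports_noun_share(self):
        turns = [
            make_turn("c", f"t{i}", "s",
                      [("i", "PPIS1"), ("saw", "VVD"), ("dogs", "NN2")])
            for i in range(5)
        ]
        prof = noun_function_insert_profile(select_turns(turns, 3, 25),
                                            ClassMap.default("c7"), sizes=[3])
        noun_final = prof[(prof["index"] == 3) & (prof["word_class"] == "noun")]
        assert noun_final["percentage"].iloc[0] == pytest.approx(100.0)
        # lexical verb position: not a modelled class, all three shares zero
        mid = prof[prof["index"] == 2]
        assert mid["percentage"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])


class TestHapaxNounProfile:
    def test_no_nouns_gives_all_zero(self):
        turns = [make_turn("c", f"t{i}", "s",
                           [("i", "PPIS1"), ("am", "VBM"), ("here", "RL")])
                 for i in range(3)]
        subset = select_turns(turns, 3, 25)
        prof = hapax_noun_profile(subset, build_frequency_table(subset),
                                  ClassMap.default("c7"))
        assert (prof["percentage"] == 0).all()

    def test_turn_final_hapax_noun_lands_at_position_one(self):
        turns = [
            make_turn("c", f"t{i}", "s",
                      [("i", "PPIS1"), ("saw", "VVD"), (f"thing{i}", "NN1")])
            for i in range(4)
        ]
        subset = select_turns(turns, 3, 25)
        prof = hapax_noun_profile(subset, build_frequency_table(subset),
                                  ClassMap.default("c7"))
        nonzero = prof[prof["percentage"] > 0]
        assert nonzero["norm_position"].tolist() == [1.0]
        assert nonzero["percentage"].iloc[0] == pytest.approx(100.0)


class TestProformEarlyShare:
    def test_every_turn_starts_with_pronoun(self):
        turns = [make_turn("c", f"t{i}", "s",
                           [("i", "PPIS1"), ("ran", "VVD"), ("home", "NN1")])
                 for i in range(5)]
        assert proform_early_share(select_turns(turns, 3, 25)) == 1.0

    def test_no_proforms_anywhere(self):
        turns = [make_turn("c", f"t{i}", "s",
                           [("dogs", "NN2"), ("ran", "VVD"), ("home", "NN1")])
                 for i in range(5)]
        assert proform_early_share(select_turns(turns, 3, 25)) == 0.0

    def test_matches_brute_force_on_fixture(self, rng):
        proforms = {"i", "you", "it"}
        turns = []
        for j in range(20):
            size = int(rng.integers(3, 12))
            forms = [str(rng.choice(["i", "you", "it", "cat", "ran", "the"]))
                     for _ in range(size)]
            turns.append(make_turn("c", f"t{j}", "s",
                                   [(f, "NN1") for f in forms]))
        subset = select_turns(turns, 3, 25)
        brute = sum(
            any(tok.form in proforms
                and (i - 1) / (t.size - 1) <= 0.2
                for i, tok in enumerate(t.tokens, start=1))
            for t in subset
        ) / len(subset)
        share = proform_early_share(subset, proforms=sorted(proforms))
        assert share == pytest.approx(brute)

    def test_empty_proform_list_rejected(self, tiny_subset):
        with pytest.raises(ValueError, match="non-empty"):
            proform_early_share(tiny_subset, proforms=[])


def test_token_table_carries_class_and_hapax_columns(tiny_subset):
    table = build_frequency_table(tiny_subset)
    df = token_table(tiny_subset, table, ClassMap.default("c7"))
    assert set(df["word_class"].unique()) <= {"content", "function", "insert"}
    # "i"/PPIS1 and "like"/VV0 occur twice -> not hapaxes; "house" once -> hapax
    house = df[df["form"] == "house"].iloc[0]
    assert bool(house["is_hapax"])
    assert not df[df["form"] == "i"]["is_hapax"].any()
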