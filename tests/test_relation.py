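"""Triplet enumeration, features, naive-Bayes scoring, direction, CV."""

import math
import random

import numpy as np
import pytest

from conftest import rows_to_pairs
from pinminer import fixtures as fx
from pinminer.corpus import Sentence
from pinminer.relation import (
    LR,
    NONE,
    RL,
    CandidateTriplet,
    TripletModel,
    crossvalidate,
    enumerate_triplets,
    extract_features,
    pairs_from_rows,
    predict_direction,
    score_triplet,
    train_model,
)
from pinminer.tagger import InteractionLexicon, Mention, ProteinDictionary, \
    tag_interaction_words, tag_proteins

LEX = InteractionLexicon(
    words={"phosphorylates": "with_direction", "methylates": "with_direction",
           "interacts": "without_direction", "binds": "without_direction"},
    variants={"phosphorylated": "phosphorylates", "bind": "binds",
              "methylated": "methylates", "phosphorylate": "phosphorylates"},
)
DICT = ProteinDictionary(entries={"PROA", "PROB", "PROC"})


def tagged(text):
    s = Sentence.from_raw("1", 0, text)
    return s, tag_proteins(s, DICT), tag_interaction_words(s, LEX)


def triplets_for(text):
    s, proteins, words = tagged(text)
    return s, enumerate_triplets(proteins, words, s)


class TestEnumerateTriplets:
    @pytest.mark.parametrize("text,expected", [
        ("PROA binds PROB", 1),
        ("PROA binds PROB and PROC", 3),       # C(3,2) x 1
        ("PROA near PROB", 0),                 # no interaction word
        ("PROA binds nothing", 0),             # single protein
    ])
    def test_combination_counts(self, text, expected):
        _, triplets = triplets_for(text)
        assert len(triplets) == expected

    def test_two_words_give_two_candidates_per_pair(self):
        _, triplets = triplets_for("PROA binds and phosphorylates PROB")
        assert len(triplets) == 2

    def test_protein_order_within_triplet(self):
        _, triplets = triplets_for("PROB binds PROA")
        t = triplets[0]
        assert t.protein_a.start < t.protein_b.start


class TestExtractFeatures:
    def test_adjacent_pair(self):
        s, triplets = triplets_for("PROA binds PROB")
        fv = extract_features(triplets[0], s)
        assert fv == {"distance_bin": "0-2", "word_position": "between",
                      "intervening_bin": "0", "negation": "no",
                      "comma_between": "no", "inflection": "s"}

    def test_negation_detected(self):
        s, triplets = triplets_for("PROA does not bind PROB")
        assert extract_features(triplets[0], s)["negation"] == "yes"

    def test_comma_and_intervening_protein(self):
        s, triplets = triplets_for("PROA , PROC and PROB interacts here")
        pair_ac_b = [t for t in triplets
                     if t.protein_a.surface == "PROA"
                     and t.protein_b.surface == "PROB"][0]
        fv = extract_features(pair_ac_b, s)
        assert fv["comma_between"] == "yes"
        assert fv["intervening_bin"] == "1"
        assert fv["word_position"] == "after"

    def test_determinism(self):
        s, triplets = triplets_for("PROA phosphorylates PROB")
        assert extract_features(triplets[0], s) == extract_features(triplets[0], s)

    def test_mentions_off_sentence_rejected(self):
        s, triplets = triplets_for("PROA binds PROB")
        other = Sentence.from_raw("1", 0, "completely different text")
        with pytest.raises(ValueError):
            extract_features(triplets[0], other)

    @pytest.mark.parametrize("surface,expected", [
        ("binds", "s"), ("bind", "base"), ("phosphorylated", "ed"),
        ("binding", "ing"), ("interaction", "nominal"),
    ])
    def test_inflection_classes(self, surface, expected):
        from pinminer.relation import _inflection_class
        assert _inflection_class(surface) == expected


def _fv(**overrides):
    base = {"distance_bin": "0-2", "word_position": "between",
            "intervening_bin": "0", "negation": "no",
            "comma_between": "no", "inflection": "s"}
    base.update(overrides)
    return base


class TestTrainAndScore:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_model([(_fv(), "true")] * 5)

    def test_posterior_normalized(self, interaction_model):
        post = interaction_model.posterior(_fv())
        assert abs(sum(post.values()) - 1.0) < 1e-9

    def test_uninformative_features_give_half(self):
        data = [(_fv(), "true")] * 10 + [(_fv(), "false")] * 10
        model = train_model(data)
        post = model.posterior(_fv())
        assert post["true"] == pytest.approx(0.5, abs=1e-12)

    def test_order_insensitive(self):
        data = [(_fv(negation="yes"), "false")] * 5 + [(_fv(), "true")] * 5
        m1 = train_model(data)
        m2 = train_model(list(reversed(data)))
        assert m1.posterior(_fv()) == m2.posterior(_fv())

    def test_perfect_feature_separates(self):
        data = [(_fv(negation="no"), "true")] * 20 + \
               [(_fv(negation="yes"), "false")] * 20
        model = train_model(data)
        assert all(
            max(model.posterior(fv), key=model.posterior(fv).get) == label
            for fv, label in data)

    def test_smoothing_to_zero_limit(self):
        data = [(_fv(), "true")] * 20 + [(_fv(negation="yes"), "false")] * 20
        model = train_model(data, smoothing=1e-12)
        assert model.posterior(_fv())["true"] == pytest.approx(1.0, abs=1e-6)

    def test_true_only_feature_value_boosts_p_true(self):
        """A value observed only in the true class never lowers P(true)."""
        data = [(_fv(inflection="ed"), "true")] * 8 + [(_fv(), "true")] * 8 + \
               [(_fv(word_position="after"), "false")] * 16
        model = train_model(data)
        p_base = model.posterior(_fv())["true"]
        p_marked = model.posterior(_fv(inflection="ed"))["true"]
        assert p_marked >= p_base

    def test_score_triplet_in_unit_interval_and_deterministic(
            self, interaction_model):
        s, triplets = triplets_for("PROA phosphorylates PROB")
        p1 = score_triplet(triplets[0], s, interaction_model)
        p2 = score_triplet(triplets[0], s, interaction_model)
        assert 0.0 <= p1 <= 1.0 and p1 == p2

    def test_kind_mismatch_rejected(self, direction_model):
        s, triplets = triplets_for("PROA phosphorylates PROB")
        with pytest.raises(ValueError):
            score_triplet(triplets[0], s, direction_model)

    def test_json_round_trip(self, interaction_model):
        clone = TripletModel.from_json(interaction_model.to_json())
        assert clone.posterior(_fv()) == interaction_model.posterior(_fv())


class TestPredictDirection:
    def test_without_direction_word_short_circuits(self, direction_model):
        s, triplets = triplets_for("PROA interacts with PROB")
        direction, prob, low = predict_direction(triplets[0], s, LEX,
                                                 direction_model)
        assert (direction, prob, low) == (NONE, None, False)

    def test_unknown_word_treated_as_undirected(self, direction_model):
        lex = InteractionLexicon(words={"binds": "without_direction"})
        s = Sentence.from_raw("1", 0, "PROA regulates PROB")
        mk = lambda a, b, kind, entry: Mention(kind, s.raw[a:b], a, b, entry, ("1", 0))
        triplet = CandidateTriplet(
            protein_a=mk(0, 4, "protein", "PROA"),
            protein_b=mk(15, 19, "protein", "PROB"),
            interaction=mk(5, 14, "interaction", "regulates"),
            sentence_ref=("1", 0))
        assert predict_direction(triplet, s, lex, direction_model)[0] == NONE

    def test_active_voice_recovered_as_lr(self, direction_model):
        """Planted rule: active-voice order implies left-to-right flow."""
        s, triplets = triplets_for("PROA methylates PROB")
        direction, prob, _ = predict_direction(triplets[0], s, LEX,
                                               direction_model)
        assert direction == LR and prob > 0.5

    def test_passive_voice_recovered_as_rl(self, direction_model):
        s, triplets = triplets_for("PROA is methylated by PROB")
        direction, prob, _ = predict_direction(triplets[0], s, LEX,
                                               direction_model)
        assert direction == RL and prob > 0.5

    def test_direction_posteriors_sum_to_one(self, direction_model):
        s, triplets = triplets_for("PROA phosphorylates PROB")
        post = direction_model.posterior(extract_features(triplets[0], s))
        assert post[LR] + post[RL] == pytest.approx(1.0, abs=1e-9)

    def test_exact_tie_resolves_lr_low_confidence(self):
        data = [(_fv(), LR)] * 10 + [(_fv(), RL)] * 10
        tie_model = train_model(data, kind="direction")
        s, triplets = triplets_for("PROA phosphorylates PROB")
        direction, prob, low = predict_direction(triplets[0], s, LEX, tie_model)
        assert (direction, prob, low) == (LR, 0.5, True)


class TestCrossvalidate:
    def test_separable_set_perfect_f(self, interaction_pairs):
        table = crossvalidate(interaction_pairs, k=10, seed=1)
        assert set(table.columns) == {"Precision (%)", "Recall (%)",
                                      "F-Measure (%)", "ROC Area (%)"}
        assert (table["F-Measure (%)"] == 100.0).all()

    def test_permuted_labels_roc_near_half(self, bundle):
        labeled = fx.generate_labeled_triplets(bundle, n_true=1000,
                                               n_false=1000, seed=3)
        pairs = rows_to_pairs(labeled.interaction)
        rng = random.Random(13)
        labels = [label for _, label in pairs]
        rng.shuffle(labels)
        permuted = [(fv, lab) for (fv, _), lab in zip(pairs, labels)]
        table = crossvalidate(permuted, k=10, seed=1)
        for auc in table["ROC Area (%)"]:
            assert 45.0 <= auc <= 55.0

    def test_confusion_counts_conserve_n(self, interaction_pairs):
        table = crossvalidate(interaction_pairs, k=5, seed=2)
        n = len(interaction_pairs)
        # per class: TP+FN = class size; recover from P/R at pooled level
        for cls, row in table.iterrows():
            size = sum(1 for _, lab in interaction_pairs if lab == cls)
            recall = row["Recall (%)"] / 100
            tp = round(recall * size)
            assert 0 <= tp <= size <= n

    def test_small_class_falls_back_unstratified(self, caplog):
        data = [(_fv(), "a")] * 3 + [(_fv(negation="yes"), "b")] * 37
        table = crossvalidate(data, k=10, seed=1)
        assert set(table.index) == {"a", "b"}

    def test_k_too_small_rejected(self, interaction_pairs):
        with pytest.raises(ValueError):
            crossvalidate(interaction_pairs, k=1)


class TestAgainstSklearn:
    def test_posterior_matches_categorical_nb(self, interaction_pairs):
        """Hand-rolled NB agrees with sklearn CategoricalNB on shared domains."""
        from sklearn.naive_bayes import CategoricalNB
        from sklearn.preprocessing import OrdinalEncoder

        X_raw = [[fv[name] for name in sorted(fv)] for fv, _ in interaction_pairs]
        y = np.array([lab for _, lab in interaction_pairs])
        enc = OrdinalEncoder()
        X = enc.fit_transform(X_raw)
        clf = CategoricalNB(alpha=1.0).fit(X, y)
        model = train_model(interaction_pairs, smoothing=1.0)

        # compare on training vectors (domains coincide there)
        probs_skl = clf.predict_proba(X)
        classes = list(clf.classes_)
        for (fv, _), row in zip(interaction_pairs[:50], probs_skl[:50]):
            mine = model.posterior(fv)
            for ci, cls in enumerate(classes):
                assert mine[cls] == pytest.approx(row[ci], abs=1e-6)
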