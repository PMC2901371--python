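"""Multinomial naive Bayes sentence classifier and its evaluation."""

import math
import random

import pytest

from envminer.classifier import (
    LabeledSentence,
    classify,
    jackknife_evaluate,
    select_features,
    tokenize_for_classifier,
    train_mnb,
)


def _corpus(rows):
    return [LabeledSentence(tuple(toks), lab) for toks, lab in rows]


TOY = _corpus(
    [
        (["lake", "sediment", "lake"], "env"),
        (["lake", "sediment"], "env"),
        (["buffer", "primer"], "exp"),
        (["primer", "primer", "buffer"], "exp"),
    ]
)


class TestSelectFeatures:
    def test_single_sentence_word_excluded(self):
        corpus = _corpus([(["rare", "lake"], "env"), (["lake"], "env"), (["buffer"], "exp"), (["buffer"], "exp")])
        vocab = select_features(corpus)
        assert "rare" not in vocab.words

    def test_doubling_rule_is_inclusive_at_the_boundary(self):
        # "word": 4 env tokens vs 2 exp tokens, in >1 sentence -> included
        corpus = _corpus(
            [
                (["word", "word"], "env"),
                (["word", "word"], "env"),
                (["word", "other"], "exp"),
                (["word", "other"], "exp"),
            ]
        )
        vocab = select_features(corpus)
        assert "word" in vocab.words
        assert vocab.count_env["word"] == 4 and vocab.count_exp["word"] == 2

    def test_balanced_word_excluded(self):
        corpus = _corpus(
            [(["even"], "env"), (["even"], "env"), (["even"], "exp"), (["even", "x"], "exp"), (["x"], "exp")]
        )
        assert "even" not in select_features(corpus).words

    def test_single_label_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            select_features(_corpus([(["a"], "env"), (["b"], "env")]))

    def test_matches_bruteforce_filter_on_random_corpora(self):
        """Selected set equals exhaustive application of the df>=2 and
        2x-frequency rules on 20 random corpora."""
        rng = random.Random(9)
        pool = [f"w{i}" for i in range(12)]
        for _ in range(20):
            corpus = [
                LabeledSentence(
                    tuple(rng.choices(pool, k=rng.randint(1, 6))),
                    rng.choice(["env", "exp"]),
                )
                for _ in range(rng.randint(6, 15))
            ]
            if len({s.label for s in corpus}) < 2:
                continue
            vocab = select_features(corpus)
            # brute force
            expected = set()
            words = {w for s in corpus for w in s.tokens}
            for w in words:
                df = sum(1 for s in corpus if w in s.tokens)
                ce = sum(s.tokens.count(w) for s in corpus if s.label == "env")
                cx = sum(s.tokens.count(w) for s in corpus if s.label == "exp")
                if df >= 2 and (ce >= 2 * cx or cx >= 2 * ce):
                    expected.add(w)
            assert set(vocab.words) == expected


class TestTrainMnb:
    def test_symmetric_corpus_has_equal_priors(self):
        model = train_mnb(TOY, select_features(TOY))
        assert model.class_log_priors["env"] == pytest.approx(math.log(0.5))
        assert model.class_log_priors["exp"] == pytest.approx(math.log(0.5))

    def test_hand_computed_posteriors(self):
        """Laplace-smoothed likelihoods and posteriors equal hand-derived
        values on the 4-sentence toy corpus, to 1e-12."""
        vocab = select_features(TOY)
        assert set(vocab.words) == {"lake", "sediment", "buffer", "primer"}
        model = train_mnb(TOY, vocab, alpha=1.0)
        # env tokens over vocab: lake x3, sediment x2 (total 5); V=4
        assert model.word_log_likelihoods["env"]["lake"] == pytest.approx(
            math.log(4 / 9), abs=1e-12
        )
        assert model.word_log_likelihoods["env"]["buffer"] == pytest.approx(
            math.log(1 / 9), abs=1e-12
        )
        # exp tokens: primer x3, buffer x2 (total 5)
        assert model.word_log_likelihoods["exp"]["primer"] == pytest.approx(
            math.log(4 / 9), abs=1e-12
        )
        label, post, prior_only = classify(model, ["lake", "sediment"])
        # p(env)*(4/9)*(3/9) vs p(exp)*(1/9)*(1/9) -> posterior 12/13
        assert label == "env" and not prior_only
        assert post == pytest.approx(12 / 13, abs=1e-12)

    def test_likelihoods_normalize_per_class(self):
        model = train_mnb(TOY, select_features(TOY), alpha=0.7)
        for lab in ("env", "exp"):
            total = sum(math.exp(v) for v in model.word_log_likelihoods[lab].values())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            train_mnb(TOY, select_features(TOY), alpha=0.0)

    def test_large_alpha_drives_posteriors_to_priors(self):
        model = train_mnb(TOY, select_features(TOY), alpha=1e9)
        label, post, _ = classify(model, ["lake", "lake", "lake"])
        assert post == pytest.approx(0.5, abs=1e-6)


class TestClassify:
    def test_exclusive_words_give_confident_label(self):
        model = train_mnb(TOY, select_features(TOY))
        label, post, _ = classify(model, ["lake", "sediment", "lake"])
        assert label == "env" and post > 0.9

    def test_no_vocabulary_tokens_prior_only(self):
        model = train_mnb(TOY, select_features(TOY))
        label, post, prior_only = classify(model, ["unseen", "tokens"])
        assert prior_only and label == "exp"  # tie broken to the majority class

    def test_posteriors_sum_to_one(self):
        model = train_mnb(TOY, select_features(TOY))
        for toks in (["lake"], ["primer", "buffer"], ["lake", "primer"]):
            _, post, _ = classify(model, toks)
            assert 0.5 - 1e-12 <= post <= 1.0 + 1e-12

    def test_adding_env_word_never_lowers_env_posterior(self):
        model = train_mnb(TOY, select_features(TOY))

        def env_posterior(toks):
            label, post, _ = classify(model, toks)
            return post if label == "env" else 1.0 - post

        base = ["lake", "primer"]
        assert env_posterior(base + ["sediment"]) >= env_posterior(base)

    def test_matches_direct_formula_on_small_corpora(self):
        """classify() equals a brute-force evaluation of the MNB formula on
        random corpora of <= 20 sentences."""
        rng = random.Random(5)
        pool = [f"w{i}" for i in range(8)]
        for _ in range(10):
            corpus = [
                LabeledSentence(tuple(rng.choices(pool, k=3)), rng.choice(["env", "exp"]))
                for _ in range(rng.randint(4, 20))
            ]
            if len({s.label for s in corpus}) < 2:
                continue
            try:
                vocab = select_features(corpus)
                model = train_mnb(corpus, vocab)
            except ValueError:
                continue
            test_toks = rng.choices(pool, k=4)
            label, post, _ = classify(model, test_toks)
            # independent direct evaluation from raw counts
            scores = {}
            n = {lab: sum(1 for s in corpus if s.label == lab) for lab in ("env", "exp")}
            for lab in ("env", "exp"):
                counts = {w: 0 for w in vocab.words}
                for s in corpus:
                    if s.label == lab:
                        for t in s.tokens:
                            if t in counts:
                                counts[t] += 1
                denom = sum(counts.values()) + len(vocab.words)
                score = math.log(n[lab] / len(corpus))
                for t in test_toks:
                    if t in counts:
                        score += math.log((counts[t] + 1) / denom)
                scores[lab] = score
            expected = "env" if scores["env"] > scores["exp"] else "exp"
            assert label == expected
            z = sum(math.exp(v - max(scores.values())) for v in scores.values())
            assert post == pytest.approx(
                math.exp(scores[label] - max(scores.values())) / z, abs=1e-12
            )

    def test_agrees_with_sklearn_multinomial_nb(self):
        """Independent cross-check against scikit-learn's MultinomialNB on
        the same count matrix and vocabulary."""
        import numpy as np
        from sklearn.naive_bayes import MultinomialNB

        rng = random.Random(13)
        pool = [f"w{i}" for i in range(10)]
        corpus = [
            LabeledSentence(tuple(rng.choices(pool, k=5)), rng.choice(["env", "exp"]))
            for _ in range(30)
        ]
        vocab = select_features(corpus)
        model = train_mnb(corpus, vocab)
        X = np.array(
            [[s.tokens.count(w) for w in vocab.words] for s in corpus]
        )
        y = [s.label for s in corpus]
        sk = MultinomialNB(alpha=1.0).fit(X, y)
        for s in corpus:
            ours, post, _ = classify(model, s)
            x = np.array([[s.tokens.count(w) for w in vocab.words]])
            theirs = sk.predict(x)[0]
            sk_post = sk.predict_proba(x)[0][list(sk.classes_).index(ours)]
            assert ours == theirs
            assert post == pytest.approx(sk_post, abs=1e-9)


class TestJackknife:
    def test_separable_corpus_is_perfect(self):
        corpus = _corpus(
            [(["lake", "marsh"], "env")] * 3
            + [(["marsh", "lake"], "env")] * 2
            + [(["buffer", "primer"], "exp")] * 3
            + [(["primer", "buffer"], "exp")] * 2
        )
        report = jackknife_evaluate(corpus)
        for lab in ("env", "exp"):
            assert report.per_label[lab]["recall"] == 1.0
            assert report.per_label[lab]["precision"] == 1.0

    def test_degenerate_two_sentence_corpus(self):
        corpus = _corpus([(["lake"], "env"), (["buffer"], "exp")])
        report = jackknife_evaluate(corpus)
        total_classified = sum(v["classified"] for v in report.per_label.values())
        assert total_classified == 2
        for lab in ("env", "exp"):
            assert set(report.per_label[lab]) == {
                "original", "classified", "correct", "recall", "precision", "f_value",
            }

    def test_permutation_invariance(self):
        rng = random.Random(3)
        corpus = _corpus(
            [(["lake", "sediment"], "env")] * 5 + [(["buffer", "primer"], "exp")] * 7
        )
        base = jackknife_evaluate(corpus).to_dict()
        for _ in range(3):
            shuffled = corpus[:]
            rng.shuffle(shuffled)
            assert jackknife_evaluate(shuffled).to_dict() == base

    def test_too_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            jackknife_evaluate(_corpus([(["a"], "env")]))


def test_tokenizer_collapses_numbers():
    assert tokenize_for_classifier("Stored at 5 degrees, pH 7.2!") == [
        "stored", "at", "<num>", "degrees", "ph", "<num>",
    ]
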