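"""Environmental vs experimental sentence classification.

Most measurements and place names in an article describe experimental
settings or manufacturers' addresses rather than the sampled environment. A
multinomial naive Bayes classifier over a filtered bag-of-words vocabulary
separates environment-describing sentences (label ``env``) from experimental
ones (``exp``).

Feature filter: a word enters the vocabulary only if it occurs in more than
one sentence and its token frequency in one class at least doubles that in
the other (inclusive: 4 vs 2 passes). Model: class priors from sentence
counts; per-class word likelihoods with Laplace smoothing
(count + alpha) / (class tokens over vocabulary + alpha * |vocabulary|);
out-of-vocabulary tokens are ignored at train and classify time.

Evaluation is leave-one-out (jackknife): for each sentence, feature
selection *and* training are redone on the remaining n-1 sentences, so no
information leaks from the held-out item.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "LabeledSentence",
    "FeatureVocabulary",
    "ClassifierModel",
    "EvaluationReport",
    "tokenize_for_classifier",
    "load_labeled_corpus",
    "select_features",
    "train_mnb",
    "classify",
    "jackknife_evaluate",
]

LABELS = ("env", "exp")

_WORD_RE = re.compile(r"[a-z]+|\d+(?:\.\d+)?")


def tokenize_for_classifier(text: str) -> list[str]:
    """Lower-case word tokens; numbers collapse to the token "<num>"."""
    out = []
    for m in _WORD_RE.finditer(text.casefold()):
        tok = m.group(0)
        out.append("<num>" if tok[0].isdigit() else tok)
    return out


@dataclass(frozen=True)
class LabeledSentence:
    tokens: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.tokens:
            raise ValueError("sentence has no tokens")

    @classmethod
    def from_text(cls, text: str, label: str) -> "LabeledSentence":
        return cls(tuple(tokenize_for_classifier(text)), label)


def load_labeled_corpus(path: str | Path) -> list[LabeledSentence]:
    """TSV with columns: label (env|exp), sentence text."""
    corpus = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            label, text = line.split("\t", 1)
        except ValueError:
            raise ValueError(f"line {lineno}: expected 'label<TAB>text'") from None
        corpus.append(LabeledSentence.from_text(text, label.strip()))
    return corpus


@dataclass
class FeatureVocabulary:
    words: tuple[str, ...]
    count_env: dict[str, int]
    count_exp: dict[str, int]
    sentence_df: dict[str, int]

    def __len__(self) -> int:
        return len(self.words)


def select_features(
    corpus: list[LabeledSentence], normalize_by_class_size: bool = False
) -> FeatureVocabulary:
    """The filtered vocabulary: sentence document frequency >= 2 and the
    token frequency in one class at least double that in the other.

    With ``normalize_by_class_size`` the doubling rule compares per-class
    token *rates* instead of raw counts (an alternative reading for
    imbalanced corpora; off by default).
    """
    labels_seen = {s.label for s in corpus}
    if len(labels_seen) < 2:
        raise ValueError("corpus must contain both labels (env and exp)")
    count: dict[str, Counter] = {lab: Counter() for lab in LABELS}
    df: Counter = Counter()
    for s in corpus:
        count[s.label].update(s.tokens)
        df.update(set(s.tokens))
    total = {lab: sum(count[lab].values()) for lab in LABELS}
    words = []
    for w in sorted(df):
        if df[w] < 2:
            continue
        ce, cx = count["env"][w], count["exp"][w]
        if normalize_by_class_size and total["env"] and total["exp"]:
            ce_v, cx_v = ce / total["env"], cx / total["exp"]
        else:
            ce_v, cx_v = ce, cx
        if ce_v >= 2 * cx_v or cx_v >= 2 * ce_v:
            words.append(w)
    return FeatureVocabulary(
        words=tuple(words),
        count_env={w: count["env"][w] for w in words},
        count_exp={w: count["exp"][w] for w in words},
        sentence_df={w: df[w] for w in words},
    )


@dataclass
class ClassifierModel:
    class_log_priors: dict[str, float]
    word_log_likelihoods: dict[str, dict[str, float]]  # label -> word -> log p
    smoothing_alpha: float
    vocabulary: FeatureVocabulary

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_log_priors": self.class_log_priors,
                "word_log_likelihoods": self.word_log_likelihoods,
                "smoothing_alpha": self.smoothing_alpha,
                "vocabulary": list(self.vocabulary.words),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        data = json.loads(text)
        words = tuple(data["vocabulary"])
        return cls(
            class_log_priors=data["class_log_priors"],
            word_log_likelihoods=data["word_log_likelihoods"],
            smoothing_alpha=data["smoothing_alpha"],
            vocabulary=FeatureVocabulary(words, {}, {}, {}),
        )


def train_mnb(
    corpus: list[LabeledSentence],
    vocab: FeatureVocabulary,
    alpha: float = 1.0,
) -> ClassifierModel:
    """Multinomial naive Bayes with Laplace smoothing over ``vocab``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not vocab.words:
        raise ValueError("empty vocabulary")
    vocab_set = set(vocab.words)
    n = {lab: 0 for lab in LABELS}
    counts: dict[str, Counter] = {lab: Counter() for lab in LABELS}
    for s in corpus:
        n[s.label] += 1
        counts[s.label].update(t for t in s.tokens if t in vocab_set)
    total_sent = sum(n.values())
    priors = {lab: math.log(n[lab] / total_sent) if n[lab] else -math.inf for lab in LABELS}
    loglik: dict[str, dict[str, float]] = {}
    V = len(vocab.words)
    for lab in LABELS:
        total_tokens = sum(counts[lab].values())
        denom = total_tokens + alpha * V
        loglik[lab] = {
            w: math.log((counts[lab][w] + alpha) / denom) for w in vocab.words
        }
    return ClassifierModel(
        class_log_priors=priors,
        word_log_likelihoods=loglik,
        smoothing_alpha=alpha,
        vocabulary=vocab,
    )


def classify(model: ClassifierModel, tokens) -> tuple[str, float, bool]:
    """(label, posterior over the two labels, prior_only flag).

    Tokens may be a LabeledSentence, a token sequence, or raw text. Ties in
    the log score go to ``exp`` (the majority class in this domain).
    """
    if isinstance(tokens, LabeledSentence):
        toks = tokens.tokens
    elif isinstance(tokens, str):
        toks = tokenize_for_classifier(tokens)
    else:
        toks = list(tokens)
    in_vocab = [t for t in toks if t in model.word_log_likelihoods[LABELS[0]]]
    scores = {}
    for lab in LABELS:
        s = model.class_log_priors[lab]
        ll = model.word_log_likelihoods[lab]
        for t in in_vocab:
            s += ll[t]
        scores[lab] = s
    # normalized posterior over the two labels
    mx = max(scores.values())
    exp_scores = {lab: math.exp(s - mx) for lab, s in scores.items()}
    z = sum(exp_scores.values())
    if scores["env"] > scores["exp"]:
        label = "env"
    else:
        label = "exp"  # documented tie-break to the majority class
    return label, exp_scores[label] / z, not in_vocab


@dataclass
class EvaluationReport:
    per_label: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        correct = sum(v["correct"] for v in self.per_label.values())
        total = sum(v["original"] for v in self.per_label.values())
        return correct / total if total else 0.0

    def to_dict(self) -> dict:
        return {"per_label": self.per_label, "accuracy": self.accuracy}


def _report(corpus, predictions) -> EvaluationReport:
    report = EvaluationReport()
    for lab in LABELS:
        original = sum(1 for s in corpus if s.label == lab)
        classified = sum(1 for p in predictions if p == lab)
        correct = sum(
            1 for s, p in zip(corpus, predictions) if s.label == lab and p == lab
        )
        recall = correct / original if original else 0.0
        precision = correct / classified if classified else 0.0
        f = 2 * recall * precision / (recall + precision) if recall + precision else 0.0
        report.per_label[lab] = {
            "original": original,
            "classified": classified,
            "correct": correct,
            "recall": recall,
            "precision": precision,
            "f_value": f,
        }
    return report


def jackknife_evaluate(
    corpus: list[LabeledSentence], alpha: float = 1.0
) -> EvaluationReport:
    """Leave-one-out evaluation with per-fold feature selection.

    For each sentence, the vocabulary is reselected and the model retrained
    on the other n-1 sentences; the held-out sentence is then classified.
    Degenerate folds (single-label remainder, or empty vocabulary) predict
    by prior alone.
    """
    if len(corpus) < 2:
        raise ValueError("jackknife needs at least 2 sentences")
    predictions = []
    for i in range(len(corpus)):
        fold = corpus[:i] + corpus[i + 1 :]
        try:
            vocab = select_features(fold)
            model = train_mnb(fold, vocab, alpha=alpha)
            label, _, _ = classify(model, corpus[i])
        except ValueError:
            # single-label or featureless fold: majority prior, tie to exp
            n_env = sum(1 for s in fold if s.label == "env")
            n_exp = len(fold) - n_env
            label = "env" if n_env > n_exp else "exp"
        predictions.append(label)
    return _report(corpus, predictions)
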