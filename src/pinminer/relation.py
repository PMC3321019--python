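"""Triplet enumeration, interaction scoring, and directionality prediction.

A candidate relation is a *triplet*: two protein mentions and one
interaction word in the same sentence.  Discrete feature vectors are
extracted per triplet and scored by a Bayesian classifier (realized here
as naive Bayes over the discrete features — a Bayesian network with a
fixed star structure; the structure is pluggable behind the
:class:`TripletModel` contract) trained on labeled triplets.  Triplets
passing the probability threshold and carrying a with-direction word are
then classified as left→right (LR: the relation flows from the
sentence-first protein to the second) or left←right (RL).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from pinminer.corpus import Sentence
from pinminer.tagger import InteractionLexicon, Mention, tokenize

logger = logging.getLogger(__name__)

LR, RL, NONE = "LR", "RL", "NONE"

#: feature schema, fixed for a model's lifetime
FEATURE_NAMES = (
    "distance_bin",       # tokens strictly between protein a and b: 0-2 / 3-5 / 6+
    "word_position",      # interaction word before / between / after the pair
    "intervening_bin",    # other protein mentions between a and b: 0 / 1 / 2+
    "negation",           # negation token within 3 tokens of the word: yes / no
    "comma_between",      # comma between a and b: yes / no
    "inflection",         # interaction word form: base / s / ed / ing / nominal
)

NEGATION_TOKENS = frozenset({
    "not", "no", "never", "cannot", "without", "neither", "nor",
    "fails", "fail", "failed", "unable", "lacks", "lack", "absence",
})


@dataclass(frozen=True)
class CandidateTriplet:
    """Two protein mentions + one interaction word from one sentence."""

    protein_a: Mention
    protein_b: Mention
    interaction: Mention
    sentence_ref: tuple[str, int]
    other_proteins: tuple[Mention, ...] = ()

    def __post_init__(self) -> None:
        if self.protein_a.start >= self.protein_b.start:
            raise ValueError("protein_a must precede protein_b in the sentence")


FeatureVector = dict  # feature name -> categorical value (str)


@dataclass
class TripletModel:
    """Naive-Bayes classifier over the discrete triplet feature schema.

    ``kind`` is ``interaction`` (labels true/false) or ``direction``
    (labels LR/RL).  ``tables[feature][label][value]`` holds training
    counts; posteriors use Laplace smoothing with constant ``smoothing``.
    """

    kind: str
    labels: tuple[str, ...]
    class_counts: dict[str, int]
    tables: dict[str, dict[str, dict[str, int]]]
    smoothing: float = 1.0
    seed: int | None = None
    version: int = 1

    def posterior(self, features: FeatureVector) -> dict[str, float]:
        """P(label | features); sums to 1 within 1e-9."""
        missing = [f for f in FEATURE_NAMES if f not in features]
        if missing:
            raise ValueError(f"feature vector missing {missing}")
        total = sum(self.class_counts.values())
        log_post = {}
        for label in self.labels:
            n_c = self.class_counts[label]
            lp = math.log(n_c / total)
            for name in FEATURE_NAMES:
                table = self.tables[name][label]
                domain = set()
                for lab in self.labels:
                    domain.update(self.tables[name][lab])
                value = features[name]
                if value not in domain:
                    domain = domain | {value}
                count = table.get(value, 0)
                lp += math.log(
                    (count + self.smoothing)
                    / (n_c + self.smoothing * len(domain))
                )
            log_post[label] = lp
        peak = max(log_post.values())
        unnorm = {lab: math.exp(lp - peak) for lab, lp in log_post.items()}
        z = sum(unnorm.values())
        return {lab: p / z for lab, p in unnorm.items()}

    def to_json(self) -> str:
        return json.dumps({
            "format": "pinminer-triplet-model",
            "version": self.version,
            "kind": self.kind,
            "labels": list(self.labels),
            "class_counts": self.class_counts,
            "tables": self.tables,
            "smoothing": self.smoothing,
            "seed": self.seed,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TripletModel":
        data = json.loads(text)
        if data.get("format") != "pinminer-triplet-model":
            raise ValueError("not a triplet model file")
        return cls(
            kind=data["kind"], labels=tuple(data["labels"]),
            class_counts=data["class_counts"], tables=data["tables"],
            smoothing=data["smoothing"], seed=data.get("seed"),
            version=data["version"],
        )


@dataclass(frozen=True)
class ScoredInteraction:
    """A triplet with its interaction probability and direction call."""

    triplet: CandidateTriplet
    probability: float
    interaction_type: str
    direction: str  # LR / RL / NONE
    direction_probability: float | None
    normalized_a: object = None
    normalized_b: object = None
    low_confidence_direction: bool = False
    evidence: str = ""  # evidence sentence, triplet terms marked

    def __post_init__(self) -> None:
        if (self.direction == NONE) != (self.direction_probability is None):
            raise ValueError("direction_probability present iff direction != NONE")


# ---------------------------------------------------------------------------
# enumeration and features


def enumerate_triplets(protein_mentions: list[Mention],
                       interaction_mentions: list[Mention],
                       sentence: Sentence) -> list[CandidateTriplet]:
    """All (unordered protein pair) x (interaction word) candidates.

    A sentence with fewer than two protein mentions or no interaction
    word yields nothing and is effectively dropped.
    """

    proteins = sorted(protein_mentions, key=lambda m: m.start)
    if len(proteins) < 2 or not interaction_mentions:
        return []
    triplets = []
    for a, b in combinations(proteins, 2):
        others = tuple(m for m in proteins if m not in (a, b))
        for word in sorted(interaction_mentions, key=lambda m: m.start):
            triplets.append(CandidateTriplet(
                protein_a=a, protein_b=b, interaction=word,
                sentence_ref=(sentence.pmid, sentence.index),
                other_proteins=others,
            ))
    return triplets


def _token_index(tokens, offset: int) -> int:
    """Index of the token containing (or first token at/after) offset."""
    for i, (_, start, end) in enumerate(tokens):
        if start <= offset < end or offset < start:
            return i
    return len(tokens) - 1


def _span_tokens(tokens, mention: Mention) -> tuple[int, int]:
    first = _token_index(tokens, mention.start)
    last = first
    for i in range(first, len(tokens)):
        if tokens[i][1] < mention.end:
            last = i
        else:
            break
    return first, last


def _bin_distance(n: int) -> str:
    if n <= 2:
        return "0-2"
    if n <= 5:
        return "3-5"
    return "6+"


def _bin_count(n: int) -> str:
    return {0: "0", 1: "1"}.get(n, "2+")


def _inflection_class(surface: str) -> str:
    word = surface.casefold()
    if word.endswith(("tion", "sion", "ment", "ance", "ase")):
        return "nominal"
    if word.endswith("ing"):
        return "ing"
    if word.endswith("ed"):
        return "ed"
    if word.endswith("s") and not word.endswith("ss"):
        return "s"
    return "base"


def extract_features(triplet: CandidateTriplet, sentence: Sentence) -> FeatureVector:
    """Compute the fixed discrete feature schema for one triplet."""

    for m in (triplet.protein_a, triplet.protein_b, triplet.interaction):
        if m.end > len(sentence.preprocessed) or \
                sentence.preprocessed[m.start:m.end] != m.surface:
            raise ValueError("triplet mentions do not lie on this sentence")

    tokens = tokenize(sentence.preprocessed)
    a_first, a_last = _span_tokens(tokens, triplet.protein_a)
    b_first, b_last = _span_tokens(tokens, triplet.protein_b)
    w_first, w_last = _span_tokens(tokens, triplet.interaction)

    between = max(0, b_first - a_last - 1)

    if w_last < a_first:
        position = "before"
    elif w_first > b_last:
        position = "after"
    else:
        position = "between"

    intervening = sum(
        1 for m in triplet.other_proteins
        if triplet.protein_a.end <= m.start and m.end <= triplet.protein_b.start
    )

    lo, hi = max(0, w_first - 3), min(len(tokens), w_last + 4)
    negation = any(
        tokens[i][0].casefold().strip(".,;:") in NEGATION_TOKENS
        for i in range(lo, hi)
    )

    span = sentence.preprocessed[triplet.protein_a.end:triplet.protein_b.start]
    comma = "," in span

    return {
        "distance_bin": _bin_distance(between),
        "word_position": position,
        "intervening_bin": _bin_count(intervening),
        "negation": "yes" if negation else "no",
        "comma_between": "yes" if comma else "no",
        "inflection": _inflection_class(triplet.interaction.surface),
    }


# ---------------------------------------------------------------------------
# training and scoring


def train_model(labeled, kind: str = "interaction", smoothing: float = 1.0,
                seed: int | None = None) -> TripletModel:
    """Fit Laplace-smoothed class-conditional count tables.

    ``labeled`` is a sequence of (FeatureVector, label) pairs; at least
    two distinct labels must be present.  The estimator is count-based,
    hence insensitive to example order; ``seed`` is recorded as training
    metadata.
    """

    labels = sorted({label for _, label in labeled})
    if len(labels) < 2:
        raise ValueError("training data must contain at least two classes")
    class_counts = {lab: 0 for lab in labels}
    tables = {name: {lab: {} for lab in labels} for name in FEATURE_NAMES}
    for features, label in labeled:
        class_counts[label] += 1
        for name in FEATURE_NAMES:
            value = features[name]
            tables[name][label][value] = tables[name][label].get(value, 0) + 1
    return TripletModel(kind=kind, labels=tuple(labels),
                        class_counts=class_counts, tables=tables,
                        smoothing=smoothing, seed=seed)


def score_triplet(triplet: CandidateTriplet, sentence: Sentence,
                  model: TripletModel) -> float:
    """Probability that the triplet states a true interaction."""
    if model.kind != "interaction":
        raise ValueError("score_triplet requires an interaction-kind model")
    return model.posterior(extract_features(triplet, sentence))["true"]


def predict_direction(triplet: CandidateTriplet, sentence: Sentence,
                      lexicon: InteractionLexicon,
                      model: TripletModel | None = None
                      ) -> tuple[str, float | None, bool]:
    """Direction call for a triplet already accepted as a true interaction.

    Returns (direction, direction_probability, low_confidence).  A
    without-direction word short-circuits to (NONE, None, False); an
    exact tie P=0.5 resolves to LR (the majority direction in curated
    training data) and is flagged low-confidence.
    """

    flag = lexicon.direction_flag(triplet.interaction.matched_entry)
    if flag is None:
        logger.warning("interaction word %r absent from lexicon; treated as "
                       "without-direction", triplet.interaction.matched_entry)
        return NONE, None, False
    if flag == "without_direction":
        return NONE, None, False
    if model is None or model.kind != "direction":
        raise ValueError("with-direction word requires a direction-kind model")
    post = model.posterior(extract_features(triplet, sentence))
    p_lr = post.get(LR, 0.0)
    if p_lr > 0.5:
        return LR, p_lr, False
    if p_lr < 0.5:
        return RL, 1.0 - p_lr, False
    return LR, 0.5, True


# ---------------------------------------------------------------------------
# labeled triplet files


def pairs_from_rows(rows) -> list[tuple[FeatureVector, str]]:
    """Turn labeled triplet rows into (FeatureVector, label) pairs.

    Each row carries (pmid, sentence_text, a_offsets, b_offsets,
    word_offsets, label) with 0-based half-open offsets into the
    sentence text; the first protein offset must precede the second.
    """

    out = []
    for pmid, text, a_span, b_span, w_span, label in rows:
        sentence = Sentence.from_raw(pmid, 0, text)

        def mention(kind, span):
            return Mention(kind=kind, surface=text[span[0]:span[1]],
                           start=span[0], end=span[1],
                           matched_entry=text[span[0]:span[1]],
                           sentence_ref=(pmid, 0))

        triplet = CandidateTriplet(
            protein_a=mention("protein", a_span),
            protein_b=mention("protein", b_span),
            interaction=mention("interaction", w_span),
            sentence_ref=(pmid, 0),
        )
        out.append((extract_features(triplet, sentence), label))
    return out


def load_labeled_tsv(path) -> list[tuple[FeatureVector, str]]:
    """Read ``pmid<TAB>sentence<TAB>a<TAB>b<TAB>word<TAB>label`` rows.

    Offset columns use ``start:end`` notation.
    """

    rows = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            pmid, text, a, b, w, label = line.rstrip("\n").split("\t")

            def span(col):
                lo, hi = col.split(":")
                return int(lo), int(hi)

            rows.append((pmid, text, span(a), span(b), span(w), label))
    return pairs_from_rows(rows)


# ---------------------------------------------------------------------------
# evaluation


def crossvalidate(labeled, k: int = 10, seed: int = 0,
                  kind: str = "interaction", smoothing: float = 1.0
                  ) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the naive-Bayes classifier.

    Returns one row per class with Precision (%), Recall (%),
    F-Measure (%), and ROC Area (%) computed on the pooled out-of-fold
    predictions (precision=TP/(TP+FP), recall=TP/(TP+FN), F=2PR/(P+R);
    ROC area is the rank statistic of the class posterior).  Classes
    with fewer than k members trigger an unstratified fallback.
    """

    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import KFold, StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    labeled = list(labeled)
    if len(labeled) < k:
        raise ValueError("need at least k labeled examples")
    y = np.array([label for _, label in labeled])
    classes = sorted(set(y))

    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < k:
        logger.warning("class with < k members; falling back to unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(np.zeros(len(y)))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(np.zeros(len(y)), y)

    predicted = np.empty(len(y), dtype=object)
    scores = {c: np.zeros(len(y)) for c in classes}
    for train_idx, test_idx in folds:
        train = [labeled[i] for i in train_idx]
        if len({lab for _, lab in train}) < 2:
            raise ValueError("fold with a single class; reduce k")
        model = train_model(train, kind=kind, smoothing=smoothing, seed=seed)
        for i in test_idx:
            post = model.posterior(labeled[i][0])
            predicted[i] = max(post, key=post.get)
            for c in classes:
                scores[c][i] = post.get(c, 0.0)

    rows = []
    for c in classes:
        tp = int(((predicted == c) & (y == c)).sum())
        fp = int(((predicted == c) & (y != c)).sum())
        fn = int(((predicted != c) & (y == c)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        auc = roc_auc_score((y == c).astype(int), scores[c])
        rows.append({
            "Class": c,
            "Precision (%)": 100 * precision,
            "Recall (%)": 100 * recall,
            "F-Measure (%)": 100 * f1,
            "ROC Area (%)": 100 * auc,
        })
    return pd.DataFrame(rows).set_index("Class")
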