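"""Random scored-interaction generators for structural invariant checks."""

from __future__ import annotations

import random

from pinminer.normalization import NormalizedGene
from pinminer.relation import LR, NONE, RL, CandidateTriplet, ScoredInteraction
from pinminer.tagger import Mention


def _mention(text, start, end, kind="protein"):
    return Mention(kind=kind, surface=text[start:end], start=start, end=end,
                   matched_entry=text[start:end], sentence_ref=("1", 0))


def scored_interaction(a, b, word, prob, direction, pmid, index):
    text = f"{a} {word} {b}"
    triplet = CandidateTriplet(
        protein_a=_mention(text, 0, len(a)),
        protein_b=_mention(text, len(a) + len(word) + 2, len(text)),
        interaction=_mention(text, len(a) + 1, len(a) + 1 + len(word),
                             "interaction"),
        sentence_ref=(pmid, index))

    def norm(sym):
        return NormalizedGene(surface=sym, gene_ids=(sym + "_id",),
                              official_symbol=sym, taxon_id="9606",
                              resolution_stage="cs_exact")

    return ScoredInteraction(
        triplet=triplet, probability=prob, interaction_type=word,
        direction=direction,
        direction_probability=None if direction == NONE else 0.9,
        normalized_a=norm(a), normalized_b=norm(b))


def random_interactions(rng: random.Random, symbols, max_n: int = 15):
    out = []
    for _ in range(rng.randint(1, max_n)):
        a, b = rng.sample(symbols, 2)
        direction = rng.choice([LR, RL, NONE])
        word = "binds" if direction == NONE else "phosphorylates"
        out.append(scored_interaction(
            a, b, word, prob=rng.random(), direction=direction,
            pmid=str(rng.randint(1, 4)), index=rng.randint(0, 3)))
    return out


def random_context(rng: random.Random):
    mentions = []
    for pmid in range(1, 5):
        for index in rng.sample([None, 0, 1, 2, 3], 2):
            mentions.append(Mention(
                kind="context", surface="asthma", start=0, end=6,
                matched_entry="asthma", sentence_ref=(str(pmid), index)))
    return mentions
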