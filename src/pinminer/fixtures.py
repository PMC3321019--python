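"""Synthetic resources and corpora with known planted ground truth.

Everything the pipeline needs — protein dictionary, interaction-word
lexicon, gene catalog, species index, toy OBO ontologies, and a MEDLINE
corpus — can be generated deterministically from a seed, with a
:class:`SyntheticTruth` record of every planted interaction and planted
negative.  Templates are deliberately simple English: the goal is exact,
offset-anchored ground truth for testing, not realistic prose.

Planted sentence kinds:

* positive active voice      "A phosphorylates B in lung tissue."  (LR)
* positive passive voice     "A is phosphorylated by B."           (RL)
* positive symmetric word    "A interacts with B in lung."         (NONE)
* negated relation           "A does not phosphorylate B ..."      (false)
* word outside the pair      "A and B were profiled ... that
                              phosphorylates many substrates."     (false)
* bare co-mention            "A and B were measured in samples."   (no triplet)

Variant surface forms (``SYM+``, ``SYM beta``) and lowercase traps (a
single-word symbol written in lower case, which the case-sensitive
tagger must ignore) are planted at configurable rates.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from pinminer.corpus import AbstractRecord, write_medline
from pinminer.normalization import GeneCatalog, GeneRecord, SpeciesIndex
from pinminer.tagger import InteractionLexicon, ProteinDictionary, _default_stopwords

HUMAN, MOUSE = "9606", "10090"

_SYMBOL_STEMS = ["ILK", "TGM", "STT", "MPK", "CDL", "FGR", "GRB", "TSP",
                 "FOXD", "AHRL", "JAKL", "NFKX", "SMAD", "WNTL"]

_WITH_DIRECTION = {
    "phosphorylates": ["phosphorylate", "phosphorylated", "phosphorylating"],
    "methylates": ["methylate", "methylated", "methylating"],
    "activates": ["activate", "activated", "activating", "co-activates"],
    "inhibits": ["inhibit", "inhibited", "inhibiting"],
    "ubiquitinates": ["ubiquitinate", "ubiquitinated", "ubiquitinating"],
    "acetylates": ["acetylate", "acetylated", "acetylating"],
}
_WITHOUT_DIRECTION = {
    "interacts": ["interact", "interacted", "interacting"],
    "binds": ["bind", "bound", "binding"],
    "associates": ["associate", "associated", "associating"],
    "complexes": ["complexed"],
    "colocalizes": ["colocalize", "colocalized", "co-localizes"],
    "dimerizes": ["dimerize", "dimerized", "dimerizing"],
}

_DISEASE_OBO = """format-version: 1.2
ontology: toydisease

[Term]
id: DIS:0000001
name: airway disease

[Term]
id: DIS:0000002
name: asthma
synonym: "bronchial asthma" EXACT []
is_a: DIS:0000001 ! airway disease

[Term]
id: DIS:0000003
name: allergic asthma
synonym: "atopic asthma" EXACT []
is_a: DIS:0000002 ! asthma

[Term]
id: DIS:0000004
name: COPD
synonym: "chronic obstructive pulmonary disease" EXACT []
is_a: DIS:0000001 ! airway disease

[Term]
id: DIS:0000005
name: retired airway entity
is_obsolete: true
"""

_TISSUE_OBO = """format-version: 1.2
ontology: toytissue

[Term]
id: TIS:0000001
name: respiratory tissue

[Term]
id: TIS:0000002
name: lung
synonym: "pulmonary tissue" EXACT []
is_a: TIS:0000001 ! respiratory tissue

[Term]
id: TIS:0000003
name: bronchial epithelium
part_of: TIS:0000002 ! lung
"""


@dataclass
class ResourceBundle:
    dictionary: ProteinDictionary
    lexicon: InteractionLexicon
    catalog: GeneCatalog
    species_index: SpeciesIndex
    obo_files: dict[str, str]  # name -> OBO text
    symbols: dict[str, list[str]]  # taxon -> official symbols

    def save(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "dictionary": out / "protein_names.txt",
            "general_terms": out / "general_terms.txt",
            "head_extensions": out / "head_extensions.txt",
            "lexicon": out / "interaction_words.tsv",
            "catalog": out / "gene_catalog.tsv",
            "species": out / "species_names.tsv",
        }
        self.dictionary.save(paths["dictionary"])
        for key, values in (("general_terms", self.dictionary.general_terms),
                            ("head_extensions", self.dictionary.head_extensions)):
            paths[key].write_text("\n".join(sorted(values)) + "\n",
                                  encoding="utf-8")
        self.lexicon.save(paths["lexicon"])
        self.catalog.save(paths["catalog"])
        self.species_index.save(paths["species"])
        for name, text in self.obo_files.items():
            path = out / f"{name}.obo"
            path.write_text(text, encoding="utf-8")
            paths[name] = path
        return paths


def make_resources(seed: int = 0, n_genes_human: int = 14,
                   n_genes_mouse: int = 6) -> ResourceBundle:
    """Generate internally consistent toy resources.

    Every catalog symbol appears in the protein dictionary; the lexicon
    carries both direction flags; each taxon has one synonym shared by
    two genes (to exercise ambiguity); ontologies have >= 2 levels.
    """

    if n_genes_human < 10:
        raise ValueError("need at least 10 human genes")
    rng = random.Random(seed)

    records: list[GeneRecord] = []
    symbols: dict[str, list[str]] = {HUMAN: [], MOUSE: []}

    def gene_block(taxon: str, n: int, id_base: int, title_case: bool):
        for i in range(n):
            stem = _SYMBOL_STEMS[i % len(_SYMBOL_STEMS)]
            symbol = f"{stem}{i + 1}"
            if title_case:
                symbol = symbol.capitalize()
            gene_id = str(id_base + i)
            synonyms = [f"{symbol}X"]
            # one ambiguous synonym shared between the first two genes
            if i in (0, 1):
                synonyms.append("SHARED1" if taxon == HUMAN else "Shared1m")
            records.append(GeneRecord(
                gene_id=gene_id, taxon_id=taxon, official_symbol=symbol,
                synonyms=tuple(synonyms),
                full_name=f"signalling factor {symbol} homolog",
                other_symbols=(f"OS-{symbol}",),
                locus_tag=f"LOC{gene_id}",
            ))
            symbols[taxon].append(symbol)

    gene_block(HUMAN, n_genes_human, 1000, title_case=False)
    gene_block(MOUSE, n_genes_mouse, 2000, title_case=True)

    catalog = GeneCatalog(records)

    stopwords = _default_stopwords()
    entries = set()
    for rec in records:
        entries.add(rec.official_symbol)
        entries.update(rec.synonyms)
    entries = {e for e in entries if len(e) > 1 and e.casefold() not in stopwords}
    dictionary = ProteinDictionary(
        entries=entries,
        general_terms={"alpha", "beta", "gamma"},
        head_extensions={"receptor", "kinase", "ligand"},
        stopwords=stopwords,
    )

    words = {w: "with_direction" for w in _WITH_DIRECTION}
    words.update({w: "without_direction" for w in _WITHOUT_DIRECTION})
    variants = {}
    for canon, forms in {**_WITH_DIRECTION, **_WITHOUT_DIRECTION}.items():
        for form in forms:
            variants[form] = canon
    lexicon = InteractionLexicon(words=words, variants=variants)

    species_index = SpeciesIndex({
        "human": HUMAN, "humans": HUMAN, "Homo sapiens": HUMAN,
        "mouse": MOUSE, "mice": MOUSE, "Mus musculus": MOUSE,
    })

    rng.random()  # reserve the stream for future size randomization
    return ResourceBundle(
        dictionary=dictionary, lexicon=lexicon, catalog=catalog,
        species_index=species_index,
        obo_files={"disease": _DISEASE_OBO, "tissue": _TISSUE_OBO},
        symbols=symbols,
    )


# ---------------------------------------------------------------------------
# corpus generation


@dataclass(frozen=True)
class PlantedItem:
    """One planted sentence with offset-anchored mentions in raw text."""

    pmid: str
    sentence_index: int
    sentence: str
    kind: str  # positive | negation | word_after | comention
    a_symbol: str
    b_symbol: str
    a_surface: str
    b_surface: str
    a_offsets: tuple[int, int]
    b_offsets: tuple[int, int]
    word: str | None = None          # canonical lexicon word
    word_surface: str | None = None
    word_offsets: tuple[int, int] | None = None
    direction: str | None = None     # LR / RL / NONE for positives


@dataclass
class SyntheticTruth:
    positives: list[PlantedItem] = field(default_factory=list)
    negatives: list[PlantedItem] = field(default_factory=list)
    traps: list[tuple[str, int, str]] = field(default_factory=list)  # pmid, idx, surface
    context_term: str = "asthma"

    def expected_edges(self) -> list[tuple[str, str, str, str]]:
        """(source, target, type, direction) multiset of the planted network."""
        edges = []
        for item in self.positives:
            if item.direction == "RL":
                src, tgt = item.b_symbol, item.a_symbol
            else:
                src, tgt = item.a_symbol, item.b_symbol
            edges.append((src, tgt, item.word, item.direction))
        return edges

    def expected_nodes(self) -> set[str]:
        nodes = set()
        for item in self.positives:
            nodes.update((item.a_symbol, item.b_symbol))
        return nodes

    def to_json(self) -> str:
        return json.dumps({
            "context_term": self.context_term,
            "positives": [asdict(p) for p in self.positives],
            "negatives": [asdict(n) for n in self.negatives],
            "traps": self.traps,
        }, indent=1)


@dataclass
class TruthSpec:
    """Study conditions for the generated corpus."""

    n_abstracts: int = 20
    positives_per_abstract: tuple[int, int] = (1, 2)
    negation_rate: float = 0.5       # P(abstract gets a negated-relation sentence)
    word_after_rate: float = 0.5     # P(abstract gets a word-outside-pair sentence)
    comention_rate: float = 0.5
    variant_rate: float = 0.3        # P(a protein surface is a variant form)
    trap_rate: float = 0.3
    passive_rate: float = 0.25       # P(a directed positive is passive = RL)
    context_term: str = "asthma"


class _SentenceBuilder:
    def __init__(self):
        self.parts: list[str] = []
        self.spans: dict[str, tuple[int, int]] = {}
        self._pos = 0

    def add(self, text: str, tag: str | None = None) -> None:
        if self.parts:
            self._pos += 1  # joining space
        start = self._pos
        self.parts.append(text)
        self._pos += len(text)
        if tag:
            self.spans[tag] = (start, self._pos)

    def finish(self) -> str:
        # terminal period attaches to the last token
        text = " ".join(self.parts) + "."
        return text


def _variant_surface(symbol: str, rng: random.Random) -> str:
    return rng.choice([symbol + "+", symbol + " beta"])


def generate_corpus(spec: TruthSpec | None = None, seed: int = 0,
                    resources: ResourceBundle | None = None,
                    out_path=None) -> tuple[list[AbstractRecord], SyntheticTruth]:
    """Generate a MEDLINE corpus with planted, offset-anchored truth.

    Species names are planted in titles and MeSH; the context term
    appears in every title so document-level co-occurrence holds for all
    planted items.  Returns the records and the truth; writes a MEDLINE
    file when ``out_path`` is given.
    """

    spec = spec or TruthSpec()
    resources = resources or make_resources(seed)
    rng = random.Random(seed + 1)
    human_symbols = resources.symbols[HUMAN]
    if len(human_symbols) < 4:
        raise ValueError("resources provide too few symbols for a corpus")

    with_dir = sorted(_WITH_DIRECTION)
    without_dir = sorted(_WITHOUT_DIRECTION)
    truth = SyntheticTruth(context_term=spec.context_term)
    records: list[AbstractRecord] = []

    for k in range(spec.n_abstracts):
        pmid = str(9000001 + k)
        title = (f"Molecular studies of {spec.context_term} in human cohort "
                 f"{k + 1}")
        sentences: list[str] = []
        index = 1  # title is sentence 0

        n_pos = rng.randint(*spec.positives_per_abstract)
        for _ in range(n_pos):
            a_sym, b_sym = rng.sample(human_symbols, 2)
            a_surf = _variant_surface(a_sym, rng) \
                if rng.random() < spec.variant_rate else a_sym
            b_surf = _variant_surface(b_sym, rng) \
                if rng.random() < spec.variant_rate else b_sym
            directed = rng.random() < 0.5
            builder = _SentenceBuilder()
            if directed and rng.random() < spec.passive_rate:
                word = rng.choice(with_dir)
                surface = _WITH_DIRECTION[word][1]  # past participle
                builder.add(a_surf, "a")
                builder.add("is")
                builder.add(surface, "w")
                builder.add("by")
                builder.add(b_surf, "b")
                builder.add("in lung tissue")
                direction = "RL"
            else:
                if directed:
                    word = rng.choice(with_dir)
                    direction = "LR"
                else:
                    word = rng.choice(without_dir)
                    direction = "NONE"
                surface = word
                builder.add(a_surf, "a")
                builder.add(surface, "w")
                if word in ("interacts", "associates", "colocalizes", "dimerizes"):
                    builder.add("with")
                builder.add(b_surf, "b")
                builder.add("in lung tissue")
            text = builder.finish()
            truth.positives.append(PlantedItem(
                pmid=pmid, sentence_index=index, sentence=text, kind="positive",
                a_symbol=a_sym, b_symbol=b_sym,
                a_surface=a_surf, b_surface=b_surf,
                a_offsets=builder.spans["a"], b_offsets=builder.spans["b"],
                word=word, word_surface=surface,
                word_offsets=builder.spans["w"], direction=direction,
            ))
            sentences.append(text)
            index += 1

        if rng.random() < spec.negation_rate:
            a_sym, b_sym = rng.sample(human_symbols, 2)
            word = rng.choice(with_dir)
            base = _WITH_DIRECTION[word][0]
            builder = _SentenceBuilder()
            builder.add(a_sym, "a")
            builder.add("does not")
            builder.add(base, "w")
            builder.add(b_sym, "b")
            builder.add("in these assays")
            text = builder.finish()
            truth.negatives.append(PlantedItem(
                pmid=pmid, sentence_index=index, sentence=text, kind="negation",
                a_symbol=a_sym, b_symbol=b_sym, a_surface=a_sym, b_surface=b_sym,
                a_offsets=builder.spans["a"], b_offsets=builder.spans["b"],
                word=word, word_surface=base, word_offsets=builder.spans["w"],
            ))
            sentences.append(text)
            index += 1

        if rng.random() < spec.word_after_rate:
            a_sym, b_sym = rng.sample(human_symbols, 2)
            word = rng.choice(with_dir + without_dir)
            builder = _SentenceBuilder()
            builder.add(a_sym, "a")
            builder.add("and")
            builder.add(b_sym, "b")
            builder.add("were profiled in a screen that")
            builder.add(word, "w")
            builder.add("many substrates")
            text = builder.finish()
            truth.negatives.append(PlantedItem(
                pmid=pmid, sentence_index=index, sentence=text, kind="word_after",
                a_symbol=a_sym, b_symbol=b_sym, a_surface=a_sym, b_surface=b_sym,
                a_offsets=builder.spans["a"], b_offsets=builder.spans["b"],
                word=word, word_surface=word, word_offsets=builder.spans["w"],
            ))
            sentences.append(text)
            index += 1

        if rng.random() < spec.comention_rate:
            a_sym, b_sym = rng.sample(human_symbols, 2)
            builder = _SentenceBuilder()
            builder.add(a_sym, "a")
            builder.add("and")
            builder.add(b_sym, "b")
            builder.add("were measured in samples")
            text = builder.finish()
            truth.negatives.append(PlantedItem(
                pmid=pmid, sentence_index=index, sentence=text, kind="comention",
                a_symbol=a_sym, b_symbol=b_sym, a_surface=a_sym, b_surface=b_sym,
                a_offsets=builder.spans["a"], b_offsets=builder.spans["b"],
            ))
            sentences.append(text)
            index += 1

        if rng.random() < spec.trap_rate:
            trap_sym = rng.choice(human_symbols).lower()
            text = f"The {trap_sym} pathway was reviewed."
            truth.traps.append((pmid, index, trap_sym))
            sentences.append(text)
            index += 1

        records.append(AbstractRecord(
            pmid=pmid, title=title, body=" ".join(sentences),
            mesh_terms=["Humans", spec.context_term.capitalize()],
            pub_date=f"{2005 + (k % 10)} Jan",
        ))

    if out_path is not None:
        write_medline(records, out_path)
    return records, truth


# ---------------------------------------------------------------------------
# tagger stress sentences


def generate_tagger_sentences(resources: ResourceBundle, n: int = 1000,
                              seed: int = 0) -> list[str]:
    """Random sentences mixing dictionary names, traps, and noise.

    Built from the fixture vocabulary: official symbols and synonyms
    (sometimes with ``+``/``-`` suffixes or absorbed modifier tokens),
    lowercase traps, general terms, head-extension nouns, and filler
    words.  Used to compare the production tagger against a brute-force
    leftmost-longest oracle.
    """

    rng = random.Random(seed)
    names = sorted(resources.dictionary.entries)
    general = sorted(resources.dictionary.general_terms)
    heads = sorted(resources.dictionary.head_extensions)
    fillers = ["the", "signal", "pathway", "was", "observed", "during",
               "expression", "while", "levels", "of", "measured"]
    sentences = []
    for _ in range(n):
        length = rng.randint(4, 12)
        tokens = []
        for _ in range(length):
            roll = rng.random()
            if roll < 0.35:
                name = rng.choice(names)
                if rng.random() < 0.2:
                    name += rng.choice(["+", "-"])
                tokens.append(name)
            elif roll < 0.45:
                tokens.append(rng.choice(names).lower())  # case trap
            elif roll < 0.55:
                tokens.append(rng.choice(general))
            elif roll < 0.65:
                tokens.append(rng.choice(heads))
            else:
                tokens.append(rng.choice(fillers))
        sentences.append(" ".join(tokens) + ".")
    return sentences


# ---------------------------------------------------------------------------
# labeled triplets for model training


@dataclass
class LabeledRow:
    pmid: str
    sentence: str
    a_offsets: tuple[int, int]
    b_offsets: tuple[int, int]
    word_offsets: tuple[int, int]
    label: str


@dataclass
class LabeledTriplets:
    interaction: list[LabeledRow] = field(default_factory=list)
    direction: list[LabeledRow] = field(default_factory=list)

    def write_tsv(self, interaction_path, direction_path=None) -> None:
        def _write(rows, path):
            with open(path, "w", encoding="utf-8") as out:
                for r in rows:
                    out.write("\t".join([
                        r.pmid, r.sentence,
                        f"{r.a_offsets[0]}:{r.a_offsets[1]}",
                        f"{r.b_offsets[0]}:{r.b_offsets[1]}",
                        f"{r.word_offsets[0]}:{r.word_offsets[1]}",
                        r.label,
                    ]) + "\n")
        _write(self.interaction, interaction_path)
        if direction_path is not None:
            _write(self.direction, direction_path)


def _row_from_builder(pmid, builder, label) -> LabeledRow:
    return LabeledRow(
        pmid=pmid, sentence=builder.finish(),
        a_offsets=builder.spans["a"], b_offsets=builder.spans["b"],
        word_offsets=builder.spans["w"], label=label,
    )


def generate_labeled_triplets(resources: ResourceBundle | None = None,
                              n_true: int = 100, n_false: int = 280,
                              n_lr: int = 116, n_rl: int = 29,
                              seed: int = 0) -> LabeledTriplets:
    """Labeled triplet sentences for training the two classifiers.

    The default interaction class ratio (100 true : 280 false, roughly
    1:2.8) and direction ratio (116 LR : 29 RL, roughly 4:1) mirror the
    curated training distributions this kind of classifier is fit on.
    """

    resources = resources or make_resources(seed)
    rng = random.Random(seed + 2)
    symbols = resources.symbols[HUMAN]
    with_dir = sorted(_WITH_DIRECTION)
    without_dir = sorted(_WITHOUT_DIRECTION)
    max_pairs = len(symbols) * (len(symbols) - 1)
    if max(n_true, n_false, n_lr, n_rl) > max_pairs * len(with_dir + without_dir):
        raise ValueError("requested more rows than generable combinations")

    out = LabeledTriplets()
    counter = 0

    def positive_builder(direction: str) -> _SentenceBuilder:
        a, b = rng.sample(symbols, 2)
        builder = _SentenceBuilder()
        if direction == "RL":
            word = rng.choice(with_dir)
            builder.add(a, "a")
            builder.add("is")
            builder.add(_WITH_DIRECTION[word][1], "w")
            builder.add("by")
            builder.add(b, "b")
        else:
            word = rng.choice(with_dir if direction == "LR" else without_dir)
            builder.add(a, "a")
            builder.add(word, "w")
            if word in ("interacts", "associates", "colocalizes", "dimerizes"):
                builder.add("with")
            builder.add(b, "b")
        builder.add("in lung tissue")
        return builder

    for i in range(n_true):
        direction = rng.choice(["LR", "LR", "RL", "NONE"])
        counter += 1
        out.interaction.append(
            _row_from_builder(f"T{counter}", positive_builder(direction), "true"))

    for i in range(n_false):
        counter += 1
        a, b = rng.sample(symbols, 2)
        builder = _SentenceBuilder()
        if rng.random() < 0.5:
            word = rng.choice(with_dir)
            builder.add(a, "a")
            builder.add("does not")
            builder.add(_WITH_DIRECTION[word][0], "w")
            builder.add(b, "b")
            builder.add("in these assays")
        else:
            word = rng.choice(with_dir + without_dir)
            builder.add(a, "a")
            builder.add("and")
            builder.add(b, "b")
            builder.add("were profiled in a screen that")
            builder.add(word, "w")
            builder.add("many substrates")
        out.interaction.append(_row_from_builder(f"F{counter}", builder, "false"))

    for direction, n in (("LR", n_lr), ("RL", n_rl)):
        for _ in range(n):
            counter += 1
            out.direction.append(
                _row_from_builder(f"D{counter}", positive_builder(direction),
                                  direction))
    return out
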