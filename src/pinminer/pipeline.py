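"""End-to-end orchestration: corpus -> tagged sentences -> scored, normalized
interactions -> filtered network, summary tables, and report files.

Stage order: retrieval/reading, sentence splitting + preprocessing,
tagging, triplet extraction + scoring, direction prediction,
normalization, network construction and reporting.  Every reported
interaction keeps provenance back to its PMID and sentence index, and
the run log records per-stage counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from pinminer import corpus as corpus_mod
from pinminer import normalization as norm_mod
from pinminer import relation as rel_mod
from pinminer import tagger as tag_mod
from pinminer.network import (
    FilterSpec,
    InteractionNetwork,
    SummaryTables,
    build_network,
    export_network,
    summarize,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and record provenance."""

    def __init__(self, stage: str, provenance: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed at {provenance}: {cause}")
        self.stage = stage
        self.provenance = provenance


@dataclass
class PipelineConfig:
    """Resources, models, filters, and output settings for one run.

    Resource fields accept either loaded objects or file paths; model
    fields accept :class:`~pinminer.relation.TripletModel` objects,
    model-JSON paths, or labeled-TSV paths to train from.
    """

    dictionary: object = None
    lexicon: object = None
    catalog: object = None
    species_index: object = None
    interaction_model: object = None
    direction_model: object = None
    context_expansions: list = dc_field(default_factory=list)
    filter_spec: FilterSpec = dc_field(default_factory=FilterSpec)
    default_taxon: str = "9606"
    seed: int = 0
    out_dir: str | Path | None = None
    highlight_markers: tuple[str, str] = ("[[", "]]")


def _load_resource(value, loader):
    if value is None or not isinstance(value, (str, Path)):
        return value
    return loader(value)


def _load_model(value, kind: str, seed: int):
    if value is None or isinstance(value, rel_mod.TripletModel):
        return value
    path = Path(value)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("{"):
        return rel_mod.TripletModel.from_json(text)
    return rel_mod.train_model(rel_mod.load_labeled_tsv(path), kind=kind, seed=seed)


def _resolve(config: PipelineConfig) -> PipelineConfig:
    config.dictionary = _load_resource(
        config.dictionary, tag_mod.ProteinDictionary.load)
    config.lexicon = _load_resource(config.lexicon, tag_mod.InteractionLexicon.load)
    config.catalog = _load_resource(config.catalog, norm_mod.GeneCatalog.load)
    config.species_index = _load_resource(
        config.species_index, norm_mod.SpeciesIndex.load)
    config.interaction_model = _load_model(
        config.interaction_model, "interaction", config.seed)
    config.direction_model = _load_model(
        config.direction_model, "direction", config.seed)
    for name in ("dictionary", "lexicon", "catalog", "species_index",
                 "interaction_model"):
        if getattr(config, name) is None:
            raise ValueError(f"pipeline config missing {name}")
    return config


def _load_corpus(corpus_source, config: PipelineConfig):
    if isinstance(corpus_source, (str, Path)):
        return corpus_mod.read_medline(corpus_source)
    if isinstance(corpus_source, (list, tuple)) and (
            not corpus_source or isinstance(corpus_source[0],
                                            corpus_mod.AbstractRecord)):
        return list(corpus_source)
    # (query, client) pair -> live/replay fetch
    query, client = corpus_source
    spec = config.filter_spec
    return corpus_mod.fetch_abstracts(
        query, max_n=spec.max_abstracts or 500,
        date_range=spec.date_range, client=client)


def run_pipeline(config: PipelineConfig, corpus_source
                 ) -> tuple[InteractionNetwork, SummaryTables, dict]:
    """Execute the full mining pipeline.

    ``corpus_source`` is a MEDLINE path, a list of AbstractRecords, or a
    ``(query, client)`` pair.  Returns the network, the three summary
    tables, and a run-log dict of per-stage counts (also written to
    ``out_dir`` along with graph and table exports when configured).
    """

    config = _resolve(config)
    counts = {}

    try:
        records = _load_corpus(corpus_source, config)
    except Exception as exc:
        raise PipelineError("retrieval", str(corpus_source), exc) from exc
    counts["abstracts"] = len(records)
    if not records:
        logger.warning("empty corpus; producing empty outputs")

    interactions: list[rel_mod.ScoredInteraction] = []
    context_mentions: list[tag_mod.Mention] = []
    counts.update(sentences=0, protein_mentions=0, interaction_mentions=0,
                  candidates=0, retained=0)
    threshold = config.filter_spec.min_probability

    for record in records:
        if not record.processable:
            continue
        try:
            taxa = norm_mod.detect_species(record, config.species_index) \
                if config.species_index is not None else []
            if not taxa:
                taxa = [config.default_taxon]
            sentences = corpus_mod.preprocess(record)
            counts["sentences"] += len(sentences)

            if config.context_expansions:
                context_mentions.extend(tag_mod.tag_context_terms(
                    record, sentences, config.context_expansions))

            norm_cache: dict[str, norm_mod.NormalizedGene] = {}
            for sentence in sentences:
                proteins = tag_mod.tag_proteins(sentence, config.dictionary)
                words = tag_mod.tag_interaction_words(sentence, config.lexicon)
                counts["protein_mentions"] += len(proteins)
                counts["interaction_mentions"] += len(words)
                triplets = rel_mod.enumerate_triplets(proteins, words, sentence)
                counts["candidates"] += len(triplets)
                for triplet in triplets:
                    prob = rel_mod.score_triplet(
                        triplet, sentence, config.interaction_model)
                    if prob < threshold:
                        continue
                    direction, dprob, low_conf = rel_mod.predict_direction(
                        triplet, sentence, config.lexicon,
                        config.direction_model)
                    norm_a = _normalize_cached(
                        triplet.protein_a.surface, taxa, config.catalog,
                        norm_cache)
                    norm_b = _normalize_cached(
                        triplet.protein_b.surface, taxa, config.catalog,
                        norm_cache)
                    evidence = _highlight(sentence, triplet,
                                          config.highlight_markers)
                    interactions.append(rel_mod.ScoredInteraction(
                        triplet=triplet, probability=prob,
                        interaction_type=triplet.interaction.matched_entry,
                        direction=direction, direction_probability=dprob,
                        normalized_a=norm_a, normalized_b=norm_b,
                        low_confidence_direction=low_conf,
                        evidence=evidence,
                    ))
                    counts["retained"] += 1
        except Exception as exc:
            raise PipelineError("mining", f"pmid {record.pmid}", exc) from exc

    try:
        net = build_network(
            interactions,
            context_mentions if config.context_expansions else None,
            config.filter_spec)
        tables = summarize(net)
    except Exception as exc:
        raise PipelineError("reporting", "network construction", exc) from exc
    counts["network_nodes"] = net.graph.number_of_nodes()
    counts["network_edges"] = net.graph.number_of_edges()

    if config.out_dir is not None:
        _write_outputs(net, tables, counts, config)
    return net, tables, counts


def _normalize_cached(surface, taxa, catalog, cache):
    key = surface
    if key not in cache:
        if catalog is None:
            cache[key] = norm_mod.NormalizedGene(surface=surface)
        else:
            cache[key] = norm_mod.normalize_mention(surface, taxa, catalog)
    return cache[key]


def _highlight(sentence, triplet, markers):
    from pinminer.network import highlight_sentence

    spans = [(m.start, m.end) for m in
             (triplet.protein_a, triplet.protein_b, triplet.interaction)]
    return highlight_sentence(sentence.preprocessed, spans, markers)


def _write_outputs(net, tables, counts, config) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_network(net, out / "network.graphml", "GraphML")
    export_network(net, out / "network.sif", "SIF")
    export_network(net, out / "interactions.tsv", "TSV",
                   markers=config.highlight_markers)
    tables.neighbors.to_csv(out / "summary_neighbors.tsv", sep="\t", index=False)
    tables.edge_strength.to_csv(out / "summary_pairs.tsv", sep="\t", index=False)
    tables.direction_degree.to_csv(out / "summary_direction.tsv", sep="\t",
                                   index=False)
    with open(out / "run.log", "w", encoding="utf-8") as log:
        for key, value in counts.items():
            log.write(f"{key}\t{value}\n")
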