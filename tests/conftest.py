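import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pinminer import fixtures as fx
from pinminer import relation as rel

SEED = 7


def rows_to_pairs(rows):
    return rel.pairs_from_rows([
        (r.pmid, r.sentence, r.a_offsets, r.b_offsets, r.word_offsets, r.label)
        for r in rows
    ])


@pytest.fixture(scope="session")
def bundle():
    return fx.make_resources(SEED)


@pytest.fixture(scope="session")
def corpus_truth(bundle):
    return fx.generate_corpus(fx.TruthSpec(), seed=SEED, resources=bundle)


@pytest.fixture(scope="session")
def labeled(bundle):
    return fx.generate_labeled_triplets(bundle, seed=SEED)


@pytest.fixture(scope="session")
def interaction_pairs(labeled):
    return rows_to_pairs(labeled.interaction)


@pytest.fixture(scope="session")
def direction_pairs(labeled):
    return rows_to_pairs(labeled.direction)


@pytest.fixture(scope="session")
def interaction_model(interaction_pairs):
    return rel.train_model(interaction_pairs, kind="interaction", seed=SEED)


@pytest.fixture(scope="session")
def direction_model(direction_pairs):
    return rel.train_model(direction_pairs, kind="direction", seed=SEED)


@pytest.fixture(scope="session")
def pipeline_config(bundle, interaction_model, direction_model):
    from pinminer.network import FilterSpec
    from pinminer.pipeline import PipelineConfig
    from pinminer.query_builder import ExpandedTermSet

    def make(**overrides):
        kwargs = dict(
            dictionary=bundle.dictionary,
            lexicon=bundle.lexicon,
            catalog=bundle.catalog,
            species_index=bundle.species_index,
            interaction_model=interaction_model,
            direction_model=direction_model,
            context_expansions=[ExpandedTermSet.identity("asthma")],
            filter_spec=FilterSpec(min_probability=0.5,
                                   context_granularity="document"),
            seed=SEED,
        )
        kwargs.update(overrides)
        return PipelineConfig(**kwargs)

    return make


@pytest.fixture()
def disease_obo(tmp_path):
    path = tmp_path / "disease.obo"
    path.write_text(fx._DISEASE_OBO, encoding="utf-8")
    return path
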