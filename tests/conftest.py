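import random

import pytest

from rehab_extract.ontology import load_ontology
from rehab_extract.preprocess import Section
from rehab_extract.rule_extractor import RuleSet, extract
from rehab_extract.standoff import from_extraction
from rehab_extract.synthetic_notes import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


@pytest.fixture(scope="session")
def ruleset(ontology):
    return RuleSet.from_ontology(ontology)


@pytest.fixture(scope="session")
def small_corpus(ontology):
    """20 gold sections under the default generation conditions."""
    return generate_corpus(20, GeneratorConfig(), rng_seed=101, ontology=ontology)


@pytest.fixture(scope="session")
def train_sequences(small_corpus):
    """(text, labels) pairs extracted from the small gold corpus."""
    return [
        (sec.text[slice(*seq.span)], seq.labels)
        for sec in small_corpus
        for seq in sec.sequences
    ]


def run_rules_on(gold_sections, ontology, rules):
    """Rule-extract predictions for gold sections, as standoff."""
    preds = []
    for g in gold_sections:
        sec = Section(
            source_filename=g.section_id,
            text=g.text,
            char_span=(0, len(g.text)),
            section_id=g.section_id,
        )
        preds.append(from_extraction(sec, extract(sec, ontology, rules)))
    return preds


@pytest.fixture(scope="session")
def rng():
    return random.Random(2024)
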