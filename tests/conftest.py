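import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from orannot.core import AnnotatorConfig
from orannot.io_formats import parse_exonerate
from orannot.pipeline import annotate
from orannot.simulate import SimulationConfig, emit_alignments, generate_genome


@pytest.fixture(scope="session")
def clean_bundle():
    """Default study conditions: 5 scaffolds x 4 genes, exact self
    alignments plus decoys, no fragmentation, no pseudogenes."""
    config = SimulationConfig(seed=42)
    ledger = generate_genome(config)
    text = emit_alignments(ledger, config)
    hits = parse_exonerate(text)
    return config, ledger, text, hits


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    _, ledger, _, hits = clean_bundle
    return ledger, annotate(hits, ledger.genome, ledger.queries, AnnotatorConfig())
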