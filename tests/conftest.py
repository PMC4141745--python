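from pathlib import Path

import pytest

from oquare import OntologyGraph, QualityModelConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def chain3_path() -> Path:
    return DATA_DIR / "chain3.owl"


@pytest.fixture()
def chain_graph() -> OntologyGraph:
    """Classes A, B, C with B⊑A, C⊑B and nothing else."""
    return OntologyGraph(classes=frozenset("ABC"), subclass_edges=(("B", "A"), ("C", "B")))


@pytest.fixture()
def diamond_graph() -> OntologyGraph:
    """B⊑A, C⊑A, D⊑B, D⊑C: two distinct root-to-leaf paths to D."""
    return OntologyGraph(
        classes=frozenset("ABCD"),
        subclass_edges=(("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")),
    )


@pytest.fixture(scope="session")
def default_config() -> QualityModelConfig:
    return QualityModelConfig.default()
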