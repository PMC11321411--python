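import pytest

from gnotofunc.annotation_io import (
    Alternative,
    ConsortiumSpec,
    GenomeAnnotation,
    ModuleDefinition,
    Step,
)
from gnotofunc.config import AnalysisConfig


def make_module(module_id, step_specs, category=""):
    """Build a module from [[{'K1'}, {'K2','K3'}], ...]: one inner list per
    step, one required-KO set per alternative."""
    steps = tuple(
        Step(tuple(Alternative(frozenset(alt)) for alt in alts))
        for alts in step_specs
    )
    return ModuleDefinition(module_id=module_id, name=module_id,
                            steps=steps, category=category)


def make_genome(genome_id, kos, taxonomy=None, counts=None):
    ko_counts = dict(counts) if counts else {k: 1 for k in kos}
    return GenomeAnnotation(genome_id=genome_id,
                            taxonomy=dict(taxonomy or {}),
                            ko_counts=ko_counts)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def four_step_module():
    # steps: {K1}, {K2 or K3}, {K4+K5 complex}, {K6}
    return make_module(
        "M4", [[{"K00001"}], [{"K00002"}, {"K00003"}],
               [{"K00004", "K00005"}], [{"K00006"}]]
    )


@pytest.fixture
def toy_consortium():
    return ConsortiumSpec(
        "toy",
        [
            make_genome("g1", {"K00001", "K00002"}),
            make_genome("g2", {"K00002", "K00003"}),
        ],
    )
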