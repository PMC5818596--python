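import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from toxpod.model import assemble_table
from toxpod.study import StudyRecord, effect_table, filter_studies
from toxpod.synthetic import BlockSpec, GeneratorConfig, generate_descriptors, generate_registry

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_generator_config(seed: int = 7) -> GeneratorConfig:
    """A down-scaled registry (120 chemicals, ~405 studies) for fast tests."""
    cfg = GeneratorConfig(
        seed=seed,
        n_chemicals=120,
        studies_per_source={"TOXREF": 330, "HESS": 50, "COSMOS": 25},
    )
    cfg.descriptor_block_specs["toxcast"] = BlockSpec(
        300, 0.15, kind="bioactivity", availability=0.5
    )
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_registry(small_config):
    return generate_registry(small_config)


@pytest.fixture(scope="session")
def small_effects(small_registry):
    records, _ = small_registry
    return effect_table(filter_studies(records))


@pytest.fixture(scope="session")
def small_blocks(small_config, small_registry):
    _, truth = small_registry
    return generate_descriptors(sorted(truth), truth, small_config)


@pytest.fixture(scope="session")
def baseline_table(small_effects):
    return assemble_table(small_effects, "baseline")


def make_record(
    study_id="S1",
    doses=(10.0, 100.0, 1000.0),
    effects=(False, False, False),
    unit="mg/kg/day",
    **kwargs,
):
    defaults = dict(
        chemical_id="C1",
        source="TOXREF",
        study_type="CHR",
        species="rat",
        strain_group="sprague_dawley",
        admin_method="gavage",
    )
    defaults.update(kwargs)
    return StudyRecord(
        study_id=study_id,
        dose_levels=[(d, unit) for d in doses],
        effects=list(effects),
        **defaults,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
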