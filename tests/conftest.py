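import pytest

from c9meth import PipelineConfig, SimulationConfig, run_pipeline, simulate_cohort

#: Seed of the default study cohort used by the cohort-level tests.
DEFAULT_SEED = 11


def small_config(seed: int = 5, **overrides) -> SimulationConfig:
    """A fast, structurally simple cohort for unit tests."""
    base = dict(
        seed=seed,
        n_individuals=5,
        reads_per_allele_range=(3, 5),
        include_cerebellum=False,
        include_longitudinal=False,
        include_pedigrees=False,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic cohort (27 individuals, all structure)."""
    return simulate_cohort(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default cohort; reused across tests."""
    out = tmp_path_factory.mktemp("default_run")
    manifest = run_pipeline(PipelineConfig(seed=DEFAULT_SEED, output_dir=str(out)))
    return out, manifest


@pytest.fixture()
def small_cohort():
    return simulate_cohort(small_config())
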