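import numpy as np
import pytest
from hypothesis import settings

from inosite import pipeline, synthetic
from inosite.cli import write_scenario_config

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """The default synthetic study condition, written to disk once."""
    outdir = tmp_path_factory.mktemp("scenario")
    spec = synthetic.ScenarioSpec(seed=1)
    scenario = synthetic.generate_scenario(spec, outdir)
    write_scenario_config(scenario, outdir / "config.ini")
    return scenario


@pytest.fixture(scope="session")
def default_run(default_scenario):
    """One full pipeline run on the default scenario."""
    config = pipeline.PipelineConfig.from_ini(
        default_scenario.files["genes_fasta"].parent / "config.ini"
    )
    return config, pipeline.run_pipeline(config)


@pytest.fixture(scope="session")
def default_rerun(default_run, tmp_path_factory):
    """A second, independent run of the same configuration."""
    import dataclasses

    config, _ = default_run
    outdir = tmp_path_factory.mktemp("rerun")
    cfg = dataclasses.replace(config, output_dir=str(outdir))
    return cfg, pipeline.run_pipeline(cfg)
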