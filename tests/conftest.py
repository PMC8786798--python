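import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic family bundle (wheat-scale: 32 homeolog
    groups, six duplicate pairs, five decoys) run once per session."""
    from tlpfam.pipeline import PipelineConfig, run_pipeline
    from tlpfam.synthetic import simulate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    family, planted, xtruth = simulate_bundle(outdir, seed=1)
    config = PipelineConfig.from_yaml(outdir / "config.yaml")
    report = run_pipeline(config)
    return {
        "dir": outdir,
        "family": family,
        "planted": planted,
        "expression_truth": xtruth,
        "report": report,
        "results": outdir / "results",
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
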