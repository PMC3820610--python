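import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lipidframe.database import default_database
from lipidframe.pipeline import RunConfig, run_pipeline
from lipidframe.simulate import default_study_design, simulate_study


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture(scope="session")
def study_noise_free(tmp_path_factory):
    """The full default synthetic study with the noise CV set to zero
    (deterministic variant): 14 samples x 2 replicates x 2 polarities,
    2 multiplexed ranges each."""
    design = default_study_design(noise_cv=0.0)
    out = tmp_path_factory.mktemp("study_nf")
    result = simulate_study(design, out, seed=11)
    return design, result


@pytest.fixture(scope="session")
def pipeline_noise_free(study_noise_free, tmp_path_factory):
    """Full pipeline run (auto lock-mass adjustment) over the noise-free study."""
    import pandas as pd

    design, result = study_noise_free
    out = tmp_path_factory.mktemp("pipeline_nf")
    config = RunConfig(
        peaklist_dir=result.peaklist_dir,
        out_dir=out,
        sample_info=result.peaklist_dir.parent / "sample_info.tsv",
    )
    manifest = run_pipeline(config)
    return {
        "design": design,
        "study": result,
        "out": out,
        "manifest": manifest,
        "quant": pd.read_csv(out / "quantified.csv"),
        "qc": pd.read_csv(out / "lockmass_qc.csv"),
        "offsets": pd.read_csv(out / "lockmass_offsets.csv"),
    }
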