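import pytest

from mycogene.config import RunConfig
from mycogene.pipeline import run_pipeline_objects
from mycogene.synthetic import SynthParams, generate


def clean_params(n_genes: int = 200, seed: int = 1) -> SynthParams:
    """Corruption-free study conditions: every gene expressed, every
    transcript complete and unmerged."""
    return SynthParams(
        seed=seed, n_genes=n_genes,
        frac_expressed=1.0, frac_truncated5=0.0, frac_merged_same=0.0,
        frac_merged_sas=0.0, frac_fp_intron=0.0,
    )


@pytest.fixture(scope="session")
def clean_truth():
    """200-gene corruption-free fixture (seed 1)."""
    return generate(clean_params())


@pytest.fixture(scope="session")
def clean_run(clean_truth):
    cfg = RunConfig(seed=1, verbosity=0)
    return run_pipeline_objects(clean_truth.genome, clean_truth.transcripts, cfg)


@pytest.fixture(scope="session")
def mixed_truth():
    """120-gene fixture with the default corruption mix (truncated,
    merged, unexpressed transcripts present)."""
    return generate(SynthParams(seed=2, n_genes=120))


@pytest.fixture(scope="session")
def mixed_run(mixed_truth):
    cfg = RunConfig(seed=2, verbosity=0)
    return run_pipeline_objects(mixed_truth.genome, mixed_truth.transcripts, cfg)


@pytest.fixture(scope="session")
def small_truth():
    """Small fixture with the default corruption mix, for cheap tests."""
    return generate(SynthParams(seed=7, n_genes=40))


@pytest.fixture()
def cfg():
    return RunConfig(seed=1, verbosity=0)
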