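import numpy as np
import pytest

from cobindscan.pipeline import PipelineConfig, run_pipeline
from cobindscan.simulate import SimConfig, SimTruth, generate


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One synthetic dataset at the default study conditions, with truth."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(seed=5)
    paths = generate(cfg, out)
    return cfg, paths, SimTruth.from_json(paths["truth"])


@pytest.fixture(scope="session")
def pipeline_report(sim_dataset, tmp_path_factory):
    """Full pipeline run on the session dataset."""
    _, paths, _ = sim_dataset
    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(
        genome_fasta=str(paths["genome_fasta"]),
        chrom_sizes=str(paths["chrom_sizes"]),
        peaks_a=str(paths["peaks_a"]),
        peaks_b=str(paths["peaks_b"]),
        annotation=str(paths["annotation"]),
        de_table=str(paths["de_table"]),
        categories=str(paths["categories"]),
        pwm_file=str(paths["pwms"]),
        out_dir=str(out),
        n_perm=2000,
        seed=7,
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
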