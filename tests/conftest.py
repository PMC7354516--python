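import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")

from phagesub.simulate import SimConfig, simulate_all  # noqa: E402
from phagesub.pipeline import PipelineConfig, run_all  # noqa: E402


MICRO_KW = dict(host_length=40_000, n_host_genes=30, phage_length=6_000,
                n_phage_genes=24, library_size=600)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture(scope="session")
def micro_sim():
    """Noisy desk-micro infection dataset (full 25-sample design, in memory)."""
    cfg = SimConfig(seed=11, **MICRO_KW)
    truth, abund, samples, pairs = simulate_all(cfg)
    return cfg, truth, abund, samples, pairs


@pytest.fixture(scope="session")
def errorfree_sim():
    """Error-free, junk-free dataset for oracle-equivalence tests."""
    cfg = SimConfig(seed=23, host_length=30_000, n_host_genes=20,
                    phage_length=5_000, n_phage_genes=16, library_size=300,
                    error_rate=0.0, junk_fraction=0.0)
    truth, abund, samples, pairs = simulate_all(cfg)
    return cfg, truth, abund, samples, pairs


@pytest.fixture(scope="session")
def micro_pipeline(tmp_path_factory):
    """Micro dataset written to disk and pushed through the whole pipeline."""
    root = tmp_path_factory.mktemp("micro_run")
    cfg = SimConfig(seed=11, **MICRO_KW)
    truth, abund, samples, pairs = simulate_all(cfg, root / "sim")
    pc = PipelineConfig(outdir=str(root / "out"),
                        host_fasta=str(root / "sim" / "host.fasta"),
                        host_gff=str(root / "sim" / "host_genes.gff3"),
                        sample_sheet=str(root / "sim" / "samples.tsv"))
    report = run_all(pc)
    return {"root": root, "config": cfg, "truth": truth, "abund": abund,
            "samples": samples, "pairs": pairs, "pipeline_config": pc,
            "report": report}
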