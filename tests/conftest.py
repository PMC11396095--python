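import pytest

from mitocms.config import PipelineConfig
from mitocms.pipeline import run_full
from mitocms.simulate import SimConfig, build_pair


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default 100-kb synthetic pair (fixed seed)."""
    return run_full(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def default_pair(default_run):
    return default_run.pair


def bare_sim_config(**kwargs) -> SimConfig:
    """A SimConfig with every plan emptied; tests switch on what they need."""
    base = dict(
        n_snps=0,
        n_ncrna_snps=0,
        n_small_indels=0,
        sv_plan=[],
        repeat_plan=[],
        snp_cds_plan={},
        chimera_plan=None,
        tm_orf_plan=None,
        extra_unique_orf_aa=[],
        seed=5,
    )
    base.update(kwargs)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def plain_pair():
    """Maintainer + byte-identical sterile (no edits planted)."""
    return build_pair(bare_sim_config())
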