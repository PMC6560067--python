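import dataclasses

import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from rnam5c.pipeline import default_demo_config, run_pipeline
from rnam5c.simulate import demo_reference, single_site_reference


@pytest.fixture(scope="session")
def demo_ref():
    return demo_reference()


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One scaled-down end-to-end pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("demo_run")
    cfg = default_demo_config(outdir, seed=11)
    cfg.simulation = dataclasses.replace(cfg.simulation, mean_coverage=60)
    result = run_pipeline(cfg)
    return cfg, result


def make_single_site_reference(seed=3, tx_len=44, site_offset=22, contig_pad=40,
                               **kw):
    return single_site_reference(seed, tx_len, site_offset, contig_pad, **kw)
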