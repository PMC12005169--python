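"""Shared fixtures: small simulated clades and one full pipeline run."""

from __future__ import annotations

import pytest

from wgdkit import PipelineConfig, SimConfig, run_pipeline, simulate_clade


@pytest.fixture(scope="session")
def sim_default():
    """Default shared-WGD clade: WGD 7.4 My, unbiased 20% fractionation."""
    return simulate_clade(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_biased():
    """Clade with strongly biased fractionation (90% of losses on B)."""
    return simulate_clade(SimConfig(n_genes=300, loss_prob=0.3,
                                    loss_bias=0.9, seed=2))


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """One end-to-end pipeline run on the default scenario."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(sim=SimConfig(seed=3), seed=3)
    report = run_pipeline(cfg, outdir)
    return report, outdir
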