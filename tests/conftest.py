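"""Shared fixtures: synthetic artifacts at the default study conditions."""

import pytest

import cnvindex as cx


@pytest.fixture(scope="session")
def default_cfg():
    return cx.SimConfig(seed=1)


@pytest.fixture(scope="session")
def artifacts(default_cfg):
    """Full synthetic dataset at default conditions, seed 1."""
    return cx.generate_all(default_cfg)


@pytest.fixture(scope="session")
def proteome_5x50():
    """The 250-gene proteome with five planted 50-gene modules, seed 1."""
    cfg = cx.SimConfig(seed=1, n_genes=250, n_planted=50)
    return cx.generate_all(cfg)["proteome"]


@pytest.fixture(scope="session")
def pipeline_result(default_cfg):
    """One full pipeline run at default synthetic conditions, seed 1."""
    cfg = cx.PipelineConfig(sim=default_cfg)
    return cx.run_pipeline(cfg)
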