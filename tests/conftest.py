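"""Shared fixtures: one full 12-taxon synthetic bundle (generated once
per session) plus the pipeline results computed on it."""

from __future__ import annotations

import numpy as np
import pytest

from snoleca.pipeline import PipelineConfig, run_stages
from snoleca.simulate import SimulationParams, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default study conditions: 2 supergroups × 6 taxa, 50 ancestral
    families, branch loss probability 0.15, 5 mobility events."""
    return simulate_bundle(SimulationParams(seed=101))


@pytest.fixture(scope="session")
def pipeline_results(bundle):
    cfg = PipelineConfig(input_dir=".", out_dir="scratch/test_out", seed=101)
    return run_stages(bundle.inputs, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def quad_tree():
    """The four-leaf reference tree ((A,B),(C,D))."""
    from snoleca.phylo import Phylogeny

    #       0
    #     1   4
    #    2 3 5 6
    return Phylogeny([-1, 0, 1, 1, 0, 4, 4], [None, None, "A", "B", None, "C", "D"])


@pytest.fixture()
def tree4():
    return quad_tree()
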