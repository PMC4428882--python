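"""Shared fixtures: one default simulated study, processed through the
geometric pipeline stages once per session."""

import numpy as np
import pytest

import wingmorph.procrustes as pro
import wingmorph.synthetic as syn


@pytest.fixture(scope="session")
def default_dataset():
    return syn.simulate_dataset(syn.default_config(seed=11))


@pytest.fixture(scope="session")
def aligned(default_dataset):
    return pro.gpa([c.coords for c in default_dataset.configurations],
                   provenance=default_dataset.specimen_table)


@pytest.fixture(scope="session")
def tangent(aligned):
    return pro.project_tangent(aligned)


@pytest.fixture(scope="session")
def shape_dataset(aligned, tangent):
    return pro.average_replicates(tangent, aligned)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
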