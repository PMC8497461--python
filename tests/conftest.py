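"""Shared fixtures: one small simulated genome, mined and classified once.

Session scope keeps the expensive steps (mining the ~630 kb genome,
classifying 36 elements) to a single run shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from ltrkit import (
    SimConfig,
    classify_catalog,
    generate_genome,
    mine_genome,
)
from ltrkit.family import default_family


@pytest.fixture(scope="session")
def family():
    return default_family()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1, chrom_length=200_000, n_chroms=2)


@pytest.fixture(scope="session")
def sim_genome(sim_config, family):
    """(genome, truth, genes) for the shared simulated genome."""
    return generate_genome(sim_config, family)


@pytest.fixture(scope="session")
def mined_elements(sim_genome, family):
    genome, _truth, _genes = sim_genome
    return mine_genome(genome, family.ltr_seq)


@pytest.fixture(scope="session")
def classified_elements(mined_elements, family):
    return classify_catalog(list(mined_elements), family)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def match_truth(element, truth, tol: int = 5):
    """Find the planted truth record matching a mined element, if any."""
    for t in truth:
        if (t.chrom == element.chrom
                and abs(t.start - element.start) <= tol
                and abs(t.end - element.end) <= tol):
            return t
    return None
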