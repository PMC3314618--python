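"""Shared fixtures: synthetic reads, loci, and small simulated libraries."""

from __future__ import annotations

import numpy as np
import pytest

from amphap454.io_formats import LocusDef, Read


def make_read(bases: str, q: int | list = 35, read_id: str = "r1", **kw) -> Read:
    quals = tuple([q] * len(bases)) if isinstance(q, int) else tuple(q)
    return Read(read_id, bases, quals, **kw)


@pytest.fixture
def toy_locus() -> LocusDef:
    return LocusDef("LOC1", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA", 400, 600)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120328)


@pytest.fixture
def tiny_sim_config():
    from amphap454.sim454 import SimConfig

    return SimConfig(
        seed=7,
        n_individuals=3,
        n_loci=2,
        n_species=2,
        mean_coverage=25,
        short_read_fraction=0.02,
    )
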