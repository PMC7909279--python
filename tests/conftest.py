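"""Shared fixtures: small synthetic databases and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

import mitophase as mp


@pytest.fixture(scope="session")
def small_suite():
    """A compact synthetic study (6 haplotypes, ~30 sites) for engine tests."""
    cfg = mp.SynDBConfig(
        n_haplogroups=3, samples_per_group=2, lambda_branch=5.0,
        lambda_private=2.0, seed=11,
    )
    return mp.make_fixture_suite(cfg, ratios=((4, 1), (2, 1), (50, 1)), n_sources=4)


@pytest.fixture(scope="session")
def default_suite():
    """The full-size study layout (32 haplotypes, 270 mixtures), no MCMC."""
    return mp.make_fixture_suite()


def toy_haplotypes(vectors, ids=None):
    ids = ids or [f"S{i}" for i in range(len(vectors))]
    return [mp.Haplotype(s, np.array(v, dtype=np.int8)) for s, v in zip(ids, vectors)]


def toy_loci(n):
    return [mp.SiteLocus(100 + 4 * j, "A", "G") for j in range(n)]
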