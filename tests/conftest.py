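from __future__ import annotations

import pytest

from syntenic import SimParams, derive_genome, make_ancestor


@pytest.fixture(scope="session")
def sim_pair():
    """A 2x200-gene ancestor and a derived genome with the default event mix."""
    params = SimParams(seed=42)
    ancestor = make_ancestor(params)
    derived, log = derive_genome(ancestor, params, "derived1")
    return params, ancestor, derived, log


@pytest.fixture(scope="session")
def small_ancestor():
    """A compact single-chromosome ancestor for alignment-scale tests."""
    params = SimParams(
        n_chromosomes=1,
        genes_per_chromosome=60,
        orphan_rate=0.05,
        n_inversions=0,
        n_deletions=0,
        n_tandem_dups=0,
        n_translocations=0,
        seed=7,
    )
    return params, make_ancestor(params)
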