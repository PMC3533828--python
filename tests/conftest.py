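"""Shared fixtures: synthetic gene-set instances and cached design runs."""

from __future__ import annotations

import pytest

import polysirna as ps

#: Seeds of the desk-scale instance batch shared by the heavier checks.
BATCH_SEEDS = tuple(range(1, 21))


@pytest.fixture(scope="session")
def small_pair():
    """One small instance (5 candidates, 2 two-member families)."""
    spec = ps.FixtureSpec(
        n_candidates=5,
        n_excluded=3,
        gene_len=60,
        n_families=2,
        family_size=2,
        planted_mismatches=2,
        decoy_families=0,
        seed=7,
    )
    pair, truth = ps.generate(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def default_run():
    """One desk-scale instance with its full design run."""
    spec = ps.FixtureSpec(seed=11)
    pair, truth = ps.generate(spec)
    result = ps.run_design(pair, spec.params)
    return spec, pair, truth, result


@pytest.fixture(scope="session")
def fixture_batch():
    """Twenty seeded desk-scale instances with design runs and oracles."""
    batch = []
    for seed in BATCH_SEEDS:
        spec = ps.FixtureSpec(seed=seed)
        pair, truth = ps.generate(spec)
        result = ps.run_design(pair, spec.params)
        oracle = ps.oracle_qualified(pair, spec.params)
        batch.append((spec, pair, truth, result, oracle))
    return batch
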