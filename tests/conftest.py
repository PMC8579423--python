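"""Shared fixtures: small simulated worlds reused across test modules."""

from __future__ import annotations

import pytest

from dormantlink.idprep import canonicalise_census, canonicalise_contacts
from dormantlink.linkage import (
    MatchWeights,
    generate_candidates,
    score_candidates,
    select_best_links,
)
from dormantlink.namebank import build_postcode_lookup
from dormantlink.synthcohort import ErrorModel, generate_world

WORLD_SEED = 7
WORLD_POPULATION = 4000


@pytest.fixture(scope="session")
def lookup():
    return build_postcode_lookup()


@pytest.fixture(scope="session")
def small_world():
    """Default-error world with all seven trials (cohort, register, truth)."""
    return generate_world(seed=WORLD_SEED, population_size=WORLD_POPULATION)


@pytest.fixture(scope="session")
def zero_world():
    """Zero-corruption world: identifiers agree exactly across sources."""
    return generate_world(
        seed=WORLD_SEED, population_size=WORLD_POPULATION, error_model=ErrorModel.zero()
    )


def link_world(world, error_model=None, threshold=0.0):
    """Canonicalise, generate candidates, score, and select links."""
    cohort, register, truth = world
    trial_canon = canonicalise_contacts(cohort.contacts, register.lookup)
    census_canon = canonicalise_census(register.census, register.lookup)
    candidates = generate_candidates(trial_canon, census_canon, register.lookup)
    scored = score_candidates(candidates, MatchWeights.from_error_model(error_model))
    decisions = select_best_links(scored, cohort.participants, threshold=threshold)
    return scored, decisions


@pytest.fixture(scope="session")
def small_world_links(small_world):
    return link_world(small_world)


@pytest.fixture(scope="session")
def zero_world_links(zero_world):
    return link_world(zero_world, error_model=ErrorModel.zero())
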