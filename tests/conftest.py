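"""Shared fixtures: hand-built micro networks and the quickstart pool."""

from __future__ import annotations

import warnings

import pytest

from butyrnet import (
    Medium,
    MetabolicNetwork,
    Reaction,
    UniverseSpec,
    build_pair_records,
    build_universe,
    make_medium,
    make_universe,
    rank_descriptors,
    sample_pool,
    simulate_training_labels,
    train_interaction_classifier,
)

# silence the intentional "no butyrate exchange" warnings raised while
# simulating non-producer diagnostic communities
pytestmark = pytest.mark.filterwarnings("ignore:no member")


def make_producer(organism_id: str = "prod", carbon: str = "c2_e",
                  need_ac: float = 1.0) -> MetabolicNetwork:
    """Minimal hand-built producer: catabolism 1 carbon -> 1 precursor +
    1 acetate, butyrate synthesis ``need_ac`` acetate + 1 precursor -> 1
    butyrate (1:1:1 by default; need_ac=2 makes the producer
    acetate-limited, so partner acetate pays off)."""
    return MetabolicNetwork(
        organism_id=organism_id,
        reactions=(
            Reaction(f"EX_{carbon}", {carbon: -1}, is_exchange=True),
            Reaction("EX_ac_e", {"ac_e": -1}, is_exchange=True),
            Reaction("EX_but_e", {"but_e": -1}, is_exchange=True),
            Reaction("CAT", {carbon: -1, "prec_c": 1, "ac_e": 1}, 0.0),
            Reaction("BUTS", {"ac_e": -need_ac, "prec_c": -1, "but_e": 1}, 0.0),
            Reaction("BIOMASS", {"prec_c": -1}, 0.0),
        ),
        biomass_reaction_id="BIOMASS",
        butyrate_exchange_id="EX_but_e",
    )


def make_feeder(organism_id: str = "feed", carbon: str = "c1_e") -> MetabolicNetwork:
    """Minimal feeder: ferments its own carbon and secretes acetate."""
    return MetabolicNetwork(
        organism_id=organism_id,
        reactions=(
            Reaction(f"EX_{carbon}", {carbon: -1}, is_exchange=True),
            Reaction("EX_ac_e", {"ac_e": -1}, is_exchange=True),
            Reaction("CAT_F", {carbon: -1, "prec_c": 1, "ac_e": 1}, 0.0),
            Reaction("BIOMASS", {"prec_c": -1}, 0.0),
        ),
        biomass_reaction_id="BIOMASS",
    )


@pytest.fixture()
def producer() -> MetabolicNetwork:
    return make_producer()


@pytest.fixture()
def feeder() -> MetabolicNetwork:
    return make_feeder()


@pytest.fixture()
def rich_medium() -> Medium:
    return Medium(uptake_caps={"c1_e": 10.0, "c2_e": 10.0, "min_e": 10.0})


@pytest.fixture(scope="session")
def quickstart():
    """The package's reference study conditions, built once per session.

    19 organisms (6 butyrate producers) sampled from the default 27-reaction
    universe, all 776 consortia of sizes 2-3 simulated, all 171 pairs
    labelled, classifier and 25-descriptor selection trained at seed 1.
    """
    seed = 1
    universe = make_universe(UniverseSpec(seed=seed))
    medium = make_medium(universe, richness=1.0, seed=seed)
    pool, manifest = sample_pool(
        universe, n_organisms=19, n_producers=6, seed=seed, medium=medium
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = simulate_training_labels(
            pool, manifest, medium, sizes=(2, 3)
        )
    universe_ids = build_universe(pool)
    records = build_pair_records(pool, medium, universe_ids)
    classifier = train_interaction_classifier(records, universe_ids, seed=seed)
    selection = rank_descriptors(records, universe_ids, seed=seed, k=25)
    return {
        "seed": seed,
        "universe": universe,
        "medium": medium,
        "pool": pool,
        "manifest": manifest,
        "labels": labels,
        "universe_ids": universe_ids,
        "records": records,
        "classifier": classifier,
        "selection": selection,
    }
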