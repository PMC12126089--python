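"""Community construction and the staged flux-balance optimisation."""

import numpy as np
import pytest

from butyrnet import (
    ConsortiumSpec,
    Medium,
    MetabolicNetwork,
    Reaction,
    build_community,
    simulate,
    simulate_training_labels,
)
from butyrnet.community import single_member_growth
from butyrnet.synthpool import UniverseSpec, make_medium, make_universe, sample_pool

from .conftest import make_feeder, make_producer
from .lp_oracle import two_stage_optimum

pytestmark = pytest.mark.filterwarnings("ignore:no member")


class TestConsortiumSpec:
    def test_of_sorts_members(self):
        assert ConsortiumSpec.of(["b", "a"]).members == ("a", "b")

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ConsortiumSpec.of(["a", "a"])

    def test_size_cap(self):
        with pytest.raises(ValueError, match="1..13"):
            ConsortiumSpec.of([f"o{i:02d}" for i in range(14)])


class TestBuildCommunity:
    def test_variable_count_is_reactions_plus_medium(self, producer, feeder,
                                                     rich_medium):
        spec = ConsortiumSpec.of(["prod", "feed"])
        model = build_community([producer, feeder], spec, rich_medium)
        # shared medium metabolites: c1_e, c2_e, ac_e, but_e
        assert model.n_variables == 6 + 4 + 4

    def test_missing_member_raises(self, producer, rich_medium):
        with pytest.raises(KeyError, match="ghost"):
            build_community([producer], ConsortiumSpec.of(["ghost", "prod"]),
                            rich_medium)

    def test_warns_without_butyrate_exchange(self, feeder, rich_medium):
        with pytest.warns(UserWarning, match="butyrate will be zero"):
            build_community([feeder], ConsortiumSpec.of(["feed"]), rich_medium)

    def test_uniform_abundances(self, producer, feeder, rich_medium):
        model = build_community(
            [producer, feeder], ConsortiumSpec.of(["prod", "feed"]), rich_medium
        )
        assert np.allclose(model.abundances, 0.5)


class TestSimulate:
    def test_single_member_community_matches_own_fba(self, producer, rich_medium):
        model = build_community([producer], ConsortiumSpec.of(["prod"]),
                                rich_medium)
        result = simulate(model, tradeoff=0.5)
        assert result.optimal
        assert result.growth_optimum == pytest.approx(
            single_member_growth(producer, rich_medium), abs=1e-8
        )

    def test_zero_carbon_medium_yields_nothing(self, producer):
        empty = Medium(uptake_caps={})
        model = build_community([producer], ConsortiumSpec.of(["prod"]), empty)
        result = simulate(model)
        assert result.optimal
        assert result.growth_optimum == pytest.approx(0.0, abs=1e-9)
        assert result.butyrate_flux == pytest.approx(0.0, abs=1e-9)

    def test_minimal_producer_matches_vertex_enumeration(self, producer,
                                                         rich_medium):
        """The 1:1:1 producer at a low growth demand: staged optima equal the
        brute-force enumeration of basic feasible solutions."""
        model = build_community([producer], ConsortiumSpec.of(["prod"]),
                                rich_medium)
        for tradeoff in (1e-6, 0.5, 1.0):
            result = simulate(model, tradeoff=tradeoff)
            g_oracle, b_oracle = two_stage_optimum(model, tradeoff)
            assert result.growth_optimum == pytest.approx(g_oracle, abs=1e-6)
            assert result.butyrate_flux == pytest.approx(b_oracle, abs=1e-6)

    def test_feeder_strictly_increases_butyrate(self, producer, feeder,
                                                rich_medium):
        alone = simulate(
            build_community([producer], ConsortiumSpec.of(["prod"]), rich_medium)
        )
        pair = simulate(
            build_community([producer, feeder],
                            ConsortiumSpec.of(["feed", "prod"]), rich_medium)
        )
        assert pair.butyrate_flux > alone.butyrate_flux + 1e-6

    def test_growth_identity_and_mass_balance(self, producer, feeder,
                                              rich_medium):
        model = build_community([producer, feeder],
                                ConsortiumSpec.of(["feed", "prod"]), rich_medium)
        result = simulate(model)
        weighted = sum(
            a * result.member_growth[m]
            for a, m in zip(model.abundances, model.members)
        )
        assert result.community_growth == pytest.approx(weighted, abs=1e-6)
        v = np.array([result.fluxes[key] for key in model.variables])
        assert np.abs(model.A_eq @ v).max() < 1e-6
        lo = np.array([b[0] for b in model.bounds])
        hi = np.array([b[1] for b in model.bounds])
        assert np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9)

    def test_tradeoff_monotonicity(self, producer, feeder, rich_medium):
        model = build_community([producer, feeder],
                                ConsortiumSpec.of(["feed", "prod"]), rich_medium)
        fluxes = [
            simulate(model, tradeoff=t).butyrate_flux
            for t in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(fluxes, fluxes[1:]))

    def test_medium_monotonicity(self, producer, feeder):
        base = {"c1_e": 4.0, "c2_e": 4.0, "min_e": 10.0}
        fluxes = []
        growths = []
        for bump in (0.0, 2.0, 6.0):
            medium = Medium(uptake_caps={**base, "c1_e": base["c1_e"] + bump})
            model = build_community([producer, feeder],
                                    ConsortiumSpec.of(["feed", "prod"]), medium)
            result = simulate(model)
            growths.append(result.growth_optimum)
            fluxes.append(result.butyrate_flux)
        assert growths == sorted(growths)
        assert fluxes == sorted(fluxes)

    def test_infeasible_maintenance_reported_not_zero(self, rich_medium):
        # positive forced biomass with no carbon access is infeasible
        starved = MetabolicNetwork(
            organism_id="stuck",
            reactions=(
                Reaction("EX_x_e", {"x_e": -1}, is_exchange=True),
                Reaction("BIOMASS", {"x_e": -1}, 1.0, 10.0),
            ),
            biomass_reaction_id="BIOMASS",
        )
        model = build_community([starved], ConsortiumSpec.of(["stuck"]),
                                rich_medium)
        result = simulate(model)
        assert result.status == "infeasible"
        assert np.isnan(result.butyrate_flux)

    def test_non_producer_pair_exports_no_butyrate(self, feeder, rich_medium):
        other = make_feeder("feed2", carbon="c2_e")
        model = build_community([feeder, other],
                                ConsortiumSpec.of(["feed", "feed2"]), rich_medium)
        result = simulate(model)
        assert result.optimal
        assert result.butyrate_flux == 0.0


class TestTrainingLabels:
    @pytest.fixture(scope="class")
    def toy_pool(self):
        universe = make_universe(UniverseSpec(seed=3))
        medium = make_medium(universe, richness=1.0, seed=3)
        pool, manifest = sample_pool(universe, 4, 2, seed=3, medium=medium)
        return pool, manifest, medium

    def test_pair_count_excludes_producer_free_subsets(self, toy_pool):
        pool, manifest, medium = toy_pool
        labels = simulate_training_labels(pool, manifest, medium, sizes=(2,))
        assert len(labels) == 5  # C(4,2) - C(2,2)

    def test_size_additivity_and_sorting(self, toy_pool):
        pool, manifest, medium = toy_pool
        both = simulate_training_labels(pool, manifest, medium, sizes=(2, 3))
        per_size = both.groupby("size").size()
        assert per_size[2] == 5 and per_size[3] == 4  # C(4,3) - C(2,3)=0 -> 4
        assert both.equals(
            both.sort_values(["size", "members"], ignore_index=True)
        )

    def test_non_producer_only_rows_never_appear(self, toy_pool):
        pool, manifest, medium = toy_pool
        labels = simulate_training_labels(pool, manifest, medium, sizes=(2, 3))
        producers = set(manifest.producers)
        for members in labels["members"]:
            assert producers.intersection(members.split(";"))

    def test_empty_enumeration_is_error(self, toy_pool):
        pool, manifest, medium = toy_pool
        with pytest.raises(ValueError, match="no consortia"):
            simulate_training_labels(pool, manifest, medium, sizes=(13,))
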