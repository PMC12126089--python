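"""Network/medium data model, JSON and SBML I/O, presence encoding."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from butyrnet import (
    MetabolicNetwork,
    Reaction,
    build_universe,
    load_medium,
    load_network,
    presence_vector,
    write_medium,
    write_network,
)
from butyrnet.netmodel import Medium, NetworkValidationError


def minimal_network(org="org_a"):
    return MetabolicNetwork(
        organism_id=org,
        reactions=(
            Reaction("EX_c1_e", {"c1_e": -1}, is_exchange=True),
            Reaction("BIOMASS", {"c1_e": -1}, 0.0),
        ),
        biomass_reaction_id="BIOMASS",
    )


class TestValidation:
    def test_minimal_two_reaction_network_is_valid(self):
        assert len(minimal_network().reactions) == 2

    def test_exchange_with_two_metabolites_rejected(self):
        with pytest.raises(NetworkValidationError, match="exactly one"):
            Reaction("EX_bad", {"a_e": -1, "b_e": -1}, is_exchange=True)

    def test_exchange_coefficient_must_be_minus_one(self):
        with pytest.raises(NetworkValidationError, match="-1"):
            Reaction("EX_bad", {"a_e": 1}, is_exchange=True)

    def test_crossed_bounds_rejected(self):
        with pytest.raises(NetworkValidationError, match="exceeds"):
            Reaction("r", {"a_c": 1}, lower_bound=1.0, upper_bound=-1.0)

    def test_zero_coefficient_rejected(self):
        with pytest.raises(NetworkValidationError, match="zero"):
            Reaction("r", {"a_c": 0.0})

    def test_missing_biomass_rejected(self):
        with pytest.raises(NetworkValidationError, match="biomass"):
            MetabolicNetwork(
                organism_id="x",
                reactions=(Reaction("r1", {"a_c": 1}),),
                biomass_reaction_id="BIOMASS",
            )

    def test_butyrate_exchange_must_be_exchange(self):
        with pytest.raises(NetworkValidationError, match="butyrate"):
            MetabolicNetwork(
                organism_id="x",
                reactions=(Reaction("BIOMASS", {"a_c": -1}),),
                biomass_reaction_id="BIOMASS",
                butyrate_exchange_id="BIOMASS",
            )

    def test_negative_medium_cap_rejected(self):
        with pytest.raises(NetworkValidationError, match=">= 0"):
            Medium(uptake_caps={"c1_e": -1.0})


class TestJsonIO:
    def test_round_trip_is_byte_stable(self, tmp_path):
        network = minimal_network()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_network(network, p1)
        write_network(load_network(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_exchange_raises_at_load(self, tmp_path):
        data = minimal_network().to_dict()
        data["reactions"][1]["stoich"] = {"a_e": -1, "b_e": -1}
        data["reactions"][1]["is_exchange"] = True
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(NetworkValidationError):
            load_network(path)

    def test_malformed_record_names_offender(self, tmp_path):
        data = minimal_network().to_dict()
        del data["reactions"][0]["stoich"]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(NetworkValidationError, match="#0"):
            load_network(path)

    def test_unknown_optional_fields_ignored(self, tmp_path):
        data = minimal_network().to_dict()
        data["annotation"] = {"source": "somewhere"}
        path = tmp_path / "extra.json"
        path.write_text(json.dumps(data))
        assert load_network(path).organism_id == "org_a"


class TestMediumIO:
    def test_round_trip(self, tmp_path):
        medium = Medium(uptake_caps={"c1_e": 10.0, "min_e": 2.5})
        path = tmp_path / "medium.tsv"
        write_medium(medium, path)
        assert load_medium(path).uptake_caps == medium.uptake_caps

    def test_duplicate_metabolite_rejected(self, tmp_path):
        path = tmp_path / "medium.tsv"
        path.write_text("metabolite_id\tmax_uptake\nc1_e\t10\nc1_e\t5\n")
        with pytest.raises(NetworkValidationError, match="duplicate"):
            load_medium(path)


class TestSbml:
    def test_reads_cobra_written_sbml(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("toy_org")
        met_c = cobra.Metabolite("c1_e", compartment="e")
        met_p = cobra.Metabolite("prec_c", compartment="c")
        ex = cobra.Reaction("EX_c1_e", lower_bound=-10, upper_bound=1000)
        ex.add_metabolites({met_c: -1})
        cat = cobra.Reaction("CAT", lower_bound=0, upper_bound=1000)
        cat.add_metabolites({met_c: -1, met_p: 1})
        bio = cobra.Reaction("BIOMASS_toy", lower_bound=0, upper_bound=1000)
        bio.add_metabolites({met_p: -1})
        model.add_reactions([ex, cat, bio])
        model.objective = "BIOMASS_toy"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(path))

        network = load_network(path, format="sbml")
        assert network.biomass_reaction_id == "BIOMASS_toy"
        assert {r.id for r in network.reactions} >= {"EX_c1_e", "CAT", "BIOMASS_toy"}
        ex_loaded = network.reaction("EX_c1_e")
        assert ex_loaded.is_exchange and ex_loaded.lower_bound == -10


class TestPresence:
    def test_examples(self):
        universe = ("r1", "r2", "r3", "r4", "r5")
        network = MetabolicNetwork(
            organism_id="x",
            reactions=(
                Reaction("r1", {"a_c": 1}),
                Reaction("r3", {"a_c": 1}),
                Reaction("r4", {"a_c": 1}),
            ),
            biomass_reaction_id="r1",
        )
        pv = presence_vector(network, universe)
        assert pv.bits.tolist() == [1, 0, 1, 1, 0]

    def test_saturation_and_empty_intersection(self):
        network = minimal_network()
        full = presence_vector(network, tuple(sorted(network.reaction_ids)))
        assert full.bits.tolist() == [1, 1]
        none = presence_vector(network, ("zz1", "zz2"))
        assert none.bits.tolist() == [0, 0]

    def test_universe_union_and_permutation_invariance(self):
        a = minimal_network("a")
        b = MetabolicNetwork(
            organism_id="b",
            reactions=(
                Reaction("EX_x_e", {"x_e": -1}, is_exchange=True),
                Reaction("R9", {"x_e": -1, "p_c": 1}, 0.0),
                Reaction("GROW", {"p_c": -1}, 0.0),
            ),
            biomass_reaction_id="GROW",
        )
        assert len(build_universe([a, b])) == 5
        assert build_universe([a, b]) == build_universe([b, a])

    def test_duplicate_organism_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate organism"):
            build_universe([minimal_network("a"), minimal_network("a")])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(["r1", "r2", "r3", "r4", "r5", "BIOMASS"]),
                   min_size=1).map(lambda s: s | {"BIOMASS"}))
    def test_presence_matches_membership(self, reaction_ids):
        network = MetabolicNetwork(
            organism_id="x",
            reactions=tuple(Reaction(r, {"a_c": 1}) for r in sorted(reaction_ids)),
            biomass_reaction_id="BIOMASS",
        )
        universe = ("BIOMASS", "r1", "r2", "r3", "r4", "r5", "zz")
        pv = presence_vector(network, universe)
        for rid, bit in zip(universe, pv.bits):
            assert bit == (1 if rid in reaction_ids else 0)
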