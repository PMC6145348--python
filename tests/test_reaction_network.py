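"""Stoichiometric balance, minimal-integer balancing, kinetics, knockout."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakeredox.reaction_network import (
    DEFAULT_SPECIES,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    balance_minimal,
    check_balance,
    default_network,
    knockout,
    rate,
)


class TestCheckBalance:
    def test_sulfide_denitrification_balanced(self, network):
        rxn = network.reaction("R12")
        assert all(v == 0 for v in check_balance(rxn, network.species).values())

    def test_methane_denitrification_balanced(self, network):
        rxn = network.reaction("R13")
        assert all(v == 0 for v in check_balance(rxn, network.species).values())

    def test_perturbed_coefficient_breaks_balance(self, network):
        rxn = network.reaction("R13")
        stoich = dict(rxn.stoich)
        stoich["NO3-"] = Fraction(-7)  # was -8
        bad = Reaction(id="bad", process_label="x", stoich=stoich, rate_law=rxn.rate_law)
        resid = check_balance(bad, network.species)
        # one N short on the reactant side; charge off by one unit
        assert resid["N"] == 1
        assert abs(resid["charge"]) == 1

    def test_unknown_species_identified(self, network):
        rxn = Reaction(
            id="x",
            process_label="x",
            stoich={"unobtainium": Fraction(-1), "CO2": Fraction(1)},
            rate_law=RateLaw(k=1.0),
        )
        with pytest.raises(KeyError, match="unobtainium"):
            check_balance(rxn, network.species)

    def test_all_default_reactions_balanced(self, network):
        for rxn in network.reactions:
            resid = check_balance(rxn, network.species)
            assert all(v == 0 for v in resid.values()), rxn.id


class TestBalanceMinimal:
    def test_sulfide_driven_denitrification_coefficients(self):
        reac, prod = balance_minimal(
            ["HS-", "NO3-", "H+"], ["SO42-", "N2", "H2O"], DEFAULT_SPECIES
        )
        assert reac == {"HS-": 5, "NO3-": 8, "H+": 3}
        assert prod == {"SO42-": 5, "N2": 4, "H2O": 4}

    def test_methane_driven_denitrification_coefficients(self):
        reac, prod = balance_minimal(
            ["CH4", "NO3-", "H+"], ["CO2", "N2", "H2O"], DEFAULT_SPECIES
        )
        assert reac == {"CH4": 5, "NO3-": 8, "H+": 8}
        assert prod == {"CO2": 5, "N2": 4, "H2O": 14}

    def test_identity_reaction(self):
        reac, prod = balance_minimal(["CH4"], ["CH4"], DEFAULT_SPECIES)
        assert reac == {"CH4": 1} and prod == {"CH4": 1}

    def test_result_passes_check_balance(self):
        reac, prod = balance_minimal(
            ["CH2O", "O2"], ["CO2", "H2O"], DEFAULT_SPECIES
        )
        stoich = {s: Fraction(-c) for s, c in reac.items()}
        stoich.update({s: Fraction(c) for s, c in prod.items()})
        rxn = Reaction(id="t", process_label="t", stoich=stoich, rate_law=RateLaw(k=1.0))
        assert all(v == 0 for v in check_balance(rxn, DEFAULT_SPECIES).values())

    def test_impossible_reaction_raises(self):
        with pytest.raises(ValueError):
            balance_minimal(["CH4"], ["SO42-"], DEFAULT_SPECIES)

    def test_underdetermined_system_raises(self):
        # two independent balanced reactions combined -> 2D solution space
        with pytest.raises(ValueError, match="dimensional"):
            balance_minimal(
                ["CH2O", "CH4", "O2"], ["CO2", "H2O"], DEFAULT_SPECIES
            )


class TestRate:
    def _law(self, **kw):
        defaults = dict(k=10.0, donor="D", K_donor=2.0)
        defaults.update(kw)
        return Reaction(
            id="r",
            process_label="r",
            stoich={"D": Fraction(-1), "P": Fraction(1)},
            rate_law=RateLaw(**defaults),
        )

    def test_zero_donor_gives_zero_rate(self):
        assert rate(self._law(), {"D": 0.0}) == 0.0

    def test_half_saturated_donor_saturated_acceptor(self):
        rxn = self._law(acceptor="A", K_acceptor=1.0)
        r = rate(rxn, {"D": 2.0, "A": 1e12})
        assert r == pytest.approx(5.0, rel=1e-9)

    def test_all_three_factors_at_half_saturation(self):
        rxn = self._law(acceptor="A", K_acceptor=3.0, inhibitor="I", K_inhibit=4.0)
        r = rate(rxn, {"D": 2.0, "A": 3.0, "I": 4.0})
        assert r == pytest.approx(1.25, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            rate(self._law(), {"D": -1.0})

    @given(
        c1=st.floats(0, 1e4, allow_nan=False),
        c2=st.floats(0, 1e4, allow_nan=False),
        inhib=st.floats(0, 1e4, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_donor_and_antitone_in_inhibitor(self, c1, c2, inhib):
        rxn = self._law(inhibitor="I", K_inhibit=5.0)
        lo_d, hi_d = sorted((c1, c2))
        assert rate(rxn, {"D": lo_d, "I": inhib}) <= rate(rxn, {"D": hi_d, "I": inhib})
        assert rate(rxn, {"D": c1, "I": inhib}) <= rate(rxn, {"D": c1, "I": 0.0})


class TestKnockout:
    def test_empty_knockout_is_identity(self, network):
        ko = knockout(network, set())
        assert [r.rate_law.k for r in ko.reactions] == [
            r.rate_law.k for r in network.reactions
        ]

    def test_double_knockout_targets_exactly_listed_processes(self, network):
        labels = {"sulfide_ox_no3", "methane_ox_no3"}
        ko = knockout(network, labels)
        for orig, new in zip(network.reactions, ko.reactions):
            if orig.process_label in labels:
                assert new.rate_law.k == 0.0
                assert orig.rate_law.k > 0  # original untouched
            else:
                assert new.rate_law.k == orig.rate_law.k

    def test_idempotent(self, network):
        labels = {"methanogenesis"}
        once = knockout(network, labels)
        twice = knockout(once, labels)
        assert [r.rate_law.k for r in once.reactions] == [
            r.rate_law.k for r in twice.reactions
        ]

    def test_knocked_out_rate_is_zero_at_any_concentration(self, network):
        ko = knockout(network, {"sulfate_reduction"})
        rxn = next(r for r in ko.reactions if r.process_label == "sulfate_reduction")
        conc = {s.name: 100.0 for s in ko.species}
        assert rate(rxn, conc) == 0.0

    def test_unknown_label_raises(self, network):
        with pytest.raises(KeyError, match="no_such_process"):
            knockout(network, {"no_such_process"})


class TestDefaultNetwork:
    def test_fourteen_processes(self, network):
        assert len(network.reactions) == 14

    def test_contains_nitrate_coupled_oxidations(self, network):
        labels = set(network.process_labels)
        assert {"sulfide_ox_no3", "methane_ox_no3"} <= labels

    def test_first_order_sulfur_precipitation(self, network):
        rxn = next(
            r for r in network.reactions if r.process_label == "sulfur_precipitation"
        )
        assert rxn.rate_law.first_order
        assert rxn.reactants == ["HS-"]

    def test_rate_constant_overrides(self):
        net = default_network({"methanogenesis": 42.0})
        rxn = next(r for r in net.reactions if r.process_label == "methanogenesis")
        assert rxn.rate_law.k == 42.0
        with pytest.raises(KeyError):
            default_network({"bogus": 1.0})

    def test_yaml_round_trip_lossless(self, network):
        text = network.to_yaml()
        again = ReactionNetwork.from_yaml(text)
        assert again.to_yaml() == text
        assert [r.stoich for r in again.reactions] == [
            r.stoich for r in network.reactions
        ]


def test_unbalanced_network_rejected():
    sp = [Species("A", 0, {"C": 1}), Species("B", 0, {"C": 2})]
    bad = Reaction(
        id="u", process_label="u",
        stoich={"A": Fraction(-1), "B": Fraction(1)},
        rate_law=RateLaw(k=1.0),
    )
    with pytest.raises(ValueError, match="unbalanced"):
        ReactionNetwork(species=sp, reactions=[bad])
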