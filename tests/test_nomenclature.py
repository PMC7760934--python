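"""Taxon-name assignment: the type/unanimity/consensus/common-rank cascade."""

import datetime as dt
import random

import pytest

from thengine.nomenclature import NameBasis, assign_name
from thengine.records import Identification, IdentificationSource, Individual, Rank

D = dt.date


def ind(pid, *idents, is_type=False, type_name_year=None):
    return Individual(
        pid, identifications=list(idents), is_type=is_type, type_name_year=type_name_year
    )


def sp(name, year=2010, source=IdentificationSource.SPECIMEN_EXPERT):
    return Identification(name, Rank.SPECIES, D(year, 1, 1), source)


def genus(name, year=2010):
    return Identification(name, Rank.GENUS, D(year, 1, 1))


class TestUnanimity:
    def test_binomial_plus_genus_determinations_take_the_species_name(
        self, thelephora_members
    ):
        decision = assign_name(thelephora_members)
        assert decision.taxon_name == "Thelephora terrestris"
        assert decision.rank is Rank.SPECIES
        assert decision.basis is NameBasis.UNANIMOUS

    def test_genus_determination_of_another_genus_blocks_unanimity(self):
        members = [ind("a", sp("Thelephora terrestris")), ind("b", genus("Tomentella sp."))]
        decision = assign_name(members)
        assert decision.basis is not NameBasis.UNANIMOUS
        assert decision.rank is not Rank.SPECIES


class TestConflictAndCommonRank:
    def test_second_species_name_forces_genus_consensus(self, thelephora_members):
        spec, living, soil = thelephora_members
        living.identifications.append(sp("Thelephora aurantiotincta", 2019))
        decision = assign_name([spec, living, soil])
        assert decision.taxon_name == "Thelephora"
        assert decision.rank is Rank.GENUS
        assert decision.basis is NameBasis.COMMON_RANK
        assert set(decision.conflicts) == {
            "Thelephora terrestris",
            "Thelephora aurantiotincta",
        }

    def test_reidentification_restores_species_unanimity(self, thelephora_members):
        spec, living, soil = thelephora_members
        living.identifications.append(sp("Thelephora aurantiotincta", 2019))
        spec.identifications.append(sp("Thelephora aurantiotincta", 2020))
        decision = assign_name([spec, living, soil])
        assert decision.taxon_name == "Thelephora aurantiotincta"
        assert decision.rank is Rank.SPECIES
        assert decision.basis is NameBasis.UNANIMOUS

    def test_same_rank_agreement_above_genus(self):
        members = [
            ind("a", Identification("Agaricales", Rank.ORDER, D(2010, 1, 1))),
            ind("b", Identification("Agaricales", Rank.ORDER, D(2012, 1, 1))),
        ]
        decision = assign_name(members)
        assert (decision.taxon_name, decision.rank) == ("Agaricales", Rank.ORDER)
        assert decision.basis is NameBasis.COMMON_RANK

    def test_disjoint_genera_stay_unnamed(self):
        members = [ind("a", sp("Amanita muscaria")), ind("b", sp("Russula emetica"))]
        decision = assign_name(members)
        assert decision.basis is NameBasis.UNNAMED
        assert decision.taxon_name is None

    def test_compatible_family_determination_keeps_species_unanimity(self, backbone):
        members = [
            ind("a", sp("Thelephora terrestris")),
            ind("b", Identification("Thelephoraceae", Rank.FAMILY, D(2012, 1, 1))),
        ]
        decision = assign_name(members, backbone=backbone)
        assert (decision.taxon_name, decision.rank) == (
            "Thelephora terrestris",
            Rank.SPECIES,
        )

    def test_backbone_lifts_cross_genus_conflict_to_the_shared_family(self, backbone):
        # Thelephora and Tomentella are both Thelephoraceae in the backbone
        members = [
            ind("a", sp("Thelephora terrestris")),
            ind("b", sp("Tomentella badia")),
        ]
        decision = assign_name(members, backbone=backbone)
        assert (decision.taxon_name, decision.rank) == ("Thelephoraceae", Rank.FAMILY)
        assert decision.basis is NameBasis.COMMON_RANK


class TestConsensus:
    def test_four_of_five_at_80_percent(self):
        members = [ind(f"m{i}", sp("Inocybe geophylla")) for i in range(4)]
        members.append(ind("m4", sp("Inocybe lilacina")))
        decision = assign_name(members, consensus_fraction=0.8)
        assert decision.taxon_name == "Inocybe geophylla"
        assert decision.basis is NameBasis.CONSENSUS

    def test_three_of_five_fails_80_percent(self):
        members = [ind(f"m{i}", sp("Inocybe geophylla")) for i in range(3)]
        members += [ind("m3", sp("Inocybe lilacina")), ind("m4", sp("Inocybe lacera"))]
        decision = assign_name(members, consensus_fraction=0.8)
        assert decision.basis is NameBasis.COMMON_RANK
        assert decision.taxon_name == "Inocybe"

    def test_consensus_off_by_default(self):
        members = [ind(f"m{i}", sp("Inocybe geophylla")) for i in range(4)]
        members.append(ind("m4", sp("Inocybe lilacina")))
        assert assign_name(members).basis is NameBasis.COMMON_RANK

    def test_full_consensus_equals_unanimity(self):
        # with fraction 1.0 the consensus branch can never beat unanimity:
        # both name the SH iff all species-rank identifications agree
        rng = random.Random(42)
        names = ["Xa aa", "Xa bb", "Xa cc"]
        for _ in range(50):
            members = [
                ind(f"m{i}", sp(rng.choice(names))) for i in range(rng.randint(1, 6))
            ]
            strict = assign_name(members, consensus_fraction=1.0)
            plain = assign_name(members)
            assert (strict.taxon_name, strict.rank) == (plain.taxon_name, plain.rank)


class TestTypes:
    def test_type_specimen_overrides_conflicting_identifications(self):
        members = [
            ind("t", sp("Yy qq"), is_type=True, type_name_year=("Yy zz", 1881)),
            ind("a", sp("Yy qq")),
        ]
        decision = assign_name(members)
        assert decision.taxon_name == "Yy zz"
        assert decision.basis is NameBasis.TYPE

    def test_earliest_type_year_wins(self):
        members = [
            ind("t1", is_type=True, type_name_year=("Zz new", 1950)),
            ind("t2", is_type=True, type_name_year=("Zz old", 1820)),
        ]
        decision = assign_name(members)
        assert decision.taxon_name == "Zz old"
        assert decision.basis is NameBasis.TYPE_PRIORITY
        assert set(decision.conflicts) == {"Zz new", "Zz old"}

    def test_same_year_ties_break_lexicographically(self):
        members = [
            ind("t1", is_type=True, type_name_year=("Zz beta", 1900)),
            ind("t2", is_type=True, type_name_year=("Zz alpha", 1900)),
        ]
        assert assign_name(members).taxon_name == "Zz alpha"


class TestProperties:
    def test_permutation_invariance(self, thelephora_members):
        import itertools

        decisions = {
            (
                assign_name(list(order)).taxon_name,
                assign_name(list(order)).rank,
                assign_name(list(order)).basis,
            )
            for order in itertools.permutations(thelephora_members)
        }
        assert len(decisions) == 1

    def test_conflicting_additions_only_degrade_the_rank(self):
        # a new member can never make a conflicted name *more* resolved:
        # compatible determinations keep the rank, conflicting ones raise it
        base = [ind("a", sp("Thelephora terrestris")), ind("b", genus("Thelephora sp."))]
        assert assign_name(base).rank is Rank.SPECIES
        compatible = assign_name(base + [ind("c", genus("Thelephora sp."))])
        assert compatible.rank is Rank.SPECIES
        conflicting = assign_name(base + [ind("c", sp("Thelephora aurantiotincta"))])
        assert conflicting.rank is Rank.GENUS
        cross_genus = assign_name(base + [ind("c", sp("Tomentella badia"))])
        assert cross_genus.rank is None or cross_genus.rank > Rank.GENUS

    def test_empty_member_list_errors(self):
        with pytest.raises(ValueError):
            assign_name([])

    def test_no_identifications_is_unnamed(self):
        decision = assign_name([ind("a"), ind("b")])
        assert decision.basis is NameBasis.UNNAMED
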