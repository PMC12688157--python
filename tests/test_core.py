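"""Unit tests for the design-object model and energy aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import foldscape as fs
from foldscape.core import EnergyTerm
from foldscape.errors import ConfigurationError, ProtocolError
from foldscape.moves import Edit, MoveProposal

from conftest import build_shared_chain_system


class FixedTerm(EnergyTerm):
    """Stub term returning a constant; sequence-only."""

    inheritable = True
    requires = None
    n_groups = 0

    def __init__(self, value, name="FixedTerm"):
        self.value = value
        self.name = name

    def evaluate(self, ctx):
        return self.value


def make_state(name, chain, weighted_values):
    bindings = [
        fs.EnergyTermBinding(FixedTerm(v, name=f"T{i}"), w, [])
        for i, (w, v) in enumerate(weighted_values)
    ]
    return fs.State(name, [chain], bindings)


class TestStateEnergy:
    def test_weighted_sum(self):
        chain = fs.Chain("A", "AA")
        state = make_state("s", chain, [(2.0, 0.3), (-1.0, 0.4)])
        system = fs.System([chain], [state])
        assert fs.state_energy(system, state, {}) == pytest.approx(0.2)

    def test_empty_sum_is_zero(self):
        chain = fs.Chain("A", "AA")
        state = fs.State("s", [chain], [])
        system = fs.System([chain], [state])
        assert fs.state_energy(system, state, {}) == 0.0

    def test_negative_weight_flips_sign(self):
        chain = fs.Chain("A", "AA")
        state = make_state("s", chain, [(-1.0, 0.8)])
        system = fs.System([chain], [state])
        assert fs.state_energy(system, state, {}) == pytest.approx(-0.8)

    def test_missing_oracle_output_names_state_and_term(self, toy_fold):
        chain = fs.Chain("A", "ACD")
        state = fs.State("complex", [chain], [
            fs.EnergyTermBinding(fs.PTMEnergy(), 1.0, [], oracle_id="fold"),
        ])
        system = fs.System([chain], [state])
        with pytest.raises(ConfigurationError, match="complex.*PTMEnergy"):
            fs.state_energy(system, state, {})


class TestSystemEnergy:
    @pytest.mark.parametrize("state_values, expected", [
        ([1.5, -0.5], 1.0),
        ([], 0.0),
        ([0.7], 0.7),
    ])
    def test_total_is_sum_over_states(self, state_values, expected):
        chain = fs.Chain("A", "AA")
        states = [
            make_state(f"s{i}", chain, [(1.0, v)])
            for i, v in enumerate(state_values)
        ]
        if not states:
            # a system with zero states is legal; its energy is the empty sum
            system = fs.System([chain], [])
        else:
            system = fs.System([chain], states)
        bd = fs.system_energy(system, {})
        assert bd.total == pytest.approx(expected)

    def test_breakdown_is_consistent(self):
        chain = fs.Chain("A", "AA")
        s1 = make_state("s1", chain, [(2.0, 0.25), (1.0, -1.0)])
        s2 = make_state("s2", chain, [(-3.0, 0.5)])
        system = fs.System([chain], [s1, s2])
        bd = fs.system_energy(system, {})
        assert bd.total == pytest.approx(sum(bd.per_state.values()), abs=1e-12)
        for name, e_s in bd.per_state.items():
            terms = [v for (s, _), v in bd.per_term.items() if s == name]
            assert e_s == pytest.approx(sum(terms), abs=1e-12)
        # raw and weighted entries are linked by the weights
        assert bd.per_term[("s1", "T0")] == pytest.approx(
            2.0 * bd.raw_per_term[("s1", "T0")])


class TestValidation:
    def test_state_chain_must_be_in_system(self):
        a, b = fs.Chain("A", "AA"), fs.Chain("B", "CC")
        state = fs.State("s", [b], [])
        with pytest.raises(ConfigurationError, match="not part of the system"):
            fs.System([a], [state])

    def test_zero_chain_state_rejected(self):
        with pytest.raises(ConfigurationError, match="at least one chain"):
            fs.State("s", [], [])

    def test_group_index_out_of_range(self):
        chain = fs.Chain("A", "ACD")
        state = fs.State("s", [chain], [
            fs.EnergyTermBinding(fs.HydrophobicEnergy(), 1.0,
                                 [fs.ResidueGroup("A", [5])]),
        ])
        with pytest.raises(ConfigurationError, match="out of range"):
            fs.System([chain], [state])

    def test_repeated_chain_in_state_warns(self):
        chain = fs.Chain("A", "ACD")
        with pytest.warns(UserWarning, match="more than once"):
            fs.State("homodimer", [chain, chain], [])

    def test_bad_amino_acid_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown amino acid"):
            fs.Residue("X")


class TestApplyMutation:
    def test_shared_chain_updates_all_states(self):
        system = build_shared_chain_system()
        move = MoveProposal([Edit("substitute", "binder", 2, "W")])
        fs.apply_mutation(system, move)
        bind, avoid = system.states
        assert bind.chain_by_id("binder").sequence == "ARWDAG"
        assert avoid.chain_by_id("binder").sequence == "ARWDAG"
        assert bind.chain_by_id("binder") is avoid.chain_by_id("binder")

    def test_apply_then_revert_is_identity(self):
        system = build_shared_chain_system()
        chain = system.chain("binder")
        before_seq = chain.sequence
        before_members = [set(r.term_memberships) for r in chain.residues]
        move = MoveProposal([
            Edit("substitute", "binder", 0, "W"),
            Edit("insert", "binder", 3, "K", tie_break=0.3),
            Edit("delete", "binder", 5),
        ])
        delta = fs.apply_mutation(system, move)
        assert chain.sequence != before_seq
        delta.revert()
        assert chain.sequence == before_seq
        assert [set(r.term_memberships) for r in chain.residues] == before_members

    def test_insertion_at_chain_end_appends(self):
        system = build_shared_chain_system()
        chain = system.chain("binder")
        move = MoveProposal([Edit("insert", "binder", len(chain), "K",
                                  tie_break=0.1)])
        fs.apply_mutation(system, move)
        assert chain.sequence.endswith("K")

    def test_immutable_residue_rejected(self):
        system = build_shared_chain_system()
        move = MoveProposal([Edit("substitute", "t1", 0, "W")])
        with pytest.raises(ProtocolError, match="immutable"):
            fs.apply_mutation(system, move)

    def test_failed_move_leaves_system_untouched(self):
        system = build_shared_chain_system()
        before = system.chain("binder").sequence
        move = MoveProposal([
            Edit("substitute", "binder", 0, "W"),
            Edit("substitute", "t1", 0, "W"),  # illegal second edit
        ])
        with pytest.raises(ProtocolError):
            fs.apply_mutation(system, move)
        assert system.chain("binder").sequence == before

    def test_deletion_to_empty_chain_rejected(self):
        chain = fs.Chain("A", "G")
        system = fs.System([chain], [fs.State("s", [chain], [])])
        with pytest.raises(ProtocolError, match="empty"):
            fs.apply_mutation(system, MoveProposal([Edit("delete", "A", 0)]))

    def test_inserted_residue_inherits_from_shared_neighbours(self):
        system = build_shared_chain_system()
        chain = system.chain("binder")
        # all binder residues are in the PAE groups of both states
        move = MoveProposal([Edit("insert", "binder", 3, "K", tie_break=0.9)])
        fs.apply_mutation(system, move)
        inserted = chain.residues[3]
        assert inserted.mutable
        assert inserted.term_memberships == chain.residues[2].term_memberships


@settings(deadline=None, max_examples=40)
@given(
    edits=st.lists(
        st.tuples(st.sampled_from(["substitute", "insert", "delete"]),
                  st.integers(0, 20), st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                  st.floats(0, 0.999)),
        min_size=1, max_size=6,
    )
)
def test_apply_revert_roundtrip_property(edits):
    """Any legal sequence of edits reverts to the exact original state."""
    chain = fs.Chain("A", "ARNDCEQGH")
    group = fs.ResidueGroup("A", [0, 2, 4])
    state = fs.State("s", [chain], [
        fs.EnergyTermBinding(fs.HydrophobicEnergy(), 1.0, [group]),
    ])
    system = fs.System([chain], [state])
    before_seq = chain.sequence
    before = [(r.amino_acid, r.mutable, frozenset(r.term_memberships))
              for r in chain.residues]
    deltas = []
    for kind, pos, aa, tie in edits:
        length = len(chain)
        if kind == "substitute":
            pos = pos % length
            move = MoveProposal([Edit("substitute", "A", pos, aa)])
        elif kind == "insert":
            pos = pos % (length + 1)
            move = MoveProposal([Edit("insert", "A", pos, aa, tie_break=tie)])
        else:
            if length <= 1:
                continue
            pos = pos % length
            move = MoveProposal([Edit("delete", "A", pos)])
        deltas.append(fs.apply_mutation(system, move))
    for delta in reversed(deltas):
        delta.revert()
    assert chain.sequence == before_seq
    assert [(r.amino_acid, r.mutable, frozenset(r.term_memberships))
            for r in chain.residues] == before
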