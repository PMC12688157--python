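"""Shared fixtures and small system builders."""

import numpy as np
import pytest
from hypothesis import settings

import foldscape as fs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_fold():
    return fs.ToyFoldOracle()


@pytest.fixture
def toy_embed():
    return fs.ToyEmbeddingOracle()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def build_hydrophobic_system(sequence="AVA", weight=1.0):
    """One chain, one state, one HydrophobicEnergy over the whole chain."""
    chain = fs.Chain("A", sequence)
    group = fs.ResidueGroup("A", range(len(sequence)))
    state = fs.State("fold", [chain], [
        fs.EnergyTermBinding(fs.HydrophobicEnergy(), weight, [group]),
    ])
    return fs.System([chain], [state])


def build_shared_chain_system():
    """Binder shared by two states (bind target 1, avoid target 2)."""
    binder = fs.Chain("binder", "ARNDAG")
    t1 = fs.Chain("t1", "KLMNP", mutable=False)
    t2 = fs.Chain("t2", "QRSTV", mutable=False)
    g_b = fs.ResidueGroup("binder", range(6))
    g1 = fs.ResidueGroup("t1", range(5))
    g2 = fs.ResidueGroup("t2", range(5))
    bind = fs.State("bind", [binder, t1], [
        fs.EnergyTermBinding(fs.PAEEnergy(), 1.0, [g_b, g1], oracle_id="fold"),
    ])
    avoid = fs.State("avoid", [binder, t2], [
        fs.EnergyTermBinding(fs.PAEEnergy(), -1.0, [g_b, g2], oracle_id="fold"),
    ])
    return fs.System([binder, t1, t2], [bind, avoid])


def recompute_from_scratch(system, oracles):
    """Independent total-energy recomputation: fresh oracle outputs per
    state, straight through system_energy (no sampler caches)."""
    outputs_by_state = {}
    total = 0.0
    for state in system.states:
        needed = {b.oracle_id for b in state.bindings if b.term.requires}
        outputs = {oid: oracles[oid](state.sequences) for oid in needed}
        total += fs.state_energy(system, state, outputs)
        outputs_by_state[state.name] = outputs
    return total
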