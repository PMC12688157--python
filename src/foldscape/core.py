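"""Hierarchical design objects and energy aggregation.

A design problem is a :class:`System`: a pool of :class:`Chain` objects
(amino-acid sequences whose residues are individually mutable or
frozen) plus one or more :class:`State` objects.  Each State names the
subset of chains it is evaluated on and carries a list of weighted
:class:`EnergyTermBinding` entries; the System energy is the sum of the
State energies, each of which is the weighted sum of its terms:

    E_system = sum_S E_S,   E_S = sum_j w_j * eps_j(chains of S)

Chains are shared by identity: a chain present in several States has
exactly one sequence, and mutating it updates every State that contains
it.  Term membership is stored on the residues themselves (as a set of
``(binding key, group slot)`` tags) so that insertions can inherit
memberships locally; the residue groups an energy term sees are
materialized views over those tags.
"""

from __future__ import annotations

import copy
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .errors import ConfigurationError, ProtocolError

#: The 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

# A membership tag is ((state_name, binding_name), group_slot).
MembershipKey = tuple[tuple[str, str], int]


@dataclass
class Residue:
    """One amino acid inside a chain.

    ``term_memberships`` holds the tags of every (binding, group slot)
    this residue belongs to; inserted residues receive tags through the
    inheritance rule implemented in :func:`inherited_memberships`.
    """

    amino_acid: str
    mutable: bool = True
    term_memberships: set[MembershipKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.amino_acid not in _AA_SET:
            raise ConfigurationError(
                f"unknown amino acid {self.amino_acid!r}; expected one of {AMINO_ACIDS}"
            )


class Chain:
    """An ordered list of residues with a stable identity.

    Identity matters: States reference Chain *objects*, so a chain
    shared across States has a single sequence by construction.
    """

    def __init__(
        self,
        chain_id: str,
        sequence: str | Iterable[Residue],
        mutable: bool | Sequence[bool] = True,
    ):
        self.chain_id = chain_id
        if isinstance(sequence, str):
            if isinstance(mutable, bool):
                flags = [mutable] * len(sequence)
            else:
                flags = list(mutable)
                if len(flags) != len(sequence):
                    raise ConfigurationError(
                        f"chain {chain_id!r}: {len(flags)} mutability flags for "
                        f"{len(sequence)} residues"
                    )
            self.residues: list[Residue] = [
                Residue(aa, mut) for aa, mut in zip(sequence, flags)
            ]
        else:
            self.residues = list(sequence)
        if len(self.residues) < 1:
            raise ConfigurationError(f"chain {chain_id!r} must have length >= 1")

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Chain({self.chain_id!r}, {self.sequence!r})"


@dataclass(frozen=True)
class ResidueGroup:
    """A possibly non-contiguous set of residue positions on one chain.

    Indices are 0-based.  Groups are the unit an energy term acts on;
    all residues of a group live on a single chain.
    """

    chain_id: str
    residue_indices: tuple[int, ...]

    def __init__(self, chain_id: str, residue_indices: Iterable[int]):
        indices = tuple(int(i) for i in residue_indices)
        if not indices:
            raise ConfigurationError("residue group must be non-empty")
        if len(set(indices)) != len(indices):
            raise ConfigurationError("residue group indices must be unique")
        object.__setattr__(self, "chain_id", chain_id)
        object.__setattr__(self, "residue_indices", indices)


@dataclass
class MaterializedGroup:
    """A residue group resolved against the current chain contents."""

    chain: Chain
    indices: tuple[int, ...]

    @property
    def sequence(self) -> str:
        return "".join(self.chain.residues[i].amino_acid for i in self.indices)

    def __len__(self) -> int:
        return len(self.indices)


class EnergyTerm(ABC):
    """Contract every energy term implements.

    Concrete terms live in :mod:`foldscape.energies`; the base class is
    defined here so the aggregation layer does not depend on them.
    ``requires`` names the kind of oracle output the term consumes
    ("fold", "embed", "property") or ``None`` for sequence-only terms.
    ``n_groups`` is the number of residue groups the term expects, or
    ``None`` when the count is variable (ring symmetry).
    """

    name: str = "EnergyTerm"
    inheritable: bool = True
    requires: str | None = None
    n_groups: int | None = 1

    @abstractmethod
    def evaluate(self, ctx: "EvalContext") -> float:
        """Return the raw (unweighted) energy value."""


@dataclass
class EvalContext:
    """Everything an energy term may need at evaluation time."""

    system: "System"
    state: "State"
    groups: list[MaterializedGroup]
    oracle_output: Any = None


class EnergyTermBinding:
    """One weighted term attached to residue groups and an oracle.

    ``weight`` may be negative — that is how a State is told to *avoid*
    a property (e.g. penalising confident binding to an off-target).
    """

    def __init__(
        self,
        term: EnergyTerm,
        weight: float,
        groups: Sequence[ResidueGroup] = (),
        oracle_id: str | None = None,
        name: str | None = None,
    ):
        weight = float(weight)
        if not (weight == weight and abs(weight) != float("inf")):
            raise ConfigurationError("binding weight must be finite")
        if term.requires is not None and oracle_id is None:
            raise ConfigurationError(
                f"term {term.name} requires a {term.requires!r} oracle but no "
                "oracle_id was given"
            )
        if term.n_groups is not None and len(groups) != term.n_groups:
            raise ConfigurationError(
                f"term {term.name} expects {term.n_groups} residue group(s), "
                f"got {len(groups)}"
            )
        self.term = term
        self.weight = weight
        self.groups = list(groups)
        self.oracle_id = oracle_id
        self.name = name if name is not None else term.name
        # chain id per group slot; survives group re-materialization
        self.group_chain_ids = [g.chain_id for g in self.groups]

    @property
    def inheritable(self) -> bool:
        return self.term.inheritable


class State:
    """A named set of chains plus the energy terms evaluated on them.

    This is a *design* state — a tuple of sequences scored together —
    not a conformational state.
    """

    def __init__(self, name: str, chains: Sequence[Chain], bindings: Sequence[EnergyTermBinding] = ()):
        if not chains:
            raise ConfigurationError(f"state {name!r} must contain at least one chain")
        self.name = name
        self.chains = list(chains)
        self.bindings = list(bindings)
        ids = [c.chain_id for c in self.chains]
        if len(set(id(c) for c in self.chains)) != len(self.chains):
            warnings.warn(
                f"state {name!r} contains the same chain object more than once "
                "(homo-oligomer); residue groups resolve against the first copy",
                stacklevel=2,
            )
        elif len(set(ids)) != len(ids):
            raise ConfigurationError(f"state {name!r} has duplicate chain ids {ids}")

    def chain_by_id(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ConfigurationError(f"state {self.name!r} has no chain {chain_id!r}")

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(c.sequence for c in self.chains)

    def residue_offset(self, chain_id: str) -> int:
        """0-based offset of a chain's first residue in the State's
        concatenated residue indexing (the order oracles see)."""
        off = 0
        for c in self.chains:
            if c.chain_id == chain_id:
                return off
            off += len(c)
        raise ConfigurationError(f"state {self.name!r} has no chain {chain_id!r}")

    @property
    def total_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass
class EnergyBreakdown:
    """Total, per-State and per-term decomposition of a System energy.

    ``per_term`` holds the weighted contributions w*eps keyed by
    ``(state name, binding name)``; ``raw_per_term`` the unweighted eps.
    """

    total: float
    per_state: dict[str, float]
    per_term: dict[tuple[str, str], float]
    raw_per_term: dict[tuple[str, str], float]


class System:
    """The full design object: chain pool plus States.

    Construction stamps each binding's residue groups onto the residues
    as membership tags and validates that every group index is in range
    and every State chain belongs to the System.
    """

    def __init__(self, chains: Sequence[Chain], states: Sequence[State]):
        self.chains = list(chains)
        self.states = list(states)
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate state names: {names}")
        chain_objs = {id(c) for c in self.chains}
        by_id = {}
        for c in self.chains:
            if c.chain_id in by_id:
                raise ConfigurationError(f"duplicate chain id {c.chain_id!r} in system")
            by_id[c.chain_id] = c
        self._chains_by_id = by_id
        #: membership tag -> is the owning term inheritable
        self._inheritable: dict[MembershipKey, bool] = {}
        for state in self.states:
            for c in state.chains:
                if id(c) not in chain_objs:
                    raise ConfigurationError(
                        f"state {state.name!r} references chain {c.chain_id!r} "
                        "that is not part of the system"
                    )
            self._register_state_bindings(state)

    def _register_state_bindings(self, state: State) -> None:
        seen: set[str] = set()
        for binding in state.bindings:
            if binding.name in seen:
                base, n = binding.name, 2
                while f"{base}_{n}" in seen:
                    n += 1
                binding.name = f"{base}_{n}"
            seen.add(binding.name)
            key_base = (state.name, binding.name)
            for slot, group in enumerate(binding.groups):
                chain = state.chain_by_id(group.chain_id)
                for idx in group.residue_indices:
                    if not 0 <= idx < len(chain):
                        raise ConfigurationError(
                            f"group index {idx} out of range for chain "
                            f"{chain.chain_id!r} (length {len(chain)}) in "
                            f"state {state.name!r}, term {binding.name}"
                        )
                    chain.residues[idx].term_memberships.add((key_base, slot))
                self._inheritable[(key_base, slot)] = binding.inheritable

    # -- lookups ---------------------------------------------------------

    def chain(self, chain_id: str) -> Chain:
        try:
            return self._chains_by_id[chain_id]
        except KeyError:
            raise ConfigurationError(f"no chain {chain_id!r} in system") from None

    @property
    def total_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def states_containing(self, chain_ids: Iterable[str]) -> list[State]:
        wanted = set(chain_ids)
        return [
            s for s in self.states
            if wanted & {c.chain_id for c in s.chains}
        ]

    def membership_inheritable(self, key: MembershipKey) -> bool:
        return self._inheritable.get(key, False)

    def materialize_group(self, state: State, binding: EnergyTermBinding, slot: int) -> MaterializedGroup:
        chain = state.chain_by_id(binding.group_chain_ids[slot])
        tag = ((state.name, binding.name), slot)
        indices = tuple(
            i for i, r in enumerate(chain.residues) if tag in r.term_memberships
        )
        return MaterializedGroup(chain, indices)

    def materialize_groups(self, state: State, binding: EnergyTermBinding) -> list[MaterializedGroup]:
        return [
            self.materialize_group(state, binding, slot)
            for slot in range(len(binding.group_chain_ids))
        ]

    def snapshot(self) -> "System":
        """Deep copy (chains, residues, states, bindings) preserving the
        shared-chain topology between States."""
        return copy.deepcopy(self)

    def restore_chains_from(self, other: "System") -> None:
        """Overwrite this system's chain contents (sequences, mutability,
        memberships) with deep copies of ``other``'s."""
        for c in self.chains:
            src = other.chain(c.chain_id)
            c.residues = [
                Residue(r.amino_acid, r.mutable, set(r.term_memberships))
                for r in src.residues
            ]


# -- energy aggregation --------------------------------------------------


def state_energy(
    system: System,
    state: State,
    oracle_outputs: Mapping[str, Any],
    breakdown: EnergyBreakdown | None = None,
) -> float:
    """Weighted sum of a State's energy terms, E_S = sum_j w_j eps_j.

    ``oracle_outputs`` maps oracle id -> the output computed for this
    State's chains.  Raw and weighted values are recorded into
    ``breakdown`` when one is passed.
    """
    total = 0.0
    for binding in state.bindings:
        output = None
        if binding.term.requires is not None:
            if binding.oracle_id not in oracle_outputs:
                raise ConfigurationError(
                    f"state {state.name!r}, term {binding.name}: no output for "
                    f"oracle {binding.oracle_id!r}"
                )
            output = oracle_outputs[binding.oracle_id]
        groups = system.materialize_groups(state, binding)
        ctx = EvalContext(system=system, state=state, groups=groups, oracle_output=output)
        raw = float(binding.term.evaluate(ctx))
        weighted = binding.weight * raw
        total += weighted
        if breakdown is not None:
            breakdown.raw_per_term[(state.name, binding.name)] = raw
            breakdown.per_term[(state.name, binding.name)] = weighted
    return total


def system_energy(system: System, oracle_outputs: Mapping[str, Any]) -> EnergyBreakdown:
    """Full-system energy E = sum_S E_S with per-term decomposition.

    Deterministic given identical sequences and oracle outputs; the
    per-State entries sum exactly to the total.
    """
    bd = EnergyBreakdown(total=0.0, per_state={}, per_term={}, raw_per_term={})
    for state in system.states:
        e_s = state_energy(system, state, oracle_outputs, breakdown=bd)
        bd.per_state[state.name] = e_s
        bd.total += e_s
    return bd


# -- mutation application -------------------------------------------------


def inherited_memberships(
    chain: Chain,
    position: int,
    system: System,
    tie_break: float | None = None,
    rng=None,
) -> set[MembershipKey]:
    """Membership tags a residue inserted at ``position`` inherits.

    Tags carried by *both* neighbours (or by the single neighbour at a
    chain boundary) are inherited outright; tags carried by exactly one
    neighbour are inherited with probability 1/2.  Tags of
    non-inheritable terms are never inherited.  ``tie_break`` (a float
    in [0, 1)) resolves the coin flip deterministically when provided;
    otherwise ``rng.random()`` is used.
    """
    left = chain.residues[position - 1].term_memberships if position > 0 else None
    right = chain.residues[position].term_memberships if position < len(chain) else None
    if left is None and right is None:  # pragma: no cover - chains are never empty
        return set()
    if left is None or right is None:
        sole = left if left is not None else right
        return {k for k in sole if system.membership_inheritable(k)}
    inherited: set[MembershipKey] = set()
    both = left & right
    either = (left | right) - both
    for key in both:
        if system.membership_inheritable(key):
            inherited.add(key)
    if either:
        if tie_break is None:
            if rng is None:
                raise ConfigurationError(
                    "insertion with differing neighbours needs a tie_break or rng"
                )
            tie_break = float(rng.random())
        # one coin per insertion: < 0.5 sides with the left neighbour
        chosen = left if tie_break < 0.5 else right
        for key in either & chosen:
            if system.membership_inheritable(key):
                inherited.add(key)
    return inherited


@dataclass
class _AppliedEdit:
    kind: str
    chain: Chain
    position: int
    old_residue: Residue | None = None
    old_amino_acid: str | None = None


class MoveDelta:
    """Handle returned by :func:`apply_mutation`; supports exact reversal."""

    def __init__(self, system: System):
        self.system = system
        self._applied: list[_AppliedEdit] = []
        self.chain_ids: set[str] = set()

    def revert(self) -> None:
        """Undo every applied edit, restoring sequences, mutability and
        term memberships byte-for-byte."""
        for edit in reversed(self._applied):
            if edit.kind == "substitute":
                edit.chain.residues[edit.position].amino_acid = edit.old_amino_acid
            elif edit.kind == "insert":
                edit.chain.residues.pop(edit.position)
            elif edit.kind == "delete":
                edit.chain.residues.insert(edit.position, edit.old_residue)
        self._applied.clear()


def apply_mutation(system: System, move, rng=None) -> MoveDelta:
    """Apply a move proposal to the shared chains, once.

    ``move`` is any object with an ``edits`` attribute; each edit has
    ``kind`` ("substitute" | "insert" | "delete"), ``chain_id``,
    ``position``, ``new_amino_acid`` (None for deletions) and, for
    insertions, an optional ``tie_break`` used by term inheritance.
    Because States hold chain objects, every State containing an edited
    chain observes the new sequence immediately.  The returned handle
    reverses the move exactly (used on Monte Carlo rejection).
    """
    delta = MoveDelta(system)
    try:
        for edit in move.edits:
            chain = system.chain(edit.chain_id)
            kind = edit.kind
            if kind == "substitute":
                if not 0 <= edit.position < len(chain):
                    raise ProtocolError(
                        f"substitution index {edit.position} out of range on "
                        f"chain {chain.chain_id!r}"
                    )
                res = chain.residues[edit.position]
                if not res.mutable:
                    raise ProtocolError(
                        f"substitution targets immutable residue {edit.position} "
                        f"on chain {chain.chain_id!r}"
                    )
                delta._applied.append(
                    _AppliedEdit("substitute", chain, edit.position,
                                 old_amino_acid=res.amino_acid)
                )
                res.amino_acid = edit.new_amino_acid
            elif kind == "insert":
                if not 0 <= edit.position <= len(chain):
                    raise ProtocolError(
                        f"insertion index {edit.position} out of range on "
                        f"chain {chain.chain_id!r}"
                    )
                memberships = inherited_memberships(
                    chain, edit.position, system,
                    tie_break=getattr(edit, "tie_break", None), rng=rng,
                )
                new_res = Residue(edit.new_amino_acid, mutable=True,
                                  term_memberships=memberships)
                chain.residues.insert(edit.position, new_res)
                delta._applied.append(_AppliedEdit("insert", chain, edit.position))
            elif kind == "delete":
                if len(chain) <= 1:
                    raise ProtocolError(
                        f"deletion would empty chain {chain.chain_id!r}"
                    )
                res = chain.residues[edit.position]
                if not res.mutable:
                    raise ProtocolError(
                        f"deletion targets immutable residue {edit.position} "
                        f"on chain {chain.chain_id!r}"
                    )
                delta._applied.append(
                    _AppliedEdit("delete", chain, edit.position, old_residue=res)
                )
                chain.residues.pop(edit.position)
            else:
                raise ProtocolError(f"unknown move kind {kind!r}")
            delta.chain_ids.add(chain.chain_id)
    except Exception:
        delta.revert()
        raise
    return delta
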