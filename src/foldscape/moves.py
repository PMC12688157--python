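"""Mutation protocols: how sequence space is stepped through.

Two proposal kernels are provided.  ``Canonical`` makes fixed-length
point substitutions: a chain is picked with probability proportional to
its number of mutable residues, ``n_mut`` distinct mutable positions
are drawn without replacement, and each is resampled from a categorical
amino-acid distribution ``p_mut`` (by default uniform over the 19
non-cysteine residues — mutating to cysteine invites stray disulfides).
Substitution may redraw the current amino acid; that self-move keeps
the kernel symmetric, which the Metropolis rule relies on for
Boltzmann sampling.

``GrandCanonical`` adds insertions and deletions, so chain length
itself becomes a sampled quantity, balanced in the energy by a
chemical-potential term.  An insertion picks one of the L+1 gap
indices uniformly; a deletion removes a uniformly chosen mutable
residue, and is never proposed on a chain of length 1.  A newly
inserted residue is mutable and inherits energy-term memberships from
its neighbours: terms carried by both neighbours are inherited, terms
carried by one are inherited with probability 1/2, and non-inheritable
terms (template match) never propagate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AMINO_ACIDS, Chain, MembershipKey, System, inherited_memberships
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

MOVE_TYPES = ("substitution", "addition", "removal")


def default_p_mut() -> dict[str, float]:
    """Uniform over the 20 amino acids except cysteine (probability 0)."""
    aa = [a for a in AMINO_ACIDS if a != "C"]
    return {a: 1.0 / len(aa) for a in aa}


def _normalize_categorical(dist: dict[str, float], domain, label: str):
    letters, probs = [], []
    for key, p in dist.items():
        if key not in domain:
            raise ConfigurationError(f"{label}: unknown category {key!r}")
        if p < 0:
            raise ConfigurationError(f"{label}: negative probability for {key!r}")
        letters.append(key)
        probs.append(float(p))
    total = sum(probs)
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ConfigurationError(f"{label}: probabilities sum to {total}, not 1")
    return letters, np.array(probs) / total


@dataclass
class MutationConfig:
    """Knobs of the canonical point-substitution kernel."""

    n_mut: int = 1
    p_mut: dict[str, float] = field(default_factory=default_p_mut)

    def __post_init__(self) -> None:
        if self.n_mut < 1:
            raise ConfigurationError("n_mut must be >= 1")
        self._letters, self._probs = _normalize_categorical(
            self.p_mut, set(AMINO_ACIDS), "p_mut")

    def sample_amino_acid(self, rng: np.random.Generator) -> str:
        return self._letters[rng.choice(len(self._letters), p=self._probs)]


@dataclass
class GrandCanonicalConfig(MutationConfig):
    """Canonical knobs plus the move-type distribution."""

    p_type: dict[str, float] = field(
        default_factory=lambda: {"substitution": 0.6, "addition": 0.2, "removal": 0.2})

    def __post_init__(self) -> None:
        super().__post_init__()
        self._types, self._type_probs = _normalize_categorical(
            self.p_type, set(MOVE_TYPES), "p_type")

    def sample_move_type(self, rng: np.random.Generator) -> str:
        return self._types[rng.choice(len(self._types), p=self._type_probs)]


@dataclass
class Edit:
    """One atomic sequence edit.

    ``position`` refers to the chain *after* the preceding edits of the
    same proposal have been applied.  ``tie_break`` resolves term
    inheritance for insertions deterministically on (re)application.
    """

    kind: str  # "substitute" | "insert" | "delete"
    chain_id: str
    position: int
    new_amino_acid: str | None = None
    tie_break: float | None = None


@dataclass
class MoveProposal:
    """An ordered list of atomic edits; may be empty if no legal move
    existed for the drawn move types."""

    edits: list[Edit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edits)


class _ShadowChain:
    """Lightweight mutable view used while composing multi-edit moves,
    so later edits see consistent positions and mutability."""

    def __init__(self, chain: Chain):
        self.chain_id = chain.chain_id
        self.mutable = [r.mutable for r in chain.residues]

    def __len__(self) -> int:
        return len(self.mutable)

    @property
    def mutable_count(self) -> int:
        return sum(self.mutable)

    def mutable_positions(self) -> list[int]:
        return [i for i, m in enumerate(self.mutable) if m]


def _pick_chain(shadows: list[_ShadowChain], rng: np.random.Generator) -> _ShadowChain:
    counts = np.array([s.mutable_count for s in shadows], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ConfigurationError("no mutable residues in the system")
    return shadows[rng.choice(len(shadows), p=counts / total)]


def propose_canonical(system: System, config: MutationConfig,
                      rng: np.random.Generator) -> MoveProposal:
    """Fixed-length point-substitution proposal.

    Chain chosen ∝ mutable-residue count; ``n_mut`` distinct mutable
    positions drawn uniformly without replacement; each resampled from
    ``p_mut``.  Chain lengths are untouched.
    """
    shadows = [_ShadowChain(c) for c in system.chains]
    shadow = _pick_chain(shadows, rng)
    positions = shadow.mutable_positions()
    n = config.n_mut
    if n > len(positions):
        logger.info(
            "n_mut=%d exceeds %d mutable residues on chain %s; mutating all",
            n, len(positions), shadow.chain_id)
        n = len(positions)
    chosen = rng.choice(len(positions), size=n, replace=False)
    edits = [
        Edit("substitute", shadow.chain_id, positions[int(i)],
             config.sample_amino_acid(rng))
        for i in sorted(chosen)
    ]
    return MoveProposal(edits=edits)


def propose_grand_canonical(system: System, config: GrandCanonicalConfig,
                            rng: np.random.Generator,
                            max_redraws: int = 10) -> MoveProposal:
    """Substitution/insertion/deletion proposal.

    Each of the ``n_mut`` attempts picks a chain (∝ mutable count),
    draws a move type from ``p_type`` and executes it; a deletion drawn
    on a length-1 chain redraws the move type (up to ``max_redraws``
    times, logged) rather than ever emitting an invalid edit.
    """
    shadows = [_ShadowChain(c) for c in system.chains]
    edits: list[Edit] = []
    for _ in range(config.n_mut):
        if not any(s.mutable_count for s in shadows):
            break  # earlier edits of this proposal consumed every mutable residue
        shadow = _pick_chain(shadows, rng)
        move_type = None
        for attempt in range(max_redraws):
            candidate = config.sample_move_type(rng)
            if candidate == "removal" and (len(shadow) <= 1 or shadow.mutable_count == 0):
                logger.info(
                    "removal drawn but chain %s cannot lose a residue; redrawing",
                    shadow.chain_id)
                continue
            if candidate == "substitution" and shadow.mutable_count == 0:
                continue
            move_type = candidate
            break
        if move_type is None:
            continue  # no legal move for this attempt
        if move_type == "substitution":
            positions = shadow.mutable_positions()
            pos = positions[int(rng.integers(len(positions)))]
            edits.append(Edit("substitute", shadow.chain_id, pos,
                              config.sample_amino_acid(rng)))
        elif move_type == "addition":
            pos = int(rng.integers(len(shadow) + 1))  # L+1 gap indices
            edits.append(Edit("insert", shadow.chain_id, pos,
                              config.sample_amino_acid(rng),
                              tie_break=float(rng.random())))
            shadow.mutable.insert(pos, True)
        else:  # removal
            positions = shadow.mutable_positions()
            pos = positions[int(rng.integers(len(positions)))]
            edits.append(Edit("delete", shadow.chain_id, pos))
            shadow.mutable.pop(pos)
    return MoveProposal(edits=edits)


def inherit_terms(position: int, chain: Chain, system: System,
                  rng: np.random.Generator | None = None,
                  tie_break: float | None = None) -> set[MembershipKey]:
    """Term memberships a residue inserted at ``position`` would adopt.

    Thin public wrapper over the rule the mutation engine applies: both
    neighbours carry the term → inherit; one does → coin flip;
    non-inheritable terms are never inherited.
    """
    return inherited_memberships(chain, position, system,
                                 tie_break=tie_break, rng=rng)
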