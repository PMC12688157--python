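"""Oracle contracts and built-in deterministic toy oracles.

An *oracle* is any black-box function of a tuple of chain sequences
that returns something an energy term can consume: a folding oracle
returns coordinates plus confidence metrics (per-residue pLDDT, scalar
pTM, a PAE matrix), an embedding oracle returns one vector per residue,
a property oracle a single scalar.

Single-chain structure predictors are coaxed into scoring multimers by
concatenating the chains, optionally joined by a flexible linker
(typically poly-glycine) and/or separated by a jump in the positional
indices so the model treats the chains as far apart in primary
structure.  :class:`MultimerEncoding` captures both knobs; linker
residues are always stripped from returned outputs, so downstream code
only ever sees design residues.

The toy oracles are pure functions of the sequence tuple — no model
weights, no randomness — yet respond non-trivially to point mutations,
which is what the samplers and the test-suite need.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, OracleError

#: Default positional-index jump between concatenated chains.
DEFAULT_POSITION_SKIP = 512

#: Upper bound of the predicted-alignment-error scale, in Angstrom.
PAE_MAX = 30.0

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class MultimerEncoding:
    """How a multi-chain State is presented to a single-chain model.

    ``linker`` is inserted between consecutive chains (empty by
    default); ``position_skip`` is added to the positional indices at
    every chain boundary (default 512).  Linker residues never appear
    in oracle outputs.
    """

    linker: str = ""
    position_skip: int = DEFAULT_POSITION_SKIP

    def __post_init__(self) -> None:
        if self.position_skip < 0:
            raise ConfigurationError("position_skip must be >= 0")


@dataclass
class AtomRecord:
    """One heavy atom of a predicted structure (coordinates in A)."""

    element: str
    atom_name: str
    residue_index: int  # 0-based over the State's concatenated residues
    chain_id: str
    xyz: np.ndarray


@dataclass
class FoldOutput:
    """Structure plus confidence set returned by a folding oracle.

    Arrays are indexed over the State's design residues in chain order
    (linker residues stripped).  ``plddt`` entries and ``ptm`` are in
    [0, 1]; ``pae`` entries in [0, ``PAE_MAX``] Angstrom.
    """

    coords: np.ndarray          # (n_atoms, 3)
    atom_names: np.ndarray      # (n_atoms,) str
    elements: np.ndarray        # (n_atoms,) str
    atom_residue_index: np.ndarray  # (n_atoms,) int, 0-based
    atom_chain_ids: np.ndarray  # (n_atoms,) str
    plddt: np.ndarray           # (n_residues,)
    ptm: float
    pae: np.ndarray             # (n_residues, n_residues)

    def __post_init__(self) -> None:
        n = len(self.plddt)
        if self.pae.shape != (n, n):
            raise ConfigurationError(
                f"PAE matrix shape {self.pae.shape} does not match "
                f"{n} residues"
            )
        if not np.all(np.isfinite(self.pae)):
            raise ConfigurationError("PAE matrix contains non-finite entries")

    @property
    def n_residues(self) -> int:
        return len(self.plddt)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(e, a, int(r), c, xyz)
            for e, a, r, c, xyz in zip(
                self.elements, self.atom_names, self.atom_residue_index,
                self.atom_chain_ids, self.coords,
            )
        ]

    def atom_mask(self, residue_indices: Sequence[int],
                  atom_names: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask over atoms selecting the given residues and,
        optionally, only the given atom names."""
        wanted = np.isin(self.atom_residue_index, np.asarray(residue_indices))
        if atom_names is not None:
            wanted &= np.isin(self.atom_names, np.asarray(atom_names))
        return wanted

    def backbone_coords(self, residue_indices: Sequence[int]) -> np.ndarray:
        return self.coords[self.atom_mask(residue_indices, BACKBONE_ATOMS)]


@dataclass
class EmbedOutput:
    """Per-residue embedding vectors (n_residues, n_dim)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ConfigurationError("embedding vectors must be a 2-D array")

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[0]


@dataclass
class PropertyOutput:
    """A single scalar produced by a property oracle."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ConfigurationError("property value must be finite")


@dataclass(frozen=True)
class CacheKey:
    """Exact-match memoization key: oracle, sequences, encoding."""

    oracle_id: str
    sequences: tuple[str, ...]
    encoding: MultimerEncoding


class Oracle(ABC):
    """Base class: memoized mapping from sequence tuples to outputs.

    The cache is a bounded LRU keyed on the exact sequence tuple plus
    encoding parameters.  Monte Carlo trajectories revisit sequences
    constantly (rejections, best-candidate reinstatement), so hit rates
    are high; correctness does not depend on the cache — with caching
    disabled all downstream energies are bit-identical.
    """

    kind: str = "property"

    def __init__(self, oracle_id: str | None = None,
                 encoding: MultimerEncoding | None = None,
                 cache_size: int = 4096):
        self.oracle_id = oracle_id or type(self).__name__
        self.encoding = encoding if encoding is not None else MultimerEncoding()
        self.cache_size = int(cache_size)
        self._cache: OrderedDict[CacheKey, object] = OrderedDict()
        self.cache_hits = 0
        self.cache_misses = 0

    def __call__(self, chains: Sequence[str]):
        sequences = tuple(chains)
        if not sequences or any(len(s) == 0 for s in sequences):
            raise OracleError("oracle input must be non-empty sequences", sequences)
        key = CacheKey(self.oracle_id, sequences, self.encoding)
        if self.cache_size > 0 and key in self._cache:
            self._cache.move_to_end(key)
            self.cache_hits += 1
            return self._cache[key]
        self.cache_misses += 1
        try:
            out = self._compute(sequences)
        except OracleError:
            raise
        except Exception as exc:  # surface adapter failures with the input
            raise OracleError(f"oracle {self.oracle_id!r} failed: {exc}", sequences) from exc
        if self.cache_size > 0:
            self._cache[key] = out
            while len(self._cache) > self.cache_size:
                self._cache.popitem(last=False)
        return out

    def clear_cache(self) -> None:
        self._cache.clear()

    @abstractmethod
    def _compute(self, sequences: tuple[str, ...]):
        ...


class FoldingOracle(Oracle):
    kind = "fold"

    def fold(self, chains: Sequence[str]) -> FoldOutput:
        return self(chains)


class EmbeddingOracle(Oracle):
    kind = "embed"

    def embed(self, chains: Sequence[str]) -> EmbedOutput:
        return self(chains)


class PropertyOracle(Oracle):
    kind = "property"


# -- encoding helpers ----------------------------------------------------


def encoded_positions(lengths: Sequence[int], encoding: MultimerEncoding) -> np.ndarray:
    """Positional indices of the design residues after concatenation.

    Consecutive chains are separated by ``len(linker)`` linker slots
    plus ``position_skip`` skipped indices; linker positions themselves
    are not returned.
    """
    positions: list[int] = []
    pos = 0
    for k, length in enumerate(lengths):
        if k > 0:
            pos += len(encoding.linker) + encoding.position_skip
        for _ in range(length):
            positions.append(pos)
            pos += 1
    return np.asarray(positions, dtype=float)


# -- toy folding oracle --------------------------------------------------

# Kyte-Doolittle hydropathy; a per-letter epsilon keeps all 20 scores
# distinct so that every substitution moves the landscape.
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
_RESIDUE_SCORE = {
    aa: _KD[aa] / 4.5 + 0.013 * i
    for i, aa in enumerate(sorted(_KD))
}

_HELIX_RISE = 1.5       # A per residue
_HELIX_TURN = 100.0     # degrees per residue
_HELIX_RADIUS = 2.3     # A
_CHAIN_SPACING = 12.0   # A between chain helix axes


def _window_scores(sequence: str, window: int = 2) -> np.ndarray:
    """Mean residue score over a +-window neighbourhood."""
    scores = np.array([_RESIDUE_SCORE[aa] for aa in sequence])
    n = len(scores)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        out[i] = scores[lo:hi].mean()
    return out


class ToyFoldOracle(FoldingOracle):
    """Deterministic stand-in for a structure predictor.

    Backbone atoms (N, CA, C, O) are laid on an idealized alpha-helical
    trace per chain (1.5 A rise, 100 deg/residue) whose radius wobbles
    with residue hydropathy, so coordinates are a pure function of the
    sequence.  Per-residue pLDDT is a smooth function of the local
    amino-acid composition, pTM the pLDDT mean, and PAE grows with
    positional separation while shrinking with the pair's confidence.
    Purely synthetic: the numbers carry no biophysical meaning, but the
    landscape responds to every point mutation, which is exactly what
    sampler tests require.
    """

    def __init__(self, oracle_id: str = "toy_fold",
                 encoding: MultimerEncoding | None = None,
                 cache_size: int = 4096):
        super().__init__(oracle_id, encoding, cache_size)

    def _compute(self, sequences: tuple[str, ...]) -> FoldOutput:
        enc = self.encoding
        lengths = [len(s) for s in sequences]
        # score profile over the *encoded* sequence (with linker), then
        # strip linker residues from all outputs
        encoded = enc.linker.join(sequences) if enc.linker else "".join(sequences)
        win = _window_scores(encoded)
        keep = np.ones(len(encoded), dtype=bool)
        if enc.linker:
            pos = 0
            for k, length in enumerate(lengths):
                if k > 0:
                    keep[pos:pos + len(enc.linker)] = False
                    pos += len(enc.linker)
                pos += length
        win = win[keep]

        plddt = 0.5 + 0.5 * np.tanh(0.8 * win)
        plddt = np.clip(plddt, 0.0, 1.0)
        ptm = float(np.clip(np.mean(plddt) * 0.95 + 0.02, 0.0, 1.0))

        positions = encoded_positions(lengths, enc)
        sep = np.abs(positions[:, None] - positions[None, :])
        conf = 0.5 * (plddt[:, None] + plddt[None, :])
        pae = PAE_MAX * (1.0 - 0.9 * conf) * (sep / (sep + 8.0))
        pae = np.clip(pae, 0.0, PAE_MAX)

        coords, names, elements, res_idx, chain_ids = [], [], [], [], []
        offsets = {
            "N": np.array([-1.46, 0.00, -0.40]),
            "C": np.array([1.52, 0.00, 0.45]),
            "O": np.array([1.90, 0.95, 1.20]),
        }
        residue = 0
        for k, seq in enumerate(sequences):
            origin = np.array([_CHAIN_SPACING * k, 0.5 * _CHAIN_SPACING * k, 0.0])
            for j, aa in enumerate(seq):
                theta = np.deg2rad(_HELIX_TURN * j)
                radius = _HELIX_RADIUS + 0.25 * _RESIDUE_SCORE[aa]
                ca = origin + np.array([
                    radius * np.cos(theta), radius * np.sin(theta), _HELIX_RISE * j,
                ])
                rot = np.array([
                    [np.cos(theta), -np.sin(theta), 0.0],
                    [np.sin(theta), np.cos(theta), 0.0],
                    [0.0, 0.0, 1.0],
                ])
                for name in BACKBONE_ATOMS:
                    xyz = ca if name == "CA" else ca + rot @ offsets[name]
                    coords.append(xyz)
                    names.append(name)
                    elements.append(name[0])  # N->N, C->C, O->O, CA->C
                    res_idx.append(residue)
                    chain_ids.append(f"chain{k}")
                residue += 1
        return FoldOutput(
            coords=np.asarray(coords),
            atom_names=np.asarray(names),
            elements=np.asarray(elements),
            atom_residue_index=np.asarray(res_idx),
            atom_chain_ids=np.asarray(chain_ids),
            plddt=plddt,
            ptm=ptm,
            pae=pae,
        )


class ToyEmbeddingOracle(EmbeddingOracle):
    """Deterministic per-residue embeddings of dimension ``n_dim``.

    Each amino acid has a fixed vector (drawn once from a constant-seed
    generator); a residue's embedding blends its own vector with its
    neighbours' so that context matters, mimicking — loosely — what a
    language model does.  Pure function of the sequence tuple.
    """

    def __init__(self, oracle_id: str = "toy_embed", n_dim: int = 8,
                 encoding: MultimerEncoding | None = None,
                 cache_size: int = 4096):
        super().__init__(oracle_id, encoding, cache_size)
        self.n_dim = int(n_dim)
        gen = np.random.default_rng(20_240_101)
        letters = sorted(_KD)
        self._table = {
            aa: gen.normal(size=self.n_dim) for aa in letters
        }

    def _compute(self, sequences: tuple[str, ...]) -> EmbedOutput:
        vectors = []
        for seq in sequences:
            base = np.stack([self._table[aa] for aa in seq])
            for i in range(len(seq)):
                v = 0.6 * base[i]
                if i > 0:
                    v = v + 0.2 * base[i - 1]
                if i < len(seq) - 1:
                    v = v + 0.2 * base[i + 1]
                vectors.append(v)
        return EmbedOutput(vectors=np.stack(vectors))


class SequencePropertyOracle(PropertyOracle):
    """Property oracle wrapping a plain function of the sequences."""

    def __init__(self, func, oracle_id: str = "property", cache_size: int = 4096):
        super().__init__(oracle_id, cache_size=cache_size)
        self._func = func

    def _compute(self, sequences: tuple[str, ...]) -> PropertyOutput:
        return PropertyOutput(value=float(self._func(sequences)))
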