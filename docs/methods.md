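# Methods

This note records the model implemented by `foldscape`, the numerical
and design choices that were genuinely open, what the built-in toy
oracles do and do not emulate, and the known limitations.

## Design objects and energy aggregation

A System holds chains and States; a State scores an ordered subset of
the chains with a weighted sum of energy terms.  The total energy is
the plain sum of State energies, and the per-State / per-term
decomposition is recorded on every evaluation (both the raw term value
ε and the weighted contribution w·ε; the CSV outputs store the
weighted values).  Additivity is exact up to floating-point summation
order; the test suite checks cached totals against from-scratch
recomputation at 1e-9.

Residue indices are 0-based everywhere in the API; structure files use
1-based residue numbering, as the format expects.

Term membership lives on the residues themselves as tags of
(binding, group-slot) pairs, and the residue groups a term sees are
materialized views over those tags.  This makes insertion inheritance a
local decision (look at the two neighbours) and keeps group indices
automatically consistent through insertions and deletions.  A State
with zero chains is rejected at construction.  The same chain object
may appear twice in a State (a homo-oligomer reading); this is allowed
but flagged with a warning, because residue groups then resolve against
the first copy only.

## Oracles

An oracle is a memoized pure function of the tuple of chain sequences.
The cache is an exact-match bounded LRU (default 4096 entries) keyed on
sequences plus encoding parameters; Monte Carlo runs revisit sequences
constantly (rejections, best-candidate reinstatement), so hit rates are
high, and correctness never depends on the cache.  Only States
containing a mutated chain are re-evaluated when computing ΔE; the
other States' energies cannot have changed, so this is mathematically
identical to full re-evaluation.

Multimer encoding follows the usual tricks for single-chain models: an
optional linker sequence between chains and a positional-index skip
(default 512, no linker) that tells the model the chains are far apart
in primary structure.  Linker residues are never part of returned
outputs; adapters for real predictors must state whether their raw PAE
includes linker rows before stripping.

pLDDT is kept on the [0, 1] scale internally; adapters for models
reporting 0–100 should divide by 100.

### Toy oracles

The toy folding oracle places backbone atoms (N, CA, C, O) on an
idealized α-helical trace (1.5 Å rise, 100°/residue) whose radius
wobbles with a per-residue hydropathy score; per-residue pLDDT is a
smooth tanh of the mean hydropathy in a ±2 window (a distinct score
per letter guarantees every substitution moves the landscape), pTM is
an affine function of the pLDDT mean, and PAE grows with positional
separation while shrinking with the pair's confidence, clipped to
[0, 30] Å.  The toy embedding oracle assigns each amino acid a fixed
vector (drawn once from a constant-seed generator) and blends it with
its neighbours'.

These oracles are pure, fast and deterministic, which is what the
sampler machinery and the test suite need.  They do **not** emulate
real structure prediction: coordinates are always near-helical, the
confidence surfaces are smooth single-basin-per-motif functions of
local composition, and there is no notion of packing, sterics or
actual inter-chain interaction.  Passing tests therefore demonstrate
the correctness of the sampling, aggregation and bookkeeping machinery
— not that any designed sequence would fold or bind in reality.
Conclusions about real designs require real oracles behind the same
contract.

## Energy terms

Choices that the formulas leave open:

* **Hydrophobic set** — the strict six residues {V, I, L, F, M, W};
  the mildly hydrophobic extension {Y, C, A, G} is an option, off by
  default.  In SASA-scaled mode each hydrophobic residue contributes
  its mean normalized per-atom SASA instead of 1, which reduces to the
  plain fraction when everything is fully exposed.
* **PAE pairs** — PAE matrices are asymmetric, so the two-group term
  averages both directed blocks (G1→G2 and G2→G1), N_pairs = 2|G1||G2|;
  single-group mode uses all ordered pairs of distinct residues.
  PAE_max defaults to exactly 30.0 Å (configurable).
* **SASA normalization** — SASA_max defaults to the free area of a
  probe-expanded sulfur atom, 4π(1.80 + 1.40)² ≈ 128.68 Å², consistent
  with the kernel's probe-inclusive spheres.
* **Backbone** means {N, CA, C, O} wherever the word appears
  (centroids, globularity, ring symmetry).
* **Template match** — the energy is the *mean squared* atom deviation
  after optimal superposition (the distance-matrix variant is the mean
  squared difference of all pairwise atom distances across the whole
  group, normalized by N(N−1)/2).  Both are exactly zero on rigid
  transforms of the template.  The term is non-inheritable: an
  inserted residue has no template counterpart.
* **Ranges** — hydrophobic, PAE and secondary-structure terms live in
  [0, 1]; the embedding term in [0, 2]; pLDDT and pTM terms in [−1, 0];
  separation, globularity and ring symmetry are in Å and unbounded
  above.

## Geometry kernels

**Shrake–Rupley SASA** samples a golden-spiral point lattice (default
1000 points) on each probe-expanded sphere; a point strictly inside any
other expanded sphere is buried.  Heavy atoms only, with vdW radii
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å and probe 1.4 Å; an unknown
element is an error naming the element.  Because a fixed lattice is
not rotation-covariant, coordinates are first moved into a
deterministic principal-axes frame (signs fixed by the third moment),
making the result exactly invariant under rigid motions of the input;
highly symmetric point sets can still flip axes, which is irrelevant
for molecular structures.  The kernel agrees with an independent
implementation (biotite's, at matched radii, points and frame) to
~1e-5 Å², and monotonicity — adding a neighbour never increases
another atom's area — holds exactly at fixed lattice orientation.

**Optimal superposition** is least-squares rigid alignment (proper
rotations only; reflections corrected) via scipy's Kabsch
implementation, with the RMSD recomputed from the aligned residuals,
which is better conditioned near zero than the solver's residual norm.

**Secondary structure** uses the P-SEA Cα-geometry criteria as
implemented in biotite; residues matching neither helix nor sheet
windows are coil, stretches shorter than five residues are coil, and a
missing Cα yields coil with a warning.

## Mutation protocols

Canonical moves pick a chain with probability proportional to its
mutable-residue count, draw n_mut distinct mutable positions without
replacement, and resample each from p_mut.  The default p_mut is
uniform over the 19 non-cysteine amino acids (cysteine invites stray
disulfides).  Substitutions may redraw the current letter; this
self-move keeps the proposal kernel symmetric under uniform p_mut,
which the Boltzmann-stationarity guarantee of plain Metropolis relies
on.

Grand-canonical moves add insertions (uniform over the L+1 gap
indices; the new residue is mutable and carries only inherited
memberships) and deletions (uniform over mutable residues, never
proposed on a chain of length 1 — a removal drawn there is redrawn,
logged, and an empty proposal is possible if no legal move exists).
Chain selection uses the same mutable-count-proportional rule as the
canonical protocol.  Inheritance: a membership carried by both
neighbours (or the single neighbour at a chain boundary) is inherited;
carried by one, inherited with probability ½ (one coin per insertion,
pre-drawn into the proposal so replay is deterministic);
non-inheritable terms never propagate.

No Metropolis–Hastings proposal correction is applied for the
asymmetry between insertion sites (L+1) and deletion sites (#mutable):
the acceptance rule is plain Metropolis.  Consequently the stationary
distribution of grand-canonical runs carries a mild length-dependent
proposal bias; for optimization (the dominant use) this only reshapes
the search, not the location of minima.  If a deletion empties a group
bound to a term that requires non-empty groups, the term raises a
configuration error at evaluation — failing loudly was preferred to
silently skipping the move.

## Samplers

At T = 0 the Metropolis rule becomes greedy: ΔE ≤ 0 accepted, ΔE > 0
rejected (the T → 0 limit, avoiding the division).  One top-level
seeded generator drives both proposals and acceptance; the seed is
recorded in the optimization log, and identical seeds give identical
trajectories with the toy oracles.  The best System is tracked by
strict improvement (ties do not churn the snapshot) and, when
reinstatement is enabled, the current System is replaced by the best
after the completing step of each interval — for simulated tempering
the default interval n_low + n_high lands this at the end of each hot
phase.  Trajectory row 0 records the initial evaluation as accepted,
before any proposal.

## Validation problem sizes

The stationarity check uses the smallest non-trivial enumerable
landscape (1 chain, length 3, alphabet {A, V}, 8 sequences) with 10⁵
steps at T = 0.5 and a total-variation budget of 0.02; the annealing
check uses a length-10 chain over {A, V} (1024 sequences, exhaustively
enumerated) with 5000-step linear cooling and 20 seeds.  Both complete
in seconds with the toy oracles; the sizes were chosen so the exact
reference (full enumeration) stays cheap while leaving the samplers a
genuinely multi-modal landscape to traverse.

## Known limitations

* Real predictor adapters (structure or embedding models) are a
  contract, not an implementation; nothing in this package validates
  designs against actual folding physics.
* Homo-oligomeric States resolve residue groups against the first copy
  of a repeated chain.
* Grand-canonical stationary distributions carry the proposal
  asymmetry noted above.
* SASA with the canonical-frame convention is exactly rigid-motion
  invariant but can change discontinuously for near-degenerate
  (symmetric) atom clouds as principal axes rotate.
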