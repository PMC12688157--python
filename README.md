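# foldscape

Programmable protein design by Monte Carlo exploration of composable
energy landscapes.

`foldscape` is for protein engineers who want to state a design goal as
an explicit, inspectable objective — "fold confidently", "bind this
target, not that one", "keep this motif rigid", "stay roughly this
long" — and let a gradient-free sampler search sequence space for it.
Because nothing needs to be differentiable, any predictor (a structure
model, a language model, a plain function of the sequence) can sit
behind the objective as a black-box *oracle*.

## The model

A design problem is a **System** Ω = ({C}, {S}): a pool of chains
C_i ∈ 𝒜^{L_i} over the 20-letter amino-acid alphabet, and a set of
**States**.  Each State S names the subset of chains it scores together
and carries weighted energy terms:

    E_Ω = Σ_S E_S,        E_S = Σ_j w_js · ε_js({C}_S)

Chains are shared by identity: a binder chain present in two States has
one sequence, so mutating it moves both State energies at once.  This
is how multi-state problems (selective binding, cross-reactivity) are
posed — a negative weight w_js turns any term into an avoidance term.

Terms ε act on *residue groups* (possibly non-contiguous index sets on
one chain) and consume oracle output: per-residue pLDDT, global pTM and
pairwise PAE matrices from a folding oracle; per-residue embedding
vectors from an embedding oracle; or nothing but the sequence.  The
built-in catalogue covers hydrophobic fraction, chemical potential
(length anchoring), pTM / pLDDT / PAE confidence terms, solvent
accessibility (Shrake–Rupley), centroid separation, globularity,
template match (RMSD and distogram flavours), secondary structure
(P-SEA), N-fold ring symmetry, and embedding cosine similarity.

Sampling is Metropolis Monte Carlo over sequences: a mutation protocol
proposes point substitutions (optionally insertions/deletions in the
grand-canonical protocol, with energy-term inheritance for inserted
residues), and a move with energy change ΔE is accepted with
probability min(1, exp(−ΔE/T)).  Temperature schedules turn the same
loop into simulated annealing (linear cooling), simulated tempering
(cold/hot cycles with best-candidate reinstatement), greedy descent
(T = 0), or equilibrium sampling (constant T) for generating diverse
candidates.

Deterministic **toy oracles** (an idealized-helix folding oracle and a
fixed-table embedding oracle, both pure functions of the sequence) make
every part of the machinery runnable and testable without any deep
learning model; real predictors plug in behind the same one-method
contract, including the usual single-chain-model multimer tricks
(glycine linker, positional-index skip — both handled by the encoding
layer, with linker residues stripped from all outputs).

## Worked example

Annealing a length-10 chain restricted to {A, V} under a whole-chain
pLDDT reward plus a hydrophobic-fraction penalty — small enough that
the true optimum is found by enumerating all 2¹⁰ sequences:

```bash
$ python examples/02_annealing_minimization.py
annealing best energy : -0.654753
annealing best seq    : AAAAAAAAAA
exhaustive minimum    : -0.654753  (AAAAAAAAAA)
```

The sampler's best energy equals the enumerated global minimum: the
cooling schedule funneled the Markov chain into the true optimum of the
1024-sequence landscape.

The other examples tour the remaining capabilities, each printing what
it computes and what the numbers mean:

| script | capability |
| --- | --- |
| `examples/01_selective_binder.py` | two-State selective binder (negative-weight interface PAE) |
| `examples/03_grand_canonical_length.py` | floating chain length under a chemical potential |
| `examples/04_energy_term_tour.py` | geometry kernels on closed-form test cases |
| `examples/05_declarative_run.py` | YAML-configured run with the full output layout |

A thin CLI wraps the declarative path: `foldscape run <config> --out
DIR`, `foldscape validate <config>`, `foldscape score <config>`.  Every
run regenerates `config.csv`, `optimization.log`, and `current/` +
`best/` trees holding per-step energies (`<state>:<Term>` columns),
per-step FASTA (chains joined with `:`) and mmCIF structures with
`.pae`/`.plddt` companion arrays.

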