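"""Run output writers and the declarative run-configuration reader.

A run directory has a fixed layout::

    <root>/
      config.csv            # one row per (State, term): state, energy_term, weight
      optimization.log      # CSV, one row per MC step: step, temperature, accepted, energy
      current/              # the running System
      best/                 # the best System so far (appended per improvement)
        energies.csv        # one row per step, one column per state:Term, plus total
        <state>.fasta       # one entry per step; chains joined with ":"
        structures/         # <State>_<Oracle>_<step>.cif (+ .pae / .plddt text arrays)

Structure files are mmCIF with 1-based residue numbering and the design
chain ids; PAE and pLDDT companions are plain-text numeric arrays
readable with ``numpy.loadtxt``.

``read_run_config`` builds a complete run (System, oracles, protocol,
minimizer) from a YAML document, for users who prefer a declarative
file over a Python script.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

import biotite.structure as struc
import biotite.structure.io.pdbx as pdbx
from biotite.sequence import ProteinSequence

from .core import Chain, EnergyTermBinding, ResidueGroup, State, System
from .energies import TERM_REGISTRY, TemplateStructure
from .errors import ConfigurationError
from .moves import GrandCanonicalConfig, MutationConfig
from .oracles import (EmbedOutput, FoldOutput, MultimerEncoding, Oracle,
                      ToyEmbeddingOracle, ToyFoldOracle)
from .samplers import (ConstantSchedule, MinimizerConfig, RunResult,
                       TrajectoryRecord, annealing_schedule,
                       tempering_schedule)

FASTA_CHAIN_SEPARATOR = ":"


# ----------------------------------------------------------------------
# individual writers
# ----------------------------------------------------------------------


def write_config_csv(system: System, path) -> None:
    """One row per (State, term) with the term's signed weight."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["state", "energy_term", "weight"])
        for state in system.states:
            for binding in state.bindings:
                writer.writerow([state.name, binding.name, repr(binding.weight)])


def read_config_csv(path) -> list[tuple[str, str, float]]:
    """Inverse of :func:`write_config_csv`: (state, term, weight) triples."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((row["state"], row["energy_term"], float(row["weight"])))
    return out


def write_state_fasta(path, state_name: str, step: int,
                      sequences: Sequence[str], energy: float | None = None) -> None:
    """Append one FASTA entry for a minimization step; multi-chain
    States join their chains with ':'."""
    header = f">step={step} state={state_name}"
    if energy is not None:
        header += f" energy={energy:.6g}"
    with open(path, "a") as fh:
        fh.write(header + "\n")
        fh.write(FASTA_CHAIN_SEPARATOR.join(sequences) + "\n")


def parse_state_fasta(path) -> list[tuple[dict, list[str]]]:
    """Read back a per-step FASTA: list of (header fields, chain list)."""
    entries = []
    header: dict | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = dict(
                    kv.split("=", 1) for kv in line[1:].split() if "=" in kv
                )
            else:
                entries.append((header, line.split(FASTA_CHAIN_SEPARATOR)))
    return entries


def energy_columns(system: System) -> list[tuple[str, str]]:
    return [(s.name, b.name) for s in system.states for b in s.bindings]


def write_energies_csv(path, trajectory: Sequence[TrajectoryRecord],
                       columns: Sequence[tuple[str, str]]) -> None:
    """One row per step; headers are '<state>:<TermName>' plus 'total'."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step"] + [f"{s}:{t}" for s, t in columns] + ["total"])
        for rec in trajectory:
            row = [rec.step]
            row += [repr(rec.per_term.get(col, 0.0)) for col in columns]
            row.append(repr(rec.energy))
            writer.writerow(row)


def write_optimization_log(path, trajectory: Sequence[TrajectoryRecord],
                           seed: int | None = None) -> None:
    """CSV with one row per MC step; the RNG seed rides in a comment
    header line so a run can be replayed."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh)
        writer.writerow(["step", "temperature", "accepted", "energy"])
        for rec in trajectory:
            writer.writerow([
                rec.step, repr(rec.temperature),
                "true" if rec.accepted else "false", repr(rec.energy),
            ])


def _fold_to_atom_array(state: State, fold: FoldOutput) -> struc.AtomArray:
    """FoldOutput → biotite AtomArray with design chain ids and 1-based
    residue numbering, ready for mmCIF serialization."""
    n = len(fold.coords)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(fold.coords, dtype=np.float32)
    # oracle chain labels, in order of appearance, map onto State chains
    seen: dict[str, int] = {}
    for cid in fold.atom_chain_ids:
        if cid not in seen:
            seen[cid] = len(seen)
    offsets = {}
    off = 0
    res_names_by_abs = {}
    for k, chain in enumerate(state.chains):
        offsets[k] = off
        for i, aa in enumerate(chain.sequence):
            res_names_by_abs[off + i] = ProteinSequence.convert_letter_1to3(aa).upper()
        off += len(chain)
    chain_ids, res_ids, res_names = [], [], []
    for i in range(n):
        k = seen[str(fold.atom_chain_ids[i])]
        abs_idx = int(fold.atom_residue_index[i])
        chain_ids.append(state.chains[k].chain_id if k < len(state.chains) else str(k))
        res_ids.append(abs_idx - offsets.get(k, 0) + 1)  # 1-based in files
        res_names.append(res_names_by_abs.get(abs_idx, "UNK"))
    # set via full arrays: the default chain_id dtype truncates long ids
    arr.set_annotation("chain_id", np.array(chain_ids))
    arr.set_annotation("res_id", np.array(res_ids, dtype=int))
    arr.set_annotation("res_name", np.array(res_names))
    arr.set_annotation("atom_name", np.array([str(a) for a in fold.atom_names]))
    arr.set_annotation("element", np.array([str(e) for e in fold.elements]))
    arr.hetero[:] = False
    return arr


def write_structure(directory, state: State, fold: FoldOutput,
                    oracle_id: str, step: int) -> Path:
    """Write <State>_<Oracle>_<step>.cif plus .pae/.plddt text arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{state.name}_{oracle_id}_{step}"
    cif_path = directory / f"{stem}.cif"
    cif = pdbx.CIFFile()
    pdbx.set_structure(cif, _fold_to_atom_array(state, fold), data_block=stem)
    cif.write(str(cif_path))
    np.savetxt(directory / f"{stem}.pae", fold.pae, fmt="%.4f")
    np.savetxt(directory / f"{stem}.plddt", fold.plddt, fmt="%.6f")
    return cif_path


def read_structure(path) -> struc.AtomArray:
    """Read a structure file written by :func:`write_structure`."""
    cif = pdbx.CIFFile.read(str(path))
    return pdbx.get_structure(cif, model=1)


# ----------------------------------------------------------------------
# run-directory orchestration
# ----------------------------------------------------------------------


class RunOutputWriter:
    """Callback that regenerates the standard run layout as a run goes.

    Attach to :meth:`MonteCarloMinimizer.run` via ``callbacks``.  The
    ``current/`` tree is appended every step; the ``best/`` tree only
    when the running energy strictly improves.  ``structure_every``
    thins structure output (0 disables it); energies and FASTA are
    always per step.
    """

    def __init__(self, root, system: System, oracles: Mapping[str, Oracle],
                 structure_every: int = 1, seed: int | None = None):
        self.root = Path(root)
        self.system = system
        self.oracles = dict(oracles)
        self.structure_every = structure_every
        self.seed = seed
        self.columns = energy_columns(system)
        self._trajectory: list[TrajectoryRecord] = []
        self._best_energy = float("inf")
        for sub in ("current", "best"):
            (self.root / sub / "structures").mkdir(parents=True, exist_ok=True)
        write_config_csv(system, self.root / "config.csv")
        for sub in ("current", "best"):
            for state in system.states:
                (self.root / sub / f"{state.name}.fasta").write_text("")

    def __call__(self, step: int, system: System, record: TrajectoryRecord) -> None:
        self._trajectory.append(record)
        self._write_tree("current", step, record)
        if record.energy < self._best_energy:
            self._best_energy = record.energy
            self._write_tree("best", step, record)
        write_energies_csv(self.root / "current" / "energies.csv",
                           self._trajectory, self.columns)
        best_records = _best_so_far(self._trajectory)
        write_energies_csv(self.root / "best" / "energies.csv",
                           best_records, self.columns)
        write_optimization_log(self.root / "optimization.log",
                               self._trajectory, seed=self.seed)

    def _write_tree(self, sub: str, step: int, record: TrajectoryRecord) -> None:
        for state in self.system.states:
            write_state_fasta(self.root / sub / f"{state.name}.fasta",
                              state.name, step, state.sequences, record.energy)
            if self.structure_every and step % self.structure_every == 0:
                for oracle_id in {b.oracle_id for b in state.bindings
                                  if b.oracle_id is not None}:
                    oracle = self.oracles.get(oracle_id)
                    if oracle is None or oracle.kind != "fold":
                        continue
                    fold = oracle(state.sequences)  # cache hit during runs
                    write_structure(self.root / sub / "structures",
                                    state, fold, oracle_id, step)


def _best_so_far(trajectory: Sequence[TrajectoryRecord]) -> list[TrajectoryRecord]:
    """Subsequence of records at which the running energy improved."""
    best = float("inf")
    out = []
    for rec in trajectory:
        if rec.energy < best:
            best = rec.energy
            out.append(rec)
    return out


# ----------------------------------------------------------------------
# declarative run configuration
# ----------------------------------------------------------------------


ORACLE_REGISTRY = {
    "ToyFoldOracle": ToyFoldOracle,
    "ToyEmbeddingOracle": ToyEmbeddingOracle,
}


@dataclass
class RunSpec:
    """Everything :func:`read_run_config` assembles from a config file."""

    system: System
    oracles: dict[str, Oracle]
    minimizer: MinimizerConfig


def _parse_residues(spec, chain_length: int, where: str) -> list[int]:
    if spec == "all":
        return list(range(chain_length))
    if isinstance(spec, str):
        indices: list[int] = []
        for part in spec.split(","):
            part = part.strip()
            if "-" in part:
                lo, hi = part.split("-")
                indices.extend(range(int(lo), int(hi) + 1))
            else:
                indices.append(int(part))
        return indices
    if isinstance(spec, list):
        return [int(i) for i in spec]
    raise ConfigurationError(f"{where}: cannot parse residue selection {spec!r}")


def _build_term(entry: dict, where: str):
    name = entry.get("term")
    if name not in TERM_REGISTRY:
        close = difflib.get_close_matches(str(name), TERM_REGISTRY, n=1)
        hint = f"; did you mean {close[0]}?" if close else ""
        raise ConfigurationError(
            f"{where}: unknown energy term {name!r}{hint} "
            f"(available: {', '.join(sorted(TERM_REGISTRY))})")
    params = dict(entry.get("params") or {})
    if name == "TemplateMatchEnergy" and "template_file" in params:
        path = params.pop("template_file")
        params["template"] = TemplateStructure.from_file(
            path, params.get("atom_set", "all_heavy"))
    if name == "EmbeddingsSimilarityEnergy" and "reference_file" in params:
        ref = np.loadtxt(params.pop("reference_file"))
        params["reference"] = EmbedOutput(vectors=np.atleast_2d(ref))
    try:
        return TERM_REGISTRY[name](**params)
    except TypeError as exc:
        raise ConfigurationError(f"{where}: bad parameters for {name}: {exc}") from None


def read_run_config(path) -> RunSpec:
    """Build a full run from a YAML document.

    Sections: ``chains`` (id, sequence, mutability mask), ``states``
    (chains, weighted terms with residue groups and oracle ids),
    ``oracles``, ``protocol`` and ``minimizer``.  Schema violations
    raise with the offending section named.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path!r} is not a mapping")
    for section in ("chains", "states", "minimizer"):
        if section not in doc:
            raise ConfigurationError(f"config missing required section {section!r}")

    chains: dict[str, Chain] = {}
    for entry in doc["chains"]:
        cid = str(entry["id"])
        seq = str(entry["sequence"]).upper()
        mut = entry.get("mutable", True)
        if isinstance(mut, list):
            flags = [False] * len(seq)
            for i in _parse_residues(mut, len(seq), f"chain {cid}"):
                flags[i] = True
            mut = flags
        chains[cid] = Chain(cid, seq, mutable=mut)

    states = []
    for sentry in doc["states"]:
        sname = str(sentry["name"])
        try:
            s_chains = [chains[cid] for cid in sentry["chains"]]
        except KeyError as exc:
            raise ConfigurationError(
                f"state {sname!r}: unknown chain {exc.args[0]!r}") from None
        bindings = []
        for tentry in sentry.get("terms", []):
            where = f"state {sname!r}"
            term = _build_term(tentry, where)
            groups = []
            for gentry in tentry.get("groups", []):
                cid = str(gentry["chain"])
                if cid not in chains:
                    raise ConfigurationError(f"{where}: unknown chain {cid!r} in group")
                groups.append(ResidueGroup(
                    cid, _parse_residues(gentry.get("residues", "all"),
                                         len(chains[cid]), where)))
            bindings.append(EnergyTermBinding(
                term=term,
                weight=float(tentry.get("weight", 1.0)),
                groups=groups,
                oracle_id=tentry.get("oracle"),
                name=tentry.get("name"),
            ))
        states.append(State(sname, s_chains, bindings))

    system = System(list(chains.values()), states)

    oracles: dict[str, Oracle] = {}
    for oid, oentry in (doc.get("oracles") or {}).items():
        otype = oentry.get("type", "ToyFoldOracle")
        if otype not in ORACLE_REGISTRY:
            raise ConfigurationError(
                f"oracle {oid!r}: unknown type {otype!r} "
                f"(available: {', '.join(sorted(ORACLE_REGISTRY))})")
        kwargs = {k: v for k, v in oentry.items() if k not in ("type", "linker",
                                                               "position_skip")}
        if "linker" in oentry or "position_skip" in oentry:
            kwargs["encoding"] = MultimerEncoding(
                linker=oentry.get("linker", ""),
                position_skip=int(oentry.get("position_skip", 512)))
        oracles[oid] = ORACLE_REGISTRY[otype](oracle_id=oid, **kwargs)

    pentry = doc.get("protocol") or {"type": "Canonical"}
    ptype = pentry.get("type", "Canonical")
    pkwargs = {}
    if "n_mut" in pentry:
        pkwargs["n_mut"] = int(pentry["n_mut"])
    if "p_mut" in pentry:
        pkwargs["p_mut"] = {str(k): float(v) for k, v in pentry["p_mut"].items()}
    if ptype == "Canonical":
        protocol = MutationConfig(**pkwargs)
    elif ptype == "GrandCanonical":
        if "p_type" in pentry:
            pkwargs["p_type"] = {str(k): float(v) for k, v in pentry["p_type"].items()}
        protocol = GrandCanonicalConfig(**pkwargs)
    else:
        raise ConfigurationError(
            f"unknown protocol type {ptype!r} (Canonical or GrandCanonical)")

    mentry = doc["minimizer"]
    mtype = mentry.get("type", "MonteCarloMinimizer")
    steps = int(mentry.get("steps", 1000))
    seed = mentry.get("seed")
    n_best = int(mentry.get("n_best_system", 0))
    if mtype in ("MonteCarloMinimizer", "constant"):
        schedule = ConstantSchedule(float(mentry.get("temperature", 1.0)))
    elif mtype == "SimulatedAnnealing":
        schedule = annealing_schedule(
            float(mentry.get("t_init", 1.0)), float(mentry.get("t_final", 0.0)), steps)
    elif mtype == "SimulatedTempering":
        n_low = int(mentry.get("n_low", 1))
        n_high = int(mentry.get("n_high", 1))
        n_cycles = int(mentry.get("n_cycles", 1))
        schedule = tempering_schedule(
            float(mentry.get("t_low", 0.1)), float(mentry.get("t_high", 1.0)),
            n_low, n_high, n_cycles)
        steps = len(schedule)
        if "n_best_system" not in mentry:
            n_best = n_low + n_high
    else:
        raise ConfigurationError(f"unknown minimizer type {mtype!r}")

    minimizer = MinimizerConfig(
        steps=steps, schedule=schedule, protocol=protocol,
        n_best_system=n_best,
        seed=None if seed is None else int(seed))
    return RunSpec(system=system, oracles=oracles, minimizer=minimizer)


def score_run_spec(spec: RunSpec):
    """Single-point energy breakdown of a RunSpec's System (no sampling)."""
    from .samplers import _Evaluator

    evaluator = _Evaluator(spec.system, spec.oracles)
    evaluator.evaluate_all()
    return evaluator.breakdown()


def execute_run(spec: RunSpec, out_dir, structure_every: int = 1) -> RunResult:
    """Run a RunSpec and regenerate the standard output layout."""
    from .samplers import MonteCarloMinimizer

    writer = RunOutputWriter(out_dir, spec.system, spec.oracles,
                             structure_every=structure_every,
                             seed=spec.minimizer.seed)
    return MonteCarloMinimizer(spec.minimizer).run(
        spec.system, spec.oracles, callbacks=[writer])
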