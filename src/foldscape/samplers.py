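"""Monte Carlo engines: the sampling loop, acceptance rule and schedules.

The engine iterates propose → evaluate ΔE → Metropolis accept/reject.
Because only States containing a mutated chain can change energy, ΔE
is computed by re-evaluating exactly those States and reusing cached
values for the rest — mathematically identical to re-evaluating the
whole System, since the other States' chains are untouched.

Three entry points mirror the usual simulated-annealing family:

* :class:`MonteCarloMinimizer` — any temperature schedule (constant by
  default), optionally reinstating the best System found so far every
  ``n_best_system`` steps.
* :class:`SimulatedAnnealing` — linear schedule from ``t_init`` down to
  ``t_final``.
* :class:`SimulatedTempering` — cycles of ``n_low`` steps at ``t_low``
  then ``n_high`` at ``t_high``, starting cold; the best System is
  reinstated at the end of each high-temperature phase.

At T = 0 the Metropolis rule degenerates to greedy descent: ΔE ≤ 0 is
accepted, ΔE > 0 rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import (EnergyBreakdown, State, System, apply_mutation,
                   state_energy)
from .errors import ConfigurationError, FoldscapeError
from .moves import (GrandCanonicalConfig, MutationConfig, MoveProposal,
                    propose_canonical, propose_grand_canonical)
from .oracles import Oracle


# ----------------------------------------------------------------------
# temperature schedules
# ----------------------------------------------------------------------


class TemperatureSchedule:
    """Mapping step index n (0-based proposal index) → temperature ≥ 0."""

    def temperature(self, step: int) -> float:
        raise NotImplementedError

    def __call__(self, step: int) -> float:
        t = self.temperature(step)
        if t < 0:
            raise ConfigurationError(f"schedule produced T={t} < 0 at step {step}")
        return t


@dataclass
class ConstantSchedule(TemperatureSchedule):
    value: float

    def temperature(self, step: int) -> float:
        return self.value


@dataclass
class ExplicitSchedule(TemperatureSchedule):
    """A schedule given as an explicit sequence; clamps to the last
    value if sampled past the end."""

    values: Sequence[float]

    def temperature(self, step: int) -> float:
        if step >= len(self.values):
            return self.values[-1]
        return self.values[step]

    def __len__(self) -> int:
        return len(self.values)


def annealing_schedule(t_init: float, t_final: float, n_steps: int) -> ExplicitSchedule:
    """Linear cooling: T_n = t_init + (t_final − t_init)·n/(n_steps−1),
    with both endpoints exact."""
    if n_steps < 2:
        raise ConfigurationError("annealing schedule needs n_steps >= 2")
    if not (t_init >= t_final >= 0):
        raise ConfigurationError("annealing requires t_init >= t_final >= 0")
    values = [
        t_init + (t_final - t_init) * n / (n_steps - 1) for n in range(n_steps)
    ]
    values[-1] = t_final
    return ExplicitSchedule(values)


def tempering_schedule(t_low: float, t_high: float, n_low: int, n_high: int,
                       n_cycles: int) -> ExplicitSchedule:
    """Cyclic [t_low × n_low, t_high × n_high] repeated n_cycles times,
    always beginning in the low-temperature phase."""
    if min(n_low, n_high, n_cycles) < 1:
        raise ConfigurationError("n_low, n_high and n_cycles must all be >= 1")
    cycle = [t_low] * n_low + [t_high] * n_high
    return ExplicitSchedule(cycle * n_cycles)


# ----------------------------------------------------------------------
# acceptance rule
# ----------------------------------------------------------------------


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion, p = min(1, exp(−ΔE/T)).

    Downhill and flat moves always pass.  At T = 0 the uphill
    acceptance probability is the limit value 0, avoiding the division.
    """
    if temperature < 0:
        raise ConfigurationError("temperature must be >= 0")
    if delta_e <= 0:
        return True
    if temperature == 0:
        return False
    return float(rng.random()) < math.exp(-delta_e / temperature)


# ----------------------------------------------------------------------
# run bookkeeping
# ----------------------------------------------------------------------


@dataclass
class TrajectoryRecord:
    """Per-step bookkeeping row (step 0 is the initial evaluation)."""

    step: int
    temperature: float
    accepted: bool
    energy: float
    per_term: dict[tuple[str, str], float]


@dataclass
class RunResult:
    """What a run returns: the best System encountered, its breakdown,
    the final current System and the full trajectory."""

    best_system: System
    best_energy: float
    best_breakdown: EnergyBreakdown
    final_system: System
    final_energy: float
    trajectory: list[TrajectoryRecord]

    @property
    def best_sequences(self) -> dict[str, str]:
        return {c.chain_id: c.sequence for c in self.best_system.chains}


@dataclass
class MinimizerConfig:
    """Full recipe for one run."""

    steps: int
    schedule: TemperatureSchedule
    protocol: MutationConfig = field(default_factory=MutationConfig)
    n_best_system: int = 0  # 0 disables periodic reinstatement
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ConfigurationError("a run needs at least one step")
        if self.n_best_system < 0:
            raise ConfigurationError("n_best_system must be >= 0")


class _Evaluator:
    """Caches per-State energies and re-evaluates only what changed."""

    def __init__(self, system: System, oracles: Mapping[str, Oracle]):
        self.system = system
        self.oracles = dict(oracles)
        self.state_energy: dict[str, float] = {}
        self.state_terms: dict[str, dict[tuple[str, str], tuple[float, float]]] = {}
        for state in system.states:
            for binding in state.bindings:
                if binding.term.requires is not None and binding.oracle_id not in self.oracles:
                    raise ConfigurationError(
                        f"state {state.name!r}, term {binding.name}: oracle "
                        f"{binding.oracle_id!r} not provided")

    def _outputs_for(self, state: State) -> dict[str, object]:
        needed = {b.oracle_id for b in state.bindings
                  if b.term.requires is not None}
        return {oid: self.oracles[oid](state.sequences) for oid in needed}

    def evaluate_state(self, state: State) -> float:
        outputs = self._outputs_for(state)
        bd = EnergyBreakdown(0.0, {}, {}, {})
        e = state_energy(self.system, state, outputs, breakdown=bd)
        self.state_energy[state.name] = e
        self.state_terms[state.name] = {
            k: (bd.raw_per_term[k], bd.per_term[k]) for k in bd.per_term
        }
        return e

    def evaluate_all(self) -> float:
        return sum(self.evaluate_state(s) for s in self.system.states)

    def reevaluate_states(self, states: Sequence[State]) -> None:
        for s in states:
            self.evaluate_state(s)

    @property
    def total(self) -> float:
        return sum(self.state_energy.values())

    def breakdown(self) -> EnergyBreakdown:
        per_term = {}
        raw = {}
        for terms in self.state_terms.values():
            for key, (r, w) in terms.items():
                raw[key] = r
                per_term[key] = w
        return EnergyBreakdown(
            total=self.total,
            per_state=dict(self.state_energy),
            per_term=per_term,
            raw_per_term=raw,
        )

    def weighted_terms(self) -> dict[tuple[str, str], float]:
        out = {}
        for terms in self.state_terms.values():
            for key, (_, w) in terms.items():
                out[key] = w
        return out


# ----------------------------------------------------------------------
# the engine
# ----------------------------------------------------------------------


class MonteCarloMinimizer:
    """Metropolis Monte Carlo over sequence space.

    ``callbacks`` receive ``(step, system, record)`` after every step
    (including step 0) and are how output writers and observers hook
    into a run without the engine knowing about files.
    """

    def __init__(self, config: MinimizerConfig):
        self.config = config

    def _propose(self, system: System, rng: np.random.Generator) -> MoveProposal:
        protocol = self.config.protocol
        if isinstance(protocol, GrandCanonicalConfig):
            return propose_grand_canonical(system, protocol, rng)
        return propose_canonical(system, protocol, rng)

    def run(self, system: System, oracles: Mapping[str, Oracle],
            callbacks: Sequence[Callable] = ()) -> RunResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        evaluator = _Evaluator(system, oracles)
        current = evaluator.evaluate_all()

        best_energy = current
        best_snapshot = system.snapshot()
        best_breakdown = evaluator.breakdown()

        trajectory: list[TrajectoryRecord] = []
        record = TrajectoryRecord(0, cfg.schedule(0), True, current,
                                  evaluator.weighted_terms())
        trajectory.append(record)
        for cb in callbacks:
            cb(0, system, record)

        for n in range(1, cfg.steps + 1):
            temperature = cfg.schedule(n - 1)
            proposal = self._propose(system, rng)
            if len(proposal) == 0:
                record = TrajectoryRecord(n, temperature, False, current,
                                          evaluator.weighted_terms())
                trajectory.append(record)
                for cb in callbacks:
                    cb(n, system, record)
                continue
            delta = apply_mutation(system, proposal, rng=rng)
            affected = system.states_containing(delta.chain_ids)
            old_entries = {
                s.name: (evaluator.state_energy[s.name],
                         evaluator.state_terms[s.name])
                for s in affected
            }
            try:
                evaluator.reevaluate_states(affected)
            except FoldscapeError:
                delta.revert()
                raise
            proposed = evaluator.total
            accepted = metropolis_accept(proposed - current, temperature, rng)
            if accepted:
                current = proposed
                if current < best_energy:  # strict improvement avoids tie churn
                    best_energy = current
                    best_snapshot = system.snapshot()
                    best_breakdown = evaluator.breakdown()
            else:
                delta.revert()
                for name, (e, terms) in old_entries.items():
                    evaluator.state_energy[name] = e
                    evaluator.state_terms[name] = terms
            record = TrajectoryRecord(n, temperature, accepted, current,
                                      evaluator.weighted_terms())
            trajectory.append(record)
            for cb in callbacks:
                cb(n, system, record)
            if cfg.n_best_system and n % cfg.n_best_system == 0:
                system.restore_chains_from(best_snapshot)
                evaluator.evaluate_all()
                current = evaluator.total

        return RunResult(
            best_system=best_snapshot,
            best_energy=best_energy,
            best_breakdown=best_breakdown,
            final_system=system,
            final_energy=current,
            trajectory=trajectory,
        )


class SimulatedAnnealing(MonteCarloMinimizer):
    """Monte Carlo with a linear cooling schedule."""

    def __init__(self, t_init: float, t_final: float, steps: int,
                 protocol: MutationConfig | None = None,
                 n_best_system: int = 0, seed: int | None = None):
        super().__init__(MinimizerConfig(
            steps=steps,
            schedule=annealing_schedule(t_init, t_final, steps),
            protocol=protocol if protocol is not None else MutationConfig(),
            n_best_system=n_best_system,
            seed=seed,
        ))


class SimulatedTempering(MonteCarloMinimizer):
    """Monte Carlo cycling between a cold and a hot phase.

    Unless overridden, the best System is reinstated every
    ``n_low + n_high`` steps, i.e. at the end of each hot phase.
    """

    def __init__(self, t_low: float, t_high: float, n_low: int, n_high: int,
                 n_cycles: int, protocol: MutationConfig | None = None,
                 n_best_system: int | None = None, seed: int | None = None):
        schedule = tempering_schedule(t_low, t_high, n_low, n_high, n_cycles)
        super().__init__(MinimizerConfig(
            steps=len(schedule),
            schedule=schedule,
            protocol=protocol if protocol is not None else MutationConfig(),
            n_best_system=(n_low + n_high) if n_best_system is None else n_best_system,
            seed=seed,
        ))


def run(system: System, config: MinimizerConfig, oracles: Mapping[str, Oracle],
        callbacks: Sequence[Callable] = ()) -> RunResult:
    """Functional entry point: run a Monte Carlo minimization."""
    return MonteCarloMinimizer(config).run(system, oracles, callbacks)
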