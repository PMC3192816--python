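"""Exact continuous-time (Gillespie) simulation of the coupled multi-lattice
exclusion process with finite tRNA recharging.

Two surfaces:

* a transparent pure-Python layer (:class:`SimulationState`,
  :func:`enabled_events`, :func:`step`) used for unit-level reasoning and
  exact-oracle validation on tiny systems, and
* :func:`run`, the production path, which drives the numba kernel and
  returns a fully populated :class:`~ribotraffic.observables.ObservableSet`.

Both implement the same stochastic semantics: initiation at rate alpha onto
codon 1 when no reader sits within the first w codons; elongation of the
ribosome reading codon j at rate kappa*a_{s(j)} when the reader ahead leaves
a w-gap; termination out of the last codon at rate beta (consuming a
charged tRNA of that codon's species by default); and one aggregated
Michaelis--Menten recharging channel per species at rate V_i b_i/(K_i+b_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernel
from .core import TranslationSystem
from .observables import ObservableSet, assemble

__all__ = [
    "Schedule",
    "SimulationState",
    "Event",
    "EventCatalogue",
    "init_state",
    "enabled_events",
    "step",
    "run",
]


@dataclass(frozen=True)
class Schedule:
    """Burn-in and measurement durations in simulated seconds."""

    burn_in: float
    measure: float
    n_blocks: int = 5
    max_events: int = 500_000_000

    def __post_init__(self):
        if self.measure <= 0:
            raise ValueError("measure time must be positive")
        if self.burn_in < 0 or self.n_blocks < 1:
            raise ValueError("invalid schedule")


class Event(NamedTuple):
    kind: str  # "init" | "elong" | "term" | "recharge"
    lattice: int
    rib: int  # index into the lattice's front-first ribosome list
    species: int  # 0-based tRNA species involved (-1 for init)
    rate: float


@dataclass
class EventCatalogue:
    events: list
    total_rate: float


@dataclass
class SimulationState:
    """Reader positions per lattice (front first) plus the tRNA pools."""

    positions: list  # list of lists of 1-based reader positions, descending
    a: np.ndarray  # charged counts
    b: np.ndarray  # bare counts
    t: float = 0.0

    def n_ribosomes(self) -> int:
        return sum(len(p) for p in self.positions)

    def check_invariants(self, system: TranslationSystem):
        assert np.array_equal(self.a + self.b, system.T), "tRNA conservation violated"
        assert np.all(self.a >= 0) and np.all(self.b >= 0)
        lat = 0
        for m in system.mrnas:
            for _ in range(m.copy_number):
                ps = self.positions[lat]
                assert all(1 <= p <= m.length for p in ps)
                for x, y in zip(ps, ps[1:]):
                    assert x - y >= system.w, "exclusion violated"
                lat += 1


def init_state(system: TranslationSystem) -> SimulationState:
    """All lattices empty, every tRNA charged, clock at zero."""
    return SimulationState(
        positions=[[] for _ in range(system.n_lattices)],
        a=system.T.copy(),
        b=np.zeros(system.n_species, dtype=np.int64),
        t=0.0,
    )


def _lattice_species(system: TranslationSystem):
    out = []
    for r, m in enumerate(system.mrnas):
        out.extend([r] * m.copy_number)
    return out


def enabled_events(system: TranslationSystem, state: SimulationState) -> EventCatalogue:
    """Enumerate every enabled reaction channel with its current rate."""
    events = []
    total = 0.0
    lat_spec = _lattice_species(system)
    inf = system.infinite_recharge
    for l, r in enumerate(lat_spec):
        m = system.mrnas[r]
        ps = state.positions[l]
        if not ps or ps[-1] > system.w:
            events.append(Event("init", l, -1, -1, system.alpha))
            total += system.alpha
        for k, p in enumerate(ps):
            s = int(m.codons[p - 1]) - 1
            if p == m.length:
                if inf or not system.termination_consumes_trna or state.a[s] >= 1:
                    events.append(Event("term", l, k, s, system.beta))
                    total += system.beta
            else:
                clear = k == 0 or ps[k - 1] >= p + 1 + system.w
                avail = system.T[s] if inf else state.a[s]
                if clear and avail >= 1:
                    rate = system.kappa * avail
                    events.append(Event("elong", l, k, s, rate))
                    total += rate
    if not inf:
        for i in range(system.n_species):
            if state.b[i] > 0:
                rate = system.V[i] * state.b[i] / (system.K[i] + state.b[i])
                events.append(Event("recharge", -1, -1, i, rate))
                total += rate
    return EventCatalogue(events, total)


def apply_event(system: TranslationSystem, state: SimulationState, ev: Event):
    if ev.kind == "init":
        state.positions[ev.lattice].append(1)
    elif ev.kind == "elong":
        state.positions[ev.lattice][ev.rib] += 1
        if not system.infinite_recharge:
            assert state.a[ev.species] >= 1
            state.a[ev.species] -= 1
            state.b[ev.species] += 1
    elif ev.kind == "term":
        state.positions[ev.lattice].pop(ev.rib)
        if system.termination_consumes_trna and not system.infinite_recharge:
            assert state.a[ev.species] >= 1
            state.a[ev.species] -= 1
            state.b[ev.species] += 1
    elif ev.kind == "recharge":
        state.b[ev.species] -= 1
        state.a[ev.species] += 1
    else:  # pragma: no cover
        raise ValueError(ev.kind)


def step(system: TranslationSystem, state: SimulationState, rng: np.random.Generator):
    """Advance the state by one sampled event; returns the waiting time."""
    cat = enabled_events(system, state)
    if cat.total_rate <= 0:
        raise ValueError("no enabled events (total rate is zero)")
    dt = rng.exponential(1.0 / cat.total_rate)
    x = rng.uniform(0.0, cat.total_rate)
    acc = 0.0
    chosen = cat.events[-1]
    for ev in cat.events:
        acc += ev.rate
        if acc > x:
            chosen = ev
            break
    apply_event(system, state, chosen)
    state.t += dt
    return state, dt


def _pack(system: TranslationSystem):
    Ls = np.array([m.length for m in system.mrnas], dtype=np.int64)
    seq = np.concatenate([m.codons - 1 for m in system.mrnas]).astype(np.int64)
    seq_off = np.concatenate([[0], np.cumsum(Ls)]).astype(np.int64)
    lat_spec = np.array(_lattice_species(system), dtype=np.int64)
    return lat_spec, seq, seq_off, Ls


def run(system: TranslationSystem, schedule: Schedule, seed: int) -> ObservableSet:
    """Burn in, then measure time-averaged steady-state observables.

    The same seed gives a bit-identical trajectory and ObservableSet.
    """
    lat_spec, seq, seq_off, Ls = _pack(system)
    (occ, hops, term, charge_int, rib_int, consumed, final_pos, final_nrib,
     final_a, final_b, t_final, n_events) = _kernel.run_kernel(
        int(seed) & 0x7FFFFFFF,
        lat_spec,
        seq,
        seq_off,
        Ls,
        system.T.astype(np.int64),
        system.V.astype(np.float64),
        system.K.astype(np.float64),
        float(system.kappa),
        float(system.alpha),
        float(system.beta),
        int(system.w),
        1 if system.termination_consumes_trna else 0,
        1 if system.infinite_recharge else 0,
        float(schedule.burn_in),
        float(schedule.measure),
        int(schedule.n_blocks),
        int(schedule.max_events),
    )
    if n_events >= schedule.max_events:
        raise RuntimeError(
            f"event budget {schedule.max_events} exhausted at t={t_final:.3g}s; "
            "increase max_events or shorten the schedule"
        )
    obs = assemble(system, schedule, seed, occ, hops, term, charge_int, rib_int, consumed)
    obs.blocks["final_state"] = {
        "positions": [
            [int(p) for p in final_pos[l, : final_nrib[l]]] for l in range(lat_spec.size)
        ],
        "a": final_a,
        "b": final_b,
        "lat_spec": lat_spec,
    }
    return obs
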