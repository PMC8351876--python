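"""Stochastic lattice model of transplanted spermatogonial stem-cell clones.

A clone is a set of GFRα1+ syncytial units living on a one-dimensional
periodic lattice (one unit per site), plus an off-lattice pool of ``m``
GFRα1- cells.  Four Poisson processes drive the dynamics:

* *incomplete division* — a unit of length ``k`` becomes length ``2k`` in
  place, at rate ``lambda_div`` per unit;
* *fragmentation and migration* — a unit of length ``k`` fragments at rate
  ``(k - 1) * eta_frag``; each of its ``k - 1`` intercellular bridges breaks
  independently with probability 1/2, one random fragment keeps the original
  site and the others are displaced to random sites within ``±r_range``.
  A displaced fragment landing on an occupied site evicts the occupant,
  whose nuclei differentiate and join the GFRα1- pool;
* *death* — a whole unit is removed at rate ``gamma_loss``, active only
  while ``t < t0_loss_end`` (the initial loss phase);
* *progenitor proliferation* — each GFRα1- cell divides at rate ``mu_prog``
  (a pure-birth process).

Trajectories are generated with an exact stochastic simulation algorithm
(next-event sampling); the piecewise-constant death rate is handled by
treating ``t0_loss_end`` as a barrier that no event jump may cross with the
pre-barrier rate set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SyncytialUnit",
    "CloneState",
    "CloneTrajectory",
    "SeedDistribution",
    "fragment_lengths",
    "event_propensities",
    "PropensityTable",
    "apply_fragmentation",
    "simulate_clone",
    "simulate_ensemble",
]


@dataclass(frozen=True)
class ModelParams:
    """Rates and lattice configuration of the clone model.

    All rates are per day; times are days post-transplantation.  The default
    rate values are placeholders in a biologically plausible regime (division
    and fragmentation elevated relative to homeostasis, a strong initial loss
    phase ending around day 8); only ``t0_loss_end`` has a published
    reference value (~8.1 days).
    """

    lambda_div: float = 0.3        # incomplete division, per unit
    eta_frag: float = 0.45         # fragmentation, per intercellular bridge
    gamma_loss: float = 0.25       # death, per unit, while t < t0_loss_end
    t0_loss_end: float = 8.1       # end of the initial loss phase
    mu_prog: float = 0.25          # proliferation, per GFRα1- cell
    r_range: int = 1               # displacement neighborhood half-width
    t_start: float = 2.0           # simulation start (day of first scoring)
    lattice_sites: int = 10_000    # periodic 1D lattice size
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_div", "eta_frag", "gamma_loss", "mu_prog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t0_loss_end < self.t_start:
            raise ValueError("t0_loss_end must be >= t_start")
        if self.r_range < 1:
            raise ValueError("r_range must be >= 1")
        if self.lattice_sites < 2 * self.r_range + 1:
            raise ValueError("lattice_sites must be >= 2*r_range + 1")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "lambda_div": self.lambda_div,
            "eta_frag": self.eta_frag,
            "gamma_loss": self.gamma_loss,
            "t0_loss_end": self.t0_loss_end,
            "mu_prog": self.mu_prog,
            "r_range": self.r_range,
            "t_start": self.t_start,
            "lattice_sites": self.lattice_sites,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass(frozen=True)
class SyncytialUnit:
    """One GFRα1+ occupant of a lattice site: a syncytium of ``length_k`` nuclei."""

    site: int
    length_k: int

    def __post_init__(self) -> None:
        if self.length_k < 1:
            raise ValueError("length_k must be >= 1")


@dataclass
class CloneState:
    """Snapshot of one clone: on-lattice units plus the GFRα1- pool ``m_prog``."""

    time: float
    units: list[SyncytialUnit]
    m_prog: int = 0

    def __post_init__(self) -> None:
        if self.m_prog < 0:
            raise ValueError("m_prog must be >= 0")
        sites = [u.site for u in self.units]
        if len(sites) != len(set(sites)):
            raise ValueError("two syncytial units occupy the same lattice site")

    @property
    def n_total(self) -> int:
        """Total GFRα1+ nuclei, n = sum_k k * n_k."""
        return sum(u.length_k for u in self.units)

    @property
    def composition(self) -> Counter:
        """Occupation numbers n_k: unit length -> count."""
        return Counter(u.length_k for u in self.units)

    def copy(self) -> "CloneState":
        return CloneState(self.time, list(self.units), self.m_prog)


@dataclass
class CloneTrajectory:
    """One stochastic realization recorded at a fixed set of times.

    ``diff_events`` records every differentiation influx into the GFRα1-
    pool as ``(time, n_cells)`` pairs (evictions during fragmentation plus
    any initial pool), which allows the expected pool size for an arbitrary
    proliferation rate mu to be reconstructed in closed form without
    re-simulation (each influx cohort grows as ``exp(mu * (t - s))`` in
    expectation under the pure-birth dynamics).
    """

    record_times: np.ndarray
    states: list[CloneState]
    params: ModelParams
    realization_seed: object = None
    diff_events: list[tuple[float, int]] = field(default_factory=list)
    m_mode: str = "stochastic"

    def state_at(self, t: float) -> CloneState:
        idx = int(np.searchsorted(self.record_times, t))
        if idx >= len(self.record_times) or self.record_times[idx] != t:
            raise KeyError(f"no snapshot recorded at t={t}")
        return self.states[idx]


# ---------------------------------------------------------------------------
# elementary event mechanics


def fragment_lengths(length_k: int, rng: np.random.Generator) -> list[int]:
    """Draw the fragment lengths produced by one fragmentation event.

    Each of the ``length_k - 1`` intercellular bridges breaks independently
    with probability 1/2; the returned lengths are the maximal runs of
    still-connected nuclei, in order along the syncytium.  A draw that breaks
    no bridge returns the intact syncytium (a real no-op event).
    """
    if length_k < 2:
        raise ValueError("fragmentation requires length_k >= 2 (no bridges otherwise)")
    lengths: list[int] = []
    run = 1
    breaks = rng.random(length_k - 1) < 0.5
    for b in breaks:
        if b:
            lengths.append(run)
            run = 1
        else:
            run += 1
    lengths.append(run)
    return lengths


@dataclass
class PropensityTable:
    """Per-event-class Poisson propensities of a clone state."""

    entries: list[tuple[str, int | None, float]]  # (event class, unit index, rate)

    def class_total(self, kind: str) -> float:
        return sum(rate for k, _, rate in self.entries if k == kind)

    @property
    def division_total(self) -> float:
        return self.class_total("division")

    @property
    def fragmentation_total(self) -> float:
        return self.class_total("fragmentation")

    @property
    def death_total(self) -> float:
        return self.class_total("death")

    @property
    def progenitor_total(self) -> float:
        return self.class_total("progenitor")

    @property
    def total(self) -> float:
        return sum(rate for _, _, rate in self.entries)


def event_propensities(state: CloneState, params: ModelParams) -> PropensityTable:
    """Propensity table for all four event classes at ``state.time``.

    Death is active only before the end of the loss phase.  An empty clone
    (no units, no pool) has total propensity zero and is absorbing.
    """
    entries: list[tuple[str, int | None, float]] = []
    death_on = state.time < params.t0_loss_end
    for i, u in enumerate(state.units):
        if params.lambda_div > 0:
            entries.append(("division", i, params.lambda_div))
        if u.length_k >= 2 and params.eta_frag > 0:
            entries.append(("fragmentation", i, (u.length_k - 1) * params.eta_frag))
        if death_on and params.gamma_loss > 0:
            entries.append(("death", i, params.gamma_loss))
    if state.m_prog > 0 and params.mu_prog > 0:
        entries.append(("progenitor", None, state.m_prog * params.mu_prog))
    return PropensityTable(entries)


def _neighbor_offset(r: int, rng: np.random.Generator) -> int:
    # uniform over the 2r sites within ±r of the origin, origin excluded
    d = int(rng.integers(0, 2 * r))
    return d - r if d < r else d - r + 1


def apply_fragmentation(
    state: CloneState,
    unit: SyncytialUnit,
    params: ModelParams,
    rng: np.random.Generator,
) -> CloneState:
    """Apply one fragmentation-and-migration event and return the new state.

    One uniformly chosen fragment keeps the original site; the others are
    displaced (in uniformly random order) to sites drawn uniformly within
    ``±r_range`` of the origin.  Each displacement onto an occupied site
    differentiates the occupant: its nuclei leave the lattice and join the
    GFRα1- pool.  Total nuclei (on-lattice plus differentiated) are conserved.
    """
    if unit not in state.units:
        raise ValueError("unit is not part of the clone state")
    occ = {u.site: u.length_k for u in state.units}
    m = state.m_prog
    frags = fragment_lengths(unit.length_k, rng)
    occ_new, m_new, _ = _place_fragments(occ, unit.site, frags, m, params, rng, None)
    units = [SyncytialUnit(s, k) for s, k in sorted(occ_new.items())]
    return CloneState(state.time, units, m_new)


def _place_fragments(occ, origin, frags, m, params, rng, diff_events, t=None):
    """Shared placement rule: stay fragment at origin, others displaced.

    Mutates nothing; returns ``(occ, m, n_evicted)`` where ``occ`` is a new
    dict.  ``diff_events`` (if given) collects eviction cohorts as (t, k).
    """
    occ = dict(occ)
    m_add = 0
    if len(frags) == 1:
        return occ, m, 0  # zero-break draw: no-op event
    stay_idx = int(rng.integers(len(frags)))
    displaced = [k for i, k in enumerate(frags) if i != stay_idx]
    occ[origin] = frags[stay_idx]
    order = rng.permutation(len(displaced)) if len(displaced) > 1 else [0]
    L = params.lattice_sites
    for i in order:
        k = displaced[int(i)]
        target = (origin + _neighbor_offset(params.r_range, rng)) % L
        if target in occ:
            k_evicted = occ[target]
            m_add += k_evicted
            if diff_events is not None:
                diff_events.append((t, k_evicted))
        occ[target] = k
    return occ, m + m_add, m_add


# ---------------------------------------------------------------------------
# exact stochastic simulation


def _validate_record_times(record_times, t_start):
    rt = np.asarray(record_times, dtype=float)
    if rt.ndim != 1 or rt.size == 0:
        raise ValueError("record_times must be a non-empty 1D sequence")
    if np.any(np.diff(rt) <= 0):
        raise ValueError("record_times must be strictly increasing")
    if rt[0] < t_start:
        raise ValueError(f"record times must be >= t_start={t_start}")
    return rt


def simulate_clone(
    initial: CloneState,
    params: ModelParams,
    record_times: Sequence[float],
    rng: np.random.Generator,
    m_mode: str = "stochastic",
) -> CloneTrajectory:
    """Simulate one clone exactly and snapshot it at ``record_times``.

    ``m_mode='stochastic'`` simulates the GFRα1- pool as a pure-birth process;
    ``m_mode='off'`` skips proliferation events (the pool then only counts
    differentiated influx; the expectation for any ``mu_prog`` can be
    recovered from ``CloneTrajectory.diff_events``).
    """
    if m_mode not in ("stochastic", "off"):
        raise ValueError("m_mode must be 'stochastic' or 'off'")
    if initial.time != params.t_start:
        raise ValueError("initial state must be at t_start")
    rt = _validate_record_times(record_times, params.t_start)

    occ = {u.site: u.length_k for u in initial.units}
    if len(occ) != len(initial.units):
        raise ValueError("two syncytial units occupy the same lattice site")
    m = initial.m_prog
    diff_events: list[tuple[float, int]] = []
    if m > 0:
        diff_events.append((params.t_start, m))

    lam = params.lambda_div
    eta = params.eta_frag
    gam = params.gamma_loss
    t0 = params.t0_loss_end
    mu = params.mu_prog if m_mode == "stochastic" else 0.0

    t = params.t_start
    U = len(occ)
    K = sum(occ.values())
    snaps: list[CloneState] = []
    idx = 0
    nrec = len(rt)

    def snap(at: float) -> None:
        units = [SyncytialUnit(s, k) for s, k in sorted(occ.items())]
        snaps.append(CloneState(at, units, m))

    while idx < nrec:
        death_on = t < t0
        a_total = lam * U + eta * (K - U) + (gam * U if death_on else 0.0) + mu * m
        if a_total <= 0.0:
            while idx < nrec:
                snap(rt[idx])
                idx += 1
            break
        t_next = t + rng.exponential(1.0 / a_total)
        if death_on and t_next > t0:
            # the loss-phase boundary is a barrier: advance, re-draw
            while idx < nrec and rt[idx] <= t0:
                snap(rt[idx])
                idx += 1
            t = t0
            continue
        while idx < nrec and rt[idx] < t_next:
            snap(rt[idx])
            idx += 1
        if idx >= nrec:
            break
        t = t_next
        u = rng.random() * a_total
        if u < lam * U:
            # incomplete division: k -> 2k in place
            sites = list(occ)
            s = sites[int(rng.integers(U))]
            K += occ[s]
            occ[s] *= 2
        elif u < lam * U + eta * (K - U):
            # fragmentation: weighted by (k - 1)
            w = (u - lam * U) / eta
            acc = 0.0
            s_frag = -1
            for s, k in occ.items():
                acc += k - 1
                if w < acc:
                    s_frag = s
                    break
            if s_frag < 0:  # float round-off guard
                s_frag = max(occ, key=occ.get)
            frags = fragment_lengths(occ[s_frag], rng)
            m_before = m
            occ, m, _ = _place_fragments(occ, s_frag, frags, m, params, rng,
                                         diff_events, t)
            U = len(occ)
            K -= m - m_before
        elif death_on and u < lam * U + eta * (K - U) + gam * U:
            sites = list(occ)
            s = sites[int(rng.integers(U))]
            K -= occ[s]
            del occ[s]
            U -= 1
        else:
            m += 1

    return CloneTrajectory(
        record_times=rt,
        states=snaps,
        params=params,
        diff_events=diff_events,
        m_mode=m_mode,
    )


# ---------------------------------------------------------------------------
# seeding and ensembles


@dataclass
class SeedDistribution:
    """Distribution of initial clone configurations at ``t_start``.

    ``entries`` is a list of ``(weight, composition, m0)`` where
    ``composition`` maps unit length -> count.  The default mixture reflects
    mostly singly isolated cells with a minority of short syncytia at the
    first observation time.
    """

    entries: list[tuple[float, dict[int, int], int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("seed distribution must have at least one entry")
        w = np.array([e[0] for e in self.entries], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be >= 0 and sum to > 0")
        total = w.sum()
        self.entries = [
            (float(wi / total), dict(comp), int(m0))
            for wi, (_, comp, m0) in zip(w, self.entries)
        ]
        self._weights = w / total

    @classmethod
    def default(cls) -> "SeedDistribution":
        return cls([
            (0.72, {1: 1}, 0),   # single A_s
            (0.18, {2: 1}, 0),   # one A_pr
            (0.07, {4: 1}, 0),   # one A_al-4
            (0.03, {1: 2}, 0),   # two separate A_s
        ])

    @classmethod
    def from_observations(cls, observations) -> "SeedDistribution":
        """Empirical distribution over observed (composition, m) records."""
        counts: Counter = Counter()
        for o in observations:
            comp = tuple(sorted((int(k), int(c)) for k, c in o.composition.items()))
            m0 = int(o.m_prog) if o.m_prog is not None else 0
            counts[(comp, m0)] += 1
        if not counts:
            raise ValueError("no observations to build a seed distribution from")
        total = sum(counts.values())
        return cls([
            (c / total, {k: n for k, n in comp}, m0)
            for (comp, m0), c in counts.items()
        ])

    def draw(self, rng: np.random.Generator) -> tuple[dict[int, int], int]:
        i = int(rng.choice(len(self.entries), p=self._weights))
        _, comp, m0 = self.entries[i]
        return dict(comp), m0


def _initial_state(comp: dict[int, int], m0: int, params: ModelParams,
                   rng: np.random.Generator) -> CloneState:
    """Place the initial units on distinct sites in a compact window."""
    n_units = sum(comp.values())
    center = params.lattice_sites // 2
    half = max(2 * params.r_range, 2 * params.r_range * n_units)
    window = np.arange(center - half, center + half + 1) % params.lattice_sites
    sites = rng.choice(window, size=n_units, replace=False) if n_units > 0 else []
    units = []
    i = 0
    for k, c in sorted(comp.items()):
        for _ in range(c):
            units.append(SyncytialUnit(int(sites[i]), int(k)))
            i += 1
    return CloneState(params.t_start, units, m0)


def simulate_ensemble(
    seed_distribution: SeedDistribution,
    params: ModelParams,
    n_realizations: int,
    record_times: Sequence[float],
    seed: int | Sequence[int] | None = None,
    m_mode: str = "stochastic",
) -> list[CloneTrajectory]:
    """Simulate independent clones, each on its own otherwise-empty lattice.

    Per-realization RNG streams are derived deterministically from
    ``(seed, realization index)``, so results are reproducible bit-for-bit
    and independent of evaluation order.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if seed is None:
        seed = params.seed
    root = list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]
    trajectories = []
    for rep in range(n_realizations):
        rng = np.random.default_rng(root + [rep])
        comp, m0 = seed_distribution.draw(rng)
        initial = _initial_state(comp, m0, params, rng)
        traj = simulate_clone(initial, params, record_times, rng, m_mode=m_mode)
        traj.realization_seed = tuple(root + [rep])
        trajectories.append(traj)
    return trajectories
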