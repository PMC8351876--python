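"""Simulation-based parameter fitting and sensitivity analysis.

The fit minimizes a composite log cost built from three residuals between
simulated and observed ensemble statistics at the fit timepoints t_i:

* R1 = sum_i || r_sim(t_i) - r_obs(t_i) ||^2   (syncytial composition),
* R2 = sum_i (1 - <n>_sim(t_i) / <n>_obs(t_i))^2   (persisting clone size),
* R3 = sum_i (S_sim(t_i) - S_obs(t_i))^2   (clone survival),

combined as C = ln R1 + ln R2 + ln R3 (each residual floored at a small
epsilon before the log).  C is minimized over (eta_frag, gamma_loss,
t0_loss_end) with CMA-ES; the incomplete-division rate lambda_div is fixed
independently (measured by live imaging in the source study).  The rates
are optimized in log space to enforce positivity; t0 is optimized linearly.

The GFRα1- pool has no feedback on the lattice dynamics, so the
proliferation rate mu_prog is fitted in a decoupled second stage: the
first-stage trajectories record every differentiation influx, the expected
pool size <m(t)> for any mu follows in closed form, and mu is obtained by
least squares of ln <m(t)>_sim against ln <m(t)>_obs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._cmaes import CMAES
from .model import CloneTrajectory, ModelParams, SeedDistribution, simulate_ensemble
from .observables import (
    DEFAULT_BINS,
    CloneObservation,
    EnsembleStatistics,
    LengthBins,
    compute_statistics,
)

__all__ = [
    "ResidualSet",
    "FitConfig",
    "FitResult",
    "SensitivityGrid",
    "compute_residuals",
    "cost",
    "expected_mean_m",
    "fit_parameters",
    "sensitivity_scan",
]

_T0_SCALE = 5.0  # days per unit of the optimizer's t0 coordinate


@dataclass(frozen=True)
class ResidualSet:
    """The three squared-residual sums entering the cost function."""

    r1: float  # composition
    r2: float  # relative persisting size
    r3: float  # survival

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.r3) < 0:
            raise ValueError("residuals must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r1, self.r2, self.r3)


@dataclass
class FitConfig:
    """Configuration of the CMA-ES fit.

    ``n_realizations`` is the ensemble size per cost evaluation; the
    reference protocol uses 10^4 realizations, the ``reduced()`` profile
    10^3 (adequate for recovery tests at a fraction of the cost).
    ``common_random_numbers`` reuses one ensemble seed for every candidate
    evaluation, making the cost surface deterministic for the optimizer.
    """

    fit_times: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 20.0)
    n_realizations: int = 10_000
    bounds: dict = field(default_factory=lambda: {
        "eta_frag": (0.02, 5.0),
        "gamma_loss": (0.005, 5.0),
        "t0_loss_end": (None, 25.0),  # lower bound defaults to t_start
    })
    mu_bounds: tuple[float, float] = (0.0, 3.0)
    x0: dict | None = None            # optional starting point per parameter
    sigma0: float = 0.6               # initial CMA step in optimizer space
    popsize: int | None = None        # default 4 + 3 ln n
    max_generations: int = 30
    seed: int = 0
    epsilon_floor: float = 1e-12
    common_random_numbers: bool = True
    bins: LengthBins = DEFAULT_BINS

    @classmethod
    def reduced(cls, **overrides) -> "FitConfig":
        """Desk-scale profile: 10^3 realizations, small CMA-ES budget."""
        kw = dict(n_realizations=1000, max_generations=20)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FitResult:
    """Best-fit parameters, cost, and the full evaluation history."""

    eta_frag: float
    gamma_loss: float
    t0_loss_end: float
    mu_prog: float | None
    cost_best: float
    residuals_best: ResidualSet
    history: list[dict]
    seed: int
    n_evaluations: int
    mu_fit_times: tuple[float, ...] = ()

    def best_params(self, fixed: ModelParams) -> ModelParams:
        """The fixed parameter set with the fitted values substituted in."""
        return fixed.replace(
            eta_frag=self.eta_frag,
            gamma_loss=self.gamma_loss,
            t0_loss_end=self.t0_loss_end,
            mu_prog=self.mu_prog if self.mu_prog is not None else fixed.mu_prog,
        )

    def to_dict(self) -> dict:
        return {
            "eta_frag": self.eta_frag,
            "gamma_loss": self.gamma_loss,
            "t0_loss_end": self.t0_loss_end,
            "mu_prog": self.mu_prog,
            "cost_best": self.cost_best,
            "residuals_best": {
                "r1": self.residuals_best.r1,
                "r2": self.residuals_best.r2,
                "r3": self.residuals_best.r3,
            },
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "mu_fit_times": list(self.mu_fit_times),
            "history": self.history,
        }


def compute_residuals(
    sim_stats: EnsembleStatistics,
    obs_stats: EnsembleStatistics,
    fit_times: Sequence[float],
) -> ResidualSet:
    """Residuals between simulated and observed statistics at ``fit_times``.

    Composition vectors are compared on the shared length bins of the two
    statistics objects (they must have been computed with the same binning).
    """
    r1 = r2 = r3 = 0.0
    for t in fit_times:
        if t not in sim_stats.by_time or t not in obs_stats.by_time:
            raise ValueError(f"fit time {t} missing from statistics")
        s, o = sim_stats[t], obs_stats[t]
        if list(s.composition_labels) != list(o.composition_labels):
            raise ValueError("composition bins of sim and obs statistics differ")
        r1 += float(np.sum((s.composition_r - o.composition_r) ** 2))
        if o.mean_n_persisting is None or o.mean_n_persisting == 0:
            raise ValueError(f"observed mean persisting size undefined at t={t}")
        n_sim = s.mean_n_persisting if s.mean_n_persisting is not None else 0.0
        r2 += (1.0 - n_sim / o.mean_n_persisting) ** 2
        r3 += (s.survival - o.survival) ** 2
    return ResidualSet(r1, r2, r3)


def cost(residuals: ResidualSet, epsilon_floor: float = 1e-12) -> float:
    """Composite log cost C = ln R1 + ln R2 + ln R3, residuals floored."""
    e = epsilon_floor
    return (
        math.log(max(residuals.r1, e))
        + math.log(max(residuals.r2, e))
        + math.log(max(residuals.r3, e))
    )


def expected_mean_m(
    trajectories: Sequence[CloneTrajectory],
    mu: float,
    times: Sequence[float],
) -> np.ndarray:
    """Expected GFRα1- pool size <m(t)> for proliferation rate ``mu``.

    Uses the recorded differentiation influx events: a cohort of k cells
    arriving at time s has expected size k * exp(mu * (t - s)) at t under
    the pure-birth dynamics.  Exact in expectation; no re-simulation needed.
    """
    times = np.asarray(times, dtype=float)
    total = np.zeros_like(times)
    for traj in trajectories:
        for s, k in traj.diff_events:
            total += np.where(times >= s, k * np.exp(mu * (times - s)), 0.0)
    return total / len(trajectories)


def _evaluate_cost(
    params: ModelParams,
    seed_dist: SeedDistribution,
    obs_stats: EnsembleStatistics,
    config: FitConfig,
    seed,
) -> tuple[float, ResidualSet, list[CloneTrajectory]]:
    trajs = simulate_ensemble(
        seed_dist, params, config.n_realizations,
        record_times=sorted(config.fit_times), seed=seed, m_mode="off",
    )
    from .observables import trajectories_to_observations
    sim_stats = compute_statistics(
        trajectories_to_observations(trajs), bins=config.bins,
    )
    res = compute_residuals(sim_stats, obs_stats, config.fit_times)
    return cost(res, config.epsilon_floor), res, trajs


def _resolve_bounds(config: FitConfig, fixed: ModelParams):
    lo_eta, hi_eta = config.bounds["eta_frag"]
    lo_gam, hi_gam = config.bounds["gamma_loss"]
    lo_t0, hi_t0 = config.bounds["t0_loss_end"]
    if lo_t0 is None:
        lo_t0 = fixed.t_start
    lo = np.array([math.log(lo_eta), math.log(lo_gam), lo_t0 / _T0_SCALE])
    hi = np.array([math.log(hi_eta), math.log(hi_gam), hi_t0 / _T0_SCALE])
    return lo, hi


def _to_x(eta: float, gamma: float, t0: float) -> np.ndarray:
    return np.array([math.log(eta), math.log(gamma), t0 / _T0_SCALE])


def _from_x(x: np.ndarray) -> tuple[float, float, float]:
    return math.exp(x[0]), math.exp(x[1]), x[2] * _T0_SCALE


def fit_parameters(
    observations: Iterable[CloneObservation],
    fixed: ModelParams,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit (eta_frag, gamma_loss, t0_loss_end) by CMA-ES, then mu_prog.

    ``fixed`` supplies lambda_div (held fixed throughout), the lattice
    configuration, and t_start.  The simulation seed distribution is the
    empirical clone-configuration distribution observed at the earliest fit
    time, so simulated statistics coincide with the data there by
    construction.
    """
    config = config or FitConfig()
    obs = list(observations)
    fit_times = tuple(sorted(config.fit_times))
    have = {o.timepoint for o in obs}
    missing = [t for t in fit_times if t not in have]
    if missing:
        raise ValueError(f"observations missing fit times {missing}")

    obs_stats = compute_statistics(obs, bins=config.bins)
    first = fit_times[0]
    seed_dist = SeedDistribution.from_observations(
        [o for o in obs if o.timepoint == first]
    )

    lo, hi = _resolve_bounds(config, fixed)
    if config.x0:
        x0 = _to_x(config.x0["eta_frag"], config.x0["gamma_loss"],
                   config.x0["t0_loss_end"])
    else:
        x0 = (lo + hi) / 2.0
    es = CMAES(x0, config.sigma0, popsize=config.popsize,
               seed=[config.seed, 101])

    history: list[dict] = []
    best_x = None
    best_cost = math.inf
    best_res = None
    clipped_warned = False
    n_eval = 0
    for gen in range(config.max_generations):
        cands = es.ask()
        fitness = np.empty(len(cands))
        for i, x in enumerate(cands):
            xc = np.clip(x, lo, hi)
            if not clipped_warned and not np.allclose(xc, x):
                warnings.warn("CMA-ES candidate outside bounds; clipped",
                              stacklevel=2)
                clipped_warned = True
            eta, gamma, t0 = _from_x(xc)
            params = fixed.replace(eta_frag=eta, gamma_loss=gamma,
                                   t0_loss_end=t0, mu_prog=0.0)
            if config.common_random_numbers:
                eval_seed = [config.seed, 10007]
            else:
                eval_seed = [config.seed, 1 + gen, i]
            c, res, _ = _evaluate_cost(params, seed_dist, obs_stats, config,
                                       eval_seed)
            n_eval += 1
            fitness[i] = c
            history.append({
                "generation": gen, "index": i,
                "eta_frag": eta, "gamma_loss": gamma, "t0_loss_end": t0,
                "r1": res.r1, "r2": res.r2, "r3": res.r3, "cost": c,
            })
            if c < best_cost:
                best_cost, best_x, best_res = c, xc.copy(), res
        if not np.all(np.isfinite(fitness)):
            raise RuntimeError("non-finite cost encountered during the fit")
        es.tell(fitness)

    eta, gamma, t0 = _from_x(best_x)

    # --- stage 2: mu from the GFRα1- pool means, first-stage params frozen
    best_params = fixed.replace(eta_frag=eta, gamma_loss=gamma,
                                t0_loss_end=t0, mu_prog=0.0)
    _, _, trajs = _evaluate_cost(best_params, seed_dist, obs_stats, config,
                                 [config.seed, 20011])
    obs_mean_m = {}
    for t in fit_times:
        mm = obs_stats[t].mean_m
        if mm is not None and mm > 0:
            obs_mean_m[t] = mm
    if obs_mean_m:
        mu_times = np.array(sorted(obs_mean_m))
        target = np.log([obs_mean_m[t] for t in mu_times])
        eps = config.epsilon_floor

        def mu_objective(mu: float) -> float:
            sim = expected_mean_m(trajs, mu, mu_times)
            return float(np.sum((np.log(np.maximum(sim, eps)) - target) ** 2))

        opt = minimize_scalar(mu_objective, bounds=config.mu_bounds,
                              method="bounded",
                              options={"xatol": 1e-4})
        mu = float(opt.x)
    else:
        mu, mu_times = None, np.array([])

    return FitResult(
        eta_frag=eta, gamma_loss=gamma, t0_loss_end=t0, mu_prog=mu,
        cost_best=best_cost, residuals_best=best_res, history=history,
        seed=config.seed, n_evaluations=n_eval,
        mu_fit_times=tuple(float(t) for t in mu_times),
    )


_PAIR_KEYS = {"eta_frag", "gamma_loss", "t0_loss_end"}


@dataclass
class SensitivityGrid:
    """Cost surface over fractional parameter offsets around a best fit.

    ``grids[(p, q)][i, j]`` is the cost with parameter p scaled by
    ``1 + offsets[i]`` and q by ``1 + offsets[j]``, the third parameter held
    at its best-fit value.  Cells whose parameters violate model invariants
    are NaN.  Adjacent contours at spacing ``contour_delta = ln 2``
    correspond to a doubling of the residual product.
    """

    offsets: np.ndarray
    grids: dict[tuple[str, str], np.ndarray]
    center: dict[str, float]
    contour_delta: float = math.log(2.0)

    @property
    def cost_min(self) -> float:
        return float(np.nanmin([np.nanmin(g) for g in self.grids.values()]))

    def contour_levels(self, n: int = 5) -> np.ndarray:
        return self.cost_min + self.contour_delta * np.arange(1, n + 1)

    def to_frame(self):
        import pandas as pd

        rows = []
        for (p, q), g in self.grids.items():
            for i, oi in enumerate(self.offsets):
                for j, oj in enumerate(self.offsets):
                    rows.append({
                        "param_row": p, "param_col": q,
                        "offset_row": oi, "offset_col": oj,
                        "cost": g[i, j],
                    })
        return pd.DataFrame(rows)


def sensitivity_scan(
    observations: Iterable[CloneObservation],
    best: ModelParams,
    config: FitConfig | None = None,
    offsets: Sequence[float] | None = None,
    pairs: Sequence[tuple[str, str]] = (
        ("eta_frag", "gamma_loss"),
        ("eta_frag", "t0_loss_end"),
        ("gamma_loss", "t0_loss_end"),
    ),
) -> SensitivityGrid:
    """Map the cost over +/-75% fractional offsets of the fitted parameters.

    ``best`` carries the best-fit (or reference) parameter values; each
    pairwise grid varies two parameters multiplicatively while the third is
    held fixed.  A cell that would violate a model invariant (e.g. the loss
    phase ending before the simulation starts) is marked NaN rather than
    failing the scan.
    """
    config = config or FitConfig()
    obs = list(observations)
    obs_stats = compute_statistics(obs, bins=config.bins)
    fit_times = tuple(sorted(config.fit_times))
    seed_dist = SeedDistribution.from_observations(
        [o for o in obs if o.timepoint == fit_times[0]]
    )
    if offsets is None:
        offsets = np.linspace(-0.75, 0.75, 7)
    offsets = np.asarray(offsets, dtype=float)

    grids: dict[tuple[str, str], np.ndarray] = {}
    for p, q in pairs:
        if p not in _PAIR_KEYS or q not in _PAIR_KEYS:
            raise ValueError(f"unknown parameter pair ({p}, {q})")
        g = np.full((offsets.size, offsets.size), np.nan)
        for i, oi in enumerate(offsets):
            for j, oj in enumerate(offsets):
                values = {
                    "eta_frag": best.eta_frag,
                    "gamma_loss": best.gamma_loss,
                    "t0_loss_end": best.t0_loss_end,
                }
                values[p] = values[p] * (1 + oi)
                values[q] = values[q] * (1 + oj)
                try:
                    params = best.replace(mu_prog=0.0, **values)
                except ValueError:
                    continue  # invalid cell stays NaN
                c, _, _ = _evaluate_cost(
                    params, seed_dist, obs_stats, config, [config.seed, 30013],
                )
                g[i, j] = c
        grids[(p, q)] = g
    return SensitivityGrid(
        offsets=offsets,
        grids=grids,
        center={
            "eta_frag": best.eta_frag,
            "gamma_loss": best.gamma_loss,
            "t0_loss_end": best.t0_loss_end,
        },
    )
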