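"""Tests of residuals, cost, the CMA-ES core, and small fits."""

import math

import numpy as np
import pytest

from sscclone import (
    FitConfig,
    ModelParams,
    ResidualSet,
    StudyDesign,
    compute_residuals,
    cost,
    expected_mean_m,
    fit_parameters,
    generate_dataset,
)
from sscclone._cmaes import CMAES
from sscclone.inference import _evaluate_cost
from sscclone.io import table_to_observations
from sscclone.model import CloneTrajectory, SeedDistribution
from sscclone.observables import EnsembleStatistics, LengthBins, TimepointStatistics

BINS2 = LengthBins((("A_s", 1, 1), ("A_pr", 2, None)))


def _stats(per_time):
    """Build an EnsembleStatistics from {t: (r_vec, mean_n, S)}."""
    by_time = {}
    for t, (r, n, s) in per_time.items():
        by_time[t] = TimepointStatistics(
            timepoint=t, n_clones=100, survival=s, mean_n_persisting=n,
            size_values=None, size_cdf=None, mean_m=None,
            composition_labels=BINS2.labels, composition_r=np.asarray(r, float),
        )
    return EnsembleStatistics(by_time=by_time, bins=BINS2)


def test_residuals_zero_on_identical_statistics():
    s = _stats({2.0: ([0.6, 0.4], 3.0, 0.5)})
    assert compute_residuals(s, s, [2.0]).as_tuple() == (0.0, 0.0, 0.0)


def test_residuals_forced_arithmetic():
    sim = _stats({2.0: ([0.6, 0.4], 3.0, 0.4)})
    obs = _stats({2.0: ([0.5, 0.5], 4.0, 0.5)})
    res = compute_residuals(sim, obs, [2.0])
    assert res.r1 == pytest.approx(0.02)
    assert res.r2 == pytest.approx(0.0625)
    assert res.r3 == pytest.approx(0.01)


def test_residuals_add_over_timepoints():
    sim = _stats({2.0: ([0.6, 0.4], 3.0, 0.4), 6.0: ([0.6, 0.4], 3.0, 0.4)})
    obs = _stats({2.0: ([0.5, 0.5], 4.0, 0.5), 6.0: ([0.5, 0.5], 4.0, 0.5)})
    res = compute_residuals(sim, obs, [2.0, 6.0])
    assert res.as_tuple() == pytest.approx((0.04, 0.125, 0.02))


def test_residuals_missing_time_or_zero_reference():
    sim = _stats({2.0: ([0.6, 0.4], 3.0, 0.4)})
    obs = _stats({2.0: ([0.5, 0.5], 4.0, 0.5)})
    with pytest.raises(ValueError):
        compute_residuals(sim, obs, [2.0, 6.0])
    obs_zero = _stats({2.0: ([0.5, 0.5], None, 0.5)})
    with pytest.raises(ValueError):
        compute_residuals(sim, obs_zero, [2.0])


def test_negative_residuals_rejected():
    with pytest.raises(ValueError):
        ResidualSet(-0.1, 0.0, 0.0)


def test_cost_examples():
    assert cost(ResidualSet(1, 1, 1)) == 0.0
    c = cost(ResidualSet(0.02, 0.0625, 0.01))
    assert c == pytest.approx(math.log(0.02) + math.log(0.0625) + math.log(0.01))
    assert c == pytest.approx(-11.29, abs=0.005)
    assert cost(ResidualSet(0.0, 1, 1), epsilon_floor=1e-12) == pytest.approx(
        math.log(1e-12))


def test_cost_shifts_by_3_log_c_under_scaling():
    base = ResidualSet(0.3, 0.07, 0.011)
    for c_scale in (0.5, 2.0, 10.0):
        scaled = ResidualSet(*(c_scale * r for r in base.as_tuple()))
        assert cost(scaled) - cost(base) == pytest.approx(3 * math.log(c_scale))


def test_expected_mean_m_closed_form():
    params = ModelParams()
    traj_a = CloneTrajectory(np.array([2.0]), [], params,
                             diff_events=[(3.0, 2), (5.0, 1)])
    traj_b = CloneTrajectory(np.array([2.0]), [], params, diff_events=[])
    got = expected_mean_m([traj_a, traj_b], mu=0.5, times=[4.0, 10.0])
    exp_t4 = 2 * math.exp(0.5 * 1.0) / 2
    exp_t10 = (2 * math.exp(0.5 * 7.0) + 1 * math.exp(0.5 * 5.0)) / 2
    assert got == pytest.approx([exp_t4, exp_t10])


# ---------------------------------------------------------------------------
# the CMA-ES core


def test_cmaes_minimizes_quadratic():
    target = np.array([1.5, -2.0, 0.5])
    es = CMAES(np.zeros(3), sigma0=1.0, seed=4)
    for _ in range(60):
        xs = es.ask()
        es.tell([float(np.sum((x - target) ** 2)) for x in xs])
    assert es.mean == pytest.approx(target, abs=1e-3)


def test_cmaes_handles_anisotropic_scaling():
    es = CMAES([3.0, 3.0], sigma0=1.0, seed=8)
    for _ in range(80):
        xs = es.ask()
        es.tell([float(100 * x[0] ** 2 + x[1] ** 2) for x in xs])
    assert np.allclose(es.mean, 0.0, atol=1e-3)


def test_cmaes_is_deterministic_for_fixed_seed():
    a = CMAES([0.0, 0.0], 0.5, seed=3)
    b = CMAES([0.0, 0.0], 0.5, seed=3)
    for _ in range(5):
        xa, xb = a.ask(), b.ask()
        assert np.array_equal(xa, xb)
        f = [float(np.sum(x ** 2)) for x in xa]
        a.tell(f)
        b.tell(f)
    assert np.array_equal(a.mean, b.mean)


# ---------------------------------------------------------------------------
# end-to-end fitting plumbing (tiny budgets; accuracy is covered by the
# recovery test in the acceptance suite)


def _tiny_dataset():
    truth = ModelParams(seed=0)
    design = StudyDesign(truth=truth, harvest_times=(2.0, 6.0, 10.0),
                         clones_per_time=60, seed=17)
    table, _ = generate_dataset(design)
    return table_to_observations(table), truth


def _tiny_config(**kw):
    base = dict(fit_times=(2.0, 6.0, 10.0), n_realizations=80,
                max_generations=2, popsize=4, seed=13)
    base.update(kw)
    return FitConfig(**base)


def test_fit_is_deterministic_for_fixed_seeds():
    obs, truth = _tiny_dataset()
    fixed = truth.replace(mu_prog=0.0)
    a = fit_parameters(obs, fixed, _tiny_config())
    b = fit_parameters(obs, fixed, _tiny_config())
    assert a.to_dict() == b.to_dict()


def test_fit_requires_all_fit_times():
    obs, truth = _tiny_dataset()
    with pytest.raises(ValueError, match="missing fit times"):
        fit_parameters(obs, truth, _tiny_config(fit_times=(2.0, 6.0, 14.0)))


def test_fit_history_records_every_evaluation():
    obs, truth = _tiny_dataset()
    res = fit_parameters(obs, truth, _tiny_config())
    assert res.n_evaluations == 2 * 4
    assert len(res.history) == res.n_evaluations
    best_in_history = min(h["cost"] for h in res.history)
    assert res.cost_best == pytest.approx(best_in_history)
    assert res.mu_prog is not None and 0 <= res.mu_prog <= 3


def test_monte_carlo_noise_shrinks_with_ensemble_size():
    """The s.d. of repeated cost evaluations at a fixed off-center parameter
    cell scales roughly as 1/sqrt(n_realizations)."""
    obs, truth = _tiny_dataset()
    from sscclone.observables import compute_statistics

    cfg_small = _tiny_config(n_realizations=150)
    cfg_big = _tiny_config(n_realizations=600)
    obs_stats = compute_statistics(obs, bins=cfg_small.bins)
    seed_dist = SeedDistribution.from_observations(
        [o for o in obs if o.timepoint == 2.0])
    # offset both rates so every residual has a dominant systematic part;
    # only then does sd(ln R) follow the 1/sqrt(n) Monte-Carlo scaling
    cell = truth.replace(eta_frag=truth.eta_frag * 1.75,
                         gamma_loss=truth.gamma_loss * 1.75, mu_prog=0.0)
    c_small = [_evaluate_cost(cell, seed_dist, obs_stats, cfg_small, [s, 1])[0]
               for s in range(20)]
    c_big = [_evaluate_cost(cell, seed_dist, obs_stats, cfg_big, [s, 1])[0]
             for s in range(20)]
    ratio = np.std(c_big) / np.std(c_small)
    # expectation 1/2 at 4x the realizations; wide band for 20 replicates
    assert 0.3 < ratio < 0.9
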