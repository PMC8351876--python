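"""Unit and property tests of the lattice clone simulator."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sscclone import (
    CloneState,
    ModelParams,
    SeedDistribution,
    SyncytialUnit,
    apply_fragmentation,
    event_propensities,
    fragment_lengths,
    simulate_clone,
    simulate_ensemble,
)


# ---------------------------------------------------------------------------
# parameter validation


@pytest.mark.parametrize("bad", [
    {"lambda_div": -0.1},
    {"eta_frag": -1.0},
    {"gamma_loss": -0.5},
    {"mu_prog": -0.2},
    {"t0_loss_end": 1.0},          # before t_start=2
    {"r_range": 0},
    {"lattice_sites": 2, "r_range": 1},
])
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        ModelParams(**bad)


def test_clone_state_rejects_shared_site():
    with pytest.raises(ValueError):
        CloneState(2.0, [SyncytialUnit(5, 1), SyncytialUnit(5, 2)])


# ---------------------------------------------------------------------------
# fragmentation draws


def test_fragment_lengths_requires_a_bridge(rng):
    with pytest.raises(ValueError):
        fragment_lengths(1, rng)


@given(st.integers(min_value=2, max_value=32), st.integers(min_value=0, max_value=2**31))
@settings(max_examples=200, deadline=None)
def test_fragment_lengths_partition_the_syncytium(k, seed):
    lengths = fragment_lengths(k, np.random.default_rng(seed))
    assert sum(lengths) == k
    assert all(f >= 1 for f in lengths)


def test_pair_splits_with_probability_half(rng):
    n = 10_000
    splits = sum(fragment_lengths(2, rng) == [1, 1] for _ in range(n))
    se = (0.25 / n) ** 0.5
    assert abs(splits / n - 0.5) < 3 * se


def _enumerated_fragment_count_dist(k):
    """Oracle: exhaustive enumeration of the 2^(k-1) bridge break patterns."""
    counts = Counter()
    for pattern in itertools.product([0, 1], repeat=k - 1):
        counts[1 + sum(pattern)] += 1
    total = 2 ** (k - 1)
    return {n: c / total for n, c in counts.items()}


def test_quad_fragment_statistics(rng):
    """A 4-chain has 2^3 equally likely break patterns: mean 2.5 fragments,
    all-singles probability 1/8."""
    dist = _enumerated_fragment_count_dist(4)
    assert sum(n * p for n, p in dist.items()) == pytest.approx(2.5)
    assert dist[4] == pytest.approx(1 / 8)
    n = 10_000
    draws = Counter(len(fragment_lengths(4, rng)) for _ in range(n))
    for frags, p in dist.items():
        se = (p * (1 - p) / n) ** 0.5
        assert abs(draws[frags] / n - p) < 4 * se


# ---------------------------------------------------------------------------
# propensities


def _state(lengths, m=0, t=2.0, spacing=3):
    units = [SyncytialUnit(100 + spacing * i, k) for i, k in enumerate(lengths)]
    return CloneState(t, units, m)


def test_propensities_hand_summed():
    p = ModelParams(lambda_div=0.3, eta_frag=0.5, gamma_loss=0.2,
                    t0_loss_end=8.0, mu_prog=0.4)
    state = _state([1, 2, 4], m=3, t=5.0)
    table = event_propensities(state, p)
    assert table.division_total == pytest.approx(3 * 0.3)
    assert table.fragmentation_total == pytest.approx((0 + 1 + 3) * 0.5)
    assert table.death_total == pytest.approx(3 * 0.2)
    assert table.progenitor_total == pytest.approx(3 * 0.4)
    assert table.total == pytest.approx(0.9 + 2.0 + 0.6 + 1.2)


def test_death_channel_off_after_loss_phase():
    p = ModelParams(gamma_loss=0.2, t0_loss_end=8.0)
    state = _state([1, 2, 4], m=3, t=9.0)
    assert event_propensities(state, p).death_total == 0.0


def test_empty_clone_is_absorbing():
    state = CloneState(5.0, [], 0)
    assert event_propensities(state, ModelParams()).total == 0.0


# ---------------------------------------------------------------------------
# fragmentation event mechanics


def test_fragmentation_conserves_nuclei_and_site_uniqueness(rng):
    """Over many repeated events, on-lattice plus differentiated nuclei are
    conserved exactly and no two units ever share a site."""
    p = ModelParams()
    for _ in range(2000):
        k = int(rng.integers(2, 9))
        neighbors = [SyncytialUnit(500 + d, int(rng.integers(1, 4)))
                     for d in (-1, 1) if rng.random() < 0.5]
        state = CloneState(3.0, [SyncytialUnit(500, k)] + neighbors, m_prog=2)
        before = state.n_total + state.m_prog
        new = apply_fragmentation(state, state.units[0], p, rng)
        assert new.n_total + new.m_prog == before
        sites = [u.site for u in new.units]
        assert len(sites) == len(set(sites))


def test_fragmentation_on_empty_lattice_keeps_all_on_lattice(rng):
    """Without neighbors inside ±r, nothing differentiates: m stays put."""
    p = ModelParams()
    state = CloneState(3.0, [SyncytialUnit(500, 2)], m_prog=0)
    saw_split = False
    for _ in range(200):
        new = apply_fragmentation(state, state.units[0], p, rng)
        assert new.m_prog == 0
        assert new.n_total == 2
        if len(new.units) == 2:
            saw_split = True
            assert {u.length_k for u in new.units} == {1}
    assert saw_split


def test_fragmentation_eviction_moves_occupant_off_lattice(rng):
    """A displaced fragment landing on an occupied site differentiates the
    occupant: its nucleus joins the GFRα1- pool, unit count is unchanged."""
    p = ModelParams(r_range=1)
    state = CloneState(3.0, [SyncytialUnit(500, 2), SyncytialUnit(501, 1)], 0)
    saw_eviction = False
    for _ in range(400):
        new = apply_fragmentation(state, state.units[0], p, rng)
        assert new.n_total + new.m_prog == 3
        if new.m_prog == 1:
            saw_eviction = True
            assert len(new.units) == 2
    assert saw_eviction


def test_fragmentation_requires_member_unit(rng):
    state = CloneState(3.0, [SyncytialUnit(500, 2)], 0)
    with pytest.raises(ValueError):
        apply_fragmentation(state, SyncytialUnit(7, 2), ModelParams(), rng)


# ---------------------------------------------------------------------------
# trajectories


def test_record_times_validated(rng):
    p = ModelParams()
    init = CloneState(2.0, [SyncytialUnit(500, 1)], 0)
    with pytest.raises(ValueError):
        simulate_clone(init, p, [1.0, 5.0], rng)
    with pytest.raises(ValueError):
        simulate_clone(init, p, [5.0, 5.0], rng)
    with pytest.raises(ValueError):
        simulate_clone(init, p, [], rng)


def test_snapshots_at_requested_times(rng):
    p = ModelParams()
    init = CloneState(2.0, [SyncytialUnit(500, 1)], 0)
    times = [2.0, 4.5, 9.0, 20.0]
    traj = simulate_clone(init, p, times, rng)
    assert [s.time for s in traj.states] == times
    assert traj.states[0].composition == Counter({1: 1})


def test_frozen_dynamics_is_constant(single_as_seed):
    p = ModelParams(lambda_div=0, eta_frag=0, gamma_loss=0, mu_prog=0)
    trajs = simulate_ensemble(single_as_seed, p, 50, [2, 10, 30], seed=5)
    for traj in trajs:
        for s in traj.states:
            assert dict(s.composition) == {1: 1}
            assert s.m_prog == 0


def test_ensemble_reproducible_bit_for_bit(default_params, single_as_seed):
    a = simulate_ensemble(single_as_seed, default_params, 100, [2, 6, 12], seed=9)
    b = simulate_ensemble(single_as_seed, default_params, 100, [2, 6, 12], seed=9)
    for ta, tb in zip(a, b):
        for sa, sb in zip(ta.states, tb.states):
            assert sa.composition == sb.composition
            assert sa.m_prog == sb.m_prog
            assert [u.site for u in sa.units] == [u.site for u in sb.units]


def test_empty_seed_distribution_rejected():
    with pytest.raises(ValueError):
        SeedDistribution([])


def test_ensemble_needs_a_realization(default_params, single_as_seed):
    with pytest.raises(ValueError):
        simulate_ensemble(single_as_seed, default_params, 0, [2.0], seed=1)


def test_site_exclusivity_throughout(default_params, single_as_seed):
    trajs = simulate_ensemble(single_as_seed, default_params, 200,
                              [2, 6, 10, 20], seed=11)
    for traj in trajs:
        for s in traj.states:
            sites = [u.site for u in s.units]
            assert len(sites) == len(set(sites))


def test_division_doubles_in_place(rng):
    """With only division active, a single unit stays a single unit whose
    length is a power of two."""
    p = ModelParams(lambda_div=0.4, eta_frag=0, gamma_loss=0, mu_prog=0)
    init = CloneState(2.0, [SyncytialUnit(500, 1)], 0)
    for seed in range(30):
        traj = simulate_clone(init.copy(), p, [2, 10, 20],
                              np.random.default_rng(seed))
        for s in traj.states:
            assert len(s.units) == 1
            k = s.units[0].length_k
            assert k & (k - 1) == 0  # power of two
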