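"""Simulators: MSD law, scenario mechanics, label invariants, datasets."""

import numpy as np
import pytest

from diffpoint.simulate import (
    LabelSeries,
    SimConfig,
    build_dataset,
    finalize_labels,
    markov_state_sequence,
    simulate_dim,
    simulate_msm,
    simulate_qtm,
    simulate_segment,
    simulate_ssm,
    simulate_tcm,
    simulate_two_segment,
)

DIRECTED_ALPHA = 1.9


def check_label_invariants(lab: LabelSeries):
    T = len(lab)
    assert np.all((lab.alpha >= 0) & (lab.alpha <= 2))
    assert np.all((lab.K >= 0) & (lab.K <= 1e6))
    assert np.all((lab.state >= 0) & (lab.state <= 3))
    # state/alpha consistency
    assert np.all(lab.alpha[lab.state == 0] == 0)
    assert np.all(lab.alpha[lab.state == 3] >= DIRECTED_ALPHA)
    assert np.all(lab.alpha[lab.state == 1] < DIRECTED_ALPHA)
    # changepoints: interior, sorted, spaced, and real changes
    cps = lab.changepoints
    bounds = np.concatenate([[0], cps, [T]])
    assert np.all(np.diff(bounds) >= 3)
    for c in cps:
        assert (
            lab.alpha[c] != lab.alpha[c - 1]
            or lab.K[c] != lab.K[c - 1]
            or lab.state[c] != lab.state[c - 1]
        )


# ---------------------------------------------------------------------------
# segments / MSD law


def test_zero_K_is_immobile():
    dx, dy = simulate_segment(0.5, 0.0, 50, np.random.default_rng(0))
    assert np.all(dx == 0) and np.all(dy == 0)


def test_single_step_variance_is_2K():
    rng = np.random.default_rng(1)
    dx = np.array([simulate_segment(1.0, 1.0, 1, rng)[0][0] for _ in range(10_000)])
    assert dx.var() == pytest.approx(2.0, abs=0.1)


@pytest.mark.parametrize("alpha", [0.7, 1.0, 1.5])
def test_ensemble_msd_slope_recovers_alpha(alpha):
    rng = np.random.default_rng(2)
    K = 1.0
    n, T = 3000, 25
    X = np.empty((n, T))
    Y = np.empty((n, T))
    for i in range(n):
        dx, dy = simulate_segment(alpha, K, T, rng)
        X[i], Y[i] = np.cumsum(dx), np.cumsum(dy)
    msd = (X**2 + Y**2).mean(axis=0)
    t = np.arange(1, 21)
    slope, intercept = np.polyfit(np.log(t), np.log(msd[:20]), 1)
    assert slope == pytest.approx(alpha, abs=0.05)
    assert np.exp(intercept) == pytest.approx(4 * K, rel=0.1)


# ---------------------------------------------------------------------------
# single state


def test_ssm_has_no_changepoints():
    traj, lab = simulate_ssm(SimConfig("SSM", seed=0))
    assert lab.changepoints.size == 0
    check_label_invariants(lab)


def test_ssm_directed_alpha_gives_state_3():
    _, lab = simulate_ssm(SimConfig("SSM", alpha_range=(1.95, 1.95), seed=1))
    assert np.all(lab.state == 3)


def test_ssm_respects_pinned_parameters():
    cfg = SimConfig("SSM", T=40, alpha_range=(1.0, 1.0), K_range=(1.0, 1.0), seed=2)
    _, lab = simulate_ssm(cfg)
    assert np.all(lab.alpha == 1.0) and np.all(lab.K == pytest.approx(1.0))


# ---------------------------------------------------------------------------
# multi state


def test_msm_identity_matrix_never_switches():
    cfg = SimConfig("MSM", T=100, transition_matrix=np.eye(2), seed=3)
    _, lab = simulate_msm(cfg)
    assert lab.changepoints.size == 0


def test_msm_raw_transition_rate_matches_geometric_oracle():
    # off-diagonal p = 0.05 -> expected transitions ~ (T-1) * 0.05
    P = np.array([[0.95, 0.05], [0.05, 0.95]])
    rng = np.random.default_rng(4)
    counts = [
        np.count_nonzero(np.diff(markov_state_sequence(P, 200, rng)))
        for _ in range(1000)
    ]
    assert np.mean(counts) == pytest.approx(199 * 0.05, abs=1.0)


def test_msm_emitted_segments_at_least_three_frames():
    rng = np.random.default_rng(5)
    for _ in range(20):
        _, lab = simulate_msm(SimConfig("MSM"), rng)
        check_label_invariants(lab)


# ---------------------------------------------------------------------------
# quenched traps


def test_qtm_sticky_trap_holds_forever():
    # dense traps covering the whole (tiny) FOV, unbinding probability 0
    cfg = SimConfig(
        "QTM", T=50, fov=10.0, n_traps=300, trap_radius=2.0,
        unbinding_prob=0.0, start=(5.0, 5.0), seed=6,
    )
    traj, lab = simulate_qtm(cfg)
    assert np.all(lab.state == 0)
    assert np.all(lab.alpha == 0) and np.all(lab.K == 0)
    assert np.all(traj.x == traj.x[0]) and np.all(traj.y == traj.y[0])


def test_qtm_without_traps_behaves_as_ssm():
    cfg = SimConfig("QTM", T=60, n_traps=0, seed=7)
    _, lab = simulate_qtm(cfg)
    assert lab.changepoints.size == 0
    assert np.all(lab.state != 0)


def test_qtm_trapped_dwell_is_geometric():
    # unbinding probability 0.1 -> mean trapped dwell 10 frames; dwells are
    # read off the frozen-position runs, which the label merging never touches
    rng = np.random.default_rng(8)
    cfg = SimConfig(
        "QTM", T=200, alpha_range=(1.0, 1.0), K_range=(5.0, 5.0),
        n_traps=300, trap_radius=1.0, unbinding_prob=0.1,
    )
    dwells = []
    while len(dwells) < 1000:
        traj, _ = simulate_qtm(cfg, rng)
        frozen = (np.diff(traj.x) == 0) & (np.diff(traj.y) == 0)
        # runs of frozen steps not touching either end (uncensored dwells)
        padded = np.concatenate([[False], frozen, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            if s > 0 and e < frozen.size:
                dwells.append(e - s)
    assert np.mean(dwells) == pytest.approx(10.0, abs=2.0)


# ---------------------------------------------------------------------------
# transient confinement


def test_tcm_closed_wall_confines_forever():
    cfg = SimConfig(
        "TCM", T=100, fov=25.0, n_compartments=1, compartment_radius=10.0,
        transition_prob=0.0, start=(12.5, 12.5),
        alpha_range=(1.0, 1.0), K_range=(3.0, 3.0), seed=9,
    )
    traj, lab = simulate_tcm(cfg)
    assert np.all(lab.state == 1)
    # never further than a diameter from any visited point
    span = max(traj.x.max() - traj.x.min(), traj.y.max() - traj.y.min())
    assert span <= 20.0 + 1e-9


def test_tcm_open_wall_lets_particle_escape():
    cfg = SimConfig(
        "TCM", T=150, fov=60.0, n_compartments=1, compartment_radius=6.0,
        transition_prob=1.0, start=(30.0, 30.0),
        alpha_range=(1.0, 1.0), K_range=(2.0, 2.0), seed=10,
    )
    found_escape = False
    rng = np.random.default_rng(10)
    for _ in range(10):
        _, lab = simulate_tcm(cfg, rng)
        if np.any(lab.state == 1) and np.any(lab.state != 1):
            found_escape = True
            break
    assert found_escape


def test_tcm_confined_alpha_below_directed_threshold():
    rng = np.random.default_rng(11)
    for _ in range(10):
        _, lab = simulate_tcm(SimConfig("TCM", alpha_range=(1.5, 2.0)), rng)
        check_label_invariants(lab)
        assert np.all(lab.alpha[lab.state == 1] < DIRECTED_ALPHA)


# ---------------------------------------------------------------------------
# dimerisation


def test_dim_distant_slow_particles_never_bind():
    cfg = SimConfig(
        "DIM", T=60, interaction_radius=0.5, K_range=(1e-6, 1e-6),
        start=[(20.0, 20.0), (100.0, 100.0)], unbinding_prob=0.0, seed=12,
    )
    for _, lab in simulate_dim(cfg):
        assert lab.changepoints.size == 0


def test_dim_bound_pair_shares_displacements():
    cfg = SimConfig(
        "DIM", T=60, interaction_radius=2.0, unbinding_prob=0.0,
        start=[(64.0, 64.0), (64.5, 64.0)], K_range=(1.0, 1.0), seed=13,
    )
    (t1, l1), (t2, l2) = simulate_dim(cfg)
    T = min(len(t1), len(t2))
    np.testing.assert_allclose(np.diff(t1.x[:T]), np.diff(t2.x[:T]), atol=1e-12)
    np.testing.assert_allclose(np.diff(t1.y[:T]), np.diff(t2.y[:T]), atol=1e-12)
    assert np.all(l1.alpha[:T] == l2.alpha[:T])


def test_dim_bound_dwell_is_geometric():
    # unbinding probability 0.05 -> mean bound dwell 20 frames
    rng = np.random.default_rng(14)
    cfg = SimConfig(
        "DIM", T=200, interaction_radius=2.0, unbinding_prob=0.05,
        start=[(64.0, 64.0), (64.5, 64.0)], K_range=(1.0, 1.0),
        alpha_range=(1.0, 1.0),
    )
    dwells = []
    while len(dwells) < 600:
        (t1, _), (t2, _) = simulate_dim(cfg, rng)
        T = min(len(t1), len(t2))
        same = (np.abs(np.diff(t1.x[:T]) - np.diff(t2.x[:T])) < 1e-9) & (
            np.abs(np.diff(t1.y[:T]) - np.diff(t2.y[:T])) < 1e-9
        )
        padded = np.concatenate([[False], same, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            if s > 0 and e < same.size:
                dwells.append(e - s)
    assert np.mean(dwells) == pytest.approx(20.0, abs=3.0)


# ---------------------------------------------------------------------------
# label finalisation


def test_finalize_merges_short_runs():
    alpha = np.array([1.0] * 5 + [0.5] * 2 + [1.0] * 5)
    K = np.ones(12)
    s = np.full(12, 2)
    lab = finalize_labels(alpha, K, s)
    assert lab.changepoints.size == 0
    assert np.all(lab.alpha == 1.0)


def test_finalize_leading_short_run_takes_successor():
    alpha = np.array([0.3] * 2 + [1.2] * 8)
    lab = finalize_labels(alpha, np.ones(10), np.full(10, 2))
    assert np.all(lab.alpha == 1.2)


# ---------------------------------------------------------------------------
# two-segment generator


def test_two_segment_changepoint_at_midpoint():
    rng = np.random.default_rng(15)
    traj, lab = simulate_two_segment((0.4, 1.6), (1.0, 1.0), T=100, rng=rng)
    assert len(traj) == 100
    np.testing.assert_array_equal(lab.changepoints, [50])
    assert np.all(lab.alpha[:50] == 0.4) and np.all(lab.alpha[50:] == 1.6)


# ---------------------------------------------------------------------------
# datasets


def test_dataset_split_ratio_and_invariants(small_dataset):
    split = np.asarray(small_dataset["split"])
    n = split.size
    assert np.count_nonzero(split == "train") == round(0.6 * n)
    assert np.count_nonzero(split == "val") == round(0.2 * n)
    for lab in small_dataset["labels"]:
        check_label_invariants(lab)


def test_dataset_exact_split_600_200_200():
    ds = build_dataset(total=1000, seed=1, recipe=[("SSM", {"T_range": (20, 22)})])
    split = np.asarray(ds["split"])
    assert (
        np.count_nonzero(split == "train"),
        np.count_nonzero(split == "val"),
        np.count_nonzero(split == "test"),
    ) == (600, 200, 200)


def test_dataset_alpha_constrained_variant():
    ds = build_dataset(
        total=30, seed=2,
        recipe=[("SSM", {"alpha_range": (1.9, 2.0), "T_range": (20, 30)}),
                ("MSM", {"alpha_range": (1.9, 2.0), "T_range": (20, 30)})],
    )
    for lab in ds["labels"]:
        moving = lab.state != 0
        assert np.all(lab.alpha[moving] >= 1.9) and np.all(lab.alpha[moving] <= 2.0)


def test_dataset_alpha_only_change_keeps_K_constant():
    ds = build_dataset(
        total=20, seed=3,
        recipe=[("MSM", {"alpha_only_change": True, "T_range": (20, 40)})],
    )
    for lab in ds["labels"]:
        assert np.unique(lab.K).size == 1


def test_dataset_deterministic_given_seed():
    kw = dict(total=15, recipe=[("SSM", {"T_range": (20, 25)}), ("QTM", {"T_range": (20, 25)})])
    a = build_dataset(seed=5, **kw)
    b = build_dataset(seed=5, **kw)
    assert len(a["trajectories"]) == len(b["trajectories"])
    for ta, tb in zip(a["trajectories"], b["trajectories"]):
        np.testing.assert_array_equal(ta.x, tb.x)
        np.testing.assert_array_equal(ta.y, tb.y)
    np.testing.assert_array_equal(a["split"], b["split"])
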