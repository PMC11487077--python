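"""BOC matrices, salience, alignment, leader-follower networks, U-turns."""

import math

import networkx as nx
import numpy as np
import pytest

from bocswarm.analysis import (
    ConfigurationError,
    baseline_salience,
    build_boc_matrix,
    detect_uturns,
    directional_alignment,
    lag_matrix,
    leader_follower_network,
    leadership,
    motion_salience,
    salience_leadership_correlation,
    segment_grid,
)
from bocswarm.dataset import TrajectoryDataset
from bocswarm.fixtures import (
    orbit_uturn,
    planted_chain_turn,
    static_scene,
)
from bocswarm.geometry import BOCParams, EllipticalAgent, boc_accumulate


def track_of(data, idx, a=15.0, b=1.5):
    return [
        EllipticalAgent(data.positions[t, idx], float(data.headings[t, idx]), a, b)
        for t in range(data.n_frames)
    ]


class TestBOCMatrix:
    def test_static_scene_zero_matrix(self):
        data = static_scene(4, n_frames=8)
        params = BOCParams(tau=0.5, alpha=1.0, dt=0.1)
        G = build_boc_matrix(data, 7, params).G
        assert np.allclose(G, 0.0)

    def test_out_of_range_pairs_zero(self):
        data = static_scene(4, n_frames=8)
        params = BOCParams(tau=0.5, alpha=1.0, dt=0.1)
        G = build_boc_matrix(data, 7, params, R_visual=1.0).G
        assert np.allclose(G, 0.0)

    def test_two_agents_match_pairwise_accumulation(self):
        # one agent pivots in place, the other watches from a fixed pose
        frames, dt = 10, 0.1
        positions = np.zeros((frames, 2, 2))
        positions[:, 1, 0] = 80.0
        headings = np.zeros((frames, 2))
        headings[:, 1] = 1.1 * dt * np.arange(frames)
        data = TrajectoryDataset(positions, headings, dt)
        params = BOCParams(tau=0.5, alpha=1.0, dt=dt)
        G = build_boc_matrix(data, 9, params, a=15.0, b=1.5).G
        for i, j in [(0, 1), (1, 0)]:
            g = boc_accumulate(track_of(data, i), track_of(data, j), 9, params)
            assert G[i, j] == pytest.approx(g, rel=1e-9)

    def test_window_out_of_bounds(self):
        data = static_scene(3, n_frames=4)
        with pytest.raises(IndexError):
            build_boc_matrix(data, 2, BOCParams(tau=0.5, dt=0.1))


class TestMotionSalience:
    def test_single_nonzero_column(self):
        G = np.zeros((4, 4))
        G[:, 2] = [3.0, 1.0, 0.0, 2.0]
        G[2, 2] = 0.0
        sal = motion_salience(G).values
        assert sal[2] == 1.0
        assert np.allclose(np.delete(sal, 2), 0.0)

    def test_constant_positive_matrix(self):
        G = np.full((5, 5), 2.0)
        np.fill_diagonal(G, 0.0)
        assert np.allclose(motion_salience(G).values, 1.0)

    def test_hand_computed_three_by_three(self):
        G = np.array([[0.0, 2.0, 4.0], [1.0, 0.0, 2.0], [3.0, 6.0, 0.0]])
        # column means over off-diagonal entries: (2, 4, 3); max 4
        sal = motion_salience(G).values
        assert np.allclose(sal, [0.5, 1.0, 0.75])

    def test_all_zero_warns_and_returns_zeros(self, caplog):
        sal = motion_salience(np.zeros((3, 3))).values
        assert np.allclose(sal, 0.0)


class TestBaselineSalience:
    def test_unknown_cue_rejected(self):
        data = static_scene(4, n_frames=8)
        with pytest.raises(ConfigurationError):
            baseline_salience(data, 7, BOCParams(tau=0.5, dt=0.1), "speed")

    def test_fp_only_all_ahead(self):
        # neighbors dead ahead of every viewer: every transient fp term is 1
        frames, dt = 8, 0.1
        positions = np.zeros((frames, 3, 2))
        positions[:, 1, 0] = 100.0
        positions[:, 2, 0] = 200.0
        headings = np.zeros((frames, 3))
        data = TrajectoryDataset(positions, headings, dt)
        params = BOCParams(tau=0.5, alpha=1.0, dt=dt, occlusion=False)
        sal = baseline_salience(data, 7, params, "fp_only")
        # viewer 0 sees both ahead; viewers 1,2 see only what is ahead of them
        assert sal.values.max() == 1.0

    def test_distance_cue_prefers_nearest(self):
        data = static_scene(4, n_frames=8, min_gap=100.0)
        params = BOCParams(tau=0.5, alpha=0.0, dt=0.1, occlusion=False)
        sal = baseline_salience(data, 7, params, "distance")
        pos = data.positions[0]
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        for i in range(4):
            nearest = int(np.argmin(d[i]))
            # the nearest neighbor of i attains i's largest per-pair cue
            fp = 1.0  # alpha = 0
            cues = np.where(np.isfinite(d[i]), 1.0 / d[i], 0.0)
            assert np.argmax(cues) == nearest

    def test_bearing_change_zero_for_rigid_translation(self):
        frames, dt = 8, 0.1
        base = np.array([[0.0, 0.0], [100.0, 30.0], [40.0, -90.0]])
        shift = np.arange(frames)[:, None, None] * np.array([5.0, 2.0])
        positions = base[None] + shift
        headings = np.zeros((frames, 3))
        data = TrajectoryDataset(positions, headings, dt)
        params = BOCParams(tau=0.5, alpha=0.0, dt=dt, occlusion=False)
        sal = baseline_salience(data, 7, params, "bearing_change")
        assert np.allclose(sal.values, 0.0)


class TestDirectionalAlignment:
    def make_shifted(self, k, n_frames=40, dt=0.1):
        base = np.zeros(n_frames)
        base[15:] = 1.2
        headings = np.stack([base, np.concatenate([np.zeros(k), base])[:n_frames]], axis=1)
        positions = np.zeros((n_frames, 2, 2))
        positions[:, 1, 0] = 50.0
        return TrajectoryDataset(positions, headings, dt)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_shifted_copy_recovers_lag(self, k):
        data = self.make_shifted(k)
        curve = directional_alignment(data, 0, 1, 0, data.n_frames - 1)
        assert curve.lambda_star == pytest.approx(k * data.dt)
        assert curve.xi.max() == pytest.approx(1.0)

    def test_identical_headings_tie_to_zero(self):
        positions = np.zeros((20, 2, 2))
        positions[:, 1, 0] = 50.0
        data = TrajectoryDataset(positions, np.full((20, 2), 0.7), 0.1)
        curve = directional_alignment(data, 0, 1, 0, 19)
        assert np.allclose(curve.xi, 1.0)
        assert curve.lambda_star == 0.0

    def test_orthogonal_headings_zero_everywhere(self):
        headings = np.zeros((20, 2))
        headings[:, 1] = math.pi / 2
        positions = np.zeros((20, 2, 2))
        positions[:, 1, 0] = 50.0
        data = TrajectoryDataset(positions, headings, 0.1)
        curve = directional_alignment(data, 0, 1, 0, 19)
        assert np.allclose(curve.xi, 0.0, atol=1e-12)

    def test_xi_matches_direct_overlap_average(self, rng):
        headings = rng.uniform(-math.pi, math.pi, (15, 2))
        positions = rng.uniform(-100, 100, (15, 2, 2))
        data = TrajectoryDataset(positions, headings, 0.1)
        curve = directional_alignment(data, 0, 1, 0, 14)
        v = data.heading_vectors()
        n = 15
        for li, lam in enumerate(range(-(n - 1), n)):
            ts = [t for t in range(n) if 0 <= t + lam < n]
            expected = np.mean([v[t, 0] @ v[t + lam, 1] for t in ts])
            assert curve.xi[li] == pytest.approx(expected, abs=1e-12)

    def test_xi_symmetry(self, rng):
        headings = rng.uniform(-math.pi, math.pi, (12, 2))
        positions = rng.uniform(-100, 100, (12, 2, 2))
        data = TrajectoryDataset(positions, headings, 0.1)
        cij = directional_alignment(data, 0, 1, 0, 11)
        cji = directional_alignment(data, 1, 0, 0, 11)
        assert np.allclose(cij.xi, cji.xi[::-1])


class TestLeaderFollowerNetwork:
    def test_planted_chain_transitive_tournament(self):
        data = planted_chain_turn(5, lag_frames=1, noise_sigma=0.0)
        net = leader_follower_network(data, 0, data.n_frames - 1)
        expected = {(i, j) for i in range(5) for j in range(i + 1, 5)}
        assert set(net.edges()) == expected

    def test_two_agents_single_edge(self):
        data = planted_chain_turn(2, lag_frames=2, noise_sigma=0.0)
        net = leader_follower_network(data, 0, data.n_frames - 1)
        assert set(net.edges()) == {(0, 1)}

    def test_synchronous_group_has_no_edges(self):
        data = planted_chain_turn(4, lag_frames=0, noise_sigma=0.0)
        net = leader_follower_network(data, 0, data.n_frames - 1)
        assert net.number_of_edges() == 0

    def test_antisymmetry(self, rng):
        headings = rng.uniform(-math.pi, math.pi, (30, 4))
        positions = rng.uniform(-200, 200, (30, 4, 2))
        data = TrajectoryDataset(positions, headings, 0.1)
        net = leader_follower_network(data, 0, 29)
        for i, j in net.edges():
            assert not net.has_edge(j, i)


class TestLeadership:
    def test_full_out_star_is_one(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(10))
        g.add_edges_from((0, j) for j in range(1, 10))
        lead = leadership(g).values
        assert lead[0] == 1.0

    def test_sink_is_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(4))
        g.add_edges_from([(0, 3), (1, 3), (2, 3)])
        assert leadership(g).values[3] == 0.0

    def test_three_node_chain(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from([(0, 1), (1, 2), (0, 2)])
        assert np.allclose(leadership(g).values, [1.0, 0.5, 0.0])


class TestSpearman:
    def test_identical_order_and_reversed(self):
        a = np.array([0.1, 0.4, 0.6, 0.9])
        assert salience_leadership_correlation(a, a * 2) == pytest.approx(1.0)
        assert salience_leadership_correlation(a, -a) == pytest.approx(-1.0)

    def test_tied_pair_matches_rank_formula(self):
        # hand computation with average ranks:
        # x = (1, 2, 2, 4, 5) -> ranks (1, 2.5, 2.5, 4, 5)
        # y = (2, 1, 3, 4, 5) -> ranks (2, 1, 3, 4, 5)
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 4.0, 5.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ry = np.array([2.0, 1.0, 3.0, 4.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert salience_leadership_correlation(x, y) == pytest.approx(expected)

    def test_constant_vector_is_nan(self):
        assert math.isnan(salience_leadership_correlation(
            np.ones(4), np.array([1.0, 2.0, 3.0, 4.0])
        ))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            salience_leadership_correlation(np.ones(3), np.ones(4))


class TestUTurnDetection:
    def test_single_switch_detected(self):
        data = orbit_uturn(5, switch_frame=60)
        windows = detect_uturns(data)
        assert len(windows) == 1
        assert windows[0].start <= 60 <= windows[0].end

    def test_constant_orbit_empty(self):
        data = orbit_uturn(5, switch_frame=None)
        assert detect_uturns(data) == []

    def test_two_switches_two_windows(self):
        data = orbit_uturn(5, switch_frame=[40, 90], n_frames=130)
        windows = detect_uturns(data)
        assert len(windows) == 2

    def test_missing_tank_geometry_raises(self):
        data = static_scene(3)
        with pytest.raises(ConfigurationError):
            detect_uturns(data)


class TestSegmentGrid:
    def test_counts(self):
        # 3 s window at dt = 0.1: tau = stride = 0.6 s -> 4 interior segments
        assert len(segment_grid((0, 30), [0.6], 0.6, 0.1)) == 4

    def test_tau_larger_than_window_empty(self):
        assert segment_grid((0, 30), [4.0], 0.6, 0.1) == []

    def test_stride_equal_window(self):
        assert len(segment_grid((0, 30), [0.6], 3.0, 0.1)) <= 1


class TestRecoveryAndInvariance:
    def test_planted_order_recovered_and_rho_positive(self):
        data = planted_chain_turn(6, lag_frames=1, noise_sigma=0.0)
        net = leader_follower_network(data, 0, data.n_frames - 1)
        lead = leadership(net).values
        assert np.all(np.diff(lead) < 0)  # strictly decreasing in chain order
        # salience window covering the staggered turns (frames 20..25)
        T = 30
        params = BOCParams(tau=1.5, alpha=1.0, dt=data.dt)
        sal = motion_salience(build_boc_matrix(data, T, params))
        rho = salience_leadership_correlation(sal, leadership(net))
        assert rho > 0

    def test_rigid_translation_leaves_outputs_unchanged(self):
        data = planted_chain_turn(4, lag_frames=1, noise_sigma=0.05, seed=3)
        moved = data.translated((1234.5, -987.0))
        T = data.n_frames - 1
        params = BOCParams(tau=1.0, alpha=1.0, dt=data.dt)
        s1 = motion_salience(build_boc_matrix(data, T, params)).values
        s2 = motion_salience(build_boc_matrix(moved, T, params)).values
        assert np.allclose(s1, s2)
        assert np.allclose(lag_matrix(data, 0, T), lag_matrix(moved, 0, T))
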