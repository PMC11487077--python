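"""Deterministic synthetic scenes and planted-structure trajectories.

These generators build the test-bench inputs for every other module: scenes
with a known BOC (a neighbor rotating in place), planted leader-follower
chains in which agent i copies agent i-1's heading with a fixed frame lag,
orbiting groups that execute a known U-turn, line groups with a heading
gradient, and static grids.  Every generator is seed-deterministic and its
trajectory outputs pass :class:`TrajectoryDataset` validation.

Heading noise is von Mises with concentration 1/sigma^2 (wrapped-normal-like
for small sigma), so sigma reads as a radian-scale standard deviation.
"""

from __future__ import annotations

import math

import numpy as np

from .dataset import TrajectoryDataset
from .geometry import EllipticalAgent

FIXTURE_KINDS = (
    "static_scene",
    "rotating_neighbor",
    "planted_chain_turn",
    "orbit_uturn",
    "line_gradient",
    "grid_group",
)


def planted_chain_turn(
    n: int,
    dt: float = 0.1,
    lag_frames: int = 1,
    turn_angle: float = math.pi / 2,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_frames: int = 60,
    turn_frame: int = 20,
    speed: float = 30.0,
    spacing: float = 50.0,
) -> TrajectoryDataset:
    """Chain of followers copying the leader's turn with per-rank lag.

    Agent 0 turns by ``turn_angle`` at ``turn_frame``; agent i's heading
    series is agent i-1's delayed by ``lag_frames`` (so rank i lags the
    leader by i * lag_frames frames), plus independent von Mises noise of
    scale ``noise_sigma`` radians.  The planted leadership order is simply
    the agent index order.
    """
    if n < 2:
        raise ValueError("need at least 2 agents")
    rng = np.random.default_rng(seed)
    base = np.zeros(n_frames)
    base[turn_frame:] = turn_angle
    headings = np.empty((n_frames, n))
    for i in range(n):
        shift = i * lag_frames
        shifted = np.concatenate([np.full(shift, base[0]), base])[:n_frames]
        headings[:, i] = shifted
    if noise_sigma > 0:
        kappa = 1.0 / noise_sigma**2
        headings = headings + rng.vonmises(0.0, kappa, size=headings.shape)
    positions = np.empty((n_frames, n, 2))
    positions[0] = np.stack([-spacing * np.arange(n), np.zeros(n)], axis=1)
    steps = speed * dt * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    positions[1:] = positions[0] + np.cumsum(steps[:-1], axis=0)
    return TrajectoryDataset(positions, headings, dt)


def orbit_uturn(
    n: int,
    tank_radius: float = 250.0,
    switch_frame: int | list[int] | None = 60,
    dt: float = 0.1,
    seed: int = 0,
    n_frames: int = 120,
    omega: float = 0.8,
    orbit_fraction: float = 0.6,
) -> TrajectoryDataset:
    """Group orbiting a circular tank, reversing direction at known frames.

    Agents sit at evenly spaced (seed-jittered) polar angles on a circle of
    radius ``orbit_fraction * tank_radius`` and orbit at angular speed
    ``omega`` (rad/s), clockwise-to-counterclockwise flips occurring at each
    frame in ``switch_frame`` (int, list, or None for no switch).  Headings
    are tangential.  Tank geometry is attached for U-turn detection.
    """
    rng = np.random.default_rng(seed)
    if switch_frame is None:
        switches: list[int] = []
    elif isinstance(switch_frame, int):
        switches = [switch_frame]
    else:
        switches = sorted(switch_frame)
    sign = np.ones(n_frames)
    for f in switches:
        sign[f:] *= -1
    dtheta = np.concatenate([[0.0], sign[:-1] * omega * dt])
    theta_t = np.cumsum(dtheta)
    base_angles = 2 * math.pi * np.arange(n) / n + rng.uniform(0, 2 * math.pi / n, n)
    r_orbit = orbit_fraction * tank_radius
    angles = base_angles[None, :] + theta_t[:, None]
    positions = r_orbit * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    headings = angles + sign[:, None] * math.pi / 2  # tangential travel
    return TrajectoryDataset(
        positions, headings, dt,
        tank_center=np.zeros(2), tank_radius=tank_radius,
    )


def rotating_neighbor_scene(
    distance: float = 60.0,
    omega: float = 1.0,
    frames: int = 10,
    dt: float = 0.1,
    a: float = 15.0,
    b: float = 4.5,
) -> tuple[list[EllipticalAgent], list[EllipticalAgent]]:
    """Static focal agent watching a neighbor rotate in place.

    The canonical nonzero-BOC input: the focal agent sits at the origin
    heading toward the neighbor, the neighbor spins at ``omega`` rad/s at a
    fixed center ``distance`` mm ahead.  Returns (focal_track, neighbor_track)
    as per-frame agent sequences.
    """
    focal = [EllipticalAgent(np.zeros(2), 0.0, a, b) for _ in range(frames)]
    neighbor = [
        EllipticalAgent(np.array([distance, 0.0]), omega * dt * t, a, b)
        for t in range(frames)
    ]
    return focal, neighbor


def static_scene(
    n: int,
    seed: int = 0,
    n_frames: int = 5,
    dt: float = 0.1,
    extent: float = 400.0,
    min_gap: float = 80.0,
) -> TrajectoryDataset:
    """Motionless group at random non-overlapping poses (rejection sampled)."""
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(-extent, extent, 2)
        if all(np.linalg.norm(p - q) >= min_gap for q in pts):
            pts.append(p)
    pos = np.array(pts)
    head = rng.uniform(-math.pi, math.pi, n)
    positions = np.repeat(pos[None], n_frames, axis=0)
    headings = np.repeat(head[None], n_frames, axis=0)
    return TrajectoryDataset(positions, headings, dt)


def line_gradient(
    n: int = 20,
    spacing: float = 50.0,
    angle_span: float = math.pi,
    n_frames: int = 2,
    dt: float = 0.1,
) -> TrajectoryDataset:
    """Line of agents with headings sweeping linearly across ``angle_span``."""
    pos = np.stack([spacing * np.arange(n), np.zeros(n)], axis=1)
    head = np.linspace(0.0, angle_span, n)
    positions = np.repeat(pos[None], n_frames, axis=0)
    headings = np.repeat(head[None], n_frames, axis=0)
    return TrajectoryDataset(positions, headings, dt)


def grid_group(
    n_side: int = 5,
    spacing: float = 60.0,
    heading: float = 0.0,
    n_frames: int = 2,
    dt: float = 0.1,
) -> TrajectoryDataset:
    """Static square grid with a common heading."""
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    pos = spacing * np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    n = pos.shape[0]
    positions = np.repeat(pos[None], n_frames, axis=0)
    headings = np.full((n_frames, n), heading)
    return TrajectoryDataset(positions, headings, dt)


def camera_selection_scene(
    rng: np.random.Generator,
    n_neighbors: int = 3,
    frames: int = 6,
    dt: float = 0.1,
    a: float = 15.0,
    b: float = 4.5,
    omega_active: tuple[float, float] = (0.5, 2.5),
    omega_jitter: float = 0.02,
    distance: tuple[float, float] = (90.0, 200.0),
    bearing_limit: float = 1.0,
) -> tuple[list[EllipticalAgent], list[list[EllipticalAgent]], int]:
    """A neighbor-selection scene with one actively maneuvering neighbor.

    Models the propagation situation in a responding swarm: one neighbor
    turns at a clearly maneuvering rate while the rest hold near-constant
    headings (residual jitter up to ``omega_jitter`` rad/s).  Neighbors sit
    at random distances and bearings within the focal agent's frontal field.
    Returns (focal_track, neighbor_tracks, index of the active turner).
    """
    focal = [EllipticalAgent(np.zeros(2), 0.0, a, b) for _ in range(frames)]
    turner = int(rng.integers(n_neighbors))
    tracks = []
    for k in range(n_neighbors):
        d = rng.uniform(*distance)
        bearing = rng.uniform(-bearing_limit, bearing_limit)
        center = d * np.array([math.cos(bearing), math.sin(bearing)])
        omega = rng.uniform(*omega_active) if k == turner else rng.uniform(0, omega_jitter)
        h0 = rng.uniform(-math.pi, math.pi)
        tracks.append([
            EllipticalAgent(center, h0 + omega * dt * t, a, b)
            for t in range(frames)
        ])
    return focal, tracks, turner


def make_fixture(kind: str, seed: int = 0, **params) -> TrajectoryDataset:
    """Dispatch by fixture kind; only kinds producing trajectory datasets."""
    table = {
        "static_scene": static_scene,
        "planted_chain_turn": planted_chain_turn,
        "orbit_uturn": orbit_uturn,
        "line_gradient": line_gradient,
        "grid_group": grid_group,
    }
    if kind not in table:
        raise ValueError(
            f"unknown fixture kind {kind!r}; trajectory kinds are {sorted(table)}"
        )
    fn = table[kind]
    if kind in ("static_scene", "planted_chain_turn", "orbit_uturn"):
        params["seed"] = seed
    return fn(**params)
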