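"""Kinematic self-propelled swarm: collective spin and collective turn.

Agents are elongated ellipses moving in the plane.  Each step, every agent
selects at most one neighbor among the visible (in-range, unoccluded) ones:

    boc     the neighbor with the largest accumulated body orientation change
            (alpha = 0 chord-change sum over the last tau window); ties go to
            the lowest agent id.
    random  a uniformly random visible neighbor from the run's seeded stream.
    vicsek  no single selection; alignment averages all visible neighbors.

Collective spin: positions are fixed; agents are stationary or spinning
(in-place rotation at omega_max).  A front-most initiator starts spinning at
the activation step and stops after accumulating a full 2*pi; every other
agent synchronously copies the motion state of its selected neighbor.

Collective turn: all agents move at constant speed v0.  Headings update by
velocity alignment with the selected neighbor,

    v_i <- normalize(v_i + k_a * v_sel),

with the per-step heading change clamped to omega_max * dt (the turn-rate
limit of a differential-drive platform; it also removes the antiparallel
fixed point at theta_info = pi).  An informed agent rotates toward, then
holds, the direction n obtained by rotating the group heading by theta_info.
A gentle pairwise repulsion displaces agents closer than r_rep apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import TrajectoryDataset
from .geometry import chord_lengths, occlusion_mask

POLICIES = ("boc", "random", "vicsek")
SCENARIOS = ("spin", "turn")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters (mm, s, rad).

    Defaults describe a group of 30 mm-long agents (semi-axes a = 15,
    b = 4.5 mm, aspect ratio 0.3) on a jittered hexagonal grid with 60 mm
    spacing, perceiving neighbors within R_visual = 100 mm (spin) or 200 mm
    (turn).
    dt = 0.23 s makes the spin initiator's full 2*pi rotation at
    omega_max = 0.83 rad/s span 33 steps.
    """

    N: int = 100
    scenario: str = "spin"
    policy: str = "boc"
    dt: float = 0.23
    n_steps: Optional[int] = None          # default 70 (spin) / 250 (turn)
    v0: float = 20.0                       # mm/s, forced 0 in spin
    omega_max: float = 0.83                # rad/s
    k_a: float = 1.0                       # alignment gain (heading averaging)
    R_visual: Optional[float] = None       # mm; default 100 (spin) / 200 (turn)
    tau: float = 0.69                      # BOC accumulation window, s
    a: float = 15.0                        # semi-major axis, mm
    b: float = 4.5                         # semi-minor axis, mm
    theta_info: float = math.pi            # informed turn angle (turn only)
    activation_step: Optional[int] = None  # default 25 (spin) / 50 (turn)
    spacing: float = 60.0                  # grid nearest-neighbor spacing, mm
    jitter: float = 0.15                   # placement jitter, fraction of spacing
    r_rep: float = 40.0                    # repulsion radius, mm (turn only)
    k_rep: float = 0.2                     # repulsion gain (turn only)
    occlusion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.scenario not in SCENARIOS:
            problems.append(f"scenario must be one of {SCENARIOS}")
        if self.policy not in POLICIES:
            problems.append(f"policy must be one of {POLICIES}")
        if self.dt <= 0:
            problems.append("dt must be positive")
        if self.N < 1:
            problems.append("N must be >= 1")
        if self.omega_max <= 0:
            problems.append("omega_max must be positive")
        if self.k_a <= 0:
            problems.append("k_a must be positive")
        if self.v0 < 0:
            problems.append("v0 must be non-negative")
        if problems:
            raise ConfigError("; ".join(problems))
        if self.n_steps is None:
            self.n_steps = 70 if self.scenario == "spin" else 250
        if self.activation_step is None:
            self.activation_step = 25 if self.scenario == "spin" else 50
        if self.R_visual is None:
            # per-scenario perception ranges, mirroring separate parameter
            # tables for the spin and turn experiments
            self.R_visual = 100.0 if self.scenario == "spin" else 200.0

    @property
    def n_tau(self) -> int:
        return max(int(round(self.tau / self.dt)), 1)


@dataclass
class SimTrace:
    """Full record of one run; replayable bit-identically from (config, seed)."""

    config: SimConfig
    dataset: TrajectoryDataset
    spinning: np.ndarray            # (steps, N) bool; all False in turn runs
    selections: np.ndarray          # (steps, N) int, -1 = none
    initiator: int
    informed_direction: np.ndarray | None  # unit n-hat (turn) or None
    initiator_stop_step: int | None        # spin: step the 2*pi completes

    @property
    def activation_step(self) -> int:
        return self.config.activation_step

    def first_spin_steps(self) -> np.ndarray:
        """Per-agent first spinning step, -1 for agents that never spin."""
        ever = self.spinning.any(axis=0)
        first = np.where(ever, self.spinning.argmax(axis=0), -1)
        return first


# ---------------------------------------------------------------------------
# placement and per-step machinery
# ---------------------------------------------------------------------------


def _hex_grid_in_disk(n: int, spacing: float, jitter: float, rng) -> np.ndarray:
    """n jittered hexagonal-lattice points, the n closest to the origin."""
    m = int(math.ceil(math.sqrt(n))) + 3
    pts = []
    for row in range(-m, m + 1):
        for col in range(-m, m + 1):
            x = (col + 0.5 * (row % 2)) * spacing
            y = row * spacing * math.sqrt(3) / 2
            pts.append((x, y))
    pts = np.array(pts)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    chosen = pts[order[:n]]
    chosen = chosen + rng.uniform(-jitter, jitter, size=chosen.shape) * spacing
    return chosen


def _beta_matrix(pos, theta, a, b) -> np.ndarray:
    eyes = pos + a * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    beta = chord_lengths(eyes[:, None, :], pos[None, :, :], theta[None, :], a, b)
    np.fill_diagonal(beta, 0.0)
    return np.nan_to_num(beta)


def _visibility(pos, theta, cfg: SimConfig) -> np.ndarray:
    d = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
    mask = d <= cfg.R_visual
    np.fill_diagonal(mask, False)
    if cfg.occlusion:
        mask &= ~occlusion_mask(pos, theta, cfg.a, cfg.b, mask)
    return mask


def select_neighbor(
    focal: int,
    g_row: np.ndarray,
    visible_row: np.ndarray,
    policy: str,
    rng: np.random.Generator,
) -> int:
    """One neighbor id for the focal agent, or -1 when none is visible.

    boc: argmax of the accumulated BOC over visible neighbors, ties to the
    smallest id.  random: uniform over visible neighbors from ``rng``.
    """
    cand = np.flatnonzero(visible_row)
    cand = cand[cand != focal]
    if cand.size == 0:
        return -1
    if policy == "random":
        return int(rng.choice(cand))
    g = g_row[cand]
    return int(cand[np.argmax(g)])  # argmax takes the first (lowest id) on ties


def align_heading(v_i: np.ndarray, v_sel: np.ndarray, k_a: float) -> np.ndarray:
    """normalize(v_i + k_a * v_sel); returns v_i unchanged for a zero sum."""
    s = v_i + k_a * v_sel
    nrm = np.linalg.norm(s)
    return v_i if nrm < 1e-12 else s / nrm


def _clamp_turn(theta_old: float, theta_des: float, max_step: float) -> float:
    d = (theta_des - theta_old + math.pi) % (2 * math.pi) - math.pi
    return theta_old + float(np.clip(d, -max_step, max_step))


def repulsion_displacements(pos: np.ndarray, r_rep: float, k_rep: float) -> np.ndarray:
    """Pairwise separating displacements -k_rep (r_rep - d) x_ij for d < r_rep."""
    n = pos.shape[0]
    rel = pos[None, :, :] - pos[:, None, :]        # rel[i, j] = x_j - x_i
    d = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[..., None] > 0, rel / np.where(d[..., None] > 0, d[..., None], 1.0), 0.0)
    overlap = np.where((d < r_rep) & (d > 0), r_rep - d, 0.0)
    np.fill_diagonal(overlap, 0.0)
    return -(k_rep * overlap[..., None] * unit).sum(axis=1)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


def run_experiment(config: SimConfig) -> SimTrace:
    """Run one collective spin or collective turn experiment.

    Agents start on a jittered hexagonal grid inside a disk with a common +x
    heading; the initiator (spin trigger or informed individual) is the
    front-most agent along that heading and activates at the configured step.
    Identical (config, seed) pairs produce bit-identical traces.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.N
    pos = _hex_grid_in_disk(n, cfg.spacing, cfg.jitter, rng)
    theta = np.zeros(n)
    initiator = int(np.argmax(pos[:, 0]))
    spin_scenario = cfg.scenario == "spin"

    n_hat = None
    if not spin_scenario:
        n_hat = np.array([math.cos(cfg.theta_info), math.sin(cfg.theta_info)])

    spinning = np.zeros(n, dtype=bool)
    cum_rot = 0.0
    initiator_done = False
    initiator_stop_step: int | None = None
    max_turn = cfg.omega_max * cfg.dt

    positions_log = np.empty((cfg.n_steps, n, 2))
    headings_log = np.empty((cfg.n_steps, n))
    spin_log = np.zeros((cfg.n_steps, n), dtype=bool)
    sel_log = np.full((cfg.n_steps, n), -1, dtype=int)

    beta_hist: list[np.ndarray] = []
    trans_hist: list[np.ndarray] = []

    for step in range(cfg.n_steps):
        beta = _beta_matrix(pos, theta, cfg.a, cfg.b)
        if beta_hist:
            trans_hist.append(np.abs(beta - beta_hist[-1]) / cfg.dt)
            if len(trans_hist) > cfg.n_tau:
                trans_hist.pop(0)
        beta_hist = [beta]
        G = np.sum(trans_hist, axis=0) if trans_hist else np.zeros((n, n))

        visible = _visibility(pos, theta, cfg)
        sels = np.array([
            select_neighbor(i, G[i], visible[i], cfg.policy, rng)
            for i in range(n)
        ])

        positions_log[step] = pos
        headings_log[step] = theta
        spin_log[step] = spinning
        sel_log[step] = sels

        if spin_scenario:
            new_spin = spinning.copy()
            for i in range(n):
                if i == initiator:
                    continue
                if cfg.policy == "vicsek":
                    vis = np.flatnonzero(visible[i])
                    if vis.size:
                        new_spin[i] = spinning[vis].mean() > 0.5
                elif sels[i] >= 0:
                    new_spin[i] = spinning[sels[i]]
            # initiator protocol: spin from activation until cumulative 2*pi
            if step >= cfg.activation_step and not initiator_done:
                new_spin[initiator] = True
            if initiator_done:
                new_spin[initiator] = False
            theta_new = theta.copy()
            rot = cfg.omega_max * cfg.dt
            theta_new[new_spin] += rot
            if new_spin[initiator]:
                cum_rot += rot
                if cum_rot >= 2 * math.pi - 1e-12:
                    initiator_done = True
                    initiator_stop_step = step
            spinning = new_spin
            theta = theta_new
        else:
            v = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
            theta_new = theta.copy()
            for i in range(n):
                if i == initiator and step >= cfg.activation_step:
                    des = math.atan2(n_hat[1], n_hat[0])
                else:
                    if cfg.policy == "vicsek":
                        vis = np.flatnonzero(visible[i])
                        if vis.size == 0:
                            continue
                        v_des = align_heading(v[i], v[vis].mean(axis=0), cfg.k_a)
                    elif sels[i] >= 0:
                        v_des = align_heading(v[i], v[sels[i]], cfg.k_a)
                    else:
                        continue
                    des = math.atan2(v_des[1], v_des[0])
                theta_new[i] = _clamp_turn(theta[i], des, max_turn)
            theta = theta_new
            v = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
            disp = repulsion_displacements(pos, cfg.r_rep, cfg.k_rep)
            pos = pos + cfg.v0 * v * cfg.dt + disp

    dataset = TrajectoryDataset(positions_log, headings_log, cfg.dt)
    return SimTrace(
        config=cfg,
        dataset=dataset,
        spinning=spin_log,
        selections=sel_log,
        initiator=initiator,
        informed_direction=n_hat,
        initiator_stop_step=initiator_stop_step,
    )
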