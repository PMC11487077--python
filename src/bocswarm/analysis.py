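"""Trajectory analysis: BOC matrices, motion salience, leadership.

Pipeline for tracked groups (e.g. fish in a circular tank): for a trajectory
segment [T - tau, T], build the matrix G of pairwise body-orientation-change
accumulations (rows = viewers, columns = perceived neighbors), reduce it to a
per-individual motion salience (max-normalized column means), reconstruct the
leader-follower network from time-lagged directional alignment

    xi_ij(lambda) = < v_i(t) . v_j(t + lambda) >,

whose argmax lag lambda*_ij signs each pairwise relation (lambda* > 0 means j
trails i, so j follows i), score leadership as the normalized out-degree
L_i = d_i_out / (N - 1), and correlate salience with leadership by Spearman
rank correlation.  Alternative per-pair cues (inverse distance, bearing
change, frontal weight alone) are provided as baselines for the same
salience computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .dataset import TrajectoryDataset
from .geometry import BOCParams, chord_lengths, occlusion_mask

logger = logging.getLogger(__name__)

BASELINE_CUES = ("distance", "bearing_change", "fp_only")


class ConfigurationError(ValueError):
    pass


@dataclass
class BOCMatrix:
    """N x N accumulated BOC over [T - tau, T]; row = viewer, column = neighbor."""

    G: np.ndarray
    T: int
    tau: float

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class MotionSalienceVector:
    """Per-individual conspicuousness, max-normalized to [0, 1]."""

    values: np.ndarray
    cue: str = "boc"


@dataclass
class AlignmentCurve:
    """Directional alignment xi_ij over a symmetric lag grid (seconds)."""

    lags: np.ndarray
    xi: np.ndarray
    lambda_star: float


@dataclass
class LeadershipVector:
    values: np.ndarray


# ---------------------------------------------------------------------------
# per-frame pair matrices (vectorized over all ordered pairs)
# ---------------------------------------------------------------------------


def _frame_chords(positions, headings, a, b) -> np.ndarray:
    """(N, N) chord-length matrix beta[i, j]: viewer i's eye vs ellipse j."""
    eyes = positions + a * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    beta = chord_lengths(
        eyes[:, None, :], positions[None, :, :], headings[None, :], a, b
    )
    np.fill_diagonal(beta, 0.0)
    return beta


def _frame_fp(positions, headings, alpha) -> np.ndarray:
    """(N, N) frontal-weight matrix fp[i, j] for viewer i toward neighbor j."""
    rel = positions[None, :, :] - positions[:, None, :]
    d = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = rel / d[..., None]
    v = np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    dot = np.einsum("id,ijd->ij", v, xhat)
    base = np.clip((1.0 + dot) / 2.0, 0.0, 1.0)
    fp = np.ones_like(base) if alpha == 0 else base ** alpha
    np.fill_diagonal(fp, 0.0)
    return np.nan_to_num(fp)


def _visible_mask(
    positions, headings, a, b, R_visual, use_occlusion
) -> np.ndarray:
    """(N, N) boolean mask of in-range, unoccluded ordered pairs at one frame."""
    d = np.linalg.norm(positions[None, :, :] - positions[:, None, :], axis=-1)
    mask = d <= R_visual
    np.fill_diagonal(mask, False)
    if use_occlusion:
        mask &= ~occlusion_mask(positions, headings, a, b, mask)
    return mask


def build_boc_matrix(
    data: TrajectoryDataset,
    T: int,
    params: BOCParams,
    R_visual: float = np.inf,
    a: float = 15.0,
    b: float = 1.5,
) -> BOCMatrix:
    """BOC matrix G(T, tau) from a tracked trajectory.

    Entry (i, j) is the accumulated chord-change rate of neighbor j as seen by
    viewer i over frames [T - n, T], frontally weighted; pairs that are out of
    visual range or occluded at the observation frame T contribute 0.  The
    diagonal is stored as 0.
    """
    n_w = params.n_frames
    if T - n_w < 0 or T >= data.n_frames:
        raise IndexError(f"window [{T - n_w}, {T}] outside trajectory")
    betas = np.array([
        _frame_chords(data.positions[t], data.headings[t], a, b)
        for t in range(T - n_w, T + 1)
    ])
    trans = np.abs(np.diff(betas, axis=0)) / params.dt
    fps = np.array([
        _frame_fp(data.positions[t], data.headings[t], params.alpha)
        for t in range(T - n_w + 1, T + 1)
    ])
    G = np.nansum(trans * fps, axis=0)
    vis = _visible_mask(
        data.positions[T], data.headings[T], a, b, R_visual, params.occlusion
    )
    G = np.where(vis, G, 0.0)
    np.fill_diagonal(G, 0.0)
    return BOCMatrix(G=G, T=T, tau=params.tau)


def motion_salience(matrix: BOCMatrix | np.ndarray, cue: str = "boc") -> MotionSalienceVector:
    """Column means of the BOC matrix (diagonal excluded), max-normalized.

    An all-zero matrix yields an all-zero salience vector with a warning.
    """
    G = matrix.G if isinstance(matrix, BOCMatrix) else np.asarray(matrix, float)
    n = G.shape[0]
    off = ~np.eye(n, dtype=bool)
    col_means = np.array([G[:, j][off[:, j]].mean() for j in range(n)])
    top = col_means.max()
    if top <= 0:
        logger.warning("all-zero cue matrix: salience undefined, returning zeros")
        return MotionSalienceVector(np.zeros(n), cue)
    return MotionSalienceVector(col_means / top, cue)


def baseline_salience(
    data: TrajectoryDataset,
    T: int,
    params: BOCParams,
    cue: str,
    R_visual: float = np.inf,
    a: float = 15.0,
    b: float = 1.5,
) -> MotionSalienceVector:
    """Motion salience from a substituted per-pair cue.

    distance        sum_t fp(t) / d_ij(t): closer neighbors score higher.
    bearing_change  sum_t |d/dt bearing of x_ij in the focal body frame| fp(t).
    fp_only         sum_t fp(t): the frontal weight alone.
    """
    if cue not in BASELINE_CUES:
        raise ConfigurationError(f"unknown cue {cue!r}; expected {BASELINE_CUES}")
    n_w = params.n_frames
    if T - n_w < 0 or T >= data.n_frames:
        raise IndexError(f"window [{T - n_w}, {T}] outside trajectory")
    frames = range(T - n_w + 1, T + 1)
    C = 0.0
    if cue == "fp_only":
        for t in frames:
            C = C + _frame_fp(data.positions[t], data.headings[t], params.alpha)
    elif cue == "distance":
        for t in frames:
            fp = _frame_fp(data.positions[t], data.headings[t], params.alpha)
            d = np.linalg.norm(
                data.positions[t][None, :, :] - data.positions[t][:, None, :],
                axis=-1,
            )
            with np.errstate(divide="ignore"):
                inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
            C = C + fp * inv
    else:  # bearing_change
        bearings = []
        for t in range(T - n_w, T + 1):
            rel = data.positions[t][None, :, :] - data.positions[t][:, None, :]
            ang = np.arctan2(rel[..., 1], rel[..., 0]) - data.headings[t][:, None]
            bearings.append(ang)
        bearings = np.array(bearings)
        dbear = np.abs(
            (np.diff(bearings, axis=0) + np.pi) % (2 * np.pi) - np.pi
        ) / params.dt
        fps = np.array([
            _frame_fp(data.positions[t], data.headings[t], params.alpha)
            for t in frames
        ])
        C = np.nansum(dbear * fps, axis=0)
    C = np.asarray(C, dtype=float)
    vis = _visible_mask(
        data.positions[T], data.headings[T], a, b, R_visual, params.occlusion
    )
    C = np.where(vis, C, 0.0)
    np.fill_diagonal(C, 0.0)
    return motion_salience(C, cue)


# ---------------------------------------------------------------------------
# leader-follower inference
# ---------------------------------------------------------------------------


def _alignment_xi(vi: np.ndarray, vj: np.ndarray) -> np.ndarray:
    """xi(lag) for lag = -(n-1)..(n-1), averaged over the valid overlap."""
    n = vi.shape[0]
    xc = (
        np.correlate(vj[:, 0], vi[:, 0], mode="full")
        + np.correlate(vj[:, 1], vi[:, 1], mode="full")
    )
    counts = n - np.abs(np.arange(-(n - 1), n))
    return np.clip(xc / counts, -1.0, 1.0)


def _argmax_lag(lags_frames: np.ndarray, xi: np.ndarray) -> int:
    """Argmax lag with ties broken toward smallest |lag|, then negative lag."""
    top = xi.max()
    cand = lags_frames[xi >= top - 1e-12]
    return int(min(cand, key=lambda k: (abs(k), k)))


def directional_alignment(
    data: TrajectoryDataset, i: int, j: int, T_b: int, T_f: int
) -> AlignmentCurve:
    """Lagged directional alignment xi_ij(lambda) over frames [T_b, T_f].

    The average runs over the shrinking overlap at each lag (no padding);
    lambda_star is the argmax lag in seconds, ties resolved toward the
    smallest magnitude and then toward the negative lag.
    """
    if i == j:
        raise ValueError("i and j must differ")
    if T_f - T_b < 1 or T_b < 0 or T_f >= data.n_frames:
        raise IndexError("alignment window must span at least 2 frames in range")
    v = data.heading_vectors()[T_b : T_f + 1]
    xi = _alignment_xi(v[:, i], v[:, j])
    n = T_f - T_b + 1
    lags_frames = np.arange(-(n - 1), n)
    star = _argmax_lag(lags_frames, xi)
    return AlignmentCurve(
        lags=lags_frames * data.dt, xi=xi, lambda_star=star * data.dt
    )


def lag_matrix(data: TrajectoryDataset, T_b: int, T_f: int) -> np.ndarray:
    """(N, N) matrix of lambda*_ij in seconds (antisymmetric up to ties)."""
    n = data.n_individuals
    lam = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lam_ij = directional_alignment(data, i, j, T_b, T_f).lambda_star
            lam[i, j] = lam_ij
            lam[j, i] = -lam_ij
    return lam


def leader_follower_network(
    data: TrajectoryDataset, T_b: int, T_f: int
) -> nx.DiGraph:
    """Directed leader-to-follower graph from pairwise alignment lags.

    lambda*_ij > 0 means j reaches its best alignment with i after a positive
    delay, i.e. j follows i: edge i -> j.  A zero lag (synchronized pair)
    yields no edge.
    """
    lam = lag_matrix(data, T_b, T_f)
    g = nx.DiGraph()
    g.add_nodes_from(range(data.n_individuals))
    n = data.n_individuals
    for i in range(n):
        for j in range(i + 1, n):
            if lam[i, j] > 0:
                g.add_edge(i, j)
            elif lam[i, j] < 0:
                g.add_edge(j, i)
    return g


def leadership(network: nx.DiGraph) -> LeadershipVector:
    """Normalized out-degree L_i = d_i_out / (N - 1) per node."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    vals = np.array([network.out_degree(i) / (n - 1) for i in range(n)])
    return LeadershipVector(vals)


def salience_leadership_correlation(
    salience: MotionSalienceVector | np.ndarray,
    leaders: LeadershipVector | np.ndarray,
) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN when either vector is constant (correlation undefined).
    """
    s = salience.values if isinstance(salience, MotionSalienceVector) else np.asarray(salience, float)
    l = leaders.values if isinstance(leaders, LeadershipVector) else np.asarray(leaders, float)
    if s.shape != l.shape:
        raise ValueError("salience and leadership vectors differ in length")
    if s.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(s) == 0 or np.ptp(l) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(s, l)
    return float(rho)


# ---------------------------------------------------------------------------
# U-turn windows and segment grids
# ---------------------------------------------------------------------------


@dataclass
class UTurnWindow:
    start: int
    end: int
    switch: int


def detect_uturns(
    data: TrajectoryDataset,
    s_pre: float = 0.5,
    s_post: float = 0.5,
) -> list[UTurnWindow]:
    """Windows around sustained sign changes of the group's angular velocity.

    The angular velocity is the group mean of each individual's rate of change
    of polar angle about the tank center.  A switch at frame k qualifies when
    the sign is stable for at least ``s_pre`` seconds before and ``s_post``
    seconds after; the returned window spans those stable stretches.
    """
    if data.tank_center is None:
        raise ConfigurationError("detect_uturns requires tank geometry")
    rel = data.positions - data.tank_center
    theta = np.unwrap(np.arctan2(rel[..., 1], rel[..., 0]), axis=0)
    omega = np.diff(theta, axis=0).mean(axis=1) / data.dt
    n_pre = max(int(round(s_pre / data.dt)), 1)
    n_post = max(int(round(s_post / data.dt)), 1)
    sign = np.sign(omega)
    windows: list[UTurnWindow] = []
    for k in range(len(omega) - 1):
        if sign[k] == 0 or sign[k + 1] == 0 or sign[k] == sign[k + 1]:
            continue
        if k + 1 < n_pre or k + 1 + n_post > len(omega):
            continue
        if not (sign[k - n_pre + 1 : k + 1] == sign[k]).all():
            continue
        if not (sign[k + 1 : k + 1 + n_post] == sign[k + 1]).all():
            continue
        windows.append(UTurnWindow(start=k + 1 - n_pre, end=k + 1 + n_post, switch=k + 1))
    return windows


def segment_grid(
    window: tuple[int, int],
    taus: list[float],
    stride: float,
    dt: float,
) -> list[tuple[int, float]]:
    """(T, tau) segment pairs covering a window of frames.

    For each tau, the first segment ends at ``start + tau`` and subsequent end
    times step by ``stride``; segments whose end reaches the window's final
    frame are excluded, keeping every [T - tau, T] strictly inside the window.
    Times are in seconds, frames are indices; returns (T_frame, tau) pairs.
    """
    start, end = window
    out: list[tuple[int, float]] = []
    n_stride = max(int(round(stride / dt)), 1)
    for tau in taus:
        n_tau = int(round(tau / dt))
        T = start + n_tau
        while T < end:
            out.append((T, tau))
            T += n_stride
    return out
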