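"""Collective-response statistics: polarization, correlation length,
information transfer speed, response accuracy and responsiveness.

polarization        phi = || mean of unit velocities ||, in [0, 1].
correlation C(r)    mean dot product of velocity fluctuations
                    u_i = v_i - <v> over pairs binned by distance; the
                    correlation length r0 is the first zero crossing of C,
                    linearly interpolated.  Only responding individuals enter.
transfer speed V_s  least-squares slope of information transfer distance
                    against response lag across individuals.
accuracy delta(t)   mean dot product of unit velocities with the informed
                    direction n, in [-1, 1].
responsiveness R    time average of 1 - V(t).n over the response window,
                    in [0, 2]; lower is better.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .analysis import lag_matrix
from .dataset import TrajectoryDataset
from .simulation import SimTrace

logger = logging.getLogger(__name__)


def _unitize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(norms > 0, norms, 1.0)


def polarization(velocities: np.ndarray) -> float:
    """Norm of the group-mean unit velocity, phi in [0, 1]."""
    return float(np.linalg.norm(_unitize(velocities).mean(axis=0)))


@dataclass
class CorrelationFunction:
    r: np.ndarray          # bin centers, mm
    C: np.ndarray
    bin_width: float
    r0: float              # correlation length, mm; NaN if C never crosses zero


def _mean_nn_distance(positions: np.ndarray) -> float:
    d = np.linalg.norm(positions[None, :, :] - positions[:, None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def correlation_function(
    velocities: np.ndarray,
    positions: np.ndarray,
    bin_width: float | None = None,
    responders: np.ndarray | None = None,
) -> CorrelationFunction:
    """Velocity-fluctuation correlation C(r) and correlation length r0.

    Fluctuations are computed over the responding subset only (all agents by
    default).  The smoothed delta filter is realized as fixed-width distance
    bins, defaulting to the mean nearest-neighbor distance; r0 interpolates
    linearly between the bins bracketing the first sign change and is NaN
    (with a warning) when C never changes sign.
    """
    v = _unitize(velocities)
    x = np.asarray(positions, dtype=float)
    if responders is not None:
        responders = np.asarray(responders, dtype=bool)
        v, x = v[responders], x[responders]
    n = v.shape[0]
    if n < 3:
        raise ValueError("correlation function needs at least 3 responders")
    u = v - v.mean(axis=0)
    if bin_width is None:
        bin_width = _mean_nn_distance(x)
    d = np.linalg.norm(x[None, :, :] - x[:, None, :], axis=-1)
    dots = u @ u.T
    iu = np.triu_indices(n, k=1)
    pair_d, pair_c = d[iu], dots[iu]
    n_bins = int(np.ceil(pair_d.max() / bin_width)) or 1
    idx = np.minimum((pair_d // bin_width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=pair_c, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    C = sums[keep] / counts[keep]
    centers = (np.arange(n_bins)[keep] + 0.5) * bin_width
    r0 = float("nan")
    sgn = np.sign(C)
    for k in range(len(C) - 1):
        if sgn[k] > 0 and sgn[k + 1] <= 0:
            # linear interpolation between bracketing bin centers
            r0 = centers[k] + (centers[k + 1] - centers[k]) * C[k] / (C[k] - C[k + 1])
            break
    if math.isnan(r0):
        logger.warning("correlation function has no zero crossing; r0 undefined")
    return CorrelationFunction(r=centers, C=C, bin_width=float(bin_width), r0=float(r0))


# ---------------------------------------------------------------------------
# information transfer speed
# ---------------------------------------------------------------------------


@dataclass
class InfoTransferResult:
    ranks: np.ndarray          # permutation ranks, 1-based; -1 for excluded
    delays: np.ndarray         # s; NaN for excluded
    distances: np.ndarray      # mm; NaN for excluded
    V_s: float                 # fitted slope, mm/s; NaN when no fit possible
    intercept: float
    r_value: float
    n_excluded: int


def _fit_speed(delays: np.ndarray, distances: np.ndarray):
    ok = np.isfinite(delays) & np.isfinite(distances)
    if ok.sum() < 2 or np.ptp(delays[ok]) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(delays[ok], distances[ok])
    return float(res.slope), float(res.intercept), float(res.rvalue)


def spin_transfer_speed(trace: SimTrace) -> InfoTransferResult:
    """Transfer speed of the spinning state from a collective-spin trace.

    Each spinner's lag is its first-spin time minus the initiator's; its
    transfer distance is its Euclidean distance to the initiator.  Ranks are
    by first-spin step (ties: distance to initiator, then id); agents that
    never spin are excluded and counted.
    """
    first = trace.first_spin_steps()
    n = first.size
    pos0 = trace.dataset.positions[0]
    dist = np.linalg.norm(pos0 - pos0[trace.initiator], axis=1)
    spun = first >= 0
    if spun.sum() < 2:
        return InfoTransferResult(
            ranks=np.where(spun, 1, -1), delays=np.where(spun, 0.0, np.nan),
            distances=np.where(spun, dist, np.nan), V_s=float("nan"),
            intercept=float("nan"), r_value=float("nan"),
            n_excluded=int((~spun).sum()),
        )
    t0 = first[trace.initiator]
    lag = np.where(spun, (first - t0) * trace.dataset.dt, np.nan)
    order = sorted(np.flatnonzero(spun), key=lambda i: (first[i], dist[i], i))
    ranks = np.full(n, -1, dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    d = np.where(spun, dist, np.nan)
    slope, intercept, rv = _fit_speed(lag, d)
    return InfoTransferResult(
        ranks=ranks, delays=lag, distances=d, V_s=slope, intercept=intercept,
        r_value=rv, n_excluded=int((~spun).sum()),
    )


def turn_ranks_and_delays(
    data: TrajectoryDataset,
    window: tuple[int, int],
    lam: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Turning ranks kappa_i and delays t_i from pairwise alignment lags.

    Scores w_ij = +1 when lambda*_ij < 0 (i follows j), -1 when
    lambda*_ij > 0, 0 on a tie; W_i = sum_j w_ij.  Ranks are ascending in W
    (ties: earlier heading-change time, then id).  Delays follow the rank
    recursion t_i = mean over kappa_j < kappa_i of (t_j + |lambda*_ij|),
    with t = 0 at kappa = 1.
    """
    if lam is None:
        lam = lag_matrix(data, window[0], window[1])
    n = data.n_individuals
    w = np.where(lam < 0, 1, np.where(lam > 0, -1, 0))
    np.fill_diagonal(w, 0)
    W = w.sum(axis=1)
    # tie-break: first frame the heading departs from its value at the window start
    head = data.headings[window[0] : window[1] + 1]
    dev = np.abs((head - head[0] + np.pi) % (2 * np.pi) - np.pi) > 1e-6
    first_change = np.where(dev.any(axis=0), dev.argmax(axis=0), dev.shape[0])
    order = sorted(range(n), key=lambda i: (W[i], first_change[i], i))
    kappa = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        kappa[i] = r
    delays = np.zeros(n)
    for i in order:
        if kappa[i] == 1:
            delays[i] = 0.0
            continue
        pred = [j for j in range(n) if kappa[j] < kappa[i]]
        delays[i] = sum(delays[j] + abs(lam[i, j]) for j in pred) / (kappa[i] - 1)
    return kappa, delays


def subgroup_radius(positions: np.ndarray, members: np.ndarray) -> float:
    """Half the maximum pairwise distance within a subgroup (0 for singletons)."""
    pts = positions[members]
    if pts.shape[0] < 2:
        return 0.0
    d = np.linalg.norm(pts[None, :, :] - pts[:, None, :], axis=-1)
    return float(d.max() / 2.0)


def turn_transfer_speed(
    positions: np.ndarray,
    delays: np.ndarray,
    density: float = 1.0,
) -> InfoTransferResult:
    """Transfer speed for a collective turn from turning delays.

    The transfer distance of individual i is the radius of the subgroup of
    agents with delay <= t_i (half its maximum pairwise distance), divided by
    the group density (fixed at 1).  V_s is the least-squares slope of
    distance against delay.
    """
    delays = np.asarray(delays, dtype=float)
    n = delays.size
    d_turn = np.empty(n)
    for i in range(n):
        members = np.flatnonzero(delays <= delays[i])
        d_turn[i] = subgroup_radius(positions, members) / density
    order = np.argsort(delays, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    slope, intercept, rv = _fit_speed(delays, d_turn)
    return InfoTransferResult(
        ranks=ranks, delays=delays, distances=d_turn, V_s=slope,
        intercept=intercept, r_value=rv, n_excluded=0,
    )


# ---------------------------------------------------------------------------
# response accuracy and responsiveness
# ---------------------------------------------------------------------------


def response_accuracy(velocities: np.ndarray, n_hat: np.ndarray) -> float:
    """delta_resp = mean dot product of unit velocities with n-hat, in [-1, 1]."""
    n_hat = np.asarray(n_hat, dtype=float)
    return float(np.mean(_unitize(velocities) @ n_hat))


def responsiveness(
    velocities: np.ndarray,
    n_hat: np.ndarray,
    dt: float,
    t0: float | None = None,
    t1: float | None = None,
) -> float:
    """Time-averaged misalignment R = <1 - V(t).n> over [t0, t1], in [0, 2].

    ``velocities`` has shape (frames, N, 2); V(t) is the mean unit velocity.
    The integral is trapezoidal over the discrete steps; t0/t1 are seconds
    from the start of the series and default to the full span.
    """
    v = _unitize(velocities)
    n_hat = np.asarray(n_hat, dtype=float)
    series = 1.0 - v.mean(axis=1) @ n_hat
    times = np.arange(len(series)) * dt
    t0 = times[0] if t0 is None else t0
    t1 = times[-1] if t1 is None else t1
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    keep = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    return float(np.trapezoid(series[keep], times[keep]) / (times[keep][-1] - times[keep][0]))


def max_spinning_lag(trace: SimTrace) -> tuple[float, int]:
    """(max lag of spinners behind the activation step in s, never-spun count)."""
    first = trace.first_spin_steps()
    spun = first >= 0
    if not spun.any():
        return float("nan"), int((~spun).sum())
    lag = (first[spun] - trace.activation_step) * trace.dataset.dt
    return float(lag.max()), int((~spun).sum())


def spatial_size(positions: np.ndarray) -> float:
    """Maximum pairwise distance within the group, mm."""
    d = np.linalg.norm(positions[None, :, :] - positions[:, None, :], axis=-1)
    return float(d.max())


def turn_responders(trace: SimTrace, threshold: float = math.pi / 2) -> np.ndarray:
    """Agents whose final heading lies within ``threshold`` of the informed
    direction (the turn-scenario responder rule)."""
    v = trace.dataset.heading_vectors()[-1]
    cosines = v @ trace.informed_direction
    return cosines > math.cos(threshold)


def trace_metrics(trace: SimTrace) -> dict:
    """Summary statistics of one simulation run.

    Spin runs report whether the spinning state reached every agent before
    the initiator finished its 2*pi rotation, the transfer speed V_s, the
    correlation length r0 (computed at the initiator-stop step over agents
    that ever spun) and the maximum spinning lag.  Turn runs report the final
    response accuracy and polarization, the responsiveness R over
    [activation, end] and r0 at the final step over responders.
    """
    cfg = trace.config
    ds = trace.dataset
    v = ds.heading_vectors()
    out: dict = {
        "scenario": cfg.scenario,
        "policy": cfg.policy,
        "N": cfg.N,
        "seed": cfg.seed,
        "spatial_size_mm": spatial_size(ds.positions[-1]),
    }
    if cfg.scenario == "spin":
        stop = trace.initiator_stop_step
        upto = ds.n_frames - 1 if stop is None else min(stop + 1, ds.n_frames - 1)
        out["all_spinning_before_initiator_done"] = bool(
            trace.spinning[: upto + 1].all(axis=1).any()
        )
        st = spin_transfer_speed(trace)
        out["V_s"] = st.V_s
        lag, never = max_spinning_lag(trace)
        out["max_spinning_lag_s"] = lag
        out["n_never_spun"] = never
        eval_step = upto
        first = trace.first_spin_steps()
        responders = (first >= 0) & (first <= eval_step)
        out["spatial_size_mm"] = spatial_size(ds.positions[eval_step])
        if responders.sum() >= 3:
            cf = correlation_function(
                v[eval_step], ds.positions[eval_step], responders=responders
            )
            out["r0_mm"] = cf.r0
        else:
            out["r0_mm"] = float("nan")
        out["polarization_final"] = polarization(v[eval_step])
    else:
        n_hat = trace.informed_direction
        out["delta_resp_final"] = response_accuracy(v[-1], n_hat)
        out["polarization_final"] = polarization(v[-1])
        out["R"] = responsiveness(v, n_hat, ds.dt, t0=cfg.activation_step * ds.dt)
        responders = turn_responders(trace)
        if responders.sum() >= 3:
            cf = correlation_function(v[-1], ds.positions[-1], responders=responders)
            out["r0_mm"] = cf.r0
        else:
            out["r0_mm"] = float("nan")
    return out
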