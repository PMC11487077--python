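"""First-person visual geometry of elliptical agents.

Each individual is modelled as a non-transparent ellipse in the plane with
semi-major axis ``a`` and semi-minor axis ``b``, its eye on the boundary at the
front along the major axis.  A neighbor's apparent body is the chord between
the two points where rays from the viewer's eye are tangent to the neighbor's
ellipse; the frame-to-frame change of that chord length, accumulated over a
short window and weighted by a frontal-preference factor, is the neighbor's
body orientation change (BOC)

    g_ij(T, tau) = sum_{t=T-n+1}^{T} |beta_j(t) - beta_j(t-1)| / dt * fp(t),
    fp(t) = ((1 + v_i(t) . x_ij(t)) / 2) ** alpha,

with ``beta_j`` the tangent-point chord length, ``v_i`` the viewer's unit
velocity (heading), ``x_ij`` the unit viewer-to-neighbor vector and ``alpha``
the anisotropy exponent tuning how strongly perception favors the front.

Tangent points are obtained in closed form in the neighbor's body frame: the
polar line of the (transformed) eye point with respect to the ellipse is the
chord of contact, so no iterative root finding is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a viewer's eye lies inside or on a neighbor's ellipse."""


class ContractViolation(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EllipticalAgent:
    """An elliptical body: center position (mm), heading (rad), semi-axes (mm).

    ``a`` is the semi-major and ``b`` the semi-minor axis; the aspect ratio
    ``b/a`` lies in (0, 1].  The eye sits on the boundary at the front of the
    ellipse along the major axis, i.e. at ``center + a * (cos h, sin h)``.
    """

    center: np.ndarray
    heading: float
    a: float
    b: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (2,):
            raise ContractViolation("center must be a 2-D point")
        if not (self.a > 0 and self.b > 0):
            raise ContractViolation("semi-axes must be positive")
        if self.b > self.a * (1 + 1e-12):
            raise ContractViolation("aspect ratio b/a must lie in (0, 1]")

    @property
    def eye(self) -> np.ndarray:
        """Eye position: boundary point at the front along the major axis."""
        return self.center + self.a * np.array(
            [math.cos(self.heading), math.sin(self.heading)]
        )

    @property
    def heading_vector(self) -> np.ndarray:
        return np.array([math.cos(self.heading), math.sin(self.heading)])


@dataclass
class TangentPair:
    """Tangent points of the viewing rays on a neighbor's ellipse boundary.

    ``beta`` is the Euclidean chord length between the two tangency points and
    ``angular_interval = (theta_min, theta_max)`` the bearing interval the body
    subtends at the viewer's eye (width < pi; ``theta_max`` may exceed pi when
    the interval wraps, i.e. the interval is [theta_min, theta_min + width]).
    """

    p_left: np.ndarray
    p_right: np.ndarray
    beta: float
    angular_interval: tuple[float, float]

    @property
    def width(self) -> float:
        lo, hi = self.angular_interval
        return hi - lo


@dataclass
class BOCParams:
    """Accumulation parameters for the body-orientation-change sum.

    tau        accumulation duration (s); rounded to a whole number of frames.
    alpha      frontal-preference exponent (>= 0); 0 disables the weighting.
    dt         frame interval (s).
    occlusion  whether occluded neighbors are discarded by callers.
    """

    tau: float
    alpha: float = 1.0
    dt: float = 1.0
    occlusion: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ContractViolation("dt must be positive")
        if self.tau < self.dt:
            raise ContractViolation("tau must be at least one frame interval")
        if self.alpha < 0:
            raise ContractViolation("alpha must be non-negative")

    @property
    def n_frames(self) -> int:
        """Number of transient terms in the window, round(tau / dt)."""
        ratio = self.tau / self.dt
        n = int(round(ratio))
        if abs(ratio - n) > 1e-9:
            logger.warning(
                "tau=%g is not an integer multiple of dt=%g; using %d frames",
                self.tau, self.dt, n,
            )
        return max(n, 1)


# ---------------------------------------------------------------------------
# vectorized core
# ---------------------------------------------------------------------------


def _body_frame_eye(eye, centers, headings):
    """Eye coordinates in each neighbor's body frame (broadcasting)."""
    eye = np.asarray(eye, dtype=float)
    centers = np.asarray(centers, dtype=float)
    headings = np.asarray(headings, dtype=float)
    rx = eye[..., 0] - centers[..., 0]
    ry = eye[..., 1] - centers[..., 1]
    c, s = np.cos(headings), np.sin(headings)
    return rx * c + ry * s, -rx * s + ry * c


def chord_lengths(eye, centers, headings, a, b):
    """Tangent-point chord lengths beta for a viewer eye and many neighbors.

    Vectorized closed form: with the eye at body-frame coordinates (ex, ey)
    and P = ex/a, Q = ey/b, R^2 = P^2 + Q^2 (> 1 outside the ellipse), the
    chord of contact has length 2 sqrt((R^2-1)(a^2 Q^2 + b^2 P^2)) / R^2.
    Entries with the eye inside or on the ellipse yield NaN.
    """
    ex, ey = _body_frame_eye(eye, centers, headings)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    P, Q = ex / a, ey / b
    R2 = P * P + Q * Q
    with np.errstate(invalid="ignore"):
        beta = 2.0 / R2 * np.sqrt(
            np.where(R2 > 1.0, (R2 - 1.0) * (a * a * Q * Q + b * b * P * P), np.nan)
        )
    return beta


def _tangent_points_body(ex, ey, a, b):
    """Two tangency points (body frame) for eye at body coords (ex, ey)."""
    P, Q = ex / a, ey / b
    R = math.hypot(P, Q)
    if R <= 1.0 + 1e-12:
        raise DegenerateGeometryError("eye inside or on the ellipse")
    phi = math.atan2(Q, P)
    delta = math.acos(1.0 / R)
    t1, t2 = phi + delta, phi - delta
    return (
        np.array([a * math.cos(t1), b * math.sin(t1)]),
        np.array([a * math.cos(t2), b * math.sin(t2)]),
    )


def _wrap(angle):
    """Wrap to (-pi, pi]."""
    return math.pi - (math.pi - angle) % (2.0 * math.pi)


def tangent_points(viewer_eye, neighbor: EllipticalAgent) -> TangentPair:
    """Tangency points, chord length and subtended bearing interval.

    The viewer's eye must lie strictly outside the neighbor ellipse; otherwise
    a :class:`DegenerateGeometryError` is raised.  The result is invariant
    under rigid transformations of the whole scene.
    """
    viewer_eye = np.asarray(viewer_eye, dtype=float)
    ex, ey = _body_frame_eye(viewer_eye, neighbor.center, neighbor.heading)
    try:
        q1, q2 = _tangent_points_body(float(ex), float(ey), neighbor.a, neighbor.b)
    except DegenerateGeometryError:
        raise DegenerateGeometryError(
            f"viewer eye {viewer_eye.tolist()} lies inside or on the ellipse of "
            f"agent at {neighbor.center.tolist()} (a={neighbor.a}, b={neighbor.b})"
        ) from None
    c, s = math.cos(neighbor.heading), math.sin(neighbor.heading)
    rot = np.array([[c, -s], [s, c]])
    p1 = neighbor.center + rot @ q1
    p2 = neighbor.center + rot @ q2
    beta = float(np.linalg.norm(p1 - p2))

    t1 = math.atan2(*(p1 - viewer_eye)[::-1])
    t2 = math.atan2(*(p2 - viewer_eye)[::-1])
    # the body subtends less than pi from outside: take the short way round
    diff = _wrap(t2 - t1)
    if diff >= 0:
        lo, width, p_right, p_left = t1, diff, p1, p2
    else:
        lo, width, p_right, p_left = t2, -diff, p2, p1
    return TangentPair(
        p_left=p_left, p_right=p_right, beta=beta,
        angular_interval=(lo, lo + width),
    )


# ---------------------------------------------------------------------------
# occlusion
# ---------------------------------------------------------------------------


def _merge_cover(intervals: list[tuple[float, float]], width: float) -> bool:
    """True iff the union of [lo, hi] intervals covers [0, width]."""
    if not intervals:
        return width <= 0
    intervals = sorted(intervals)
    reach = 0.0
    eps = 1e-12
    for lo, hi in intervals:
        if lo > reach + eps:
            return False
        reach = max(reach, hi)
        if reach >= width - eps:
            return True
    return reach >= width - eps


def occluded_neighbors(
    focal: EllipticalAgent, others: Sequence[EllipticalAgent]
) -> set[int]:
    """Indices of ``others`` fully hidden from the focal eye by nearer bodies.

    A neighbor is occluded iff its entire bearing interval at the focal eye is
    covered by the union of the bearing intervals of agents whose eye-to-center
    distance is strictly smaller.  Partial occlusion keeps the neighbor.
    """
    if not others:
        return set()
    eye = focal.eye
    pairs = [tangent_points(eye, o) for o in others]
    dists = [float(np.linalg.norm(o.center - eye)) for o in others]
    occluded: set[int] = set()
    for j, pj in enumerate(pairs):
        lo_j, hi_j = pj.angular_interval
        width = hi_j - lo_j
        cover: list[tuple[float, float]] = []
        for k, pk in enumerate(pairs):
            if k == j or dists[k] >= dists[j]:
                continue
            lo_k, w_k = pk.angular_interval[0], pk.width
            rel = _wrap(lo_k - lo_j)
            # replicate around the circle so wrap-around intervals clip cleanly
            for base in (rel - 2 * math.pi, rel, rel + 2 * math.pi):
                lo, hi = max(base, 0.0), min(base + w_k, width)
                if hi > lo:
                    cover.append((lo, hi))
        if _merge_cover(cover, width):
            occluded.add(j)
    return occluded


def interval_matrices(positions, headings, a, b):
    """Vectorized bearing intervals for every ordered (viewer, neighbor) pair.

    Returns ``(lo, width, dist)`` arrays of shape (N, N): the interval
    [lo, lo + width] subtended by neighbor j's body at viewer i's eye, and the
    eye-to-center distance.  Diagonal entries and degenerate pairs (eye inside
    the neighbor's ellipse) hold NaN.
    """
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    eyes = positions + a * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    ex, ey = _body_frame_eye(eyes[:, None, :], positions[None, :, :], headings[None, :])
    P, Q = ex / a, ey / b
    R2 = P * P + Q * Q
    bad = R2 <= 1.0 + 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arctan2(Q, P)
        delta = np.arccos(np.clip(1.0 / np.sqrt(np.where(bad, np.nan, R2)), -1.0, 1.0))
    c, s = np.cos(headings)[None, :], np.sin(headings)[None, :]
    angles = []
    for sign in (+1.0, -1.0):
        t = phi + sign * delta
        bx, by = a * np.cos(t), b * np.sin(t)
        wx = positions[None, :, 0] + bx * c - by * s
        wy = positions[None, :, 1] + bx * s + by * c
        angles.append(np.arctan2(wy - eyes[:, None, 1], wx - eyes[:, None, 0]))
    a1, a2 = angles
    diff = np.pi - (np.pi - (a2 - a1)) % (2.0 * np.pi)
    lo = np.where(diff >= 0, a1, a2)
    width = np.abs(diff)
    dist = np.linalg.norm(positions[None, :, :] - eyes[:, None, :], axis=-1)
    return lo, width, dist


def _split_pieces(start: float, width: float) -> list[tuple[float, float]]:
    """Arc [start, start + width] as pieces of [0, 2*pi), split at the wrap."""
    two_pi = 2.0 * math.pi
    s = start % two_pi
    e = s + width
    if e <= two_pi:
        return [(s, e)]
    return [(s, two_pi), (0.0, e - two_pi)]


class _ArcUnion:
    """Union of disjoint arcs on [0, 2*pi), with coverage queries."""

    __slots__ = ("starts", "ends")

    def __init__(self) -> None:
        self.starts: list[float] = []
        self.ends: list[float] = []

    def covers(self, s: float, e: float, eps: float = 1e-9) -> bool:
        import bisect

        k = bisect.bisect_right(self.starts, s + eps) - 1
        return k >= 0 and self.ends[k] >= e - eps

    def add(self, s: float, e: float) -> None:
        import bisect

        i = bisect.bisect_left(self.starts, s)
        # absorb any arcs this one touches
        if i > 0 and self.ends[i - 1] >= s:
            i -= 1
            s = self.starts[i]
        j = i
        while j < len(self.starts) and self.starts[j] <= e:
            e = max(e, self.ends[j])
            j += 1
        self.starts[i:j] = [s]
        self.ends[i:j] = [e]


def occlusion_mask(positions, headings, a, b, range_mask) -> np.ndarray:
    """(N, N) boolean mask: entry (i, j) True iff neighbor j is fully hidden
    from viewer i by the union of in-range agents strictly nearer to i's eye.

    Per viewer, neighbors are swept in order of increasing eye-to-center
    distance while a running union of subtended arcs is maintained, so each
    coverage test is exact and O(log k); equal-distance neighbors are tested
    against the union before either is inserted (neither occludes the other).
    Agrees with :func:`occluded_neighbors` pair by pair.
    """
    lo, width, dist = interval_matrices(positions, headings, a, b)
    n = lo.shape[0]
    valid = range_mask & np.isfinite(width)
    occluded = np.zeros((n, n), dtype=bool)
    for i in range(n):
        cand = np.flatnonzero(valid[i])
        if cand.size < 2:
            continue
        order = cand[np.argsort(dist[i, cand], kind="stable")]
        union = _ArcUnion()
        k = 0
        while k < order.size:
            # group exact distance ties: they cannot occlude one another
            grp = [order[k]]
            while k + 1 < order.size and dist[i, order[k + 1]] == dist[i, order[k]]:
                k += 1
                grp.append(order[k])
            k += 1
            for j in grp:
                pieces = _split_pieces(lo[i, j], width[i, j])
                occluded[i, j] = all(union.covers(s, e) for s, e in pieces)
            for j in grp:
                for s, e in _split_pieces(lo[i, j], width[i, j]):
                    union.add(s, e)
    return occluded


# ---------------------------------------------------------------------------
# frontal weighting and BOC accumulation
# ---------------------------------------------------------------------------


def frontal_weight(v_focal, x_rel, alpha: float) -> float:
    """Frontal-preference factor ((1 + v.x)/2)^alpha in [0, 1].

    Both vectors must be unit length (tolerance 1e-9).  Equals 1 for a
    directly-ahead neighbor, 0 for one directly behind (alpha > 0), and is
    identically 1 when alpha = 0.
    """
    v = np.asarray(v_focal, dtype=float)
    x = np.asarray(x_rel, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL or abs(np.linalg.norm(x) - 1.0) > _UNIT_TOL:
        raise ContractViolation("frontal_weight requires unit vectors")
    if alpha < 0:
        raise ContractViolation("alpha must be non-negative")
    base = (1.0 + float(v @ x)) / 2.0
    base = min(max(base, 0.0), 1.0)  # guard rounding at the endpoints
    return base ** alpha if alpha != 0 else 1.0


class InsufficientWindowError(ValueError):
    """Raised when a BOC window holds fewer than two frames."""


def boc_accumulate(
    focal_track: Sequence[EllipticalAgent],
    neighbor_track: Sequence[EllipticalAgent],
    T: int,
    params: BOCParams,
) -> float:
    """Accumulated body orientation change g_ij(T, tau) of one neighbor.

    ``T`` indexes the final frame of the window within the given tracks; the
    window spans frames T - n .. T with n = round(tau / dt).  Non-negative;
    zero for a completely static scene.  With alpha = 0 this reduces to the
    plain accumulated chord-length change rate.
    """
    n = params.n_frames
    t0 = T - n
    if t0 < 0 or T >= len(focal_track) or T >= len(neighbor_track) or n < 1:
        raise InsufficientWindowError(
            f"window [{t0}, {T}] not covered by tracks of length "
            f"{len(focal_track)}/{len(neighbor_track)}"
        )
    betas = np.array(
        [tangent_points(focal_track[t].eye, neighbor_track[t]).beta
         for t in range(t0, T + 1)]
    )
    total = 0.0
    for k, t in enumerate(range(t0 + 1, T + 1)):
        rel = neighbor_track[t].center - focal_track[t].center
        d = np.linalg.norm(rel)
        if d == 0:
            raise DegenerateGeometryError("coincident agent centers")
        fp = frontal_weight(focal_track[t].heading_vector, rel / d, params.alpha)
        total += abs(betas[k + 1] - betas[k]) / params.dt * fp
    return total
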