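import math

import numpy as np
import pytest

from bocswarm.geometry import EllipticalAgent


def boundary_points(agent: EllipticalAgent, m: int) -> np.ndarray:
    """Dense deterministic sample of the ellipse boundary in world frame."""
    t = np.linspace(0.0, 2.0 * math.pi, m, endpoint=False)
    xb = agent.a * np.cos(t)
    yb = agent.b * np.sin(t)
    c, s = math.cos(agent.heading), math.sin(agent.heading)
    return np.stack(
        [agent.center[0] + xb * c - yb * s, agent.center[1] + xb * s + yb * c],
        axis=1,
    )


def chord_oracle(eye, agent: EllipticalAgent, m: int = 20_001) -> float:
    """Tangent-chord length by dense boundary sampling: the chord between the
    boundary points of extremal bearing as seen from the eye.  The coarse
    argmax is refined twice on progressively finer local grids."""
    eye = np.asarray(eye, dtype=float)
    cdir = agent.center - eye
    cang = math.atan2(cdir[1], cdir[0])
    c, s = math.cos(agent.heading), math.sin(agent.heading)

    def bearing_offset(t):
        px = agent.center[0] + agent.a * np.cos(t) * c - agent.b * np.sin(t) * s
        py = agent.center[1] + agent.a * np.cos(t) * s + agent.b * np.sin(t) * c
        ang = np.arctan2(py - eye[1], px - eye[0])
        return (ang - cang + math.pi) % (2 * math.pi) - math.pi, px, py

    t = np.linspace(0.0, 2.0 * math.pi, m, endpoint=False)
    off, _, _ = bearing_offset(t)

    def refine(t_best, sign):
        step = 2.0 * math.pi / m
        for _ in range(2):
            local = np.linspace(t_best - 2 * step, t_best + 2 * step, 2001)
            o, _, _ = bearing_offset(local)
            t_best = local[np.argmax(sign * o)]
            step = 4 * step / 2000
        _, px, py = bearing_offset(np.array([t_best]))
        return np.array([px[0], py[0]])

    p_hi = refine(t[np.argmax(off)], +1.0)
    p_lo = refine(t[np.argmin(off)], -1.0)
    return float(np.linalg.norm(p_hi - p_lo))


def ray_hits_ellipse(origin, direction, agent: EllipticalAgent) -> bool:
    """True iff the ray origin + t*direction (t > 0) intersects the ellipse."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    c, s = math.cos(agent.heading), math.sin(agent.heading)
    rot = np.array([[c, s], [-s, c]])
    o = rot @ (origin - agent.center)
    d = rot @ direction
    A = (d[0] / agent.a) ** 2 + (d[1] / agent.b) ** 2
    B = 2 * (o[0] * d[0] / agent.a**2 + o[1] * d[1] / agent.b**2)
    C = (o[0] / agent.a) ** 2 + (o[1] / agent.b) ** 2 - 1.0
    disc = B * B - 4 * A * C
    if disc < 0:
        return False
    sq = math.sqrt(disc)
    t1, t2 = (-B - sq) / (2 * A), (-B + sq) / (2 * A)
    return t1 > 0 or t2 > 0


def occlusion_oracle(focal, others, n_rays: int = 720) -> set[int]:
    """Brute-force ray casting: neighbor j is occluded iff every ray through
    the interior of its subtended interval first meets some strictly nearer
    agent (equivalently, hits a nearer agent at all, by interval coverage)."""
    from bocswarm.geometry import tangent_points

    eye = focal.eye
    pairs = [tangent_points(eye, o) for o in others]
    dists = [float(np.linalg.norm(o.center - eye)) for o in others]
    out = set()
    for j, pj in enumerate(pairs):
        lo, hi = pj.angular_interval
        margin = (hi - lo) * 1e-4
        angles = np.linspace(lo + margin, hi - margin, n_rays)
        nearer = [others[k] for k in range(len(others)) if dists[k] < dists[j]]
        if not nearer:
            continue
        covered = all(
            any(
                ray_hits_ellipse(eye, (math.cos(t), math.sin(t)), nb)
                for nb in nearer
            )
            for t in angles
        )
        if covered:
            out.add(j)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_scene(rng, n, extent=300.0, a=15.0, b=6.0, min_gap=None):
    """Non-overlapping random elliptical agents (rejection sampled)."""
    min_gap = min_gap if min_gap is not None else 2.2 * a
    pts = []
    while len(pts) < n:
        p = rng.uniform(-extent, extent, 2)
        if all(np.linalg.norm(p - q) >= min_gap for q in pts):
            pts.append(p)
    return [
        EllipticalAgent(p, float(rng.uniform(-math.pi, math.pi)), a, b)
        for p in pts
    ]
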