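"""Pinhole-camera emulation of onboard vision and bounding-box BOC.

A robot-mounted camera is idealized as a pinhole projecting a 3-D point
p = (p_x, p_y, p_z), expressed in the camera frame with the optical axis
along +z, to image coordinates (u_x, u_y) = (f p_x / p_z, f p_y / p_z).
Each neighbor is an ellipsoid standing on the ground plane (semi-axes a, b
in the plane, a fixed height out of it); its image footprint is summarized
by the axis-aligned bounding box of the projected surface, and the
frame-to-frame change of the box area serves as a camera-side estimate of
body orientation change that needs no tangent geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import EllipticalAgent

MESH_U, MESH_V = 64, 32  # fixed ellipsoid surface parameterization


class BehindCameraError(ValueError):
    """Raised when a point or body is not strictly in front of the camera."""


@dataclass
class PinholeCamera:
    """Pinhole camera: focal length (image units), 3-D pose in world frame.

    The optical axis must not be vertical; image x points to the camera's
    right, image y up (world +z).
    """

    f: float
    position: np.ndarray
    optical_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("focal length must be positive")
        self.position = np.asarray(self.position, dtype=float)
        axis = np.asarray(self.optical_axis, dtype=float)
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            raise ValueError("optical axis must be nonzero")
        self.optical_axis = axis / nrm

    def basis(self) -> np.ndarray:
        """Rows are the camera frame axes (right, up, forward) in world coords."""
        z = self.optical_axis
        up = np.array([0.0, 0.0, 1.0])
        y = up - (up @ z) * z
        ny = np.linalg.norm(y)
        if ny < 1e-12:
            raise ValueError("optical axis may not be vertical")
        y = y / ny
        x = np.cross(z, y)  # viewer's right
        return np.stack([x, y, z])

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.position) @ self.basis().T

    @classmethod
    def at_agent_eye(cls, agent: EllipticalAgent, f: float = 1.0) -> "PinholeCamera":
        """Camera mounted at the agent's eye, looking along its heading."""
        eye = agent.eye
        return cls(
            f=f,
            position=np.array([eye[0], eye[1], 0.0]),
            optical_axis=np.array(
                [math.cos(agent.heading), math.sin(agent.heading), 0.0]
            ),
        )


@dataclass
class BoundingBox:
    u_min: float
    u_max: float
    v_min: float
    v_max: float

    @property
    def area(self) -> float:
        return (self.u_max - self.u_min) * (self.v_max - self.v_min)


def project_point(camera: PinholeCamera, p) -> tuple[float, float]:
    """Project a 3-D world point: (f p_x / p_z, f p_y / p_z) in camera frame.

    Points with non-positive depth raise :class:`BehindCameraError`.
    """
    pc = camera.to_camera(np.asarray(p, dtype=float))
    if pc[2] <= 0:
        raise BehindCameraError(f"point {list(p)} is behind the camera (z={pc[2]:.3g})")
    return float(camera.f * pc[0] / pc[2]), float(camera.f * pc[1] / pc[2])


def _ellipsoid_mesh(agent: EllipticalAgent, height: float) -> np.ndarray:
    """Deterministic (MESH_U x MESH_V) vertex sample of the agent's ellipsoid.

    Semi-axes (a, b, height); the body stands with its center at z = height so
    it rests on the ground plane.
    """
    uu = np.linspace(0.0, 2.0 * math.pi, MESH_U, endpoint=False)
    vv = np.linspace(0.0, math.pi, MESH_V)
    u, v = np.meshgrid(uu, vv, indexing="ij")
    xb = agent.a * np.cos(u) * np.sin(v)
    yb = agent.b * np.sin(u) * np.sin(v)
    zb = height * np.cos(v)
    c, s = math.cos(agent.heading), math.sin(agent.heading)
    xw = agent.center[0] + xb * c - yb * s
    yw = agent.center[1] + xb * s + yb * c
    zw = height + zb
    return np.stack([xw, yw, zw], axis=-1).reshape(-1, 3)


def ellipsoid_bbox(
    camera: PinholeCamera, agent: EllipticalAgent, height: float | None = None
) -> BoundingBox:
    """Image-plane bounding box of an agent's projected ellipsoid surface.

    The surface is sampled on a fixed 64 x 32 deterministic mesh and every
    vertex must be strictly in front of the camera.  ``height`` (the third
    semi-axis) defaults to the minor semi-axis b.
    """
    height = agent.b if height is None else height
    pc = camera.to_camera(_ellipsoid_mesh(agent, height))
    if (pc[:, 2] <= 0).any():
        raise BehindCameraError("agent is not fully in front of the camera")
    u = camera.f * pc[:, 0] / pc[:, 2]
    v = camera.f * pc[:, 1] / pc[:, 2]
    return BoundingBox(float(u.min()), float(u.max()), float(v.min()), float(v.max()))


def bbox_boc(areas: Sequence[float], dt: float, window: int | None = None) -> float:
    """Accumulated bounding-box area change sum |A(t) - A(t-1)| / dt.

    ``window`` limits the sum to the last ``window`` transients (all by
    default).  Non-negative, zero for a static relative pose.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        raise ValueError("need at least two frames of areas")
    trans = np.abs(np.diff(areas)) / dt
    if window is not None:
        trans = trans[-window:]
    return float(trans.sum())
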