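"""Tracked-trajectory container and its CSV schema.

A :class:`TrajectoryDataset` holds per-frame positions (mm) and headings (rad)
for a fixed group of individuals at a constant frame interval ``dt`` (s),
optionally together with the geometry of a circular tank.  The on-disk format
is a long CSV with header ``frame,id,x_mm,y_mm,heading_rad``; the loader
validates that every (frame, id) cell is present exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CSV_COLUMNS = ["frame", "id", "x_mm", "y_mm", "heading_rad"]


class SchemaError(ValueError):
    """Raised for malformed or non-rectangular trajectory tables."""


@dataclass
class TrajectoryDataset:
    """frames x individuals array of poses at a fixed frame interval.

    positions  (n_frames, n_individuals, 2) array, mm.
    headings   (n_frames, n_individuals) array, rad (direction of travel).
    dt         frame interval, s.
    tank_center / tank_radius  optional circular-tank geometry, mm.
    """

    positions: np.ndarray
    headings: np.ndarray
    dt: float
    tank_center: np.ndarray | None = None
    tank_radius: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise SchemaError("positions must have shape (frames, ids, 2)")
        if self.headings.shape != self.positions.shape[:2]:
            raise SchemaError("headings shape must match positions")
        if self.dt <= 0:
            raise SchemaError("dt must be positive")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.headings).all()):
            raise SchemaError("coordinates must be finite")
        if self.tank_center is not None:
            self.tank_center = np.asarray(self.tank_center, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    def heading_vectors(self) -> np.ndarray:
        """(frames, ids, 2) unit velocity vectors."""
        return np.stack([np.cos(self.headings), np.sin(self.headings)], axis=-1)

    def translated(self, offset) -> "TrajectoryDataset":
        offset = np.asarray(offset, dtype=float)
        center = None if self.tank_center is None else self.tank_center + offset
        return TrajectoryDataset(
            self.positions + offset, self.headings.copy(), self.dt,
            tank_center=center, tank_radius=self.tank_radius,
        )

    # -- CSV round trip ----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        f, n = self.n_frames, self.n_individuals
        frames = np.repeat(np.arange(f), n)
        ids = np.tile(np.arange(n), f)
        return pd.DataFrame({
            "frame": frames,
            "id": ids,
            "x_mm": self.positions[:, :, 0].ravel(),
            "y_mm": self.positions[:, :, 1].ravel(),
            "heading_rad": self.headings.ravel(),
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float, **tank) -> "TrajectoryDataset":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        frames = np.sort(df["frame"].unique())
        ids = np.sort(df["id"].unique())
        if not np.array_equal(frames, np.arange(len(frames))):
            raise SchemaError("frames must be contiguous starting at 0")
        pivot_checks = df.groupby(["frame", "id"]).size()
        if (pivot_checks != 1).any() or len(pivot_checks) != len(frames) * len(ids):
            raise SchemaError("table is not rectangular: every (frame, id) "
                              "must appear exactly once")
        df = df.sort_values(["frame", "id"])
        pos = df[["x_mm", "y_mm"]].to_numpy().reshape(len(frames), len(ids), 2)
        head = df["heading_rad"].to_numpy().reshape(len(frames), len(ids))
        return cls(pos, head, dt, **tank)

    @classmethod
    def load_csv(cls, path, dt: float, **tank) -> "TrajectoryDataset":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise SchemaError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dataframe(df, dt, **tank)
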