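"""Open-field and cylinder-test metrics.

Distance, movement-bout velocity and video inactivity (pixel change < 0.8%)
summarise locomotion; posture is scored by the second-central-moment body
elongation

    E = 100 * sqrt((Sxx - Syy)^2 + 4 Sxy^2) / (Sxx + Syy),

which is 0 for a perfectly circular contour and 100 for a collinear one, and
is cut into contracted (< 50), normal, and stretched (> 70) states.  Limb-use
asymmetry in the cylinder test is the percentage of wall contacts made with
the impaired (contralesional) forelimb out of all contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Contour",
    "distance_and_velocity",
    "inactivity_periods",
    "elongation",
    "posture_state",
    "cylinder_asymmetry",
]

POSTURE_CONTRACTED = 50.0
POSTURE_STRETCHED = 70.0
MOVEMENT_FLOOR_CM_S = 0.5


@dataclass
class Trajectory:
    """Center-of-gravity track in cm at uniform sampling."""

    x: np.ndarray
    y: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and equally long")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.fs

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return cls(df["x_cm"].to_numpy(), df["y_cm"].to_numpy(), fs, t0=float(t[0]))


@dataclass
class Contour:
    """Body-contour point set (cm) with its center (centroid unless supplied)."""

    points: np.ndarray  # (n, 2)
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if self.center is None:
            self.center = self.points.mean(axis=0)
        else:
            self.center = np.asarray(self.center, dtype=float)


def distance_and_velocity(
    traj: Trajectory,
    interval: tuple[float, float] | None = None,
    movement_floor: float = MOVEMENT_FLOOR_CM_S,
) -> tuple[float, float]:
    """Total path length (cm) and mean speed over moving samples (cm/s).

    ``interval`` restricts the analysis to [t0, t1] in seconds.  The bout
    velocity averages the per-step speed over steps strictly above
    ``movement_floor``; it is nan when the animal never moves.
    """
    x, y = traj.x, traj.y
    if interval is not None:
        sel = (traj.t >= interval[0]) & (traj.t <= interval[1])
        x, y = x[sel], y[sel]
    if x.size < 2:
        raise ValueError("need at least two samples")
    steps = np.hypot(np.diff(x), np.diff(y))
    distance = float(steps.sum())
    speed = steps * traj.fs
    moving = speed > movement_floor
    bout_velocity = float(speed[moving].mean()) if moving.any() else float("nan")
    return distance, bout_velocity


def inactivity_periods(
    frame_change: np.ndarray,
    fs: float,
    threshold: float = 0.8,
) -> tuple[float, list[tuple[float, float]]]:
    """Inactive fraction and segments where the pixel-change % is strictly below threshold."""
    fc = np.asarray(frame_change, dtype=float)
    if fc.size == 0:
        return 0.0, []
    mask = fc < threshold
    segments = []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    for i0, i1 in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        segments.append((i0 / fs, i1 / fs))
    return float(mask.mean()), segments


def elongation(contour: Contour | np.ndarray, center: np.ndarray | None = None) -> float:
    """Body elongation in percent from the second central moments of the contour."""
    if isinstance(contour, Contour):
        pts, c = contour.points, contour.center
    else:
        pts = np.asarray(contour, dtype=float)
        c = np.asarray(center, dtype=float) if center is not None else pts.mean(axis=0)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 contour points")
    dx = pts[:, 0] - c[0]
    dy = pts[:, 1] - c[1]
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    sxy = float(np.dot(dx, dy))
    denom = sxx + syy
    if denom == 0:
        raise ValueError("all contour points coincide with the center")
    return 100.0 * float(np.sqrt((sxx - syy) ** 2 + 4 * sxy ** 2)) / denom


def posture_state(e: float) -> str:
    """Posture from elongation %: contracted (<50), normal, stretched (>70)."""
    if not 0 <= e <= 100:
        raise ValueError("elongation must be within [0, 100]")
    if e > POSTURE_STRETCHED:
        return "stretched"
    if e < POSTURE_CONTRACTED:
        return "contracted"
    return "normal"


def cylinder_asymmetry(contacts_contra: int, contacts_ipsi: int, contacts_both: int) -> float:
    """Impaired-forelimb wall contacts as % of all wall contacts."""
    if min(contacts_contra, contacts_ipsi, contacts_both) < 0:
        raise ValueError("counts must be nonnegative")
    total = contacts_contra + contacts_ipsi + contacts_both
    if total == 0:
        raise ValueError("no wall contacts")
    return 100.0 * contacts_contra / total
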