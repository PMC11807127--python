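"""Directed front-rear polarity angles and the cue directional intensity ratio.

A directed polarity feature is the bearing from a "rear" reference centroid
to a "front" target centroid,

    alpha = sigma * atan2(ybar_f - ybar_r, xbar_f - xbar_r)   (mod 2*pi),

reported in degrees [0, 360) in a y-up frame.  Concretely: nucleus->Golgi
polarity (rear = nucleus, front = organelle), nucleus displacement (rear =
cell-shape centroid, front = nucleus) and marker polarity (rear = cell-shape
centroid, front = intensity-weighted centroid of a marker channel).

The cue directional intensity ratio s_r quantifies the front/rear intensity
asymmetry of a marker with respect to a known cue direction alpha_p: with
A_l the rear half-plane of the cell (pixels whose offset from the cell-shape
centroid projects negatively onto the cue unit vector),

    s_r = 1 - 2 * (sum_{A_l} I) / (sum_{cell} I)  in  [-1, 1],

-1 = all signal against the cue, 0 = balanced, +1 = all signal along the cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .moments import DEFAULT_Y_AXIS_SIGN, EmptyRegionError, central_moments

#: Centroids closer than this (px) count as coincident -> no polarity.
COINCIDENT_TOL = 1e-9


@dataclass
class CueConfig:
    """External cue (e.g. flow) direction and axis convention."""

    alpha_p_deg: float = 0.0
    sigma: int = DEFAULT_Y_AXIS_SIGN

    def __post_init__(self) -> None:
        self.alpha_p_deg = float(self.alpha_p_deg) % 360.0
        if self.sigma not in (+1, -1):
            raise ValueError("sigma must be +1 or -1")


@dataclass
class CellEntity:
    """One cell's masks and channel views; the unit of feature extraction."""

    label: int
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray | None = None
    organelle_mask: np.ndarray | None = None
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.nucleus_mask is not None:
            self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.organelle_mask is not None:
            self.organelle_mask = np.asarray(self.organelle_mask, dtype=bool)


def _shape_centroid(mask: np.ndarray) -> tuple[float, float]:
    yy, xx = np.nonzero(np.asarray(mask, dtype=bool))
    if xx.size == 0:
        raise EmptyRegionError("empty mask")
    return float(xx.mean()), float(yy.mean())


def _weighted_centroid(channel: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    mset = central_moments(np.asarray(channel, dtype=float), np.asarray(mask, dtype=bool))
    return mset.centroid


def front_rear_angle(
    rear_centroid: tuple[float, float],
    front_centroid: tuple[float, float],
    sigma: int = DEFAULT_Y_AXIS_SIGN,
) -> float:
    """Directed bearing (deg, [0, 360)) from rear to front centroid.

    NaN when the centroids coincide (no polarity axis).
    """
    dx = front_centroid[0] - rear_centroid[0]
    dy = front_centroid[1] - rear_centroid[1]
    if math.hypot(dx, dy) <= COINCIDENT_TOL:
        return float("nan")
    alpha = sigma * math.atan2(dy, dx)
    return math.degrees(alpha % (2.0 * math.pi)) % 360.0


def nucleus_golgi_polarity(
    cell: CellEntity,
    sigma: int = DEFAULT_Y_AXIS_SIGN,
    organelle_channel: str | None = None,
    weighted: bool = True,
) -> float:
    """Bearing from the nucleus centroid to the organelle (Golgi) centroid.

    When ``weighted`` and an organelle channel is named, the front centroid
    is intensity-weighted over the organelle mask; otherwise binary.
    """
    if cell.nucleus_mask is None or not cell.nucleus_mask.any():
        return float("nan")
    if cell.organelle_mask is None or not cell.organelle_mask.any():
        return float("nan")
    rear = _shape_centroid(cell.nucleus_mask)
    if weighted and organelle_channel is not None and organelle_channel in cell.channels:
        ch = np.asarray(cell.channels[organelle_channel], dtype=float)
        if float(ch[cell.organelle_mask].sum()) > 0:
            front = _weighted_centroid(ch, cell.organelle_mask)
        else:
            front = _shape_centroid(cell.organelle_mask)
    else:
        front = _shape_centroid(cell.organelle_mask)
    return front_rear_angle(rear, front, sigma)


def nucleus_displacement(cell: CellEntity, sigma: int = DEFAULT_Y_AXIS_SIGN) -> float:
    """Bearing from the cell-shape centroid to the nucleus centroid."""
    if cell.nucleus_mask is None or not cell.nucleus_mask.any():
        return float("nan")
    rear = _shape_centroid(cell.cell_mask)
    front = _shape_centroid(cell.nucleus_mask)
    return front_rear_angle(rear, front, sigma)


def marker_polarity(
    cell: CellEntity, channel_name: str, sigma: int = DEFAULT_Y_AXIS_SIGN
) -> float:
    """Bearing from the cell-shape centroid to the marker intensity centroid."""
    ch = np.asarray(cell.channels[channel_name], dtype=float)
    if float(ch[cell.cell_mask].sum()) <= 0:
        return float("nan")
    rear = _shape_centroid(cell.cell_mask)
    front = _weighted_centroid(ch, cell.cell_mask)
    return front_rear_angle(rear, front, sigma)


def cue_intensity_ratio(
    cell: CellEntity, channel_name: str, cue: CueConfig
) -> float:
    """Cue directional intensity ratio s_r in [-1, 1].

    The rear half-plane is taken with respect to the intensity-independent
    cell-shape centroid; pixels with exactly zero projection onto the cue
    vector are assigned to the front half (tie rule).
    """
    ch = np.asarray(cell.channels[channel_name], dtype=float)
    mask = cell.cell_mask
    total = float(ch[mask].sum())
    if total <= 0:
        return float("nan")
    cx, cy = _shape_centroid(mask)
    a = math.radians(cue.alpha_p_deg)
    ux, uy = math.cos(a), cue.sigma * math.sin(a)  # cue vector in pixel coords
    yy, xx = np.nonzero(mask)
    t = (xx - cx) * ux + (yy - cy) * uy
    rear = t < 0.0
    rear_sum = float(ch[yy[rear], xx[rear]].sum())
    return 1.0 - 2.0 * rear_sum / total
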