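"""Image moments of masked grey-scale regions.

All shape, orientation and polarity features in this package reduce to raw
and central image moments of a (masked) intensity grid,

    m_ij  = sum_x sum_y x^i y^j I(x, y)
    mu_ij = sum_x sum_y (x - xbar)^i (y - ybar)^j I(x, y)

with pixel coordinates 0-based at pixel centres, ``x`` the column index and
``y`` the row index.  The direction of the y-axis is not fixed here: a sign
``sigma`` (+1 for a y-axis pointing up, -1 for raster order with row 0 at the
top) is carried by :class:`Image2D` and applied by the angular features, not
by the moments themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Maximum total moment order i + j computed.
MAX_ORDER = 3

#: Default y-axis sign: raster images store row 0 at the top.
DEFAULT_Y_AXIS_SIGN = -1


class EmptyRegionError(ValueError):
    """Raised when a region has zero total mass (m_00 = 0)."""


@dataclass
class Image2D:
    """A 2-D scalar intensity grid with optional physical pixel size.

    Parameters
    ----------
    values
        2-D array of finite intensities (arbitrary units).
    pixel_size
        Physical length of one pixel in micrometres, or ``None``.
    y_axis_sign
        +1 if the y-axis points up, -1 for raster order (default).
    """

    values: np.ndarray
    pixel_size: float | None = None
    y_axis_sign: int = DEFAULT_Y_AXIS_SIGN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.y_axis_sign not in (+1, -1):
            raise ValueError("y_axis_sign must be +1 or -1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MomentSet:
    """Raw and central moments up to order :data:`MAX_ORDER` plus centroid."""

    raw: dict[tuple[int, int], float]
    central: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def centroid(self) -> tuple[float, float]:
        """Centre of mass ``(xbar, ybar)`` in pixel coordinates."""
        m00 = self.raw[(0, 0)]
        return self.raw[(1, 0)] / m00, self.raw[(0, 1)] / m00


def _as_image(image: Image2D | np.ndarray) -> Image2D:
    if isinstance(image, Image2D):
        return image
    return Image2D(np.asarray(image, dtype=float))


def _masked_coords(
    image: Image2D, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (x, y, I) over the masked pixels; x = column, y = row."""
    vals = image.values
    if mask is None:
        yy, xx = np.nonzero(np.ones_like(vals, dtype=bool))
        return xx.astype(float), yy.astype(float), vals.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {vals.shape}"
        )
    if not mask.any():
        raise EmptyRegionError("mask has no true pixel")
    yy, xx = np.nonzero(mask)
    return xx.astype(float), yy.astype(float), vals[yy, xx]


def raw_moments(
    image: Image2D | np.ndarray, mask: np.ndarray | None = None
) -> MomentSet:
    """Raw moments ``m_ij`` for ``i + j <= 3`` over the (masked) image.

    For binary shape moments pass an intensity grid identically 1 on the
    mask (e.g. ``mask.astype(float)`` with ``mask=mask``).

    Raises
    ------
    EmptyRegionError
        If the mask is empty or the total intensity in the region is zero,
        in which case the centroid would be undefined.
    """
    image = _as_image(image)
    x, y, inten = _masked_coords(image, mask)
    raw: dict[tuple[int, int], float] = {}
    # precompute powers once; order <= 3 keeps this tiny
    xp = [np.ones_like(x), x, x * x, x * x * x]
    yp = [np.ones_like(y), y, y * y, y * y * y]
    for i in range(MAX_ORDER + 1):
        for j in range(MAX_ORDER + 1 - i):
            raw[(i, j)] = float(np.sum(xp[i] * yp[j] * inten))
    if raw[(0, 0)] == 0.0:
        raise EmptyRegionError("region has zero total intensity (m_00 = 0)")
    return MomentSet(raw=raw)


def centroid(moments: MomentSet) -> tuple[float, float]:
    """Centre of mass ``(xbar, ybar) = (m_10/m_00, m_01/m_00)``."""
    if moments.raw[(0, 0)] == 0.0:
        raise EmptyRegionError("m_00 = 0: centroid undefined")
    return moments.centroid


def central_moments(
    image: Image2D | np.ndarray, mask: np.ndarray | None = None
) -> MomentSet:
    """Raw and central moments ``mu_ij`` for ``i + j <= 3``.

    ``mu_00 = m_00`` and ``mu_10 = mu_01 = 0`` up to floating error.
    """
    image = _as_image(image)
    mset = raw_moments(image, mask)
    xbar, ybar = mset.centroid
    x, y, inten = _masked_coords(image, mask)
    dx, dy = x - xbar, y - ybar
    xp = [np.ones_like(dx), dx, dx * dx, dx * dx * dx]
    yp = [np.ones_like(dy), dy, dy * dy, dy * dy * dy]
    for i in range(MAX_ORDER + 1):
        for j in range(MAX_ORDER + 1 - i):
            mset.central[(i, j)] = float(np.sum(xp[i] * yp[j] * inten))
    return mset


def axis_lengths(moments: MomentSet) -> tuple[float, float]:
    """Full major/minor axis lengths of the intensity-equivalent ellipse.

    The eigenvalues ``l1 >= l2`` of the normalised second-moment matrix
    ``[[mu20, mu11], [mu11, mu02]] / mu00`` give the axis lengths as
    ``4 * sqrt(l)``, matching the full axes of a uniform ellipse with the
    same second moments.

    A degenerate (e.g. single-pixel or collinear) region yields
    ``minor_len = 0``.
    """
    if not moments.central:
        raise ValueError("central moments required; call central_moments first")
    mu00 = moments.central[(0, 0)]
    if mu00 <= 0:
        raise EmptyRegionError("mu_00 <= 0")
    mu20 = moments.central[(2, 0)] / mu00
    mu02 = moments.central[(0, 2)] / mu00
    mu11 = moments.central[(1, 1)] / mu00
    common = np.hypot(mu20 - mu02, 2.0 * mu11)
    l1 = 0.5 * (mu20 + mu02 + common)
    l2 = 0.5 * (mu20 + mu02 - common)
    l2 = max(l2, 0.0)
    return 4.0 * float(np.sqrt(l1)), 4.0 * float(np.sqrt(l2))
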