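"""Synthetic monolayer generator with full ground truth.

Emulates the structure of a confluent endothelial monolayer image: one
convex-ish (elliptical, Voronoi-clipped) cell per grid site, one nucleus
per cell, one compact organelle blob per cell, a junction signal
concentrated in a band on the cell boundaries, and a marker channel with a
controllable intracellular gradient or nucleus/cytosol partition.  Every
generative parameter (orientations, bearings, ratios) is emitted in a
ground-truth table, so each extracted feature and each collective statistic
can be tested by parameter recovery.

All bearings and orientations in the spec and the ground truth are y-up
angles (the same sigma convention as the extraction modules); the generator
converts to raster coordinates internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .circstats import AngleSample
from .moments import DEFAULT_Y_AXIS_SIGN

_BG = 50.0          # camera offset / background level
_FG = 1000.0        # foreground level of nucleus and organelle stains


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic monolayer image.

    Orientation / bearing distributions are given as tuples:
    ``("fixed", angle_deg)`` or ``("vonmises", mu_deg, kappa)``; orientation
    is axial (period 180 deg), bearings are directional.
    """

    image_size: tuple[int, int] = (768, 768)       # (height, width) px
    n_cells: int = 49
    jitter_frac: float = 0.05                       # centre jitter, fraction of spacing
    semi_major_frac: tuple[float, float] = (0.30, 0.42)  # of grid spacing
    lwr_range: tuple[float, float] = (1.4, 2.6)
    orientation: tuple = ("vonmises", 0.0, 0.0)     # axial; kappa=0 -> uniform
    nucleus_scale: float = 0.45                     # nucleus radius / semi-minor axis
    nucleus_displacement_frac: float = 0.25         # of semi-minor axis
    nucleus_bearing: tuple = ("vonmises", 0.0, 0.0)
    organelle_radius: float = 4.0                   # px
    organelle_bearing: tuple = ("vonmises", 0.0, 0.0)  # from the nucleus centre
    marker_model: Literal["uniform", "gradient", "ratio"] = "uniform"
    marker_bearing: float = 0.0                     # gradient bearing, deg (y-up)
    marker_slope: float = 10.0                      # intensity / px along the bearing
    marker_base: float = 500.0
    marker_ratio: float = 3.0                       # nucleus:cytosol intensity ratio
    junction_width: int = 3                         # band dilation radius, px
    junction_bright_fraction: float = 0.5           # q: Bernoulli bright share in band
    junction_high: float = 800.0
    junction_low: float = 200.0
    noise_sd: float = 5.0
    sigma: int = DEFAULT_Y_AXIS_SIGN
    seed: int = 0


@dataclass
class SyntheticImage:
    channels: dict[str, np.ndarray]
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    organelle_labels: np.ndarray
    ground_truth: pd.DataFrame
    spec: SyntheticSpec = field(repr=False, default=None)


def sample_von_mises(n: int, mu: float, kappa: float, seed: int = 0,
                     mode: Literal["directional", "axial"] = "directional") -> AngleSample:
    """Seeded von Mises sample (radians); kappa = 0 gives the uniform circle.

    Axial mode draws directional angles concentrated at 2*mu and halves
    them, so the axial sample concentrates at mu with period 180 deg.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    if mode == "axial":
        theta = rng.vonmises(2.0 * mu, kappa, size=n)
        return AngleSample(theta / 2.0, mode="axial")
    return AngleSample(rng.vonmises(mu, kappa, size=n), mode="directional")


def _draw_angle(rng: np.random.Generator, dist: tuple, axial: bool) -> float:
    """One angle in degrees from a ('fixed', a) or ('vonmises', mu, kappa) spec."""
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "vonmises":
        mu, kappa = math.radians(dist[1]), float(dist[2])
        if axial:
            return math.degrees(rng.vonmises(2 * mu, kappa) / 2.0) % 180.0
        return math.degrees(rng.vonmises(mu, kappa)) % 360.0
    raise ValueError(f"unknown angle distribution {kind!r}")


def _bearing_vector(bearing_deg: float, sigma: int) -> tuple[float, float]:
    """Unit vector of a y-up bearing in raster (x right, y down) coordinates."""
    b = math.radians(bearing_deg)
    return math.cos(b), sigma * math.sin(b)


def _ellipse_mask(shape, cx, cy, a, b, phi_deg, sigma) -> np.ndarray:
    """Rasterise an ellipse with y-up major-axis angle phi."""
    h, w = shape
    ux, uy = _bearing_vector(phi_deg, sigma)
    x0, x1 = max(0, int(cx - a - 2)), min(w, int(cx + a + 3))
    y0, y1 = max(0, int(cy - a - 2)), min(h, int(cy + a + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    p = (dx * ux + dy * uy) / a
    q = (-dx * uy + dy * ux) / b
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = p * p + q * q <= 1.0
    return out


def _disc_mask(shape, cx, cy, r) -> np.ndarray:
    h, w = shape
    x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
    y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return out


def _ellipse_boundary_distance(a, b, ux, uy, dx0, dy0, vx, vy) -> float:
    """Largest t >= 0 with the point (dx0, dy0) + t (vx, vy) inside the
    ellipse (semi-axes a, b; major axis (ux, uy)); offsets in pixel coords
    relative to the ellipse centre."""
    # rotate into ellipse frame
    p0, q0 = dx0 * ux + dy0 * uy, -dx0 * uy + dy0 * ux
    pv, qv = vx * ux + vy * uy, -vx * uy + vy * ux
    # (p0 + t pv)^2/a^2 + (q0 + t qv)^2/b^2 = 1
    A = (pv / a) ** 2 + (qv / b) ** 2
    B = 2 * (p0 * pv / a**2 + q0 * qv / b**2)
    C = (p0 / a) ** 2 + (q0 / b) ** 2 - 1.0
    disc = B * B - 4 * A * C
    if A == 0 or disc < 0:
        return 0.0
    return max(0.0, (-B + math.sqrt(disc)) / (2 * A))


def generate(spec: SyntheticSpec) -> SyntheticImage:
    """Generate one monolayer image stack with ground truth.

    Cells are ellipses on a jittered grid, clipped to their Voronoi region
    (nearest grid seed), which guarantees non-overlap; the grid spacing and
    the semi-axis cap make clipping a rare no-op, so realised shapes match
    the generative parameters.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    n_cols = int(math.ceil(math.sqrt(spec.n_cells * w / h)))
    n_rows = int(math.ceil(spec.n_cells / n_cols))
    sx, sy = w / n_cols, h / n_rows
    s = min(sx, sy)
    a_lo, a_hi = spec.semi_major_frac
    if a_hi > 0.45:
        raise ValueError(
            f"infeasible packing: semi_major_frac upper bound {a_hi} > 0.45 "
            "would let neighbouring cells overlap"
        )
    if 2 * a_hi + 2 * spec.jitter_frac > 1.0 or a_hi + spec.jitter_frac > 0.5:
        raise ValueError(
            f"infeasible packing: jitter_frac {spec.jitter_frac} too large for "
            f"semi-major bound {a_hi} (cells could overlap or be clipped)"
        )

    # seed points (cell centres) on the jittered grid
    centres = []
    for k in range(spec.n_cells):
        i, j = k % n_cols, k // n_cols
        cx = (i + 0.5) * sx + rng.uniform(-1, 1) * spec.jitter_frac * s
        cy = (j + 0.5) * sy + rng.uniform(-1, 1) * spec.jitter_frac * s
        centres.append((cx, cy))
    centres = np.asarray(centres)

    # Voronoi owner of every pixel (safety clip for non-overlap)
    from scipy.spatial import cKDTree

    yy, xx = np.mgrid[0:h, 0:w]
    _, owner = cKDTree(centres).query(np.column_stack([xx.ravel(), yy.ravel()]))
    owner = owner.reshape(h, w)

    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    organelle_labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    for k in range(spec.n_cells):
        label = k + 1
        cx, cy = centres[k]
        a = rng.uniform(a_lo, a_hi) * s
        ratio = rng.uniform(*spec.lwr_range)
        b = a / ratio
        phi = _draw_angle(rng, spec.orientation, axial=True)
        cmask = _ellipse_mask((h, w), cx, cy, a, b, phi, spec.sigma) & (owner == k)
        if not cmask.any():
            raise ValueError(f"infeasible geometry: cell {label} rasterised empty")
        cell_labels[cmask] = label

        ux, uy = _bearing_vector(phi, spec.sigma)
        # nucleus: disc displaced from the cell centre along a sampled bearing,
        # capped so it stays inside the ellipse
        rn = spec.nucleus_scale * b
        psi = _draw_angle(rng, spec.nucleus_bearing, axial=False)
        nvx, nvy = _bearing_vector(psi, spec.sigma)
        d_want = spec.nucleus_displacement_frac * b
        d_max = _ellipse_boundary_distance(a, b, ux, uy, 0.0, 0.0, nvx, nvy) - rn - 1.0
        d = min(d_want, max(d_max, 0.0))
        nx, ny = cx + d * nvx, cy + d * nvy
        nmask = _disc_mask((h, w), nx, ny, rn) & cmask
        nucleus_labels[nmask] = label

        # organelle: disc next to the nucleus along a sampled bearing
        ro = spec.organelle_radius
        omega = _draw_angle(rng, spec.organelle_bearing, axial=False)
        ovx, ovy = _bearing_vector(omega, spec.sigma)
        do_want = rn + ro + 2.0
        do_max = (
            _ellipse_boundary_distance(a, b, ux, uy, nx - cx, ny - cy, ovx, ovy)
            - ro - 1.0
        )
        do = min(do_want, max(do_max, 0.0))
        ox, oy = nx + do * ovx, ny + do * ovy
        omask = _disc_mask((h, w), ox, oy, ro) & cmask & ~nmask
        organelle_labels[omask] = label

        sr_sign = (
            float(np.sign(round(math.cos(math.radians(spec.marker_bearing)), 12)))
            if spec.marker_model == "gradient"
            else 0.0
        )
        # Expected marker-polarity bearing: the intensity-weighted centroid
        # of a linear gradient shifts along Sigma @ g_hat, with Sigma the
        # shape's second-moment tensor (diag(a^2, b^2)/4 in the ellipse
        # frame), so elongated cells rotate the bearing toward their long
        # axis.  This is the analytically expected direction, not a bias.
        if spec.marker_model == "gradient":
            rel = math.radians(spec.marker_bearing - phi)
            marker_expect = (
                phi
                + math.degrees(
                    math.atan2(b * b * math.sin(rel), a * a * math.cos(rel))
                )
            ) % 360.0
        else:
            marker_expect = float("nan")
        rows.append(
            dict(
                label=label, cx=cx, cy=cy,
                semi_major=a, semi_minor=b,
                orientation_deg=phi % 180.0, lwr=a / b,
                nucleus_bearing_deg=psi, nucleus_displacement_px=d,
                organelle_bearing_deg=omega, organelle_distance_px=do,
                marker_model=spec.marker_model,
                marker_bearing_deg=(
                    spec.marker_bearing if spec.marker_model == "gradient" else np.nan
                ),
                marker_polarity_expected_deg=marker_expect,
                marker_ratio=(
                    spec.marker_ratio if spec.marker_model == "ratio" else np.nan
                ),
                s_r_sign=sr_sign,
                junction_width=spec.junction_width,
                junction_bright_fraction=spec.junction_bright_fraction,
            )
        )

    channels = _render_channels(
        spec, cell_labels, nucleus_labels, organelle_labels, centres, rng
    )
    return SyntheticImage(
        channels=channels,
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        organelle_labels=organelle_labels,
        ground_truth=pd.DataFrame(rows),
        spec=spec,
    )


def _render_channels(spec, cell_labels, nucleus_labels, organelle_labels, centres, rng):
    from .junctions import cell_contour  # local import to avoid cycle at import time
    from skimage.morphology import dilation, disk

    h, w = cell_labels.shape
    nucleus_ch = np.full((h, w), _BG)
    nucleus_ch[nucleus_labels > 0] = _FG
    organelle_ch = np.full((h, w), _BG)
    organelle_ch[organelle_labels > 0] = _FG

    # junction: bright/low Bernoulli mixture in a band around all cell contours
    contours = np.zeros((h, w), dtype=bool)
    for lbl in np.unique(cell_labels):
        if lbl == 0:
            continue
        contours |= cell_contour(cell_labels == lbl)
    band = dilation(contours, disk(spec.junction_width))
    junction_ch = np.full((h, w), _BG)
    bern = rng.random((h, w)) < spec.junction_bright_fraction
    junction_ch[band] = np.where(bern[band], spec.junction_high, spec.junction_low)

    marker_ch = np.full((h, w), 20.0)
    yy, xx = np.mgrid[0:h, 0:w]
    for k, (cx, cy) in enumerate(centres):
        cmask = cell_labels == k + 1
        if spec.marker_model == "uniform":
            marker_ch[cmask] = spec.marker_base
        elif spec.marker_model == "gradient":
            gx, gy = _bearing_vector(spec.marker_bearing, spec.sigma)
            proj = (xx[cmask] - cx) * gx + (yy[cmask] - cy) * gy
            marker_ch[cmask] = np.maximum(spec.marker_base + spec.marker_slope * proj, 0.0)
        elif spec.marker_model == "ratio":
            marker_ch[cmask] = spec.marker_base
            marker_ch[cmask & (nucleus_labels > 0)] = spec.marker_base * spec.marker_ratio
        else:
            raise ValueError(f"unknown marker model {spec.marker_model!r}")

    channels = {
        "junction": junction_ch,
        "nucleus": nucleus_ch,
        "organelle": organelle_ch,
        "marker": marker_ch,
    }
    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.maximum(
                channels[name] + rng.normal(0.0, spec.noise_sd, size=(h, w)), 0.0
            )
    return channels
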