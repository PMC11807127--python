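import math

import numpy as np
import pytest

import cellpol as cp


def circ_diff_deg(a, b, period=360.0):
    """Smallest absolute angular difference on a circle of the given period."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % period
    return np.minimum(d, period - d)


def rasterise_ellipse(a, b, phi_deg, size=201, sigma=-1):
    """Binary raster of an ellipse with y-up major-axis angle phi."""
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    ux = math.cos(math.radians(phi_deg))
    uy = sigma * math.sin(math.radians(phi_deg))
    dx, dy = xx - c, yy - c
    p = (dx * ux + dy * uy) / a
    q = (-dx * uy + dy * ux) / b
    return p * p + q * q <= 1.0


def disc_mask(r, size=None, cx=None, cy=None):
    size = size or (2 * int(r) + 5)
    cx = size // 2 if cx is None else cx
    cy = size // 2 if cy is None else cy
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def monolayer():
    """One default synthetic monolayer with a marker gradient at 30 deg."""
    spec = cp.SyntheticSpec(
        n_cells=49,
        seed=11,
        nucleus_bearing=("vonmises", 0.0, 1.0),
        organelle_bearing=("vonmises", 210.0, 4.0),
        marker_model="gradient",
        marker_bearing=30.0,
    )
    return cp.generate(spec)


@pytest.fixture(scope="session")
def monolayer_features(monolayer):
    cfg = cp.RunConfig(
        channels={"junction": 0, "nucleus": 1, "organelle": 2, "marker": 3},
        cue_direction_deg=0.0,
    )
    df, report = cp.extract_image_features(
        monolayer.channels,
        cfg,
        cell_labels=monolayer.cell_labels,
        nucleus_labels=monolayer.nucleus_labels,
        image_id="fixture",
    )
    return df.set_index("label").join(
        monolayer.ground_truth.set_index("label"), rsuffix="_gt"
    )
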