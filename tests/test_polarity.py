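"""Front-rear polarity angles and the cue directional intensity ratio."""

import math

import numpy as np
import pytest

import cellpol as cp

from conftest import circ_diff_deg, disc_mask


def make_cell(size=61, r_cell=25):
    mask = disc_mask(r_cell, size=size)
    return mask, size // 2


class TestFrontRearAngle:
    def test_east_is_zero(self):
        assert cp.front_rear_angle((0, 0), (1, 0), sigma=+1) == 0.0

    def test_sign_convention(self):
        assert cp.front_rear_angle((0, 0), (0, 1), sigma=+1) == 90.0
        assert cp.front_rear_angle((0, 0), (0, 1), sigma=-1) == 270.0

    def test_coincident_is_nan(self):
        assert math.isnan(cp.front_rear_angle((3.0, 4.0), (3.0, 4.0)))

    @pytest.mark.parametrize("sigma", [+1, -1])
    def test_quadrant_oracle(self, rng, sigma):
        """Agrees with plain vector geometry in all four quadrants."""
        for _ in range(50):
            rear = rng.uniform(-10, 10, 2)
            front = rng.uniform(-10, 10, 2)
            if np.allclose(rear, front):
                continue
            got = cp.front_rear_angle(tuple(rear), tuple(front), sigma)
            dx, dy = front - rear
            want = math.degrees(
                math.atan2(sigma * dy, dx) % (2 * math.pi)
            ) % 360.0
            assert circ_diff_deg(got, want) < 1e-9


class TestNucleusGolgiPolarity:
    def _cell_with_organelle(self, bearing_deg, dist=12, sigma=-1):
        mask, c = make_cell()
        b = math.radians(bearing_deg)
        ox = c + dist * math.cos(b)
        oy = c + dist * sigma * math.sin(b)
        nucleus = disc_mask(6, size=61, cx=c, cy=c)
        organelle = disc_mask(3, size=61, cx=int(round(ox)), cy=int(round(oy)))
        ch = np.where(organelle, 500.0, 10.0)
        return cp.CellEntity(
            1, mask, nucleus_mask=nucleus, organelle_mask=organelle,
            channels={"organelle": ch},
        )

    @pytest.mark.parametrize("bearing", [0.0, 90.0, 210.0, 333.0])
    def test_synthetic_placement(self, bearing):
        cell = self._cell_with_organelle(bearing)
        got = cp.nucleus_golgi_polarity(cell, sigma=-1, organelle_channel="organelle")
        assert circ_diff_deg(got, bearing) < 4.0  # integer placement tolerance

    def test_concentric_is_nan(self):
        mask, c = make_cell()
        nucleus = disc_mask(8, size=61, cx=c, cy=c)
        organelle = disc_mask(4, size=61, cx=c, cy=c)
        cell = cp.CellEntity(1, mask, nucleus_mask=nucleus, organelle_mask=organelle)
        assert math.isnan(cp.nucleus_golgi_polarity(cell))

    def test_swapping_targets_shifts_180(self):
        cell = self._cell_with_organelle(40.0)
        fwd = cp.nucleus_golgi_polarity(cell)
        swapped = cp.CellEntity(
            1, cell.cell_mask, nucleus_mask=cell.organelle_mask,
            organelle_mask=cell.nucleus_mask,
        )
        back = cp.nucleus_golgi_polarity(swapped)
        assert circ_diff_deg(fwd, (back + 180.0) % 360.0) < 1e-6

    def test_missing_organelle_is_nan(self):
        mask, c = make_cell()
        cell = cp.CellEntity(1, mask, nucleus_mask=disc_mask(6, size=61))
        assert math.isnan(cp.nucleus_golgi_polarity(cell))


class TestMarkerPolarity:
    def test_delta_spot_bearing(self):
        mask, c = make_cell()
        ch = np.full(mask.shape, 0.0)
        # spot at bearing 45 deg (y-up, sigma=-1): up-right in raster coords
        ch[c - 10, c + 10] = 100.0
        cell = cp.CellEntity(1, mask, channels={"m": ch})
        got = cp.marker_polarity(cell, "m", sigma=-1)
        assert circ_diff_deg(got, 45.0) < 2.0

    def test_uniform_marker_is_nan(self):
        mask, _ = make_cell()
        cell = cp.CellEntity(1, mask, channels={"m": np.where(mask, 3.0, 0.0)})
        assert math.isnan(cp.marker_polarity(cell, "m"))

    def test_linear_gradient_along_x(self):
        mask, _ = make_cell()
        xx = np.tile(np.arange(mask.shape[1], dtype=float), (mask.shape[0], 1))
        cell = cp.CellEntity(1, mask, channels={"m": 1.0 + 0.1 * xx})
        assert circ_diff_deg(cp.marker_polarity(cell, "m", sigma=+1), 0.0) < 0.5


def test_nucleus_displacement_bearing():
    mask, c = make_cell()
    nucleus = disc_mask(6, size=61, cx=c + 9, cy=c)  # displaced east
    cell = cp.CellEntity(1, mask, nucleus_mask=nucleus)
    assert circ_diff_deg(cp.nucleus_displacement(cell), 0.0) < 1.0


class TestCueIntensityRatio:
    def test_uniform_symmetric_cell_is_zero(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[5:25, 4:36] = True  # even extents: no zero-projection pixels
        cell = cp.CellEntity(1, mask, channels={"m": np.where(mask, 2.0, 0.0)})
        s = cp.cue_intensity_ratio(cell, "m", cp.CueConfig(0.0))
        assert s == pytest.approx(0.0, abs=0.02)

    def test_all_rear_intensity_is_minus_one(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[5:15, 2:38] = True
        ch = np.zeros(mask.shape)
        ch[:, :18] = 5.0  # strictly left of the centroid column (19.5)
        cell = cp.CellEntity(1, mask, channels={"m": ch * mask})
        s = cp.cue_intensity_ratio(cell, "m", cp.CueConfig(0.0))
        assert s == pytest.approx(-1.0)

    def test_75_percent_front(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[5:15, 0:40] = True
        ch = np.where(mask, 1.0, 0.0)
        # front half (x >= 20) carries 3x the intensity of the rear half
        ch[:, 20:] *= 3.0
        cell = cp.CellEntity(1, mask, channels={"m": ch})
        s = cp.cue_intensity_ratio(cell, "m", cp.CueConfig(0.0))
        assert s == pytest.approx(1.0 - 2.0 * 0.25)

    def test_cue_reversal_flips_sign(self, rng):
        mask = np.zeros((30, 30), dtype=bool)
        mask[4:26, 4:26] = True
        ch = rng.uniform(0.1, 5.0, size=mask.shape) * mask
        cell = cp.CellEntity(1, mask, channels={"m": ch})
        for alpha in (0.0, 45.0, 123.0):
            s1 = cp.cue_intensity_ratio(cell, "m", cp.CueConfig(alpha))
            s2 = cp.cue_intensity_ratio(cell, "m", cp.CueConfig(alpha + 180.0))
            assert s2 == pytest.approx(-s1, abs=1e-12)

    def test_bounds_property(self, rng):
        for _ in range(20):
            mask = rng.random((15, 15)) < 0.6
            if not mask.any():
                continue
            ch = rng.uniform(0, 10, size=mask.shape) * mask
            if ch.sum() == 0:
                continue
            cell = cp.CellEntity(1, mask, channels={"m": ch})
            s = cp.cue_intensity_ratio(
                cell, "m", cp.CueConfig(float(rng.uniform(0, 360)))
            )
            assert -1.0 <= s <= 1.0

    def test_zero_intensity_is_nan(self):
        mask, _ = make_cell()
        cell = cp.CellEntity(1, mask, channels={"m": np.zeros(mask.shape)})
        assert math.isnan(cp.cue_intensity_ratio(cell, "m", cp.CueConfig(0.0)))

    def test_translation_invariance(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[4:16, 6:20] = True
        ch = np.zeros(mask.shape)
        ch[4:16, 6:20] = np.arange(12 * 14, dtype=float).reshape(12, 14) + 1
        cell1 = cp.CellEntity(1, mask, channels={"m": ch})
        mask2 = np.roll(np.roll(mask, 11, axis=0), 13, axis=1)
        ch2 = np.roll(np.roll(ch, 11, axis=0), 13, axis=1)
        cell2 = cp.CellEntity(1, mask2, channels={"m": ch2})
        cue = cp.CueConfig(77.0)
        assert cp.cue_intensity_ratio(cell1, "m", cue) == pytest.approx(
            cp.cue_intensity_ratio(cell2, "m", cue), abs=1e-12
        )


def test_marker_polarity_consistent_with_sr(monolayer_features):
    """Gradient at bearing beta: marker polarity ~ beta (shape-corrected)
    and sign(s_r) = sign(cos(beta - alpha_p))."""
    df = monolayer_features
    err = circ_diff_deg(
        df["angle_marker_polarity_deg"], df["marker_polarity_expected_deg"]
    )
    assert np.nanmedian(err) < 3.0
    expected_sign = np.sign(np.cos(np.deg2rad(df["marker_bearing_deg"])))
    assert (np.sign(df["cue_intensity_ratio"]) == expected_sign).all()
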