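"""Junction morphometrics from dilated cell outlines.

The one-pixel inner contour of each cell mask is dilated by a user-defined
thickness (a disc radius in px) to give the *interface region*: a band
straddling both sides of the cell boundary, where junction proteins such as
VE-cadherin live.  Within that band, Otsu thresholding separates junction
protein from background, yielding three normalised features:

- interface occupancy  = protein area / interface area
- intensity per interface area = mean junction intensity over the band
- cluster density      = mean junction intensity over the protein area

The band thickness is the single parameter of the whole junction analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion

from .moments import EmptyRegionError

DEFAULT_JUNCTION_THICKNESS = 3  # px
OTSU_NBINS = 256


@dataclass
class JunctionRecord:
    label: int
    interface_area: float              # px^2
    protein_area: float                # px^2, Otsu-positive; NaN if Otsu undefined
    interface_occupancy: float         # protein/interface in [0, 1]; NaN if undefined
    intensity_per_interface_area: float
    cluster_density: float             # mean intensity over protein area
    touches_border: bool = False


def cell_contour(cell_mask: np.ndarray) -> np.ndarray:
    """One-pixel inner contour of a binary mask (mask minus its erosion)."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    return cell_mask & ~erosion(cell_mask)


def interface_region(cell_mask: np.ndarray, thickness: int) -> np.ndarray:
    """Dilate the one-pixel cell contour by a disc of radius ``thickness``.

    The region straddles both sides of the boundary and is clipped at image
    bounds; it is *not* clipped to the cell's own mask, because junction
    signal lives on both sides of a shared boundary.
    """
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise EmptyRegionError("empty cell mask")
    return dilation(cell_contour(cell_mask), disk(thickness))


def otsu_threshold(values: np.ndarray, nbins: int = OTSU_NBINS) -> float:
    """Otsu threshold of a 1-D sample over ``nbins`` bins between min and max.

    Raises ValueError on a constant sample (the two-class split is undefined).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.min() == values.max():
        raise ValueError("constant intensity: Otsu threshold undefined")
    return float(threshold_otsu(values, nbins=nbins))


def junction_stats(
    region: np.ndarray,
    junction_channel: np.ndarray,
    label: int = 0,
    touches_border: bool = False,
) -> JunctionRecord:
    """Junction features over a precomputed interface region.

    Otsu is computed on the intensity histogram restricted to the region;
    the protein area is the set of region pixels at or above the threshold.
    A constant-intensity region leaves occupancy undefined (NaN) while the
    mean intensity is still reported.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise EmptyRegionError("empty interface region")
    vals = np.asarray(junction_channel, dtype=float)[region]
    interface_area = float(region.sum())
    mean_intensity = float(vals.mean())
    try:
        thr = otsu_threshold(vals)
    except ValueError:
        return JunctionRecord(
            label=label,
            interface_area=interface_area,
            protein_area=float("nan"),
            interface_occupancy=float("nan"),
            intensity_per_interface_area=mean_intensity,
            cluster_density=float("nan"),
            touches_border=touches_border,
        )
    positive = vals >= thr
    protein_area = float(positive.sum())
    cluster = float(vals[positive].mean()) if protein_area > 0 else float("nan")
    return JunctionRecord(
        label=label,
        interface_area=interface_area,
        protein_area=protein_area,
        interface_occupancy=protein_area / interface_area,
        intensity_per_interface_area=mean_intensity,
        cluster_density=cluster,
        touches_border=touches_border,
    )


def junction_record(
    cell_mask: np.ndarray,
    junction_channel: np.ndarray,
    thickness: int = DEFAULT_JUNCTION_THICKNESS,
    label: int = 0,
) -> JunctionRecord:
    """Interface region + junction features for one cell mask."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    region = interface_region(cell_mask, thickness)
    border = bool(
        cell_mask[0, :].any()
        or cell_mask[-1, :].any()
        or cell_mask[:, 0].any()
        or cell_mask[:, -1].any()
    )
    return junction_stats(region, junction_channel, label=label, touches_border=border)
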