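"""Compartmentalised intensity readouts: nucleus, cytosol and membrane.

The cytosol is the strict complement of the nucleus within the cell
(cytosol = cell \\ nucleus), so totals partition exactly:
total(cell) = total(nucleus) + total(cytosol).  The membrane is a band of
user-defined thickness around the cell contour (the same construction as
the junction interface region) and overlaps the cytosol; it is a separate
readout, not a third partition element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .junctions import interface_region
from .moments import EmptyRegionError

DEFAULT_MEMBRANE_THICKNESS = 3  # px


@dataclass
class CompartmentStats:
    """Areas, totals and means per compartment plus the nucleus/cytosol ratio."""

    label: int
    area_cell: float
    area_nucleus: float
    area_cytosol: float
    area_membrane: float
    total_cell: float
    total_nucleus: float
    total_cytosol: float
    total_membrane: float
    mean_cell: float
    mean_nucleus: float
    mean_cytosol: float
    mean_membrane: float
    ratio_nucleus_cytosol: float  # mean(nucleus)/mean(cytosol); NaN if undefined


def _region_stats(channel: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    area = float(mask.sum())
    if area == 0:
        return 0.0, 0.0, float("nan")
    total = float(channel[mask].sum())
    return area, total, total / area


def compartment_stats(
    cell,
    channel_name: str,
    membrane_thickness: int = DEFAULT_MEMBRANE_THICKNESS,
    ratio_on: str = "mean",
) -> CompartmentStats:
    """Per-compartment intensity statistics for one cell.

    Parameters
    ----------
    cell
        A :class:`~cellpol.polarity.CellEntity` with a nonempty nucleus mask
        for nucleus/cytosol readouts.
    channel_name
        Name of the channel in ``cell.channels`` to quantify.
    membrane_thickness
        Dilation radius (px, >= 1) of the cell contour for the membrane band.
    ratio_on
        ``"mean"`` (default) or ``"total"``: which quantity enters the
        nucleus/cytosol ratio.
    """
    if membrane_thickness < 1:
        raise ValueError("membrane_thickness must be >= 1")
    channel = np.asarray(cell.channels[channel_name], dtype=float)
    cmask = cell.cell_mask
    if not cmask.any():
        raise EmptyRegionError("empty cell mask")
    nmask = (
        cell.nucleus_mask & cmask
        if cell.nucleus_mask is not None
        else np.zeros_like(cmask)
    )
    cyto = cmask & ~nmask
    memb = interface_region(cmask, membrane_thickness)

    a_cell, t_cell, m_cell = _region_stats(channel, cmask)
    a_nuc, t_nuc, m_nuc = _region_stats(channel, nmask)
    a_cyt, t_cyt, m_cyt = _region_stats(channel, cyto)
    a_mem, t_mem, m_mem = _region_stats(channel, memb)

    if a_nuc == 0 or a_cyt == 0:
        ratio = float("nan")
    elif ratio_on == "total":
        ratio = t_nuc / t_cyt if t_cyt != 0 else float("nan")
    else:
        ratio = m_nuc / m_cyt if m_cyt != 0 else float("nan")

    return CompartmentStats(
        label=cell.label,
        area_cell=a_cell, area_nucleus=a_nuc, area_cytosol=a_cyt, area_membrane=a_mem,
        total_cell=t_cell, total_nucleus=t_nuc, total_cytosol=t_cyt, total_membrane=t_mem,
        mean_cell=m_cell, mean_nucleus=m_nuc, mean_cytosol=m_cyt, mean_membrane=m_mem,
        ratio_nucleus_cytosol=ratio,
    )
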