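"""Instance segmentation backends, organelle mask assignment and
cell/nucleus matching.

Deep-learning segmenters (Cellpose, DeepCell, micro-SAM) are pluggable
adapters selected by name; none is bundled.  A deterministic classical
backend (Otsu nuclei + marker-controlled watershed on the junction channel)
is built in for testing and as a dependency-free fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .polarity import CellEntity

logger = logging.getLogger("cellpol")

MIN_NUCLEUS_AREA = 20  # px, classical backend speckle filter


class BackendUnavailableError(RuntimeError):
    """A named segmentation adapter is not installed or not registered."""


@dataclass
class MatchReport:
    """Bookkeeping of :func:`match_and_filter`; counts reconcile exactly."""

    retained: int = 0
    dropped_no_nucleus: int = 0
    dropped_multi_nucleus: int = 0
    dropped_border: int = 0
    dropped_labels: dict[int, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return (
            self.retained
            + self.dropped_no_nucleus
            + self.dropped_multi_nucleus
            + self.dropped_border
        )


def validate_label_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.allclose(mask, np.round(mask)):
            raise ValueError("label mask must contain integers")
        mask = mask.astype(np.int32)
    if mask.min() < 0:
        raise ValueError("label mask must be nonnegative (0 = background)")
    return mask


def builtin_classical_segment(
    nucleus_channel: np.ndarray,
    junction_channel: np.ndarray,
    min_nucleus_area: int = MIN_NUCLEUS_AREA,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical segmentation: Otsu nuclei, watershed cells.

    Nuclei are Otsu-thresholded and labelled by connected components.  Cell
    bodies are recovered by marker-controlled watershed using the junction
    channel as the elevation map (junction signal is bright on boundaries,
    so basins are the dark cell interiors), seeded from the nuclei.
    """
    nucleus_channel = np.asarray(nucleus_channel, dtype=float)
    junction_channel = np.asarray(junction_channel, dtype=float)
    if nucleus_channel.min() == nucleus_channel.max():
        logger.warning("nucleus channel constant: no foreground, zero instances")
        z = np.zeros(nucleus_channel.shape, dtype=np.int32)
        return z, z.copy()
    thr = threshold_otsu(nucleus_channel)
    fg = nucleus_channel > thr
    lab, _ = ndimage.label(fg)  # 4-connected
    sizes = np.bincount(lab.ravel())
    fg &= sizes[lab] >= min_nucleus_area  # drop speckle
    nuclei, n_nuc = ndimage.label(fg)
    if n_nuc == 0:
        logger.warning("no nuclei above Otsu threshold: zero instances")
        z = np.zeros(nucleus_channel.shape, dtype=np.int32)
        return z, z.copy()
    cells = watershed(junction_channel, markers=nuclei)
    return cells.astype(np.int32), nuclei.astype(np.int32)


_BACKENDS = {"classical": builtin_classical_segment}


def segment(
    image_channels: dict[str, np.ndarray],
    backend_name: str = "classical",
    backend_config: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to a segmentation backend; returns (cell, nucleus) label masks.

    Only the built-in ``classical`` backend ships with the package; external
    adapters must be registered in ``_BACKENDS`` by the integration that
    provides them.  An unavailable backend raises immediately (never a
    silent fallback).
    """
    if backend_name not in _BACKENDS:
        raise BackendUnavailableError(
            f"segmentation backend {backend_name!r} is not available; "
            f"registered backends: {sorted(_BACKENDS)}"
        )
    cfg = backend_config or {}
    for key in ("nucleus", "junction"):
        if key not in image_channels:
            raise ValueError(f"backend {backend_name!r} requires channel {key!r}")
    return _BACKENDS[backend_name](
        image_channels["nucleus"], image_channels["junction"], **cfg
    )


def golgi_instance_mask(
    organelle_channel: np.ndarray, cell_mask: np.ndarray
) -> np.ndarray:
    """Organelle instances: global Otsu on the channel, labels inherited
    from the cell segmentation underneath each positive pixel.

    A blob straddling two cells is split along the cell boundary.  A
    constant channel yields an empty mask.
    """
    organelle_channel = np.asarray(organelle_channel, dtype=float)
    cell_mask = validate_label_mask(cell_mask)
    if organelle_channel.min() == organelle_channel.max():
        return np.zeros_like(cell_mask)
    thr = threshold_otsu(organelle_channel)
    positive = organelle_channel > thr
    return np.where(positive, cell_mask, 0).astype(cell_mask.dtype)


def match_and_filter(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    channels: dict[str, np.ndarray] | None = None,
    organelle_mask: np.ndarray | None = None,
    exclude_border: bool = True,
) -> tuple[list[CellEntity], MatchReport]:
    """Assign nuclei to cells and keep cells with exactly one nucleus.

    Each nucleus goes to the cell covering the majority of its area (ties
    broken towards the lower cell label).  Cells with zero or two-plus
    nuclei are dropped, as are border-touching cells when
    ``exclude_border`` (truncated cells bias shape and polarity features).
    All drops are logged with a reason.
    """
    cell_mask = validate_label_mask(cell_mask)
    nucleus_mask = validate_label_mask(nucleus_mask)
    if cell_mask.shape != nucleus_mask.shape:
        raise ValueError("cell and nucleus masks must share a shape")
    if organelle_mask is not None:
        organelle_mask = validate_label_mask(organelle_mask)

    cell_labels = [int(v) for v in np.unique(cell_mask) if v != 0]
    assigned: dict[int, list[int]] = {c: [] for c in cell_labels}
    for nuc in (int(v) for v in np.unique(nucleus_mask) if v != 0):
        under = cell_mask[nucleus_mask == nuc]
        under = under[under != 0]
        if under.size == 0:
            continue
        vals, counts = np.unique(under, return_counts=True)
        best = vals[counts == counts.max()].min()  # majority, lower label on ties
        assigned[int(best)].append(nuc)

    border = set()
    if exclude_border:
        edge = np.concatenate(
            [cell_mask[0, :], cell_mask[-1, :], cell_mask[:, 0], cell_mask[:, -1]]
        )
        border = {int(v) for v in np.unique(edge) if v != 0}

    report = MatchReport()
    entities: list[CellEntity] = []
    for c in cell_labels:
        nucs = assigned[c]
        if c in border:
            report.dropped_border += 1
            report.dropped_labels[c] = "touches image border"
        elif len(nucs) == 0:
            report.dropped_no_nucleus += 1
            report.dropped_labels[c] = "no assigned nucleus"
        elif len(nucs) > 1:
            report.dropped_multi_nucleus += 1
            report.dropped_labels[c] = f"{len(nucs)} assigned nuclei"
        else:
            cmask = cell_mask == c
            nmask = (nucleus_mask == nucs[0]) & cmask
            omask = None
            if organelle_mask is not None:
                omask = (organelle_mask == c) & cmask
            entities.append(
                CellEntity(
                    label=c,
                    cell_mask=cmask,
                    nucleus_mask=nmask,
                    organelle_mask=omask,
                    channels=dict(channels or {}),
                )
            )
            report.retained += 1
    for lbl, reason in report.dropped_labels.items():
        logger.info("cell %d dropped: %s", lbl, reason)
    logger.info(
        "match_and_filter: %d retained, %d no-nucleus, %d multi-nucleus, %d border",
        report.retained, report.dropped_no_nucleus,
        report.dropped_multi_nucleus, report.dropped_border,
    )
    return entities, report
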