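"""Run configuration, readers/writers and orchestration.

Three execution scenarios are supported: a single multi-channel image, an
image stack (images x channels x y x x) and a folder tree whose first-level
sub-folders name experimental conditions.  Inputs are TIFF (images and
integer label masks) plus a YAML run configuration; outputs are per-image
and merged per-cell CSV feature tables, a per-image collective-statistics
CSV, rose-plot SVGs, a run log and a copy of the resolved configuration —
all non-proprietary text formats, stamped with package version, seed and a
configuration hash for replicability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .circstats import (
    AngleSample,
    mean_ci,
    rao_spacing_test,
    rayleigh_test,
    signed_polarity_index,
    v_test,
    watson_test,
)
from .intensity import DEFAULT_MEMBRANE_THICKNESS, compartment_stats
from .junctions import DEFAULT_JUNCTION_THICKNESS, junction_record
from .morphology import morphology_record
from .polarity import (
    CueConfig,
    cue_intensity_ratio,
    marker_polarity,
    nucleus_displacement,
    nucleus_golgi_polarity,
)
from .segmentation import (
    golgi_instance_mask,
    match_and_filter,
    segment,
    validate_label_mask,
)

logger = logging.getLogger("cellpol")

#: Directional angle columns and the offset (deg) of their expected
#: polarisation direction from the cue: the organelle relocates upstream,
#: so the nucleus->Golgi axis is expected to point against the cue.
ANGLE_FEATURES: dict[str, float] = {
    "angle_nucleus_golgi_deg": 180.0,
    "angle_nucleus_displacement_deg": 0.0,
    "angle_marker_polarity_deg": 0.0,
}
AXIAL_FEATURES: dict[str, float] = {"orientation_deg": 0.0}


@dataclass
class RunConfig:
    input_path: str = "."
    mode: str = "single"                    # single | stack | folder
    channels: dict = field(default_factory=dict)   # name -> index in the TIFF
    cell_mask_path: str | None = None       # precomputed label masks (skip segmentation)
    nucleus_mask_path: str | None = None
    pixel_size: float | None = None
    cue_direction_deg: float = 0.0
    y_axis_sign: int = -1
    junction_thickness_px: int = DEFAULT_JUNCTION_THICKNESS
    membrane_thickness_px: int = DEFAULT_MEMBRANE_THICKNESS
    golgi_weighted_centroid: bool = True
    ratio_on: str = "mean"                  # nucleus/cytosol ratio on mean or total
    segmentation: dict = field(default_factory=lambda: {"backend": "classical"})
    exclude_border_cells: bool = True
    output_dir: str = "cellpol_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "stack", "folder"):
            raise ValueError(f"mode must be single|stack|folder, got {self.mode!r}")
        if self.y_axis_sign not in (+1, -1):
            raise ValueError("y_axis_sign must be +1 or -1")
        if not self.channels and self.cell_mask_path is None:
            raise ValueError(
                "config needs at least one mask source: channels for "
                "segmentation or a precomputed cell_mask_path"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, filling defaults."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF; returns (h, w), (c, h, w) or (n, c, h, w)."""
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim not in (2, 3, 4):
        raise ValueError(
            f"{path}: expected a 2-D image, a channels x y x x image or an "
            f"images x channels x y x x stack, got shape {arr.shape}"
        )
    return arr


def _split_channels(frame: np.ndarray, channel_map: dict) -> dict[str, np.ndarray]:
    if frame.ndim == 2:
        frame = frame[None]
    out = {}
    for name, idx in channel_map.items():
        if idx >= frame.shape[0]:
            raise ValueError(
                f"channel {name!r} has index {idx} but image has only "
                f"{frame.shape[0]} channels"
            )
        out[name] = frame[idx].astype(float)
    return out


def extract_image_features(
    channels: dict[str, np.ndarray],
    config: RunConfig,
    cell_labels: np.ndarray | None = None,
    nucleus_labels: np.ndarray | None = None,
    image_id: str = "image",
    filename: str = "",
):
    """Feature table for one image; segments first when no masks are given."""
    if cell_labels is None or nucleus_labels is None:
        seg = dict(config.segmentation)
        backend = seg.pop("backend", "classical")
        cell_labels, nucleus_labels = segment(channels, backend, seg or None)
    cell_labels = validate_label_mask(cell_labels)
    nucleus_labels = validate_label_mask(nucleus_labels)

    organelle_labels = None
    if "organelle" in channels:
        organelle_labels = golgi_instance_mask(channels["organelle"], cell_labels)

    entities, report = match_and_filter(
        cell_labels,
        nucleus_labels,
        channels=channels,
        organelle_mask=organelle_labels,
        exclude_border=config.exclude_border_cells,
    )
    sigma = config.y_axis_sign
    cue = CueConfig(alpha_p_deg=config.cue_direction_deg, sigma=sigma)
    rows = []
    for cell in entities:
        yy, xx = np.nonzero(cell.cell_mask)
        row: dict = {
            "filename": filename,
            "image_id": image_id,
            "label": cell.label,
            "centroid_x": float(xx.mean()),
            "centroid_y": float(yy.mean()),
        }
        morph = morphology_record(
            cell.label, cell.cell_mask, config.pixel_size,
            alpha_p_deg=config.cue_direction_deg, sigma=sigma,
        )
        row.update(
            area=morph.area, area_um2=morph.area_um2, perimeter=morph.perimeter,
            orientation_deg=morph.orientation_phi_deg, lwr=morph.lwr,
            circularity=morph.circularity, eccentricity=morph.eccentricity,
            symmetry_score=morph.symmetry_score,
        )
        if cell.nucleus_mask is not None:
            row["angle_nucleus_displacement_deg"] = nucleus_displacement(cell, sigma)
        if cell.organelle_mask is not None:
            row["angle_nucleus_golgi_deg"] = nucleus_golgi_polarity(
                cell, sigma, organelle_channel="organelle",
                weighted=config.golgi_weighted_centroid,
            )
        if "marker" in channels:
            row["angle_marker_polarity_deg"] = marker_polarity(cell, "marker", sigma)
            row["cue_intensity_ratio"] = cue_intensity_ratio(cell, "marker", cue)
            comp = compartment_stats(
                cell, "marker", config.membrane_thickness_px, config.ratio_on
            )
            row.update(
                area_nucleus=comp.area_nucleus, area_cytosol=comp.area_cytosol,
                area_membrane=comp.area_membrane,
                total_cell=comp.total_cell, total_nucleus=comp.total_nucleus,
                total_cytosol=comp.total_cytosol, total_membrane=comp.total_membrane,
                mean_cell=comp.mean_cell, mean_nucleus=comp.mean_nucleus,
                mean_cytosol=comp.mean_cytosol, mean_membrane=comp.mean_membrane,
                ratio_nucleus_cytosol=comp.ratio_nucleus_cytosol,
            )
        if "junction" in channels:
            jrec = junction_record(
                cell.cell_mask, channels["junction"],
                thickness=config.junction_thickness_px, label=cell.label,
            )
            row.update(
                interface_area=jrec.interface_area,
                protein_area=jrec.protein_area,
                interface_occupancy=jrec.interface_occupancy,
                intensity_per_interface_area=jrec.intensity_per_interface_area,
                cluster_density=jrec.cluster_density,
            )
        rows.append(row)
    missing = [
        name for name in ("organelle", "marker", "junction") if name not in channels
    ]
    if missing:
        logger.info(
            "image %s: channels %s not configured; their features are skipped",
            image_id, missing,
        )
    return pd.DataFrame(rows), report


def summarise_image(
    df: pd.DataFrame, config: RunConfig, image_id: str = "image"
) -> pd.DataFrame:
    """Collective circular statistics per angular feature of one image.

    Single-cell angles within a monolayer are correlated, so uniformity
    tests are computed per image; the per-image indices (R, V) are the unit
    of inference across conditions.
    """
    cue = config.cue_direction_deg
    out = []
    features = [
        (name, "directional", offset)
        for name, offset in ANGLE_FEATURES.items()
    ] + [(name, "axial", offset) for name, offset in AXIAL_FEATURES.items()]
    for name, mode, offset in features:
        if name not in df.columns:
            continue
        vals = df[name].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            continue
        sample = AngleSample.from_degrees(vals, mode=mode)
        expected = (cue + offset) % 360.0
        summ = signed_polarity_index(sample, expected)
        lo, hi = mean_ci(sample, seed=config.seed)
        rec = {
            "image_id": image_id, "feature": name, "n": sample.n,
            "mean_deg": summ.mean_deg, "R": summ.R, "S": summ.S,
            "V": summ.V, "c": summ.c, "alpha_p_deg": expected,
            "ci_low_deg": lo, "ci_high_deg": hi, "ci_level": 0.95,
        }
        if sample.n >= 4:
            rec["p_rayleigh"] = rayleigh_test(sample).p_value
            rec["p_vtest"] = v_test(sample, expected).p_value
            rec["p_watson"] = watson_test(sample).p_value
            rec["p_rao"] = rao_spacing_test(sample, seed=config.seed).p_value
        out.append(rec)
    return pd.DataFrame(out)


def write_features(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """CSV with '.' decimals, ',' separator, UTF-8, and a provenance header.

    Angle columns are degrees: directional in [0, 360), axial in [0, 180),
    measured from the x-axis with y up (y_axis_sign handles raster order).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# cellpol {__version__} seed={config.seed} "
            f"config_hash={config.config_hash()} "
            f"angles=degrees y_axis_sign={config.y_axis_sign}\n"
        )
        df.to_csv(fh, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def export_rose(sample: AngleSample, path: str | Path, n_bins: int = 24) -> None:
    """Rose (circular histogram) plot as SVG/PDF; axial duplicates drawn
    transparent."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .circstats import rose_histogram

    rose = rose_histogram(sample, n_bins=n_bins)
    centres = np.deg2rad(
        (rose.bin_edges_deg[:-1] + rose.bin_edges_deg[1:]) / 2.0
    )
    width = 2 * np.pi / n_bins
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.bar(centres, rose.counts, width=width, color="tab:red", alpha=0.9)
    if rose.duplicated is not None:
        ax.bar(centres, rose.duplicated, width=width, color="tab:red", alpha=0.3)
    fig.savefig(str(path))
    plt.close(fig)


def _iter_frames(config: RunConfig):
    """Yield (image_id, filename, condition, channel dict) per image."""
    src = Path(config.input_path)
    if config.mode == "single":
        arr = read_image(src)
        yield src.stem, src.name, "", _split_channels(arr, config.channels)
    elif config.mode == "stack":
        arr = read_image(src)
        if arr.ndim != 4:
            raise ValueError(
                f"stack mode expects images x channels x y x x, got {arr.shape}"
            )
        for i in range(arr.shape[0]):
            yield f"{src.stem}_{i:03d}", src.name, "", _split_channels(
                arr[i], config.channels
            )
    else:  # folder: first-level sub-folders are conditions
        for tif in sorted(src.rglob("*.tif")) + sorted(src.rglob("*.tiff")):
            rel = tif.relative_to(src)
            condition = rel.parts[0] if len(rel.parts) > 1 else ""
            try:
                arr = read_image(tif)
            except (ValueError, OSError) as exc:
                logger.error("skipping unreadable file %s: %s", tif, exc)
                continue
            yield tif.stem, tif.name, condition, _split_channels(arr, config.channels)


def run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute a full extraction run and write all artifacts to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("cellpol %s starting run, config hash %s, seed %d",
                __version__, config.config_hash(), config.seed)
    try:
        resolved = asdict(config)
        resolved["_version"] = __version__
        resolved["_config_hash"] = config.config_hash()
        with open(out / "config_resolved.yml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)

        cell_labels = nucleus_labels = None
        if config.cell_mask_path:
            cell_labels = validate_label_mask(read_image(config.cell_mask_path))
        if config.nucleus_mask_path:
            nucleus_labels = validate_label_mask(read_image(config.nucleus_mask_path))

        tables, summaries = [], []
        for image_id, fname, condition, channels in _iter_frames(config):
            df, report = extract_image_features(
                channels, config,
                cell_labels=cell_labels, nucleus_labels=nucleus_labels,
                image_id=image_id, filename=fname,
            )
            if condition:
                df.insert(2, "condition", condition)
            logger.info(
                "image %s: %d cells retained (%d dropped)",
                image_id, report.retained, report.total - report.retained,
            )
            if not df.empty:
                write_features(df, out / f"features_{image_id}.csv", config)
                summ = summarise_image(df, config, image_id=image_id)
                if condition and not summ.empty:
                    summ.insert(1, "condition", condition)
                summaries.append(summ)
            tables.append(df)

        merged = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        if not merged.empty:
            write_features(merged, out / "features_merged.csv", config)
        summary = (
            pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
        )
        if not summary.empty:
            write_features(summary, out / "summary_collective.csv", config)
        logger.info("run finished: %d images, %d cells",
                    len(tables), 0 if merged.empty else len(merged))
        return {"features": merged, "summary": summary}
    finally:
        logger.removeHandler(handler)
        handler.close()
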