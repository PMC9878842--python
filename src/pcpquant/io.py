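"""Shared readers and writers: TIFF images, ROI JSON, CSV tables, config.

Conventions, enforced everywhere:

- pixel coordinates are 0-based, ``x`` = column, ``y`` = row;
- pixel ``(r, c)`` spans the square ``[c, c+1) x [r, r+1)`` with its center
  at ``(c + 0.5, r + 0.5)``;
- polygons are rasterized by pixel-center inclusion (a pixel belongs to the
  ROI iff its center lies strictly inside the polygon), the half-open rule:
  an axis-aligned square with integer corners covers exactly the pixels
  whose indices lie in the half-open index ranges.
- multi-page TIFFs are channel stacks (page = channel); label masks are
  single-channel 16-bit TIFFs; tables are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely import contains_xy
from shapely.geometry import Polygon

from pcpquant.junctions import ROISet


def read_image(path) -> np.ndarray:
    """Read a TIFF as a channel-indexed array.

    A single-page file returns shape ``(H, W)``; a multi-page file returns
    ``(n_pages, H, W)`` with one page per channel (or z-slice).
    """
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError(f"expected a TIFF file, got {path.name}")
    return tifffile.imread(path)


def write_image(path, image: np.ndarray) -> None:
    """Write an array as a (multi-page, for 3-D input) TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image))


def project(stack: np.ndarray, method: str = "average") -> np.ndarray:
    """Average- or maximum-intensity projection along the first axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("projection expects a 3-D stack (slices, H, W)")
    if method in ("average", "aip", "mean"):
        return stack.mean(axis=0)
    if method in ("max", "mip"):
        return stack.max(axis=0)
    raise ValueError(f"unknown projection method: {method!r}")


# ---------------------------------------------------------------------------
# polygon ROIs


def _check_simple(vertices: np.ndarray) -> None:
    """Reject self-intersecting polygons, naming the offending vertex."""
    n = len(vertices)
    ring = Polygon(vertices)
    if ring.is_valid:
        return
    # locate the first edge pair that crosses, for the error message
    from shapely.geometry import LineString

    edges = [LineString([vertices[i], vertices[(i + 1) % n]]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the ring
            if edges[i].crosses(edges[j]):
                raise ValueError(
                    f"polygon self-intersects: edge from vertex {i} crosses "
                    f"edge from vertex {j}")
    raise ValueError("polygon is invalid (degenerate or self-touching)")


def rasterize_polygon(vertices, shape) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    ``vertices`` is a sequence of ``[x, y]`` points in pixel units
    (0-based, x = column); ``shape`` is the image ``(H, W)``.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise ValueError("polygon needs at least 3 [x, y] vertices")
    _check_simple(vertices)
    poly = Polygon(vertices)
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    r0, r1 = max(0, int(np.floor(miny))), min(h, int(np.ceil(maxy)) + 1)
    c0, c1 = max(0, int(np.floor(minx))), min(w, int(np.ceil(maxx)) + 1)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def _roi_to_mask(entry, shape, base_dir: Path) -> np.ndarray:
    """One ROI spec -> boolean mask. Accepts polygon lists or mask TIFF paths."""
    if isinstance(entry, dict) and "mask" in entry:
        mask = read_image(base_dir / entry["mask"])
        if mask.shape != tuple(shape):
            raise ValueError("ROI mask shape does not match the image")
        return mask.astype(bool)
    if isinstance(entry, dict) and "polygon" in entry:
        entry = entry["polygon"]
    return rasterize_polygon(entry, shape)


def read_rois(path, image_shape) -> list[ROISet]:
    """Read a JSON file of ROI sets and rasterize them against an image shape.

    Schema: a list of objects with keys ``junction``, ``cell``,
    ``background`` (each a polygon — list of ``[x, y]`` vertices — or
    ``{"mask": "relative/path.tif"}``), plus optional ``image_ref`` and
    ``cell_roi_kind`` (``"contour"`` or ``"filled"``).
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError("ROI file must contain a JSON list of ROI sets")
    out = []
    for i, entry in enumerate(data):
        missing = {"junction", "cell", "background"} - set(entry)
        if missing:
            raise ValueError(f"ROI set {i} missing keys: {sorted(missing)}")
        out.append(ROISet(
            junction_roi=_roi_to_mask(entry["junction"], image_shape, path.parent),
            cell_roi=_roi_to_mask(entry["cell"], image_shape, path.parent),
            background_roi=_roi_to_mask(entry["background"], image_shape,
                                        path.parent),
            image_ref=entry.get("image_ref", ""),
            cell_roi_kind=entry.get("cell_roi_kind", "contour")))
    return out


def write_rois(path, roi_sets: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump(roi_sets, fh, indent=2)


# ---------------------------------------------------------------------------
# run configuration


KNOWN_CONFIG_KEYS = {
    "simulate": {"kind", "params"},
    "follicles": {"min_area", "threshold_method", "fixed_thresholds",
                  "pairing_radius", "ring_coverage_min", "offset_ratio_min",
                  "bin_width", "rose_bin_width"},
    "polarity": {"ring_width", "min_pixels", "bin_width",
                 "include_border_cells"},
    "je": {"clip_negative"},
    "frap": {"n_prebleach", "min_points"},
}


def validate_config(config: dict) -> dict:
    """Reject unknown stages and unknown keys inside each stage block."""
    if not isinstance(config, dict):
        raise ValueError("config must be a JSON object")
    for stage, block in config.items():
        if stage in ("seed", "out", "log_level"):
            continue
        if stage not in KNOWN_CONFIG_KEYS:
            raise ValueError(f"unknown config section: {stage!r}")
        unknown = set(block) - KNOWN_CONFIG_KEYS[stage]
        if unknown:
            raise ValueError(
                f"unknown keys in config section {stage!r}: {sorted(unknown)}")
    return config


def read_config(path) -> dict:
    with open(path) as fh:
        return validate_config(json.load(fh))


def write_sidecar_config(outdir, config: dict) -> None:
    """Write the resolved configuration beside a run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
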