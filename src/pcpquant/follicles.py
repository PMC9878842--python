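"""Hair-follicle polarity: segmentation, classification, growth angles.

A developing hair follicle carries two progenitor markers with a stereotyped
geometry: P-cadherin in an anterior core, Sox9 in the posterior. In a
polarized follicle the Sox9 domain is an offset crescent; in an unpolarized
("bicycle wheel") follicle Sox9 forms a full ring around a central
P-cadherin cluster. The classifier uses two geometric signatures of the
ring phenotype — angular coverage of Sox9 about the P-cadherin centroid, and
the Sox9-to-P-cadherin centroid offset relative to follicle radius — and for
polarized follicles reports the growth angle as the direction of the vector
from the Sox9 centroid to the P-cadherin centroid (anterior = 0°).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label, regionprops

from pcpquant.geometry import (
    angular_coverage_deg,
    circular_mean_resultant,
    pixel_angles_deg,
    rose_histogram,
)

QC_OK = "ok"
QC_LOW_AREA = "low_area"
QC_UNPAIRED = "unpaired"
QC_AMBIGUOUS = "ambiguous"


@dataclass
class FollicleSegmentation:
    """One follicle's paired marker regions.

    ``pcad_pixels`` / ``sox9_pixels`` are ``(rows, cols)`` index arrays.
    ``follicle_center`` is the centroid of the union of both regions;
    ``follicle_radius_est`` is the maximum distance of a Sox9 pixel from the
    P-cadherin centroid (the outer follicle radius for both ring and
    crescent geometries).
    """

    follicle_id: int
    pcad_pixels: tuple[np.ndarray, np.ndarray]
    sox9_pixels: tuple[np.ndarray, np.ndarray]
    follicle_center: tuple[float, float]
    follicle_radius_est: float
    qc_flag: str = QC_OK


@dataclass
class FollicleCall:
    """Polarity decision for one follicle.

    ``angle`` (degrees in [0, 360), anterior = 0°) is defined iff
    ``polarized``; ``coverage`` is the angular extent of Sox9 about the
    P-cadherin centroid; ``offset_ratio`` the centroid separation in units
    of follicle radius.
    """

    follicle_id: int
    polarized: bool
    angle: float  # NaN when not polarized
    coverage: float
    offset_ratio: float
    qc_flag: str = QC_OK


@dataclass
class PolaritySummary:
    n_total: int
    n_polarized: int
    pct_polarized: float
    rose_edges: np.ndarray
    rose_counts: np.ndarray
    circular_mean: float  # NaN when no polarized follicles
    circular_resultant: float


def _components(channel, threshold_method, fixed_threshold, min_area):
    """Threshold one channel and return component regionprops above min_area."""
    if threshold_method in ("triangle", "otsu"):
        if np.ptp(channel) == 0:
            return []
        # triangle is the default: robust when the foreground occupies a tiny
        # fraction of pixels, where Otsu collapses into the background mode
        fn = threshold_triangle if threshold_method == "triangle" else threshold_otsu
        thr = fn(channel)
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = fixed_threshold
    else:
        raise ValueError(f"unknown threshold_method: {threshold_method!r}")
    mask = channel > thr
    return [r for r in regionprops(label(mask)) if r.area >= min_area]


def segment_follicles(
    image: np.ndarray,
    min_area: int = 30,
    threshold_method: str = "triangle",
    fixed_thresholds: tuple[float, float] | None = None,
    pairing_radius: float | None = None,
) -> list[FollicleSegmentation]:
    """Segment and pair P-cadherin / Sox9 regions into follicles.

    Parameters
    ----------
    image
        ``(2, H, W)`` array; channel 0 = P-cadherin, channel 1 = Sox9.
    min_area
        Components smaller than this (pixels) are dropped.
    threshold_method
        ``"triangle"`` (default; robust for sparse foreground), ``"otsu"``,
        or ``"fixed"`` (use ``fixed_thresholds``).
    pairing_radius
        Maximum P-cadherin-to-Sox9 centroid distance for pairing; default is
        3x the median equivalent component radius.

    Returns paired segmentations; unpaired components of either channel are
    emitted with ``qc_flag="unpaired"`` and should be excluded from calls.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a two-channel image with shape (2, H, W)")

    ft = (None, None) if fixed_thresholds is None else fixed_thresholds
    pcad = _components(image[0], threshold_method, ft[0], min_area)
    sox9 = _components(image[1], threshold_method, ft[1], min_area)
    if not pcad or not sox9:
        warnings.warn("a channel is empty after thresholding; no follicles found")

    if pairing_radius is None:
        radii = [np.sqrt(r.area / np.pi) for r in pcad + sox9]
        pairing_radius = 3.0 * float(np.median(radii)) if radii else 0.0

    # greedy nearest-centroid matching, closest pairs first
    pairs = []
    for i, p in enumerate(pcad):
        for j, s in enumerate(sox9):
            d = float(np.hypot(p.centroid[0] - s.centroid[0],
                               p.centroid[1] - s.centroid[1]))
            if d <= pairing_radius:
                pairs.append((d, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_s: set[int] = set()
    out: list[FollicleSegmentation] = []
    fid = 0
    for d, i, j in pairs:
        if i in used_p or j in used_s:
            continue
        used_p.add(i)
        used_s.add(j)
        p, s = pcad[i], sox9[j]
        p_rc = (p.coords[:, 0], p.coords[:, 1])
        s_rc = (s.coords[:, 0], s.coords[:, 1])
        all_r = np.concatenate([p_rc[0], s_rc[0]])
        all_c = np.concatenate([p_rc[1], s_rc[1]])
        center = (float(all_r.mean()), float(all_c.mean()))
        radius = float(np.hypot(s_rc[0] - p.centroid[0],
                                s_rc[1] - p.centroid[1]).max())
        out.append(FollicleSegmentation(
            follicle_id=fid, pcad_pixels=p_rc, sox9_pixels=s_rc,
            follicle_center=center, follicle_radius_est=radius))
        fid += 1
    for i, p in enumerate(pcad):
        if i not in used_p:
            out.append(FollicleSegmentation(
                follicle_id=fid, pcad_pixels=(p.coords[:, 0], p.coords[:, 1]),
                sox9_pixels=(np.array([], int), np.array([], int)),
                follicle_center=(float(p.centroid[0]), float(p.centroid[1])),
                follicle_radius_est=float(np.sqrt(p.area / np.pi)),
                qc_flag=QC_UNPAIRED))
            fid += 1
    for j, s in enumerate(sox9):
        if j not in used_s:
            out.append(FollicleSegmentation(
                follicle_id=fid, pcad_pixels=(np.array([], int), np.array([], int)),
                sox9_pixels=(s.coords[:, 0], s.coords[:, 1]),
                follicle_center=(float(s.centroid[0]), float(s.centroid[1])),
                follicle_radius_est=float(np.sqrt(s.area / np.pi)),
                qc_flag=QC_UNPAIRED))
            fid += 1
    return out


def classify_follicle(
    seg: FollicleSegmentation,
    ring_coverage_min: float = 300.0,
    offset_ratio_min: float = 0.15,
    bin_width: float = 10.0,
) -> FollicleCall:
    """Classify one follicle as polarized or non-polarized.

    Non-polarized iff the Sox9 angular coverage about the P-cadherin
    centroid is at least ``ring_coverage_min`` degrees OR the centroid
    offset ratio is below ``offset_ratio_min``; otherwise polarized, with
    the growth angle pointing from the Sox9 centroid toward the P-cadherin
    centroid.
    """
    pr, pc = seg.pcad_pixels
    sr, sc = seg.sox9_pixels
    if pr.size == 0 or sr.size == 0:
        flag = QC_UNPAIRED if seg.qc_flag == QC_UNPAIRED else QC_LOW_AREA
        return FollicleCall(seg.follicle_id, False, np.nan, np.nan, np.nan, flag)

    pcad_centroid = (float(pr.mean()), float(pc.mean()))
    sox9_centroid = (float(sr.mean()), float(sc.mean()))

    phis = pixel_angles_deg(sr, sc, pcad_centroid)
    coverage = angular_coverage_deg(phis, bin_width=bin_width)

    offset = float(np.hypot(sox9_centroid[0] - pcad_centroid[0],
                            sox9_centroid[1] - pcad_centroid[1]))
    if seg.follicle_radius_est <= 0:
        return FollicleCall(seg.follicle_id, False, np.nan, coverage, np.nan,
                            QC_AMBIGUOUS)
    offset_ratio = offset / seg.follicle_radius_est

    if coverage >= ring_coverage_min or offset_ratio < offset_ratio_min:
        return FollicleCall(seg.follicle_id, False, np.nan, coverage,
                            offset_ratio, QC_OK)

    # growth angle: Sox9 (posterior) centroid -> P-cadherin (anterior) centroid
    dy = -(pcad_centroid[0] - sox9_centroid[0])
    dx = pcad_centroid[1] - sox9_centroid[1]
    angle = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
    return FollicleCall(seg.follicle_id, True, angle, coverage, offset_ratio, QC_OK)


def classify_follicles(segs, **kwargs) -> list[FollicleCall]:
    """Classify every QC-clean segmentation (unpaired ones are flagged, not called)."""
    return [classify_follicle(s, **kwargs) for s in segs]


def summarize_calls(calls, bin_width: float = 20.0) -> PolaritySummary:
    """Cumulative polarity percentage and rose-plot bins over polarized angles."""
    clean = [c for c in calls if c.qc_flag == QC_OK]
    if not clean:
        raise ValueError("no follicles to summarize after QC exclusion")
    angles = [c.angle for c in clean if c.polarized]
    n_total = len(clean)
    n_pol = len(angles)
    edges, counts = rose_histogram(angles, bin_width=bin_width)
    if n_pol:
        mean, resultant = circular_mean_resultant(angles)
    else:
        mean, resultant = np.nan, np.nan
    return PolaritySummary(
        n_total=n_total, n_polarized=n_pol,
        pct_polarized=100.0 * n_pol / n_total,
        rose_edges=edges, rose_counts=counts,
        circular_mean=mean, circular_resultant=resultant)


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabulate calls for CSV export."""
    return pd.DataFrame([{
        "follicle_id": c.follicle_id,
        "polarized": c.polarized,
        "angle_deg": c.angle,
        "coverage_deg": c.coverage,
        "offset_ratio": c.offset_ratio,
        "qc_flag": c.qc_flag,
    } for c in calls])
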