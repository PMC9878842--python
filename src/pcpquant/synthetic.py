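"""Synthetic fixture generators with attached ground truth.

Every generator emulates one input class the analysis stages consume:

- :func:`make_follicle_image` — two-channel backskin images of hair
  follicles: a central P-cadherin core plus either a full Sox9 ring
  (unpolarized, "bicycle wheel" phenotype) or an offset Sox9 crescent
  (polarized, growth angle drawn from a von Mises distribution).
- :func:`make_cell_mesh` — a Voronoi mesh of basal cells whose membrane
  intensity is modulated along a planar polarity axis,
  ``I(phi) = base + amplitude * cos(2 (phi - axis))``.
- :func:`make_cellpair_image` — two adjacent cell footprints sharing a
  junction band whose intensity is ``enrichment_factor`` times the membrane
  level, with junction / cell-pair / background ROIs.
- :func:`make_frap_traces` — FRAP intensity traces (bleach, reference and
  background ROIs) with pre-bleach frames, instantaneous bleach, one-phase
  exponential recovery, acquisition bleaching, and additive Gaussian noise.

All randomness flows from the ``seed`` field of the parameter object; the
same seed reproduces bit-identical output. Noise is additive Gaussian on a
constant background, so every generator admits an exact noiseless check
against its closed-form pixel/sample model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from pcpquant.geometry import pixel_angles_deg


class PlacementError(RuntimeError):
    """Raised when non-overlapping follicle placement fails.

    Signals that the requested follicle count exceeds what the image area
    can hold at the required center-to-center spacing.
    """


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# parameter objects


@dataclass(frozen=True)
class FollicleSimParams:
    """Parameters of the synthetic backskin follicle image.

    ``polarized_fraction`` is the Bernoulli probability that a follicle is
    polarized; polarized growth angles are drawn from a von Mises
    distribution with mean ``angle_mean`` (degrees, anterior = 0°) and
    concentration ``angle_concentration`` (kappa >= 0; 0 is uniform).
    The Sox9 crescent of a polarized follicle spans ``crescent_width``
    degrees centered opposite the growth direction.
    """

    image_size: tuple[int, int] = (1024, 1024)
    n_follicles: int = 40
    follicle_radius: float = 20.0
    core_radius: float = 8.0
    polarized_fraction: float = 0.7
    angle_mean: float = 0.0
    angle_concentration: float = 4.0
    crescent_width: float = 120.0
    noise_sd: float = 0.0
    background_level: float = 0.0
    foreground_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.core_radius < self.follicle_radius,
               "core_radius must be smaller than follicle_radius")
        _check(0.0 <= self.polarized_fraction <= 1.0,
               "polarized_fraction must be in [0, 1]")
        _check(0.0 < self.crescent_width < 360.0,
               "crescent_width must be in (0, 360)")
        _check(self.angle_concentration >= 0.0, "kappa must be >= 0")
        _check(self.n_follicles >= 1, "need at least one follicle")
        _check(self.noise_sd >= 0.0, "noise_sd must be >= 0")
        _check(self.foreground_level > 0.0, "foreground_level must be > 0")


@dataclass(frozen=True)
class MeshSimParams:
    """Parameters of the synthetic basal-cell mesh.

    Membrane intensity follows ``base_intensity +
    modulation_amplitude * cos(2 (phi - polarity_axis))`` where ``phi`` is a
    membrane pixel's angular position about its cell centroid.
    """

    n_cells: int = 64
    domain_size: tuple[int, int] = (512, 512)
    membrane_width: int = 2
    base_intensity: float = 100.0
    modulation_amplitude: float = 50.0
    polarity_axis: float = 0.0
    noise_sd: float = 0.0
    jitter: float = 0.05  # seed displacement, as a fraction of lattice spacing
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_cells >= 4, "n_cells must be >= 4")
        _check(0.0 <= self.jitter < 0.5, "jitter must be in [0, 0.5)")
        _check(self.modulation_amplitude <= self.base_intensity,
               "modulation_amplitude must not exceed base_intensity")
        _check(self.modulation_amplitude >= 0.0, "amplitude must be >= 0")
        _check(self.membrane_width >= 1, "membrane_width must be >= 1")
        _check(0.0 <= self.polarity_axis < 180.0,
               "polarity_axis must be in [0, 180)")
        _check(self.noise_sd >= 0.0, "noise_sd must be >= 0")


@dataclass(frozen=True)
class PairSimParams:
    """Parameters of the two-cell junction-enrichment fixture."""

    image_size: tuple[int, int] = (128, 128)
    junction_length: int = 40
    band_width: int = 3
    membrane_intensity: float = 100.0
    enrichment_factor: float = 2.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.enrichment_factor >= 0.0, "enrichment_factor must be >= 0")
        _check(self.junction_length >= 4, "junction_length too small")
        _check(self.band_width >= 1, "band_width must be >= 1")
        _check(self.noise_sd >= 0.0, "noise_sd must be >= 0")
        h, w = self.image_size
        _check(self.junction_length + 2 * self.band_width + 8 < h,
               "junction does not fit in image height")


@dataclass(frozen=True)
class FRAPSimParams:
    """Parameters of simulated FRAP acquisitions.

    Defaults mirror a typical confocal protocol: three pre-bleach reference
    frames, an instantaneous bleach, then 60 recovery frames at 5-s
    intervals. ``mobile_fraction`` is the recovering share of the bleached
    signal (immobile fraction = 1 - mobile_fraction); ``rate_k`` is the
    one-phase association rate. ``acquisition_bleach_rate`` applies a shared
    exponential decay to all fluorescent ROIs.
    """

    n_prebleach: int = 3
    n_recovery: int = 60
    frame_interval: float = 5.0
    bleach_depth: float = 0.8
    mobile_fraction: float = 0.6
    rate_k: float = 0.02
    acquisition_bleach_rate: float = 0.0
    background_level: float = 50.0
    signal_level: float = 1000.0
    noise_sd: float = 0.0
    n_traces: int = 1
    seed: int = 0
    bleach_duration: float = 5.9  # dead time between last pre-bleach and t=0

    def __post_init__(self) -> None:
        _check(self.n_prebleach >= 1, "need at least one pre-bleach frame")
        _check(self.n_recovery >= 2, "need at least two recovery frames")
        _check(self.frame_interval > 0.0, "frame_interval must be > 0")
        _check(0.0 < self.bleach_depth <= 1.0, "bleach_depth must be in (0, 1]")
        _check(0.0 <= self.mobile_fraction <= 1.0,
               "mobile_fraction must be in [0, 1]")
        _check(self.rate_k > 0.0, "rate_k must be > 0")
        _check(self.acquisition_bleach_rate >= 0.0,
               "acquisition_bleach_rate must be >= 0")
        _check(self.signal_level > 0.0, "signal_level must be > 0")
        _check(self.noise_sd >= 0.0, "noise_sd must be >= 0")
        _check(self.n_traces >= 1, "n_traces must be >= 1")


# ---------------------------------------------------------------------------
# follicle images


def _place_centers(rng, image_size, radius, n, max_tries=20000):
    """Rejection-sample follicle centers with center-to-center > 2*radius."""
    h, w = image_size
    margin = radius + 2.0
    _check(h > 2 * margin and w > 2 * margin, "image too small for follicle radius")
    centers: list[tuple[float, float]] = []
    min_d2 = (2.0 * radius) ** 2
    for _ in range(max_tries):
        if len(centers) == n:
            break
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - rc) ** 2 + (c - cc) ** 2 > min_d2 for rc, cc in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise PlacementError(
            f"placed only {len(centers)}/{n} follicles of radius {radius} in a "
            f"{h}x{w} image after {max_tries} tries; lower the density"
        )
    return centers


def make_follicle_image(params: FollicleSimParams):
    """Render a two-channel follicle image and its ground truth.

    Returns ``(image, truth)`` where ``image`` has shape ``(2, H, W)``
    (channel 0 = P-cadherin, channel 1 = Sox9) and ``truth`` is a DataFrame
    with one row per follicle: ``follicle_id, center_row, center_col,
    polarized, angle_deg`` (angle is NaN for unpolarized follicles).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    centers = _place_centers(rng, params.image_size, params.follicle_radius,
                             params.n_follicles)

    polarized = rng.random(params.n_follicles) < params.polarized_fraction
    angles = np.degrees(
        rng.vonmises(np.radians(params.angle_mean),
                     max(params.angle_concentration, 1e-12),
                     params.n_follicles)
    ) % 360.0

    img = np.zeros((2, h, w), dtype=float)
    rows, cols = np.mgrid[0:h, 0:w]
    half_width = params.crescent_width / 2.0
    records = []
    for i, (cr, cc) in enumerate(centers):
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        core = d2 <= params.core_radius ** 2
        annulus = (d2 > params.core_radius ** 2) & (d2 <= params.follicle_radius ** 2)
        img[0][core] = params.foreground_level
        if polarized[i]:
            # crescent centered opposite the growth direction
            phi = pixel_angles_deg(rows[annulus], cols[annulus], (cr, cc))
            delta = np.abs((phi - (angles[i] + 180.0) + 180.0) % 360.0 - 180.0)
            sel = np.zeros_like(annulus)
            sel[annulus] = delta <= half_width
            img[1][sel] = params.foreground_level
        else:
            img[1][annulus] = params.foreground_level
        records.append({
            "follicle_id": i,
            "center_row": cr,
            "center_col": cc,
            "polarized": bool(polarized[i]),
            "angle_deg": float(angles[i]) if polarized[i] else np.nan,
        })

    img += params.background_level
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    truth = pd.DataFrame.from_records(records)
    return img, truth


def match_to_truth(centers_rc, truth: pd.DataFrame) -> np.ndarray:
    """Match detected follicle centers to ground-truth rows.

    ``centers_rc`` is a sequence of ``(row, col)`` detected centers; returns
    the index of the nearest truth follicle for each (recovery tests compare
    call *i* against ``truth.iloc[match[i]]``).
    """
    truth_xy = truth[["center_row", "center_col"]].to_numpy()
    tree = cKDTree(truth_xy)
    _, idx = tree.query(np.asarray(centers_rc, dtype=float))
    return idx


# ---------------------------------------------------------------------------
# basal-cell meshes


def _membrane_band(mask: np.ndarray, width: int) -> np.ndarray:
    """Pixels of a cell within ``width`` of its outline (4-connected erosion)."""
    from scipy.ndimage import binary_erosion

    eroded = binary_erosion(mask, iterations=width, border_value=0)
    return mask & ~eroded


def make_cell_mesh(params: MeshSimParams):
    """Generate a Voronoi cell mesh with axis-modulated membrane intensity.

    Returns ``(labels, intensity, truth)``. ``labels`` is an integer label
    image (cell IDs 1..n); ``intensity`` carries the membrane signal;
    ``truth`` has one row per cell: ``cell_id, centroid_row, centroid_col,
    polarity_axis_deg, expected_magnitude, expected_axis_deg`` where the
    expected values are the brute-force noiseless nematic order
    ``|sum I exp(2i phi)| / sum I`` over that cell's membrane pixels.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.domain_size
    # jittered hexagonal packing: epithelial cells are near-isotropic, and an
    # unmodulated mesh must carry ~zero shape-driven nematic signal
    n_cols = max(2, int(np.ceil(np.sqrt(params.n_cells * w / h))))
    n_rows = max(2, int(np.ceil(params.n_cells / n_cols)))
    dy, dx = h / n_rows, w / n_cols
    pts = []
    for i in range(n_rows):
        for j in range(n_cols):
            pts.append((dy * (i + 0.5), dx * (j + 0.5 + (0.25 if i % 2 else -0.25))))
    pts = np.asarray(pts[:params.n_cells])
    spacing = min(dy, dx)
    seeds = pts + rng.uniform(-params.jitter * spacing, params.jitter * spacing,
                              size=pts.shape)
    rows, cols = np.mgrid[0:h, 0:w]
    # nearest-seed assignment == rasterized Voronoi tessellation
    tree = cKDTree(seeds)
    _, owner = tree.query(np.column_stack([rows.ravel(), cols.ravel()]))
    labels = owner.reshape(h, w).astype(np.uint16) + 1

    intensity = np.zeros((h, w), dtype=float)
    axis_rad = np.radians(params.polarity_axis)
    records = []
    for cid in range(1, params.n_cells + 1):
        mask = labels == cid
        if not mask.any():  # seed swallowed by a neighbour (possible at tiny domains)
            continue
        rr, cc = np.nonzero(mask)
        centroid = (rr.mean(), cc.mean())
        band = _membrane_band(mask, params.membrane_width)
        br, bc = np.nonzero(band)
        phi = np.radians(pixel_angles_deg(br, bc, centroid))
        vals = (params.base_intensity
                + params.modulation_amplitude * np.cos(2.0 * (phi - axis_rad)))
        intensity[br, bc] = vals
        q = np.sum(vals * np.exp(2j * phi)) / np.sum(vals)
        touches = bool(rr.min() == 0 or cc.min() == 0
                       or rr.max() == h - 1 or cc.max() == w - 1)
        records.append({
            "cell_id": cid,
            "centroid_row": centroid[0],
            "centroid_col": centroid[1],
            "polarity_axis_deg": params.polarity_axis,
            "expected_magnitude": float(np.abs(q)),
            "expected_axis_deg": float((np.degrees(np.angle(q)) / 2.0) % 180.0),
            "touches_border": touches,
        })

    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    truth = pd.DataFrame.from_records(records)
    return labels, intensity, truth


# ---------------------------------------------------------------------------
# cell-pair junction fixtures


@dataclass(frozen=True)
class PairROISet:
    """Masks of the three measurement regions of a pair fixture."""

    junction: np.ndarray
    cell_pair: np.ndarray  # membrane contour band of both cells, junction excluded
    background: np.ndarray


def make_cellpair_image(params: PairSimParams):
    """Render two adjacent rectangular cells sharing an enriched junction.

    Returns ``(image, rois, truth)``. Membrane (outline) pixels sit at
    ``membrane_intensity``, the shared junction band at
    ``enrichment_factor * membrane_intensity``; ``background_level`` is added
    everywhere. The cell-pair ROI is the membrane contour band excluding the
    junction, so the oracle enrichment ratio on a noiseless fixture equals
    ``enrichment_factor`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    bw = params.band_width
    jl = params.junction_length

    # two rectangles sharing a vertical edge at the image mid-column
    top = (h - jl) // 2
    bot = top + jl
    mid = w // 2
    left0, right1 = max(4, mid - w // 3), min(w - 4, mid + w // 3)

    cells = np.zeros((h, w), dtype=bool)
    cells[top:bot, left0:right1] = True

    outline = np.zeros((h, w), dtype=bool)
    outline[top:top + bw, left0:right1] = True
    outline[bot - bw:bot, left0:right1] = True
    outline[top:bot, left0:left0 + bw] = True
    outline[top:bot, right1 - bw:right1] = True

    junction = np.zeros((h, w), dtype=bool)
    junction[top:bot, mid - bw // 2: mid - bw // 2 + bw] = True

    membrane = outline & ~junction

    img = np.full((h, w), params.background_level, dtype=float)
    img[membrane] = params.background_level + params.membrane_intensity
    img[junction] = (params.background_level
                     + params.enrichment_factor * params.membrane_intensity)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)

    background = np.zeros((h, w), dtype=bool)
    background[2:top - 2, 2:left0 - 2] = True

    rois = PairROISet(junction=junction, cell_pair=membrane, background=background)
    truth = pd.DataFrame([{
        "enrichment_factor": params.enrichment_factor,
        "membrane_intensity": params.membrane_intensity,
        "background_level": params.background_level,
    }])
    return img, rois, truth


# ---------------------------------------------------------------------------
# FRAP traces


def frap_recovery_model(t, bleach_depth, mobile_fraction, rate_k):
    """Normalized post-bleach recovery: (1 - depth) + depth * m * (1 - e^{-kt})."""
    t = np.asarray(t, dtype=float)
    return (1.0 - bleach_depth) + bleach_depth * mobile_fraction * (
        1.0 - np.exp(-rate_k * t))


def make_frap_traces(params: FRAPSimParams):
    """Simulate FRAP acquisitions as a long-format trace table.

    Returns ``(traces, truth)``. ``traces`` has columns ``trace_id, frame,
    time_s, bleach, reference, background`` with ``time_s = 0`` at the first
    post-bleach frame (pre-bleach frames have negative times separated by the
    bleach dead time). The bleach-ROI model is ``background + S * D(t) * f(t)``
    with ``f = 1`` pre-bleach and the one-phase recovery post-bleach, and
    ``D(t) = exp(-acquisition_bleach_rate * t)`` shared with the reference ROI.
    """
    rng = np.random.default_rng(params.seed)
    t_pre = -params.bleach_duration - params.frame_interval * np.arange(
        params.n_prebleach - 1, -1, -1)
    t_post = params.frame_interval * np.arange(params.n_recovery)
    times = np.concatenate([t_pre, t_post])
    n_frames = times.size

    f = np.ones(n_frames)
    f[params.n_prebleach:] = frap_recovery_model(
        t_post, params.bleach_depth, params.mobile_fraction, params.rate_k)
    decay = np.exp(-params.acquisition_bleach_rate * times)

    frames = np.arange(n_frames)
    tables = []
    truth_rows = []
    for tid in range(params.n_traces):
        bleach = params.background_level + params.signal_level * decay * f
        reference = params.background_level + params.signal_level * decay
        background = np.full(n_frames, params.background_level)
        if params.noise_sd > 0:
            bleach = bleach + rng.normal(0, params.noise_sd, n_frames)
            reference = reference + rng.normal(0, params.noise_sd, n_frames)
            background = background + rng.normal(0, params.noise_sd, n_frames)
        tables.append(pd.DataFrame({
            "trace_id": tid,
            "frame": frames,
            "time_s": times,
            "bleach": bleach,
            "reference": reference,
            "background": background,
        }))
        truth_rows.append({
            "trace_id": tid,
            "mobile_fraction": params.mobile_fraction,
            "immobile_fraction": 1.0 - params.mobile_fraction,
            "rate_k": params.rate_k,
            "bleach_depth": params.bleach_depth,
        })
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truth_rows)
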