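"""Angle conventions and circular statistics shared by all stages.

Global convention: angles in degrees, anterior = 0°, increasing
counterclockwise in a right-handed (x-right, y-up) frame. Because image row
indices increase downward, the row offset is negated when computing angles
from pixel coordinates.
"""

from __future__ import annotations

import numpy as np


def pixel_angles_deg(rows, cols, center_rc) -> np.ndarray:
    """Angular position of pixels about a center, in [0, 360).

    Parameters
    ----------
    rows, cols
        Pixel indices (array-like).
    center_rc
        ``(row, col)`` of the center, in pixel units.

    Returns
    -------
    ndarray of angles in degrees, anterior = 0°, counterclockwise positive.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    dy = -(rows - center_rc[0])  # row axis points down; negate for y-up
    dx = cols - center_rc[1]
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def circular_mean_resultant(angles_deg, period: float = 360.0):
    """First trigonometric moment of a sample of angles.

    Returns ``(mean_angle_deg, resultant_length)`` where the mean is in
    ``[0, period)`` and the resultant length is in [0, 1]. ``period=180``
    treats the data as axial (nematic): angles are doubled before averaging
    and the mean is halved back.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular mean of an empty sample is undefined")
    wrap = 360.0 / period
    z = np.exp(1j * np.radians(a * wrap)).mean()
    mean = (np.degrees(np.angle(z)) / wrap) % period
    return mean, float(np.abs(z))


def angular_coverage_deg(angles_deg, bin_width: float = 10.0) -> float:
    """Total angular extent occupied by a pixel set, via bin occupancy.

    The circle is divided into ``360/bin_width`` bins; coverage is the number
    of occupied bins times the bin width, in [0, 360].
    """
    if 360.0 % bin_width:
        raise ValueError("bin_width must divide 360")
    a = np.asarray(angles_deg, dtype=float) % 360.0
    n_bins = int(round(360.0 / bin_width))
    occupied = np.unique((a // bin_width).astype(int) % n_bins)
    return occupied.size * bin_width


def rose_histogram(angles_deg, bin_width: float = 20.0, period: float = 360.0):
    """Histogram of angles over ``[0, period)`` with fixed-width bins.

    Returns ``(bin_edges, counts)``; edges have length ``n_bins + 1``.
    """
    if period % bin_width:
        raise ValueError("bin_width must divide the period")
    n_bins = int(round(period / bin_width))
    edges = np.linspace(0.0, period, n_bins + 1)
    counts, _ = np.histogram(np.asarray(angles_deg, dtype=float) % period, bins=edges)
    return edges, counts
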