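"""Junction-enrichment scoring and distribution comparison.

The junction enrichment (JE) of a labelled cell-cell junction is the ratio
of the mean fluorescence along the junction to the mean over the cell pair
(or single cell), both measured on a background-subtracted image:

    JE = junction mean / cell (pair) mean,   after background correction.

A membrane protein uniformly distributed over the cell surface scores
JE ~ 1; junctional recruitment scores above 1. Distributions of JE scores
between experimental groups are compared with the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

QC_OK = "ok"
QC_UNDEFINED = "undefined_ratio"
QC_JUNCTION_OUTSIDE = "junction_outside_cell"


@dataclass
class ROISet:
    """Measurement regions for one junction, as boolean pixel masks.

    ``cell_roi`` may be a membrane contour band or a filled footprint; the
    convention is recorded in ``cell_roi_kind`` because the expected JE
    differs between the two.
    """

    junction_roi: np.ndarray
    cell_roi: np.ndarray
    background_roi: np.ndarray
    image_ref: str = ""
    cell_roi_kind: str = "contour"  # "contour" or "filled"


@dataclass
class JEResult:
    je: float  # NaN when undefined
    junction_mean: float
    cell_mean: float
    background_mean: float
    qc_flag: str = QC_OK
    cell_roi_kind: str = "contour"


@dataclass
class GroupComparison:
    statistic: float  # KS D in [0, 1]
    p_value: float
    n1: int
    n2: int


def background_correct(image: np.ndarray, background_roi: np.ndarray,
                       clip_negative: bool = True):
    """Subtract the background-ROI mean from the whole image.

    Returns ``(corrected, background_mean)``. Negative values are clipped
    at zero by default so downstream ROI means stay interpretable as
    non-negative fluorescence.
    """
    image = np.asarray(image, dtype=float)
    background_roi = np.asarray(background_roi, dtype=bool)
    if not background_roi.any():
        raise ValueError("background ROI is empty")
    bg = float(image[background_roi].mean())
    corrected = image - bg
    if clip_negative:
        corrected = np.clip(corrected, 0.0, None)
    return corrected, bg


def junction_enrichment(corrected: np.ndarray, roi_set: ROISet,
                        background_mean: float = np.nan) -> JEResult:
    """JE ratio of one junction on a background-corrected image."""
    corrected = np.asarray(corrected, dtype=float)
    jmask = np.asarray(roi_set.junction_roi, dtype=bool)
    cmask = np.asarray(roi_set.cell_roi, dtype=bool)
    if not jmask.any() or not cmask.any():
        raise ValueError("junction and cell ROIs must be non-empty")
    # a filled cell ROI should contain its junction; contour ROIs exclude it
    qc = QC_OK
    if roi_set.cell_roi_kind == "filled" and (jmask & ~cmask).any():
        qc = QC_JUNCTION_OUTSIDE
    jmean = float(corrected[jmask].mean())
    cmean = float(corrected[cmask].mean())
    if cmean <= 0:
        return JEResult(np.nan, jmean, cmean, background_mean, QC_UNDEFINED,
                        roi_set.cell_roi_kind)
    return JEResult(jmean / cmean, jmean, cmean, background_mean, qc,
                    roi_set.cell_roi_kind)


def score_junction(image: np.ndarray, roi_set: ROISet,
                   clip_negative: bool = True) -> JEResult:
    """Background-correct then score: the full per-junction pipeline."""
    corrected, bg = background_correct(image, roi_set.background_roi,
                                       clip_negative=clip_negative)
    return junction_enrichment(corrected, roi_set, background_mean=bg)


def compare_groups(scores_a, scores_b, method: str = "asymp") -> GroupComparison:
    """Two-sample KS test between JE score distributions.

    ``method`` is passed to :func:`scipy.stats.ks_2samp` (``"asymp"`` for the
    asymptotic distribution, ``"exact"`` for small samples).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per group")
    res = stats.ks_2samp(a, b, method=method)
    return GroupComparison(statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           n1=a.size, n2=b.size)
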