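"""FRAP trace correction, normalization, one-phase fitting, immobile fraction.

Processing chain for fluorescence recovery after photobleaching:

1. **Correct** for background and acquisition bleaching: subtract the
   background ROI frame-wise, then divide by the reference ROI's
   background-subtracted signal rescaled to its pre-bleach mean,

       corrected_t = (bleach_t - bg_t) /
                     [(ref_t - bg_t) / mean_prebleach(ref - bg)].

2. **Normalize** to the full scale of the bleach,

       norm_t = (F_t - F_bleach) / (F_ini - F_bleach),

   where F_ini is the mean corrected pre-bleach intensity and F_bleach the
   corrected intensity at the first post-bleach frame — so the first
   post-bleach point maps to 0 and the pre-bleach level to 1.

3. **Fit** the one-phase association model

       Y(t) = Y0 + (Plateau - Y0) * (1 - exp(-k t)),   t = 0 at first
       post-bleach frame,

   by bounded least squares with multi-start initialization (k seeded from
   the observed half-recovery time).

4. The **immobile fraction** is 1 - (Plateau - Y0) / (1 - Y0): the share of
   the bleached signal that never recovers.

Fits with r^2 <= 0.93 are flagged as unreliable but still reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_SQUARED_WARN = 0.93
_EPS = 1e-6


@dataclass
class FRAPTrace:
    """Raw ROI intensity series of one acquisition.

    Times are frame timestamps in seconds, strictly increasing, with the
    first ``n_prebleach`` frames preceding the bleach.
    """

    times: np.ndarray
    bleach_roi: np.ndarray
    reference_roi: np.ndarray
    background_roi: np.ndarray
    n_prebleach: int = 3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.reference_roi = np.asarray(self.reference_roi, dtype=float)
        self.background_roi = np.asarray(self.background_roi, dtype=float)
        n = self.times.size
        if not (self.bleach_roi.size == self.reference_roi.size
                == self.background_roi.size == n):
            raise ValueError("all series must have equal length")
        if self.n_prebleach < 1 or self.n_prebleach >= n:
            raise ValueError("n_prebleach must be in [1, n_frames)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class NormalizedTrace:
    """Post-bleach recovery on the normalized scale; t = 0 at first frame."""

    t: np.ndarray
    value: np.ndarray


@dataclass
class FRAPFit:
    Y0: float
    Plateau: float
    k: float  # per second; NaN for degenerate (flat) traces
    r_squared: float
    immobile_fraction: float
    converged: bool
    qc_flag: str = "ok"


def correct_trace(trace: FRAPTrace) -> np.ndarray:
    """Background- and acquisition-bleach-corrected intensity series."""
    ref = trace.reference_roi - trace.background_roi
    if np.any(ref <= 0):
        bad = int(np.argmax(ref <= 0))
        raise ValueError(
            f"reference ROI not above background at frame {bad}; "
            "cannot correct for acquisition bleaching")
    ref_pre = ref[:trace.n_prebleach].mean()
    return (trace.bleach_roi - trace.background_roi) / (ref / ref_pre)


def normalize_trace(corrected: np.ndarray, n_prebleach: int,
                    times: np.ndarray | None = None) -> NormalizedTrace:
    """Full-scale normalization; output starts at the first post-bleach frame."""
    corrected = np.asarray(corrected, dtype=float)
    f_ini = corrected[:n_prebleach].mean()
    f_bleach = corrected[n_prebleach]
    if abs(f_ini - f_bleach) < _EPS:
        raise ValueError("no bleach depth: pre-bleach mean equals first "
                         "post-bleach intensity")
    post = corrected[n_prebleach:]
    value = (post - f_bleach) / (f_ini - f_bleach)
    if times is None:
        t = np.arange(post.size, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
        t = times[n_prebleach:] - times[n_prebleach]
    return NormalizedTrace(t=t, value=value)


def one_phase_association(t, y0, plateau, k):
    """Y(t) = Y0 + (Plateau - Y0) * (1 - exp(-k t))."""
    t = np.asarray(t, dtype=float)
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def immobile_fraction(y0: float, plateau: float) -> tuple[float, str]:
    """1 - (Plateau - Y0)/(1 - Y0), clipped to [0, 1].

    Returns ``(value, qc_flag)``; the flag is ``"clipped"`` when the raw
    value fell outside [0, 1] (fit noise can push Plateau above 1 or below
    Y0). Undefined when Y0 >= 1 (no bleach depth on the normalized scale).
    """
    if y0 >= 1.0 - _EPS:
        raise ValueError("immobile fraction undefined: Y0 >= 1")
    raw = 1.0 - (plateau - y0) / (1.0 - y0)
    clipped = min(max(raw, 0.0), 1.0)
    return clipped, ("clipped" if clipped != raw else "ok")


def _r_squared(y, y_hat) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < _EPS else -np.inf
    return 1.0 - ss_res / ss_tot


# fit bounds: Y0 in [-0.2, 1], Plateau in [-0.2, 1.5], k in (0, 10] /s
_BOUNDS = ([-0.2, -0.2, 1e-6], [1.0, 1.5, 10.0])


def fit_recovery(norm: NormalizedTrace, min_points: int = 8) -> FRAPFit:
    """Bounded least-squares fit of the one-phase association model.

    Multi-start: k is initialized from the observed half-recovery time and
    from a coarse logarithmic grid; the best-residual solution wins.
    Degenerate (flat) traces are returned with Plateau = Y0 and k = NaN.
    """
    t, y = norm.t, norm.value
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} post-bleach points")

    if np.ptp(y) < _EPS:  # flat trace: k unidentifiable
        c = float(np.mean(y))
        imm, flag = immobile_fraction(c, c)
        return FRAPFit(Y0=c, Plateau=c, k=np.nan, r_squared=1.0,
                       immobile_fraction=imm, converged=True, qc_flag=flag)

    y0_init = float(y[0])
    plateau_init = float(np.mean(y[-max(3, y.size // 10):]))

    # k from half-recovery time: first t where y crosses midway to plateau
    k_starts = [0.01, 0.1, 1.0]
    half = y0_init + 0.5 * (plateau_init - y0_init)
    crossing = np.nonzero(y >= half)[0] if plateau_init > y0_init else []
    if len(crossing) and t[crossing[0]] > 0:
        k_starts.insert(0, float(np.log(2.0) / t[crossing[0]]))

    def resid(p):
        return one_phase_association(t, *p) - y

    best = None
    for k0 in k_starts:
        p0 = np.clip([y0_init, plateau_init, k0],
                     _BOUNDS[0], _BOUNDS[1])
        try:
            sol = least_squares(resid, p0, bounds=_BOUNDS, method="trf")
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        warnings.warn("one-phase association fit failed to converge")
        return FRAPFit(Y0=np.nan, Plateau=np.nan, k=np.nan, r_squared=np.nan,
                       immobile_fraction=np.nan, converged=False,
                       qc_flag="optimizer_failed")

    y0_fit, plateau_fit, k_fit = best.x
    r2 = _r_squared(y, one_phase_association(t, *best.x))
    imm, flag = immobile_fraction(y0_fit, plateau_fit)
    converged = r2 > R_SQUARED_WARN
    if not converged and flag == "ok":
        flag = "low_r_squared"
    return FRAPFit(Y0=float(y0_fit), Plateau=float(plateau_fit),
                   k=float(k_fit), r_squared=r2, immobile_fraction=imm,
                   converged=converged, qc_flag=flag)


def process_trace(trace: FRAPTrace) -> tuple[NormalizedTrace, FRAPFit]:
    """correct -> normalize -> fit for one raw trace."""
    corrected = correct_trace(trace)
    norm = normalize_trace(corrected, trace.n_prebleach, times=trace.times)
    return norm, fit_recovery(norm)


@dataclass
class ConditionSummary:
    """Per-condition aggregate of normalized recovery curves.

    The headline estimator fits the per-timepoint averaged trace (matching
    how pooled recovery curves are conventionally analysed); per-trace fits
    are kept alongside for dispersion estimates.
    """

    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    pooled_fit: FRAPFit
    per_trace_fits: list[FRAPFit] = field(default_factory=list)
    n_traces: int = 0


def summarize_frap(norms: list[NormalizedTrace]) -> ConditionSummary:
    """Mean +/- SD of normalized curves and a fit of the averaged trace."""
    if len(norms) < 2:
        raise ValueError("need at least 2 traces per condition")
    t0 = norms[0].t
    for n in norms[1:]:
        if n.t.shape != t0.shape or not np.allclose(n.t, t0):
            raise ValueError("traces are on mismatched time grids")
    values = np.vstack([n.value for n in norms])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    pooled = fit_recovery(NormalizedTrace(t=t0, value=mean))
    per_trace = [fit_recovery(n) for n in norms]
    return ConditionSummary(t=t0, mean=mean, sd=sd, pooled_fit=pooled,
                            per_trace_fits=per_trace, n_traces=len(norms))


def traces_from_table(table: pd.DataFrame, n_prebleach: int = 3) -> list[FRAPTrace]:
    """Build FRAPTrace objects from a long-format table.

    Expected columns: ``time_s, bleach, reference, background`` and
    optionally ``trace_id`` (single trace assumed when absent).
    """
    required = {"time_s", "bleach", "reference", "background"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    if "trace_id" not in table.columns:
        table = table.assign(trace_id=0)
    out = []
    for _, grp in table.groupby("trace_id", sort=True):
        grp = grp.sort_values("time_s")
        out.append(FRAPTrace(
            times=grp["time_s"].to_numpy(),
            bleach_roi=grp["bleach"].to_numpy(),
            reference_roi=grp["reference"].to_numpy(),
            background_roi=grp["background"].to_numpy(),
            n_prebleach=n_prebleach))
    return out


def fits_to_frame(fits: list[FRAPFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "Y0": f.Y0,
        "Plateau": f.Plateau,
        "k_per_s": f.k,
        "r_squared": f.r_squared,
        "immobile_fraction": f.immobile_fraction,
        "converged": f.converged,
        "qc_flag": f.qc_flag,
    } for f in fits])
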