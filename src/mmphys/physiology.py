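"""Population physiology statistics and auxiliary computations.

Cell-volume geometry (spherocylinder), coefficient-of-variation tables,
cross-correlations of mean-normalized parameters, imaging discretization
error, turbidostat growth-interval fitting, and the binned time-series
machinery used for nutrient-shift analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "volume_from_dimensions",
    "length_from_volume",
    "discretization_error",
    "compute_cv_table",
    "cross_correlation_matrix",
    "ODTrace",
    "fit_growth_intervals",
    "BinnedSeries",
    "binned_series",
    "normalize_to_baseline",
    "shape_filter",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def volume_from_dimensions(length, width):
    """Cell volume (μm³) for a cylinder of diameter ``width`` with
    hemispherical end caps: π(W/2)²(L − W) + (4/3)π(W/2)³.

    Accepts scalars or arrays; requires L ≥ W > 0.
    """
    L = np.asarray(length, dtype=float)
    W = np.asarray(width, dtype=float)
    if np.any(W <= 0):
        raise ValueError("width must be positive")
    if np.any(L < W):
        raise ValueError("length must be at least the width (no cylinder segment)")
    r = W / 2.0
    vol = math.pi * r**2 * (L - W) + (4.0 / 3.0) * math.pi * r**3
    if np.ndim(length) == 0 and np.ndim(width) == 0:
        return float(vol)
    return vol


def length_from_volume(volume, width):
    """Inverse of :func:`volume_from_dimensions` at fixed width.

    Using V = π(W/2)²·(L − W/3), the length is L = V/(π(W/2)²) + W/3.
    """
    V = np.asarray(volume, dtype=float)
    W = np.asarray(width, dtype=float)
    if np.any(W <= 0):
        raise ValueError("width must be positive")
    area = math.pi * (W / 2.0) ** 2
    L = V / area + W / 3.0
    if np.ndim(volume) == 0 and np.ndim(width) == 0:
        return float(L)
    return L


def discretization_error(frames_per_generation) -> float:
    """Maximum relative size error from frame-quantized division detection.

    With exponential growth and ``k`` images per generation a cell grows by
    a factor 2^(1/k) between consecutive frames, so the division length read
    at the detection frame can overshoot the true one by 2^(1/k) − 1
    (≈ 4% at k = 16).
    """
    k = float(frames_per_generation)
    if k < 1:
        raise ValueError("frames_per_generation must be >= 1")
    return 2.0 ** (1.0 / k) - 1.0


# ---------------------------------------------------------------------------
# CV table and correlations
# ---------------------------------------------------------------------------

def compute_cv_table(records: pd.DataFrame, parameters) -> pd.DataFrame:
    """Per-parameter mean, sample SD, CV and n, sorted ascending by CV.

    ``records`` is a DataFrame with one row per cell generation.  Parameters
    with zero mean get CV = NaN and are flagged (sorted last).  Uses the
    n−1 sample SD throughout; CV is reported as a fraction.
    """
    rows = []
    for p in parameters:
        x = pd.to_numeric(records[p], errors="coerce").dropna().to_numpy()
        if x.size < 2:
            raise ValueError(f"parameter {p!r} has fewer than 2 finite values")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        cv = sd / mean if mean != 0 else np.nan
        rows.append({"parameter": p, "mean": mean, "sd": sd, "cv": cv,
                     "n": int(x.size), "flagged": mean == 0})
    table = pd.DataFrame(rows)
    return (table.sort_values("cv", kind="stable", na_position="last")
                 .reset_index(drop=True))


def cross_correlation_matrix(records: pd.DataFrame, parameters) -> pd.DataFrame:
    """Pairwise regression slope and Pearson r on mean-normalized parameters.

    Every parameter is divided by its mean; for each ordered pair (x, y) the
    least-squares slope of y on x, the Pearson correlation and the number of
    complete records are reported.  Constant parameters are flagged with
    NaN slope/r.
    """
    sub = records[list(parameters)].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < 10:
        raise ValueError("need at least 10 complete records")
    norm = sub / sub.mean()
    rows = []
    for px in parameters:
        x = norm[px].to_numpy()
        for py in parameters:
            y = norm[py].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                slope = r = np.nan
            else:
                slope = float(np.polyfit(x, y, 1)[0])
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"x": px, "y": py, "slope": slope, "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# turbidostat
# ---------------------------------------------------------------------------

@dataclass
class ODTrace:
    """Optical-density time series from a turbidostat run.

    ``times`` (min) and ``od`` are sample arrays; ``dilution_times`` are the
    instants at which the culture was diluted back to the low set-point.
    A sample at exactly a dilution time is post-dilution.
    """

    times: np.ndarray
    od: np.ndarray
    dilution_times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.dilution_times = np.asarray(self.dilution_times, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have the same shape")


def fit_growth_intervals(trace: ODTrace, min_samples: int = 3) -> pd.DataFrame:
    """Fit an exponential I = I0·2^(t/τ) to each inter-dilution interval.

    Returns one row per interval with the fitted doubling time ``tau_min``,
    growth rate ``lambda_per_min`` = ln2/τ, and ``doublings`` over the
    interval, computed from the fitted line evaluated at the interval
    boundaries (so a noiseless 0.05 → 0.2 cycle yields exactly 2).
    Intervals with fewer than ``min_samples`` positive samples are skipped.
    """
    bounds = np.concatenate([[trace.times[0]], trace.dilution_times,
                             [trace.times[-1] + 1e-9]])
    rows = []
    for i, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
        mask = (trace.times >= t0) & (trace.times < t1)
        t = trace.times[mask]
        od = trace.od[mask]
        ok = od > 0
        if ok.sum() < min_samples:
            continue
        t, od = t[ok], od[ok]
        slope, intercept = np.polyfit(t, np.log2(od), 1)
        if slope <= 0:
            continue
        tau = 1.0 / slope
        rows.append({
            "interval": i,
            "t_start_min": float(t0),
            "t_end_min": float(t1),
            "n_samples": int(len(t)),
            "tau_min": float(tau),
            "lambda_per_min": float(LN2 / tau),
            "doublings": float(slope * (t1 - t0)),
        })
    if not rows:
        raise ValueError("no interval with enough positive samples to fit")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binned time series (nutrient-shift analysis)
# ---------------------------------------------------------------------------

@dataclass
class BinnedSeries:
    """Fixed-width binned means of a scattered time series.

    ``mask`` is True where the bin holds at least the minimum number of
    points; SEM uses the sample SD (n−1).
    """

    centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    bin_width: float


def binned_series(times, values, bin_width: float = 12.0, min_n: int = 5,
                  anchor: float | None = None) -> BinnedSeries:
    """Bin ``values`` by time into fixed-width bins (default 12 min).

    Bins are anchored at ``anchor`` (default: the earliest timestamp); bins
    with fewer than ``min_n`` points are masked but still reported.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise ValueError("empty input series")
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    if anchor is None:
        anchor = float(t.min())
    idx = np.floor((t - anchor) / bin_width).astype(int)
    nbin = idx.max() + 1
    centers = anchor + (np.arange(nbin) + 0.5) * bin_width
    means = np.full(nbin, np.nan)
    sems = np.full(nbin, np.nan)
    counts = np.zeros(nbin, dtype=int)
    for i in range(nbin):
        sel = v[idx == i]
        counts[i] = sel.size
        if sel.size:
            means[i] = sel.mean()
            sems[i] = np.std(sel, ddof=1) / np.sqrt(sel.size) if sel.size > 1 else np.nan
    mask = counts >= min_n
    return BinnedSeries(centers=centers, means=means, sems=sems,
                        counts=counts, mask=mask, bin_width=float(bin_width))


def normalize_to_baseline(times, values, event_time: float,
                          baseline_window: float = 240.0,
                          min_points: int = 5):
    """Divide a series by its mean over [event_time − window, event_time).

    Mirrors the shift-experiment convention of normalizing every parameter
    to its average in the 4 h before the shift.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    sel = (t >= event_time - baseline_window) & (t < event_time) & np.isfinite(v)
    if sel.sum() < min_points:
        raise ValueError(
            f"baseline window holds {int(sel.sum())} points (< {min_points})")
    return v / v[sel].mean()


# ---------------------------------------------------------------------------
# fixed-cell snapshot filter
# ---------------------------------------------------------------------------

def shape_filter(records: pd.DataFrame, k_sd: float = 3.0,
                 columns=("length_um", "width_um")):
    """Keep snapshot cells whose length and width lie within ``k_sd`` sample
    SDs of the population mean (single pass, statistics from the unfiltered
    set).  Returns (kept, report) where report maps column -> n excluded.

    This 3-SD filter applies to fixed-cell population snapshots; lineage
    records use the 4-SD multi-parameter filter in :mod:`mmphys.traces`.
    """
    keep = np.ones(len(records), dtype=bool)
    report = {}
    for col in columns:
        x = records[col].to_numpy(dtype=float)
        mean, sd = x.mean(), x.std(ddof=1)
        ok = np.abs(x - mean) <= k_sd * sd
        report[col] = int((~ok).sum())
        keep &= ok
    return records[keep].reset_index(drop=True), report
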