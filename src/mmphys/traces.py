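"""Per-generation physiology extraction from frame-level traces.

From a mother-machine frame table (one tracked lineage per trap) this
module segments generations at division events (a > 35% drop in length
between consecutive frames), fits the per-generation elongation rate,
reads birth/division sizes and septum positions, and — given replication
start/end event annotations — assigns the C period, D period, initiation
size per origin (s_i) and the number of overlapping cell cycles (n_oc) to
each generation.

Replication events come from an annotation table (here: the simulator's
ground-truth initiation/termination times); inferring them from focus
counts is the job of the ensemble module.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .physiology import length_from_volume, volume_from_dimensions

__all__ = [
    "fit_elongation_rate",
    "build_generations",
    "assign_cell_cycles",
    "filter_outliers",
    "DEFAULT_FILTER_PARAMETERS",
]

LN2 = math.log(2.0)

#: Parameters screened by the 4-SD lineage outlier filter.
DEFAULT_FILTER_PARAMETERS = (
    "septum_position", "lambda_per_min", "tau_min",
    "L_b_um", "L_d_um", "delta_d_um",
)


def fit_elongation_rate(times, sizes):
    """Least-squares slope of ln(size) against time.

    Generic log-linear elongation fit: feed lengths for a length-based
    rate or volumes for the volumetric growth rate.  Requires at least 3
    frames with positive sizes.  Returns the rate in 1/min.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 frames to fit an elongation rate")
    if np.any(s <= 0):
        raise ValueError("sizes must be positive for a log-linear fit")
    slope, _ = np.polyfit(t, np.log(s), 1)
    return float(slope)


def _segment_lineage(times, lengths, drop_threshold):
    """Indices [start, end) of generations split at length drops."""
    drops = np.flatnonzero(lengths[1:] < (1.0 - drop_threshold) * lengths[:-1])
    bounds = np.concatenate([[0], drops + 1, [len(times)]])
    return list(zip(bounds[:-1], bounds[1:]))


def build_generations(frames: pd.DataFrame, drop_threshold: float = 0.35,
                      equilibration: float = 180.0) -> pd.DataFrame:
    """Build per-generation records from a frame table.

    Division is recorded at the first frame where the tracked cell's size
    drops by more than ``drop_threshold`` between consecutive frames.  The
    drop test runs on the spherocylinder volume (computed per frame from
    length and width) rather than raw length: septation conserves volume,
    so the volume ratio across a division is the septum fraction itself
    (~0.5), whereas the length ratio is diluted by the polar caps and by
    mother/daughter width differences and can graze a length-based cut.
    Birth/division lengths are read at the first/last frame of the
    generation; volumes use the spherocylinder formula; the elongation rate
    is fitted on the volume series (exponential under balanced
    biosynthesis); the septum position is the daughter's birth length over
    the mother's division length.  The first (unbounded birth) and last
    (no observed division) segments of each lineage are dropped, as are
    births before ``equilibration`` min (the pre-steady-state window).

    Returns a DataFrame with one row per generation.
    """
    required = {"time_min", "lineage", "length_um", "width_um"}
    missing = required - set(frames.columns)
    if missing:
        raise ValueError(f"frame table lacks columns: {sorted(missing)}")
    rows = []
    for lineage, grp in frames.groupby("lineage", sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        L = grp["length_um"].to_numpy(dtype=float)
        W = grp["width_um"].to_numpy(dtype=float)
        V = volume_from_dimensions(L, W)
        segments = _segment_lineage(t, V, drop_threshold)
        for gen_idx in range(1, len(segments) - 1):
            a, b = segments[gen_idx]
            if b - a < 3:
                continue
            tt, ll, ww = t[a:b], L[a:b], W[a:b]
            width = float(ww.mean())
            vol = volume_from_dimensions(ll, np.full_like(ll, width))
            lam = fit_elongation_rate(tt, vol)
            lnV0 = float(np.polyfit(tt - tt[0], np.log(vol), 1)[1])
            # the true division lies between the last frame of one cell and
            # the first frame of the next; the midpoint is the unbiased
            # estimate of the event time (birth = parent's division)
            prev_b = segments[gen_idx - 1][1]
            next_a = segments[gen_idx + 1][0]
            t_b = float(0.5 * (t[prev_b - 1] + tt[0]))
            t_d = float(0.5 * (tt[-1] + t[next_a]))
            L_b, L_d = float(ll[0]), float(ll[-1])
            septum = float(L[next_a] / ll[-1]) if next_a < len(L) else np.nan
            rows.append({
                "lineage": lineage,
                "cell_id": f"{lineage}.{gen_idx}",
                "parent_id": f"{lineage}.{gen_idx - 1}",
                "t_b_min": t_b,
                "t_d_min": t_d,
                "tau_min": t_d - t_b,
                "L_b_um": L_b,
                "L_d_um": L_d,
                "delta_d_um": L_d - L_b,
                "W_um": width,
                "S_b_um3": float(vol[0]),
                "S_d_um3": float(vol[-1]),
                "lambda_per_min": lam,
                "_lnV_at_birth": lnV0,
                "_t_fit_anchor": float(tt[0]),
                "septum_position": septum,
            })
    records = pd.DataFrame(rows)
    if len(records):
        records = records[records["t_b_min"] >= equilibration].reset_index(drop=True)
    return records


def assign_cell_cycles(records: pd.DataFrame, events: pd.DataFrame,
                       min_consecutive: int = 4,
                       match_tolerance: float = 2.0):
    """Fill C, D, s_i and n_oc from replication event annotations.

    ``events`` needs columns lineage, t_init_min, t_term_min, n_ori.  Each
    initiation is matched to its division FIFO-style (the oldest
    unresolved round takes the earliest unclaimed division after its
    termination); ``n_oc`` counts divisions strictly between initiation and
    that division.  The true size at initiation S_i is interpolated from
    the generation's fitted exponential, and s_i = S_i / n_ori.  Lineages
    with fewer than ``min_consecutive`` recorded generations are skipped
    (cell-cycle assignment needs several consecutive generations).
    ``match_tolerance`` (min) lets a division whose frame-quantized time
    falls marginally before the annotated termination still be claimed
    (a round with a very short D period divides within one frame of
    terminating); the resulting slightly negative D is measurement
    noise, not an error.

    Returns ``(records, events_out, n_unassigned)`` where ``records``
    gains the cycle columns (first initiation per generation) and
    ``events_out`` is the per-event table.
    """
    needed = {"lineage", "t_init_min", "t_term_min", "n_ori"}
    if not needed <= set(events.columns):
        raise ValueError(f"event table lacks columns: {sorted(needed - set(events.columns))}")
    records = records.copy()
    for col in ("t_i_min", "L_i_um", "S_i_um3", "n_ori_at_init", "s_i_um3",
                "C_min", "D_min", "n_oc"):
        records[col] = np.nan
    ev_rows = []
    n_unassigned = 0
    for lineage, recs in records.groupby("lineage", sort=True):
        evs = events[events["lineage"] == lineage].sort_values("t_init_min")
        if len(recs) < min_consecutive:
            n_unassigned += len(evs)
            continue
        recs = recs.sort_values("t_b_min")
        div_times = recs["t_d_min"].to_numpy(dtype=float)
        claimed = np.zeros(div_times.size, dtype=bool)
        first_in_gen: set = set()
        for ev in evs.itertuples(index=False):
            t_i, t_term, n_ori = ev.t_init_min, ev.t_term_min, int(ev.n_ori)
            C = t_term - t_i
            # generation containing the initiation
            gi = np.searchsorted(recs["t_b_min"].to_numpy(), t_i, side="right") - 1
            if gi < 0 or t_i >= recs["t_d_min"].iloc[gi]:
                n_unassigned += 1
                continue
            # earliest unclaimed division after termination
            cand = np.flatnonzero((div_times > t_term - match_tolerance)
                                  & ~claimed)
            if cand.size == 0:
                n_unassigned += 1
                continue
            di = cand[0]
            claimed[di] = True
            t_div = div_times[di]
            D = t_div - t_term
            n_oc = int(np.sum((div_times > t_i) & (div_times < t_div)))
            row = recs.iloc[gi]
            S_i = math.exp(row["_lnV_at_birth"] +
                           row["lambda_per_min"] * (t_i - row["_t_fit_anchor"]))
            L_i = length_from_volume(S_i, row["W_um"])
            vals = {"t_i_min": t_i, "L_i_um": L_i, "S_i_um3": S_i,
                    "n_ori_at_init": n_ori, "s_i_um3": S_i / n_ori,
                    "C_min": C, "D_min": D, "n_oc": n_oc}
            ev_rows.append({"lineage": lineage, "cell_id": row["cell_id"],
                            "t_term_min": t_term, "t_div_min": t_div, **vals})
            if row["cell_id"] not in first_in_gen:
                first_in_gen.add(row["cell_id"])
                idx = records.index[records["cell_id"] == row["cell_id"]][0]
                for k, v in vals.items():
                    records.loc[idx, k] = v
    events_out = pd.DataFrame(ev_rows)
    return records, events_out, n_unassigned


def filter_outliers(records: pd.DataFrame, k_sd: float = 4.0,
                    parameters=DEFAULT_FILTER_PARAMETERS):
    """Single-pass population filter: keep records with every parameter
    within ``k_sd`` sample SDs of its unfiltered mean.

    Returns ``(kept, report)`` with per-parameter exclusion counts.
    Raises if everything is excluded (degenerate input).
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to filter")
    keep = np.ones(len(records), dtype=bool)
    report = {}
    for p in parameters:
        x = records[p].to_numpy(dtype=float)
        mean, sd = np.nanmean(x), np.nanstd(x, ddof=1)
        if not math.isfinite(k_sd):
            report[p] = 0
            continue
        ok = np.abs(x - mean) <= k_sd * sd
        ok |= np.isnan(x)  # missing values are not grounds for exclusion
        report[p] = int((~ok).sum())
        keep &= ok
    if not keep.any():
        raise ValueError("outlier filter excluded every record")
    return records[keep].reset_index(drop=True), report
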