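"""Growth-rate-inhibition (GR) values from endpoint counts and time courses.

The GR value normalizes a drug-response readout by the division rate of
untreated cells, removing the confounding effect of variable proliferation
rates between plates, days and laboratories:

    GR(c) = 2 ** ( log2(x_c / x_0) / log2(x_ctrl / x_0) ) - 1

where x_c is the treated count at the assay endpoint, x_0 the count at the
time of drug addition, and x_ctrl the vehicle-control count at the endpoint.
GR = 1 means uninhibited growth, 0 complete arrest (cytostasis), and -1
complete killing; values are left unclipped (and flagged) when sampling
noise pushes them outside [-1, 1], since clipping would bias downstream
standard-error estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .plate_io import CONTROL, UNTREATED_T0

__all__ = [
    "GRComputationError",
    "viable_counts",
    "gr_value",
    "gr_table",
    "instantaneous_gr",
    "doubling_time",
]


class GRComputationError(ValueError):
    pass


def viable_counts(nuclei_count, dead_count, include_dead: bool = False):
    """Viable cells from nuclei and dead-stain counts.

    Default (dead-exclusive): viable = max(0, nuclei - dead), per the SOP
    convention of not counting dead-stain-positive nuclei.  The
    dead-inclusive variant (viable = nuclei) reproduces the discordant
    counting algorithms seen in practice, which systematically inflate GR.
    """
    nuclei = np.asarray(nuclei_count, dtype=float)
    dead = np.asarray(dead_count, dtype=float)
    if (nuclei < 0).any() or (dead < 0).any():
        raise ValueError("counts must be >= 0")
    if include_dead:
        return nuclei if nuclei.ndim else float(nuclei)
    if (dead > nuclei).any():
        warnings.warn(
            "dead count exceeds nuclei count for some wells; clamping viable to 0",
            stacklevel=2,
        )
    out = np.maximum(nuclei - dead, 0.0)
    return out if out.ndim else float(out)


def gr_value(x_c, x_0, x_ctrl):
    """GR value for treated count(s) x_c given baseline x_0 and control x_ctrl.

    x_c may be scalar or array; x_c = 0 returns the limit -1 exactly.
    Raises GRComputationError when controls did not grow (x_ctrl <= x_0).
    """
    x_0 = float(x_0)
    x_ctrl = float(x_ctrl)
    if x_0 <= 0:
        raise GRComputationError(f"x_0 must be > 0, got {x_0}")
    if x_ctrl <= x_0:
        raise GRComputationError(
            f"control growth insufficient: x_ctrl={x_ctrl} <= x_0={x_0}"
        )
    x_c = np.asarray(x_c, dtype=float)
    if (x_c < 0).any():
        raise GRComputationError("treated counts must be >= 0")
    denom = np.log2(x_ctrl / x_0)
    with np.errstate(divide="ignore"):
        ratio = np.where(x_c > 0, np.log2(np.maximum(x_c, 1e-300) / x_0) / denom, -np.inf)
    gr = np.where(x_c > 0, 2.0 ** ratio - 1.0, -1.0)
    return gr if gr.ndim else float(gr)


def gr_table(
    dataset: pd.DataFrame,
    readout: str = "viable_count",
    ctrl_stat: str = "mean",
) -> pd.DataFrame:
    """Per-well GR values from a tidy endpoint well table.

    x_0 is the mean of the untreated t=0 wells of the same biological
    replicate (shared across that replicate's plates); x_ctrl is the
    per-plate mean (or median, ``ctrl_stat``) of vehicle-control wells.
    Returns one row per treated well with the replicate address, gr, the
    three counts, and flags for gr > 1 and zero-count censoring.
    """
    if ctrl_stat not in ("mean", "median"):
        raise ValueError(f"ctrl_stat must be 'mean' or 'median', got {ctrl_stat!r}")
    df = dataset[dataset["readout_type"] == readout]
    if df.empty:
        raise GRComputationError(f"no rows with readout_type={readout!r}")

    t0 = df[df["drug"] == UNTREATED_T0]
    x0_by_rep = t0.groupby(["center_id", "scientist_id", "bio_rep"])["value"].mean()

    ctrl = df[df["drug"] == CONTROL]
    agg = "median" if ctrl_stat == "median" else "mean"
    ctrl_by_plate = ctrl.groupby(
        ["center_id", "scientist_id", "bio_rep", "plate_id"]
    )["value"].agg(agg)

    treated = df[~df["drug"].isin((CONTROL, UNTREATED_T0))]
    if treated.empty:
        raise GRComputationError("dataset contains no treated wells")

    rows = []
    for (center, scientist, bio_rep, plate), grp in treated.groupby(
        ["center_id", "scientist_id", "bio_rep", "plate_id"], sort=True
    ):
        if (center, scientist, bio_rep) not in x0_by_rep.index:
            raise GRComputationError(
                f"missing untreated t=0 plate for bio_rep {bio_rep} "
                f"({center}/{scientist})"
            )
        if (center, scientist, bio_rep, plate) not in ctrl_by_plate.index:
            raise GRComputationError(f"plate {plate!r} has no control wells")
        x_0 = float(x0_by_rep.loc[(center, scientist, bio_rep)])
        x_ctrl = float(ctrl_by_plate.loc[(center, scientist, bio_rep, plate)])
        x_c = grp["value"].to_numpy()
        gr = np.atleast_1d(gr_value(x_c, x_0, x_ctrl))
        sub = grp[["drug", "concentration", "row", "col"]].reset_index(drop=True)
        sub.insert(0, "center_id", center)
        sub.insert(1, "scientist_id", scientist)
        sub.insert(2, "bio_rep", bio_rep)
        sub.insert(3, "plate_id", plate)
        sub["gr"] = gr
        sub["x_c"] = x_c
        sub["x_0"] = x_0
        sub["x_ctrl"] = x_ctrl
        sub["gr_above_1"] = gr > 1.0
        sub["censored_zero_count"] = x_c == 0
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["drug", "concentration", "bio_rep", "plate_id", "row", "col"]
    ).reset_index(drop=True)


def _window_slope(t: np.ndarray, log2y: np.ndarray) -> float:
    """OLS slope of log2(count) vs time (doublings/h)."""
    return float(np.polyfit(t, log2y, 1)[0])


def instantaneous_gr(
    timecourse: pd.DataFrame,
    window_h: float = 12.0,
    step_h: float = 2.0,
    readout: str = "viable_count",
) -> pd.DataFrame:
    """Windowed (instantaneous) GR values from a live-cell time course.

    Per moving window of width ``window_h`` advancing by ``step_h``, the
    treated and plate-matched control growth rates k (doublings/h) are the
    OLS slopes of log2(count) vs time pooled over that group's wells, and
    gr_t = 2**(k_treated / k_ctrl) - 1.  Windows whose control rate is <= 0
    or that contain < 3 timepoints are omitted.  Returns a tidy frame with
    one row per (bio_rep, plate, drug, concentration, window center).
    """
    if window_h <= 0 or step_h <= 0:
        raise ValueError("window_h and step_h must be > 0")
    df = timecourse[timecourse["readout_type"] == readout]
    if df.empty:
        raise GRComputationError(f"no rows with readout_type={readout!r}")
    t_max = float(df["timepoint_h"].max())
    if t_max < window_h:
        raise GRComputationError(
            f"time span {t_max} h shorter than window {window_h} h"
        )
    half = window_h / 2.0
    centers = np.arange(half, t_max - half + 1e-9, step_h)

    rows = []
    for (bio_rep, plate), plate_df in df.groupby(["bio_rep", "plate_id"], sort=True):
        ctrl = plate_df[plate_df["drug"] == CONTROL]
        if ctrl.empty:
            raise GRComputationError(f"plate {plate!r} has no control wells")
        treated = plate_df[~plate_df["drug"].isin((CONTROL, UNTREATED_T0))]
        ctrl_t = ctrl["timepoint_h"].to_numpy()
        ctrl_v = ctrl["value"].to_numpy()
        for center in centers:
            lo, hi = center - half - 1e-9, center + half + 1e-9
            cmask = (ctrl_t >= lo) & (ctrl_t <= hi) & (ctrl_v > 0)
            if np.unique(ctrl_t[cmask]).size < 3:
                continue
            k_ctrl = _window_slope(ctrl_t[cmask], np.log2(ctrl_v[cmask]))
            if k_ctrl <= 0:
                continue  # flagged by omission: no net control growth here
            for (drug, conc), grp in treated.groupby(["drug", "concentration"]):
                tt = grp["timepoint_h"].to_numpy()
                vv = grp["value"].to_numpy()
                mask = (tt >= lo) & (tt <= hi) & (vv > 0)
                if np.unique(tt[mask]).size < 3:
                    continue
                k_tr = _window_slope(tt[mask], np.log2(vv[mask]))
                rows.append({
                    "bio_rep": bio_rep, "plate_id": plate,
                    "drug": drug, "concentration": conc,
                    "t_center": float(center),
                    "k_treated": k_tr, "k_ctrl": k_ctrl,
                    "gr_t": 2.0 ** (k_tr / k_ctrl) - 1.0,
                })
    if not rows:
        raise GRComputationError("no analyzable windows in time course")
    return pd.DataFrame.from_records(rows)


def doubling_time(timepoints_h, counts) -> float:
    """Population doubling time (h) from a control time course: 1/k with k the
    global OLS slope of log2(count) vs time.  Scale-invariant in counts."""
    t = np.asarray(timepoints_h, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.size < 3:
        raise GRComputationError("need >= 3 timepoints to estimate doubling time")
    if (y <= 0).any():
        raise GRComputationError("counts must be > 0")
    k = _window_slope(t, np.log2(y))
    if k <= 0:
        raise GRComputationError(f"no net growth (k = {k:.4g} doublings/h)")
    return 1.0 / k
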