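"""Sigmoidal GR dose-response fitting and derived metrics.

Fits GR(c) = gr_inf + (1 - gr_inf) / (1 + (c/gec50)^h_gr) to per-condition
GR values by bounded least squares, with a nested F-test fallback to the
flat model GR(c) = mean when the sigmoid is not statistically warranted.

Derived metrics:

* GR50   - concentration where the fitted curve crosses GR = 0.5 (potency);
           censored to a bound when the curve never crosses 0.5 in range.
* GRmax  - mean measured GR at the highest tested concentration (efficacy);
           deliberately the measured value, not the fitted asymptote, since
           it depends on the tested dose range.
* GR_inf - fitted lower asymptote (efficacy at infinite dose).
* GEC50  - fitted mid-point of the response.
* h_GR   - Hill slope.
* GR_AOC - normalized area over the curve in log10-concentration space.

Dose-range adequacy flags mark fits whose GEC50 falls outside the tested
range or whose measured range never reaches the lower plateau - both make
parameter estimates unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit",
    "fit_dose_response",
    "fit_groups",
    "fits_to_frame",
    "aoc",
    "dose_range_flags",
    "compare_assays",
    "CENSOR_EXACT",
    "CENSOR_GT_CMAX",
    "CENSOR_LT_CMIN",
]

CENSOR_EXACT = "exact"
CENSOR_GT_CMAX = "greater_than_cmax"
CENSOR_LT_CMIN = "less_than_cmin"

F_TEST_ALPHA = 0.05
HILL_BOUNDS = (0.1, 5.0)


@dataclass
class DoseResponseFit:
    """Fitted GR curve, derived metrics and range flags for one drug/group."""

    drug: str
    group: tuple = ()
    fit_kind: str = "sigmoid"  # "sigmoid" | "flat"
    gr_inf: float = np.nan
    gec50: float | None = None
    h_gr: float | None = None
    gr50: float = np.nan  # value, or the censoring bound
    gr50_censoring: str = CENSOR_EXACT
    gr_max: float = np.nan
    gr_aoc: float = np.nan
    rss: float = np.nan
    rss_flat: float = np.nan
    f_pvalue: float = np.nan
    n_concentrations: int = 0
    c_min: float = np.nan
    c_max: float = np.nan
    flags: set = field(default_factory=set)

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if self.fit_kind == "flat":
            return np.full_like(conc, self.gr_inf)
        return _sigmoid(conc, self.gr_inf, self.gec50, self.h_gr)


def _sigmoid(c, gr_inf, gec50, h):
    return gr_inf + (1.0 - gr_inf) / (1.0 + (np.asarray(c, dtype=float) / gec50) ** h)


def aoc(gr_values, concentrations) -> float:
    """Normalized area over the GR curve: trapezoidal integral of (1 - GR)
    over log10(c), divided by the log10 range.  0 = no effect anywhere,
    1 = complete arrest (GR = 0) everywhere; monotone in pointwise GR."""
    gr = np.asarray(gr_values, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 2:
        raise ValueError("aoc requires >= 2 concentrations")
    if (conc <= 0).any():
        raise ValueError("concentrations must be > 0")
    order = np.argsort(conc)
    logc = np.log10(conc[order])
    span = logc[-1] - logc[0]
    if span <= 0:
        raise ValueError("concentrations must span a nonzero range")
    return float(np.trapezoid(1.0 - gr[order], logc) / span)


def _solve_gr50(gr_inf: float, gec50: float, h: float) -> float | None:
    """Closed-form crossing of the fitted sigmoid with GR = 0.5 (None if the
    curve never reaches 0.5)."""
    if gr_inf >= 0.5:
        return None
    return gec50 * (0.5 / (0.5 - gr_inf)) ** (1.0 / h)


def fit_dose_response(
    records,
    drug: str | None = None,
    group: tuple = (),
    alpha: float = F_TEST_ALPHA,
) -> DoseResponseFit:
    """Fit one drug x replicate-group dose-response.

    ``records`` is a DataFrame with ``concentration`` and ``gr`` columns (a
    ``drug`` column supplies the name if ``drug`` is None).  Fitting uses
    the per-concentration mean GR, bounds gr_inf in [-1, 1], h_gr in
    [0.1, 5], gec50 in [c_min/100, c_max*100], and a 3-point multi-start
    over gec50.  A nested F-test (sigmoid, 3 parameters, vs flat mean,
    1 parameter) at ``alpha`` decides the flat fallback.
    """
    if isinstance(records, pd.DataFrame):
        if drug is None:
            drugs = records["drug"].unique() if "drug" in records else []
            if len(drugs) != 1:
                raise ValueError("pass a single-drug table or an explicit drug name")
            drug = str(drugs[0])
        conc = records["concentration"].to_numpy(dtype=float)
        gr = records["gr"].to_numpy(dtype=float)
    else:
        conc, gr = (np.asarray(a, dtype=float) for a in records)
        drug = drug or "drug"

    ok = np.isfinite(conc) & np.isfinite(gr) & (conc > 0)
    conc, gr = conc[ok], gr[ok]
    # per-concentration mean GR is the fitted quantity
    means = pd.Series(gr).groupby(pd.Series(conc)).mean()
    c = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    order = np.argsort(c)
    c, y = c[order], y[order]
    n = c.size
    if n < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {n}")
    c_min, c_max = float(c[0]), float(c[-1])

    flat_level = float(np.mean(y))
    rss_flat = float(np.sum((y - flat_level) ** 2))

    # bounded least squares on (gr_inf, log10 gec50, h), multi-start in gec50
    lo = np.array([-1.0, math.log10(c_min / 100.0), HILL_BOUNDS[0]])
    hi = np.array([1.0, math.log10(c_max * 100.0), HILL_BOUNDS[1]])
    log_mid = (math.log10(c_min) + math.log10(c_max)) / 2.0

    def resid(p):
        return _sigmoid(c, p[0], 10.0 ** p[1], p[2]) - y

    gr_inf0 = float(np.clip(np.min(y), -1.0, 1.0))
    best = None
    for log_g0 in (math.log10(c_min), log_mid, math.log10(c_max)):
        p0 = np.clip(np.array([gr_inf0, log_g0, 1.0]), lo, hi)
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lo, hi))
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"sigmoid fit failed for {drug}")
    p = best.x
    rss_sig = float(np.sum(resid(p) ** 2))
    if rss_sig > rss_flat:  # flat is a boundary case of the sigmoid family
        rss_sig = rss_flat

    # nested F-test: sigmoid (3 params) vs flat (1 param)
    df1, df2 = 2, n - 3
    if rss_flat <= 0:
        f_pvalue = 1.0  # all-identical GR values: flat, zero residual
    elif rss_sig <= 0:
        f_pvalue = 0.0
    elif df2 <= 0:
        f_pvalue = 1.0
    else:
        f_stat = ((rss_flat - rss_sig) / df1) / (rss_sig / df2)
        f_pvalue = float(stats.f.sf(f_stat, df1, df2))

    gr_max = float(np.mean(gr[conc == c_max]))
    gr_aoc = aoc(y, c)
    fit = DoseResponseFit(
        drug=drug, group=tuple(group), gr_max=gr_max, gr_aoc=gr_aoc,
        rss_flat=rss_flat, f_pvalue=f_pvalue, n_concentrations=n,
        c_min=c_min, c_max=c_max,
    )
    if f_pvalue >= alpha:
        fit.fit_kind = "flat"
        fit.gr_inf = flat_level
        fit.rss = rss_flat
        fit.gr50_censoring = CENSOR_GT_CMAX if flat_level >= 0.5 else CENSOR_LT_CMIN
        fit.gr50 = c_max if flat_level >= 0.5 else c_min
        fit.flags.add("gr50_undefined")
        return fit

    fit.fit_kind = "sigmoid"
    fit.gr_inf = float(p[0])
    fit.gec50 = float(10.0 ** p[1])
    fit.h_gr = float(p[2])
    fit.rss = rss_sig
    gr50 = _solve_gr50(fit.gr_inf, fit.gec50, fit.h_gr)
    if gr50 is None or gr50 > c_max:
        fit.gr50 = c_max
        fit.gr50_censoring = CENSOR_GT_CMAX
        fit.flags.add("gr50_undefined")
    elif gr50 < c_min:
        fit.gr50 = c_min
        fit.gr50_censoring = CENSOR_LT_CMIN
        fit.flags.add("gr50_undefined")
    else:
        fit.gr50 = float(gr50)
        fit.gr50_censoring = CENSOR_EXACT
    fit.flags |= dose_range_flags(fit, c)
    return fit


def dose_range_flags(fit: DoseResponseFit, concentrations) -> set:
    """Dose-range adequacy flags for a sigmoid fit.

    ``gec50_out_of_range``: fitted mid-point outside the tested range - the
    fit is extrapolating the transition.  ``no_lower_plateau``: the fitted
    curve at the top dose is still > 0.1 GR units away from its asymptote,
    so the measured range never reached the plateau and gr_inf (and the
    measured gr_max) depend strongly on where the series was truncated.
    """
    if fit.fit_kind != "sigmoid":
        raise ValueError("dose_range_flags applies to sigmoid fits")
    conc = np.asarray(concentrations, dtype=float)
    c_min, c_max = float(conc.min()), float(conc.max())
    flags = set()
    if not (c_min <= fit.gec50 <= c_max):
        flags.add("gec50_out_of_range")
    gr_at_top = float(fit.predict(c_max))
    if abs(gr_at_top - fit.gr_inf) > 0.1:
        flags.add("no_lower_plateau")
    return flags


def fit_groups(
    gr_table: pd.DataFrame,
    group_by: list[str] | tuple[str, ...] = (),
    alpha: float = F_TEST_ALPHA,
) -> list[DoseResponseFit]:
    """Fit every drug (x replicate group) in a GR table."""
    group_by = list(group_by)
    fits = []
    for key, grp in gr_table.groupby(["drug", *group_by], sort=True):
        key = key if isinstance(key, tuple) else (key,)
        fits.append(
            fit_dose_response(grp, drug=key[0], group=tuple(key[1:]), alpha=alpha)
        )
    return fits


def fits_to_frame(fits: list[DoseResponseFit], group_names: list[str] = ()) -> pd.DataFrame:
    """Tidy one-row-per-fit table (flags joined with '|')."""
    rows = []
    for f in fits:
        row = {"drug": f.drug}
        for name, val in zip(group_names, f.group):
            row[name] = val
        if not group_names and f.group:
            row["group"] = "/".join(map(str, f.group))
        row.update({
            "fit_kind": f.fit_kind, "gr_inf": f.gr_inf,
            "gec50": f.gec50 if f.gec50 is not None else np.nan,
            "h_gr": f.h_gr if f.h_gr is not None else np.nan,
            "gr50": f.gr50, "gr50_censoring": f.gr50_censoring,
            "gr_max": f.gr_max, "gr_aoc": f.gr_aoc,
            "rss": f.rss, "f_pvalue": f.f_pvalue,
            "n_concentrations": f.n_concentrations,
            "c_min": f.c_min, "c_max": f.c_max,
            "flags": "|".join(sorted(f.flags)),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def compare_assays(fits_a, fits_b) -> pd.DataFrame:
    """Per-drug metric deltas between two assay readouts (A - B).

    Reports delta gr_max always; delta log10(GR50) only where both GR50s
    are uncensored; a ``gr50_discordant`` flag when GR50 is defined in one
    readout but censored in the other (the classic count-vs-ATP failure
    mode); drugs present in only one set are reported as incomparable.
    """
    def as_map(fits):
        if isinstance(fits, dict):
            return dict(fits)
        return {f.drug: f for f in fits}

    a, b = as_map(fits_a), as_map(fits_b)
    rows = []
    for drug in sorted(set(a) | set(b)):
        if drug not in a or drug not in b:
            rows.append({
                "drug": drug, "comparable": False,
                "delta_gr_max": np.nan, "delta_log10_gr50": np.nan,
                "gr50_discordant": False,
                "missing_from": "A" if drug not in a else "B",
            })
            continue
        fa, fb = a[drug], b[drug]
        a_def = fa.gr50_censoring == CENSOR_EXACT
        b_def = fb.gr50_censoring == CENSOR_EXACT
        rows.append({
            "drug": drug, "comparable": True,
            "delta_gr_max": fa.gr_max - fb.gr_max,
            "delta_log10_gr50": (
                math.log10(fa.gr50) - math.log10(fb.gr50) if a_def and b_def else np.nan
            ),
            "gr50_discordant": a_def != b_def,
            "missing_from": "",
        })
    return pd.DataFrame(
        rows, columns=["drug", "comparable", "delta_gr_max", "delta_log10_gr50",
                       "gr50_discordant", "missing_from"],
    )
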