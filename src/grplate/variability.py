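"""Replicate-error metrology for GR values and GR metrics.

Technical and biological standard errors of GR values are computed per
drug-dose pair with the sample formulas

    SE = sigma / sqrt(n),     sigma = sqrt( sum_i (x_i - mu)^2 / (n - 1) )

where the x_i are GR values across replicates.

* Technical scope: one SE per (drug, dose, biological replicate) over all
  of that replicate's technical GR values (all wells on all plates of the
  day).  With 8 drugs x 8 doses x 3 biological replicates this yields 192
  SE values.
* Biological scope: the technical unit is the plate-level mean GR; for
  each drug-dose pair every combination choosing one technical unit per
  biological replicate is enumerated, and each combination of b values
  yields one SE.  With t = 3 plates and b = 3 days that is 3^3 = 27 SEs
  per pair, 27 x 64 = 1728 in a complete 8x8 dataset.

Distribution summaries (mean, linear-interpolation 90th percentile, and a
Gaussian KDE) describe each scope's error distribution; a mean SE of s in
log10(GR50) corresponds to a 10**s-fold uncertainty in the GR50 itself.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SESummary",
    "technical_se",
    "biological_se",
    "metric_se",
    "summarize_se",
    "fold_change_of_log10_se",
]


def _se_row(values: np.ndarray) -> tuple[int, float, float, float]:
    """(n, mu, sigma, se) with the n-1 sample standard deviation."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    return n, mu, sigma, sigma / math.sqrt(n)


def technical_se(gr_table: pd.DataFrame) -> pd.DataFrame:
    """One SE per (drug, concentration, bio_rep) across all technical GR
    values (wells x plates) of that biological replicate.  Cells with fewer
    than 2 technical values are skipped with a warning."""
    rows = []
    skipped = 0
    for (drug, conc, bio_rep), grp in gr_table.groupby(
        ["drug", "concentration", "bio_rep"], sort=True
    ):
        if len(grp) < 2:
            skipped += 1
            continue
        n, mu, sigma, se = _se_row(grp["gr"].to_numpy())
        rows.append({
            "drug": drug, "concentration": conc, "scope": "technical",
            "bio_rep": bio_rep, "combo_index": -1,
            "n": n, "mu": mu, "sigma": sigma, "se": se,
        })
    if skipped:
        warnings.warn(
            f"{skipped} (drug, dose, bio_rep) cell(s) had < 2 technical "
            "replicates and were skipped", stacklevel=2,
        )
    return pd.DataFrame.from_records(rows)


def biological_se(
    gr_table: pd.DataFrame,
    technical_unit: str = "plate_id",
) -> pd.DataFrame:
    """Biological SEs per drug-dose pair via one-technical-unit-per-day
    combinatorics.

    The technical unit defaults to the plate: wells are first averaged to a
    plate-level mean GR, then for each drug-dose pair all prod(t_i)
    combinations picking one unit from each of the b biological replicates
    are enumerated; each combination of b GR values yields one SE (n = b).
    Raises when b < 2 (the sample SD is undefined).
    """
    unit_means = (
        gr_table.groupby(["drug", "concentration", "bio_rep", technical_unit])["gr"]
        .mean()
        .reset_index()
    )
    rows = []
    for (drug, conc), grp in unit_means.groupby(["drug", "concentration"], sort=True):
        per_rep = [
            sub["gr"].to_numpy()
            for _, sub in grp.groupby("bio_rep", sort=True)
        ]
        b = len(per_rep)
        if b < 2:
            raise ValueError(
                f"biological SE undefined for {drug} @ {conc}: "
                f"only {b} biological replicate(s)"
            )
        for idx, combo in enumerate(itertools.product(*per_rep)):
            n, mu, sigma, se = _se_row(np.array(combo))
            rows.append({
                "drug": drug, "concentration": conc, "scope": "biological",
                "bio_rep": -1, "combo_index": idx,
                "n": n, "mu": mu, "sigma": sigma, "se": se,
            })
    return pd.DataFrame.from_records(rows)


def metric_se(fits_frame: pd.DataFrame) -> pd.DataFrame:
    """SE of GR metrics (gr_max, gr_aoc, log10(gr50)) across replicate fits.

    ``fits_frame`` holds one fitted curve per (drug, replicate group) (see
    ``fitting.fits_to_frame``).  Censored GR50 values are excluded from the
    log10(GR50) SE, with the exclusion count reported; when every GR50 for
    a drug is censored that SE is NaN (unavailable).
    """
    rows = []
    for drug, grp in fits_frame.groupby("drug", sort=True):
        if len(grp) < 2:
            warnings.warn(f"{drug}: fewer than 2 replicate fits; skipped",
                          stacklevel=2)
            continue
        row = {"drug": drug, "n_fits": len(grp)}
        for metric in ("gr_max", "gr_aoc"):
            n, mu, sigma, se = _se_row(grp[metric].to_numpy())
            row[f"se_{metric}"] = se
        exact = grp[grp["gr50_censoring"] == "exact"]
        row["n_gr50_censored"] = len(grp) - len(exact)
        if len(exact) >= 2:
            n, mu, sigma, se = _se_row(np.log10(exact["gr50"].to_numpy()))
            row["se_log10_gr50"] = se
        else:
            row["se_log10_gr50"] = np.nan
        rows.append(row)
    return pd.DataFrame.from_records(rows)


@dataclass
class SESummary:
    """Distribution summary of a set of SE values."""

    group: tuple
    n: int
    mean_se: float
    p90_se: float
    kde_grid: np.ndarray
    kde_density: np.ndarray

    def to_dict(self) -> dict:
        return {
            "group": list(self.group), "n": self.n,
            "mean_se": self.mean_se, "p90_se": self.p90_se,
        }


def _kde(values: np.ndarray, n_grid: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (Scott bandwidth) on [0, 1.1*max], renormalized so the
    density integrates to 1 on its own grid (SE values live near zero, so
    untruncated kernels would leak mass below the support)."""
    hi = float(values.max()) * 1.1
    if hi <= 0:
        hi = 1e-6
    grid = np.linspace(0.0, hi, n_grid)
    if np.ptp(values) == 0 or values.size < 2:
        # degenerate sample: narrow Gaussian centered on the single value
        center = float(values[0])
        width = max(abs(center), hi) * 1e-2
        density = np.exp(-0.5 * ((grid - center) / width) ** 2)
    else:
        density = stats.gaussian_kde(values, bw_method="scott")(grid)
    area = np.trapezoid(density, grid)
    return grid, density / area


def summarize_se(
    se_values,
    group: tuple = (),
    n_grid: int = 256,
) -> SESummary:
    """Mean, 90th percentile (linear-interpolation quantile) and Gaussian KDE
    of a set of SE values."""
    values = (
        se_values["se"].to_numpy()
        if isinstance(se_values, pd.DataFrame)
        else np.asarray(se_values, dtype=float)
    )
    if values.size == 0:
        raise ValueError("cannot summarize an empty group")
    grid, density = _kde(values, n_grid=n_grid)
    return SESummary(
        group=tuple(group),
        n=int(values.size),
        mean_se=float(values.mean()),
        p90_se=float(np.quantile(values, 0.9)),  # linear interpolation
        kde_grid=grid,
        kde_density=density,
    )


def summarize_se_by(se_frame: pd.DataFrame, group_by: list[str]) -> list[SESummary]:
    """Per-group summaries (e.g. by scope, or by scope and drug); empty groups
    are omitted with a warning."""
    out = []
    for key, grp in se_frame.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if grp.empty:  # pragma: no cover - groupby does not emit empty groups
            warnings.warn(f"group {key} empty; omitted", stacklevel=2)
            continue
        out.append(summarize_se(grp, group=key))
    return out


def fold_change_of_log10_se(se_log10: float) -> float:
    """Fold-change uncertainty implied by an SE in log10 units: 10**se.
    An SE of 0.07 in log10(GR50) is a 1.17-fold variation; 0.18 is ~1.5-fold."""
    if se_log10 < 0:
        raise ValueError("se must be >= 0")
    return float(10.0 ** se_log10)
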