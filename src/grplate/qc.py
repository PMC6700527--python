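"""Spatial plate QC: edge-effect detection on untreated growth plates.

Temperature gradients and uneven evaporation depress growth near microtiter
plate borders.  Given a full plate of untreated cell counts, this module
reports the fractional deviation of each row, column and edge-distance band
from the plate mean, and flags rows/columns whose counts differ
significantly from the rest of the plate (Welch two-sample t-test per group
vs its complement, Bonferroni-corrected across all rows + columns).

Detection only: spatial normalization (LOESS smoothing and the like) is out
of scope - the recommended countermeasure is randomized dispensing, which
converts the systematic spatial bias into random error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EdgeEffectReport", "edge_effect_analysis", "edge_distance"]

DEFAULT_ALPHA = 0.01


def edge_distance(n_rows: int, n_cols: int) -> np.ndarray:
    """Matrix of well distances from the nearest plate border (0 = outermost)."""
    r = np.arange(1, n_rows + 1)[:, None]
    c = np.arange(1, n_cols + 1)[None, :]
    return np.minimum.reduce([
        np.broadcast_to(r - 1, (n_rows, n_cols)),
        np.broadcast_to(c - 1, (n_rows, n_cols)),
        np.broadcast_to(n_rows - r, (n_rows, n_cols)),
        np.broadcast_to(n_cols - c, (n_rows, n_cols)),
    ])


@dataclass
class EdgeEffectReport:
    """Deviation-from-plate-mean summary with significance flags.

    Deviations are (group mean - plate mean) / plate mean; the
    count-weighted mean deviation over all wells is 0 by construction.
    Bands collapse edge distances >= ``band_cap`` into one interior band.
    """

    dims: tuple[int, int]
    plate_mean: float
    alpha: float
    row_deviation: np.ndarray
    col_deviation: np.ndarray
    band_deviation: dict[str, float]
    row_pvalue: np.ndarray
    col_pvalue: np.ndarray
    row_flag: np.ndarray
    col_flag: np.ndarray
    n_tests: int

    def flagged_rows(self) -> list[int]:
        return [int(i) + 1 for i in np.flatnonzero(self.row_flag)]

    def flagged_cols(self) -> list[int]:
        return [int(i) + 1 for i in np.flatnonzero(self.col_flag)]

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "plate_mean": self.plate_mean,
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "row_deviation": self.row_deviation.tolist(),
            "col_deviation": self.col_deviation.tolist(),
            "band_deviation": self.band_deviation,
            "row_pvalue_adjusted": self.row_pvalue.tolist(),
            "col_pvalue_adjusted": self.col_pvalue.tolist(),
            "flagged_rows": self.flagged_rows(),
            "flagged_cols": self.flagged_cols(),
        }


def _welch_p(group: np.ndarray, rest: np.ndarray) -> float:
    if np.ptp(group) == 0 and np.ptp(rest) == 0:
        return 1.0 if group.mean() == rest.mean() else 0.0
    return float(stats.ttest_ind(group, rest, equal_var=False).pvalue)


def edge_effect_analysis(
    plate,
    alpha: float = DEFAULT_ALPHA,
    band_cap: int = 2,
) -> EdgeEffectReport:
    """Edge-effect report for one full rectangular plate of counts.

    ``plate`` is a (rows, cols) array (or DataFrame) of untreated well
    counts; missing (NaN) wells are an error listing the wells.  Per row,
    column and edge band the fractional deviation from the plate mean is
    reported; per row/column a Welch test against all other wells is
    Bonferroni-adjusted across the rows + cols tests and flagged when the
    adjusted p-value is below ``alpha``.
    """
    mat = np.asarray(
        plate.to_numpy() if isinstance(plate, pd.DataFrame) else plate, dtype=float
    )
    if mat.ndim != 2:
        raise ValueError(f"plate must be 2-D, got shape {mat.shape}")
    n_rows, n_cols = mat.shape
    if np.isnan(mat).any():
        missing = [
            f"({r + 1},{c + 1})" for r, c in zip(*np.nonzero(np.isnan(mat)))
        ]
        raise ValueError(f"plate has missing wells: {', '.join(missing[:20])}")
    plate_mean = float(mat.mean())
    if plate_mean == 0:
        raise ValueError("plate mean is zero; deviations undefined")

    row_dev = (mat.mean(axis=1) - plate_mean) / plate_mean
    col_dev = (mat.mean(axis=0) - plate_mean) / plate_mean

    dist = edge_distance(n_rows, n_cols)
    band_dev = {}
    capped = np.minimum(dist, band_cap)
    for d in range(band_cap + 1):
        label = f"{d}" if d < band_cap else f"{d}+"
        sel = mat[capped == d]
        if sel.size:
            band_dev[label] = float((sel.mean() - plate_mean) / plate_mean)

    n_tests = n_rows + n_cols
    row_p = np.empty(n_rows)
    for i in range(n_rows):
        rest = np.delete(mat, i, axis=0).ravel()
        row_p[i] = _welch_p(mat[i], rest)
    col_p = np.empty(n_cols)
    for j in range(n_cols):
        rest = np.delete(mat, j, axis=1).ravel()
        col_p[j] = _welch_p(mat[:, j], rest)
    # Bonferroni across all row + column tests
    row_p = np.minimum(row_p * n_tests, 1.0)
    col_p = np.minimum(col_p * n_tests, 1.0)

    return EdgeEffectReport(
        dims=(n_rows, n_cols),
        plate_mean=plate_mean,
        alpha=alpha,
        row_deviation=row_dev,
        col_deviation=col_dev,
        band_deviation=band_dev,
        row_pvalue=row_p,
        col_pvalue=col_p,
        row_flag=row_p < alpha,
        col_flag=col_p < alpha,
        n_tests=n_tests,
    )
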