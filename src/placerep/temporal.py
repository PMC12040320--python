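"""Temporal non-stationarity of field and population firing.

Three levels: a per-field Gamma-GLM likelihood-ratio test asking whether
a natural time spline (3 df) improves on a base model containing current
direction (mirroring the direction test with roles swapped, tested at
alpha = 0.0083 after spline-knot x orientation correction); PCHIP
resampling of per-field rate time series so pairs of repeating fields
can be Pearson-correlated at equal length; and population-vector
correlations between equal-duration session windows, whose decay with
window lag measures representational drift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .directionality import GLMResult, _binary_direction, _lrt, _spline_basis
from .errors import DataError

TIME_GLM_ALPHA = 0.05 / 6  # 3 spline knots x up to 2 orientations per field


def glm_time_lrt(table: pd.DataFrame, spline_df: int = 3) -> GLMResult:
    """LRT for a time spline over a current-direction base model."""
    ori = table.attrs["orientation"]
    y = table["norm_rate"].to_numpy(float) + 1.0
    t = table["t"].to_numpy(float)
    if np.ptp(t) == 0:
        raise DataError("all passes share one timestamp; time effect untestable")
    cur = _binary_direction(table["direction"], ori)
    base = np.column_stack([np.ones_like(y), cur])
    S = _spline_basis(t, spline_df)  # includes intercept
    alt = np.column_stack([S, cur])
    if len(y) <= alt.shape[1] + 1:
        raise DataError("too few passes to estimate the time spline")
    return _lrt(y, base, alt, df=spline_df)


def pchip_resample(times: np.ndarray, values: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a rate time series with monotone (PCHIP) interpolation.

    The interpolant reproduces the original knots exactly and does not
    overshoot the local data range on monotone segments. Evaluation
    points are uniform on [t_min, t_max].
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise DataError("resampling needs >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing (no duplicates)")
    f = PchipInterpolator(t, v)
    return f(np.linspace(t[0], t[-1], n_points))


def pairwise_time_correlation(
    series: list[tuple[np.ndarray, np.ndarray]],
    n_points: int | None = None,
) -> list[float]:
    """Pearson r between every pair of rate time series of one cell.

    Each series is (times, values); both members of a pair are PCHIP-
    resampled to a common length (the longer of the two by default)
    before correlating. Constant series yield NaN with a warning flag
    left to the caller (they are skipped here).
    """
    out = []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            ta, va = series[i]
            tb, vb = series[j]
            npts = n_points or max(len(ta), len(tb))
            ra = pchip_resample(ta, va, npts)
            rb = pchip_resample(tb, vb, npts)
            if np.std(ra) == 0 or np.std(rb) == 0:
                out.append(np.nan)
                continue
            out.append(float(stats.pearsonr(ra, rb)[0]))
    return out


def pv_window_correlation(
    pass_tables: dict[str, pd.DataFrame],
    session_duration_s: float,
    n_windows: int = 6,
) -> dict:
    """Population-vector correlations between equal session windows.

    The population vector of a window holds, per unit, the mean
    normalized rate over that unit's alley passes falling in the window;
    a unit with no pass in a window contributes 0. Windows whose vector
    is constant are dropped with their rows left NaN. Returns the
    (n_windows x n_windows) Pearson correlation matrix and the least-
    squares slope of correlation against absolute window lag.
    """
    units = sorted(pass_tables)
    if len(units) < 2:
        raise DataError("need >= 2 active units for population vectors")
    edges = np.linspace(0, session_duration_s, n_windows + 1)
    pv = np.zeros((n_windows, len(units)))
    for u, unit in enumerate(units):
        tb = pass_tables[unit]
        t = tb["t"].to_numpy(float)
        r = tb["norm_rate"].to_numpy(float)
        for w in range(n_windows):
            sel = (t >= edges[w]) & (t < edges[w + 1])
            pv[w, u] = r[sel].mean() if sel.any() else 0.0

    keep = [w for w in range(n_windows) if np.std(pv[w]) > 0]
    corr = np.full((n_windows, n_windows), np.nan)
    for a in keep:
        for b in keep:
            corr[a, b] = (
                1.0 if a == b else float(stats.pearsonr(pv[a], pv[b])[0])
            )
    lags, vals = [], []
    for a in keep:
        for b in keep:
            if a < b:
                lags.append(b - a)
                vals.append(corr[a, b])
    if len(set(lags)) < 2:
        slope = np.nan
    else:
        slope = float(np.polyfit(lags, vals, 1)[0])
    return {"corr": corr, "slope": slope, "windows_kept": keep, "pv": pv}
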