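"""Per-field directional rate statistics.

Passes through an orientation portion of a field carry a normalized rate
and a travel direction. Three complementary tests are used: a two-sided
Mann-Whitney comparison of normalized pass rates between directions, a
signed directionality index (positive direction = north/east), and a
Gamma GLM likelihood-ratio test in which the base model explains the
rate (+1 offset, inverse link) with a natural time spline (3 df) and the
alternative adds binary current direction — so directional effects must
improve the fit over and above slow temporal drift. Prospective and
retrospective coding are tested the same way with previous/next
direction regressors on top of time + current direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

from .errors import DataError
from .maze import DIRECTION_PAIRS, POSITIVE_DIRECTION


@dataclass
class GLMResult:
    lrt_stat: float
    p: float
    df: int
    deviance_base: float
    deviance_alt: float
    rmse_base: float
    rmse_alt: float
    converged: bool = True


@dataclass
class DirectionalityResult:
    portion_id: str
    orientation: str
    n_passes: int
    u_stat: float | None = None
    p_mw: float | None = None
    abs_delta: float | None = None
    di: float | None = None
    glm: GLMResult | None = None
    flags: list[str] = dc_field(default_factory=list)


def _direction_groups(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str, str]:
    ori = table.attrs.get("orientation")
    if ori not in DIRECTION_PAIRS:
        raise DataError("pass table lacks a vertical/horizontal orientation attribute")
    d_pos, d_neg = DIRECTION_PAIRS[ori]
    pos = table.loc[table["direction"] == d_pos, "norm_rate"].to_numpy(float)
    neg = table.loc[table["direction"] == d_neg, "norm_rate"].to_numpy(float)
    if len(pos) < 2 or len(neg) < 2:
        raise DataError("need >= 2 passes in each direction")
    return pos, neg, d_pos, d_neg


def mw_direction_test(table: pd.DataFrame) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney on normalized pass rates by direction.

    Returns (U, p, |mean difference|). Ties are handled by midranks.
    """
    pos, neg, _, _ = _direction_groups(table)
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), float(abs(pos.mean() - neg.mean()))


def directionality_index(table: pd.DataFrame) -> float:
    """Signed DI: (mean rate in positive direction - mean in negative) /
    overall mean. North and east are the positive directions."""
    pos, neg, _, _ = _direction_groups(table)
    overall = np.concatenate([pos, neg]).mean()
    if overall == 0:
        raise DataError("zero overall mean rate; DI undefined")
    return float((pos.mean() - neg.mean()) / overall)


# ---------------------------------------------------------------------------
# Gamma GLM with natural time spline


def _spline_basis(t: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with an intercept column; boundary
    knots at the first/last pass times."""
    t = np.asarray(t, dtype=float)
    if np.ptp(t) == 0:
        raise DataError("all passes share one timestamp; time spline degenerate")
    return np.asarray(dmatrix("cr(t, df=DF)", {"t": t, "DF": df}, return_type="matrix"))


def _fit_gamma(y: np.ndarray, X: np.ndarray):
    import warnings

    fam = sm.families.Gamma(link=sm.families.links.InversePower())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # inverse link domain notice
        model = sm.GLM(y, X, family=fam)
        with np.errstate(all="ignore"):
            try:
                res = model.fit(maxiter=100, tol=1e-8)
            except Exception as e:
                raise DataError(f"Gamma GLM failed: {e}") from None
    if not np.isfinite(res.deviance):
        raise DataError("Gamma GLM failed to converge")
    return res


def _lrt(y: np.ndarray, X_base: np.ndarray, X_alt: np.ndarray, df: int) -> GLMResult:
    """Analysis-of-deviance likelihood-ratio test for nested Gamma GLMs.

    The statistic is (dev_base - dev_alt) / phi with the dispersion phi
    estimated from the alternative model's deviance; referenced to a
    chi-square with ``df`` degrees of freedom.
    """
    res_b = _fit_gamma(y, X_base)
    res_a = _fit_gamma(y, X_alt)
    df_resid = max(len(y) - np.linalg.matrix_rank(X_alt), 1)
    phi = res_a.deviance / df_resid
    stat = max((res_b.deviance - res_a.deviance) / max(phi, 1e-12), 0.0)
    rmse_b = float(np.sqrt(np.mean((y - res_b.mu) ** 2)))
    rmse_a = float(np.sqrt(np.mean((y - res_a.mu) ** 2)))
    return GLMResult(
        lrt_stat=float(stat),
        p=float(stats.chi2.sf(stat, df)),
        df=df,
        deviance_base=float(res_b.deviance),
        deviance_alt=float(res_a.deviance),
        rmse_base=rmse_b,
        rmse_alt=rmse_a,
    )


def _binary_direction(values: pd.Series, orientation: str) -> np.ndarray:
    """Positive direction (N or E) coded 1, the opposite 0."""
    pos = POSITIVE_DIRECTION[orientation]
    return (values.to_numpy() == pos).astype(float)


def glm_direction_lrt(table: pd.DataFrame, spline_df: int = 3) -> GLMResult:
    """LRT for current direction over a time-spline base model."""
    ori = table.attrs["orientation"]
    y = table["norm_rate"].to_numpy(float) + 1.0  # offset keeps Gamma support
    S = _spline_basis(table["t"].to_numpy(), spline_df)
    if len(y) <= S.shape[1] + 1:
        raise DataError("too few passes to estimate spline + direction terms")
    d = _binary_direction(table["direction"], ori)
    return _lrt(y, S, np.column_stack([S, d]), df=1)


def glm_prospective_retrospective(
    table: pd.DataFrame, spline_df: int = 3
) -> dict[str, GLMResult]:
    """LRTs for previous and next direction, each over a base model with
    the time spline and current direction."""
    ori = table.attrs["orientation"]
    sub = table.dropna(subset=["prev_direction", "next_direction"])
    if len(sub) < spline_df + 4:
        raise DataError("too few passes with previous/next labels")
    y = sub["norm_rate"].to_numpy(float) + 1.0
    S = _spline_basis(sub["t"].to_numpy(), spline_df)
    cur = _binary_direction(sub["direction"], ori)
    base = np.column_stack([S, cur])
    out = {}
    for name, col in (("previous", "prev_direction"), ("next", "next_direction")):
        reg = _binary_direction(sub[col], ori)
        out[name] = _lrt(y, base, np.column_stack([base, reg]), df=1)
    return out


def analyze_field_portion(table: pd.DataFrame, spline_df: int = 3) -> DirectionalityResult:
    """Run Mann-Whitney, DI and the direction GLM on one portion table."""
    res = DirectionalityResult(
        portion_id=table.attrs.get("portion_id", ""),
        orientation=table.attrs["orientation"],
        n_passes=len(table),
    )
    try:
        res.u_stat, res.p_mw, res.abs_delta = mw_direction_test(table)
        res.di = directionality_index(table)
    except DataError as e:
        res.flags.append(f"mw_skipped: {e}")
    try:
        res.glm = glm_direction_lrt(table, spline_df)
    except DataError as e:
        res.flags.append(f"glm_skipped: {e}")
    return res


def shuffle_direction_control(
    tables: list[pd.DataFrame],
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    spline_df: int = 3,
    seed: int = 0,
) -> dict:
    """Fictive-direction control: permute direction labels within each
    field portion and rerun the direction LRT.

    Returns the mean fraction of portions significant per shuffle and
    the unshuffled fraction for comparison.
    """
    rng = np.random.default_rng(seed)
    observed = []
    for tb in tables:
        try:
            observed.append(glm_direction_lrt(tb, spline_df).p < alpha)
        except DataError:
            pass
    fracs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        sig = []
        for tb in tables:
            shuf = tb.copy()
            shuf["direction"] = rng.permutation(shuf["direction"].to_numpy())
            shuf.attrs = dict(tb.attrs)
            try:
                sig.append(glm_direction_lrt(shuf, spline_df).p < alpha)
            except DataError:
                pass
        fracs[s] = np.mean(sig) if sig else np.nan
    return {
        "observed_fraction": float(np.mean(observed)) if observed else np.nan,
        "shuffled_fractions": fracs,
        "mean_shuffled_fraction": float(np.nanmean(fracs)) if n_shuffles else np.nan,
    }


def chisq_goodness_of_fit(observed, expected="equal") -> tuple[float, int, float]:
    """Chi-square goodness of fit; expected='equal' spreads the total
    evenly. Returns (statistic, df, p)."""
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise DataError("observed counts must be non-negative")
    if isinstance(expected, str) and expected == "equal":
        exp = np.full(len(obs), obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
    if (exp <= 0).any():
        raise DataError("expected counts must be positive")
    stat, p = stats.chisquare(obs, exp)
    return float(stat), len(obs) - 1, float(p)


def binomial_fraction_test(k: int, n: int, alpha: float = 0.05) -> float:
    """One-sided binomial p for observing >= k significant fields out of
    n at false-positive rate alpha."""
    return float(stats.binomtest(k, n, alpha, alternative="greater").pvalue)
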