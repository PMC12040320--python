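"""Within-cell comparisons of same-orientation repeating field pairs.

Each pair of commonly oriented fields of a cell is tagged with the
corridor relation of its host alleys (same straight corridor or not),
the centroid distance and alley-graph path length between them, both
fields' directionality indices and sampling biases, and the correlation
between their mean responses to shared trajectory types
(previous-current-next direction sequences). Group-level statistics are
ordinary least squares between the paired DIs, a Fisher r-to-z contrast
between corridor groups, a label shuffle preserving the group sizes, and
Hartigan's dip test on the trajectory-response correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._dip import dip_pvalue_montecarlo, dip_statistic
from .errors import DataError
from .maze import MazeGeometry, same_corridor


@dataclass
class FieldRecord:
    """Directionality summary of one oriented field portion."""

    unit_id: str
    portion_id: str
    orientation: str
    alley_id: str  # dominant host alley
    di: float
    n_pos: int = 0
    n_neg: int = 0
    centroid_bins: tuple[float, float] | None = None
    trajectory_means: dict[str, float] = dc_field(default_factory=dict)

    @property
    def sampling_bias(self) -> float:
        return sampling_bias_counts(self.n_pos, self.n_neg)


@dataclass
class FieldPair:
    unit_id: str
    field_a: FieldRecord
    field_b: FieldRecord
    orientation: str
    same_corridor: bool
    centroid_distance_bins: float | None = None
    path_length_alleys: int | None = None
    trajectory_r: float | None = None

    @property
    def di_a(self) -> float:
        return self.field_a.di

    @property
    def di_b(self) -> float:
        return self.field_b.di


def sampling_bias_counts(n_a: int, n_b: int) -> float:
    """Passes in the more-sampled direction over total passes."""
    total = n_a + n_b
    if total == 0:
        raise DataError("sampling bias needs >= 1 pass")
    return max(n_a, n_b) / total


def build_field_pairs(
    records: list[FieldRecord],
    geometry: MazeGeometry,
    min_shared_trajectories: int = 3,
) -> list[FieldPair]:
    """All unordered same-orientation pairs of fields within each cell."""
    by_unit: dict[str, list[FieldRecord]] = {}
    for r in records:
        by_unit.setdefault(r.unit_id, []).append(r)
    pairs = []
    for unit, recs in by_unit.items():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if a.orientation != b.orientation:
                    continue
                dist = None
                if a.centroid_bins is not None and b.centroid_bins is not None:
                    dist = float(np.hypot(
                        a.centroid_bins[0] - b.centroid_bins[0],
                        a.centroid_bins[1] - b.centroid_bins[1],
                    ))
                pairs.append(
                    FieldPair(
                        unit_id=unit,
                        field_a=a,
                        field_b=b,
                        orientation=a.orientation,
                        same_corridor=same_corridor(geometry, a.alley_id, b.alley_id),
                        centroid_distance_bins=dist,
                        path_length_alleys=geometry.alley_graph_distance(a.alley_id, b.alley_id),
                        trajectory_r=trajectory_response_correlation(
                            a, b, min_shared=min_shared_trajectories
                        ),
                    )
                )
    return pairs


def pair_direction_correlation(pairs: list[FieldPair]) -> dict:
    """OLS of DI_b on DI_a across pairs, with quadrant sharing counts.

    Returns r^2, signed r, slope, p (slope F test), n, and the counts of
    pairs sharing (quadrants I/III) vs not sharing (II/IV) directional
    tuning; zero-DI pairs are excluded from the sharing counts.
    """
    if len(pairs) < 3:
        raise DataError("need >= 3 pairs for the OLS correlation")
    di_a = np.array([p.di_a for p in pairs])
    di_b = np.array([p.di_b for p in pairs])
    if np.std(di_a) == 0 or np.std(di_b) == 0:
        raise DataError("degenerate DI variance; correlation undefined")
    X = sm.add_constant(di_a)
    res = sm.OLS(di_b, X).fit()
    slope = float(res.params[1])
    r2 = float(res.rsquared)
    signs = np.sign(di_a) * np.sign(di_b)
    return {
        "r2": r2,
        "r": float(np.sign(slope) * np.sqrt(r2)),
        "slope": slope,
        "p": float(res.f_pvalue),
        "n": len(pairs),
        "n_sharing": int((signs > 0).sum()),
        "n_not_sharing": int((signs < 0).sum()),
    }


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int, one_sided: bool = True):
    """Independent-sample Fisher r-to-z comparison of two correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the
    one-sided p tests r1 > r2.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise DataError("|r| must be < 1 for the Fisher transform")
    if n1 <= 3 or n2 <= 3:
        raise DataError("need n > 3 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = float(stats.norm.sf(z)) if one_sided else float(2 * stats.norm.sf(abs(z)))
    return float(z), p


def corridor_shuffle_test(
    pairs: list[FieldPair], n_shuffles: int = 1000, seed: int = 0
) -> dict:
    """Shuffle corridor labels across pairs, preserving group sizes, and
    compare the observed r^2(same) - r^2(different) to the null 95th
    percentile."""
    labels = np.array([p.same_corridor for p in pairs])
    n_same = int(labels.sum())
    if n_same == 0 or n_same == len(pairs):
        raise DataError("both corridor groups must be non-empty")

    def delta(lab):
        same = [p for p, l in zip(pairs, lab) if l]
        diff = [p for p, l in zip(pairs, lab) if not l]
        return (
            pair_direction_correlation(same)["r2"]
            - pair_direction_correlation(diff)["r2"]
        )

    observed = delta(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = delta(rng.permutation(labels))
    pct = float(np.percentile(null, 95)) if n_shuffles else np.nan
    return {
        "observed_delta_r2": float(observed),
        "null_95th": pct,
        "null": null,
        "significant": bool(n_shuffles) and observed > pct,
    }


def trajectory_response_correlation(
    a: FieldRecord, b: FieldRecord, min_shared: int = 3
) -> float | None:
    """Pearson r between the two fields' mean normalized rates per
    trajectory type (previous-current-next direction sequence), over the
    types sampled in both fields; None with fewer than ``min_shared``
    shared types."""
    shared = sorted(set(a.trajectory_means) & set(b.trajectory_means))
    if len(shared) < min_shared:
        return None
    va = np.array([a.trajectory_means[k] for k in shared])
    vb = np.array([b.trajectory_means[k] for k in shared])
    if np.std(va) == 0 or np.std(vb) == 0:
        return None
    return float(stats.pearsonr(va, vb)[0])


def trajectory_means_from_table(table: pd.DataFrame) -> dict[str, float]:
    """Mean normalized rate per (prev, current, next) trajectory type."""
    sub = table.dropna(subset=["prev_direction", "next_direction"])
    out = {}
    for (pd_, cd, nd), grp in sub.groupby(
        ["prev_direction", "direction", "next_direction"]
    ):
        out[f"{pd_}-{cd}-{nd}"] = float(grp["norm_rate"].mean())
    return out


def dip_test(values, n_boot: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Hartigan's dip test of unimodality.

    Returns (dip statistic, Monte-Carlo p-value under the uniform null
    at matched sample size). Requires n >= 4.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise DataError("dip test needs >= 4 observations")
    d = dip_statistic(v)
    return d, dip_pvalue_montecarlo(d, len(v), n_boot=n_boot, seed=seed)


def pairs_to_frame(pairs: list[FieldPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [p.unit_id for p in pairs],
            "field_a": [p.field_a.portion_id for p in pairs],
            "field_b": [p.field_b.portion_id for p in pairs],
            "orientation": [p.orientation for p in pairs],
            "relation": ["same" if p.same_corridor else "different" for p in pairs],
            "di_a": [p.di_a for p in pairs],
            "di_b": [p.di_b for p in pairs],
            "bias_a": [p.field_a.sampling_bias for p in pairs],
            "bias_b": [p.field_b.sampling_bias for p in pairs],
            "dist_bins": [p.centroid_distance_bins for p in pairs],
            "path_len": [p.path_length_alleys for p in pairs],
            "traj_r": [p.trajectory_r for p in pairs],
        }
    )
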