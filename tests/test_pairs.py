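"""Pairwise field comparisons, Fisher z, corridor shuffle, dip test."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linprog

from placerep._dip import dip_statistic
from placerep.errors import DataError
from placerep.maze import build_standard_maze
from placerep.pairs import (
    FieldPair,
    FieldRecord,
    build_field_pairs,
    corridor_shuffle_test,
    dip_test,
    fisher_z_compare,
    pair_direction_correlation,
    sampling_bias_counts,
    trajectory_response_correlation,
)


@pytest.fixture(scope="module")
def geom():
    return build_standard_maze()


def rec(unit, pid, alley, di, orientation="vertical", traj=None, n_pos=5, n_neg=5):
    return FieldRecord(
        unit_id=unit,
        portion_id=pid,
        orientation=orientation,
        alley_id=alley,
        di=di,
        n_pos=n_pos,
        n_neg=n_neg,
        centroid_bins=(0.0, 0.0),
        trajectory_means=traj or {},
    )


def mk_pair(di_a, di_b, same=True):
    return FieldPair(
        unit_id="u",
        field_a=rec("u", "a", "V00", di_a),
        field_b=rec("u", "b", "V01", di_b),
        orientation="vertical",
        same_corridor=same,
    )


# ---------------------------------------------------------------------------
# pair construction


def test_three_aligned_fields_give_three_pairs(geom):
    records = [rec("u", f"f{i}", a, 0.1 * i) for i, a in enumerate(["V00", "V11", "V22"])]
    pairs = build_field_pairs(records, geom)
    assert len(pairs) == 3


def test_mixed_orientation_gives_no_pairs(geom):
    records = [rec("u", "f0", "V00", 0.1), rec("u", "f1", "H00", 0.2, orientation="horizontal")]
    assert build_field_pairs(records, geom) == []


def test_corridor_relation_and_path_length(geom):
    records = [rec("u", "f0", "H00", 0.1, "horizontal"), rec("u", "f1", "H10", 0.2, "horizontal")]
    (pair,) = build_field_pairs(records, geom)
    assert pair.same_corridor  # one row corridor
    assert pair.path_length_alleys == geom.alley_graph_distance("H00", "H10")
    records2 = [rec("u", "f0", "V00", 0.1), rec("u", "f1", "V10", 0.2)]
    (pair2,) = build_field_pairs(records2, geom)
    assert not pair2.same_corridor


# ---------------------------------------------------------------------------
# OLS correlation


def test_identical_dis_r2_one():
    pairs = [mk_pair(d, d) for d in np.linspace(-1, 1, 10)]
    res = pair_direction_correlation(pairs)
    assert res["r2"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(1.0)
    assert res["n_sharing"] == 10 and res["n_not_sharing"] == 0


def test_negated_dis_r2_one_negative_slope():
    pairs = [mk_pair(d, -d) for d in np.linspace(-1, 1, 11) if d != 0]
    res = pair_direction_correlation(pairs)
    assert res["r2"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(-1.0)
    assert res["r"] < 0
    assert res["n_sharing"] == 0 and res["n_not_sharing"] == 10


def test_independent_dis_low_r2(rng):
    hits = 0
    for r in range(30):
        pairs = [mk_pair(a, b) for a, b in rng.standard_normal((500, 2))]
        res = pair_direction_correlation(pairs)
        hits += res["r2"] < 0.02 and res["p"] > 0.05
    assert hits >= 27  # >= 90% of runs


def test_r2_equals_squared_pearson():
    rng = np.random.default_rng(2)
    di = rng.standard_normal((50, 2))
    di[:, 1] += 0.5 * di[:, 0]
    pairs = [mk_pair(a, b) for a, b in di]
    res = pair_direction_correlation(pairs)
    r = stats.pearsonr(di[:, 0], di[:, 1])[0]
    assert res["r2"] == pytest.approx(r**2)
    assert res["r"] == pytest.approx(r)


# ---------------------------------------------------------------------------
# Fisher z


def test_fisher_z_equal_correlations():
    z, p = fisher_z_compare(0.5, 50, 0.5, 80)
    assert z == 0.0 and p == 0.5


def test_fisher_z_published_group_comparison():
    """r = sqrt(0.237) vs sqrt(0.017) at n = 54 and 155 gives z ~ 2.49."""
    z, p = fisher_z_compare(np.sqrt(0.237), 54, np.sqrt(0.017), 155)
    assert z == pytest.approx(2.49, abs=0.05)
    assert p == pytest.approx(0.0063, abs=0.002)


def test_fisher_z_antisymmetric():
    z1, _ = fisher_z_compare(0.6, 40, 0.2, 60)
    z2, _ = fisher_z_compare(0.2, 60, 0.6, 40)
    assert z1 == pytest.approx(-z2)


def test_fisher_z_domain_errors():
    with pytest.raises(DataError):
        fisher_z_compare(1.0, 10, 0.5, 10)
    with pytest.raises(DataError):
        fisher_z_compare(0.5, 3, 0.5, 10)


def test_fisher_z_matches_permutation(rng):
    """Fisher z p-value agrees with a label permutation within MC error."""
    n1, n2 = 60, 60
    x = rng.standard_normal(n1 + n2)
    y = np.where(np.arange(n1 + n2) < n1, 0.6, 0.0) * x + rng.standard_normal(n1 + n2)
    r1 = stats.pearsonr(x[:n1], y[:n1])[0]
    r2 = stats.pearsonr(x[n1:], y[n1:])[0]
    z, p = fisher_z_compare(r1, n1, r2, n2)
    null = []
    for _ in range(400):
        perm = rng.permutation(n1 + n2)
        r1p = stats.pearsonr(x[perm[:n1]], y[perm[:n1]])[0]
        r2p = stats.pearsonr(x[perm[n1:]], y[perm[n1:]])[0]
        null.append(np.arctanh(r1p) - np.arctanh(r2p))
    p_perm = np.mean(np.array(null) >= np.arctanh(r1) - np.arctanh(r2))
    assert abs(p - p_perm) < 0.07


# ---------------------------------------------------------------------------
# corridor shuffle


def test_corridor_shuffle_detects_planted_effect(rng):
    same = []
    for _ in range(50):
        a = rng.standard_normal()
        same.append(mk_pair(a, a + 0.3 * rng.standard_normal(), same=True))
    diff = [mk_pair(a, b, same=False) for a, b in rng.standard_normal((150, 2))]
    res = corridor_shuffle_test(same + diff, n_shuffles=200, seed=0)
    assert res["significant"]
    assert res["observed_delta_r2"] > res["null_95th"]


def test_corridor_shuffle_calibrated_on_common_population(rng):
    hits = 0
    reps = 40
    for r in range(reps):
        pairs = [
            mk_pair(a, b, same=(i < 54))
            for i, (a, b) in enumerate(rng.standard_normal((209, 2)))
        ]
        res = corridor_shuffle_test(pairs, n_shuffles=100, seed=r)
        hits += res["significant"]
    assert hits / reps <= 0.15  # nominal 5% within MC slack


def test_corridor_shuffle_zero_shuffles_reports_observed_only():
    rng = np.random.default_rng(1)
    pairs = [mk_pair(a, b, same=bool(i % 2)) for i, (a, b) in enumerate(rng.standard_normal((20, 2)))]
    res = corridor_shuffle_test(pairs, n_shuffles=0, seed=0)
    assert not res["significant"] and np.isnan(res["null_95th"])


# ---------------------------------------------------------------------------
# sampling bias and trajectory correlation


def test_sampling_bias_values():
    assert sampling_bias_counts(5, 5) == 0.5
    assert sampling_bias_counts(7, 3) == 0.7
    assert sampling_bias_counts(10, 0) == 1.0
    with pytest.raises(DataError):
        sampling_bias_counts(0, 0)


def test_trajectory_correlation_trivial_cases():
    base = {"N-N-N": 1.0, "S-N-N": 2.0, "N-N-S": 3.0, "S-S-S": 4.0}
    a = rec("u", "a", "V00", 0.1, traj=base)
    b_same = rec("u", "b", "V01", 0.1, traj=dict(base))
    assert trajectory_response_correlation(a, b_same) == pytest.approx(1.0)
    b_neg = rec("u", "b", "V01", 0.1, traj={k: -v for k, v in base.items()})
    assert trajectory_response_correlation(a, b_neg) == pytest.approx(-1.0)
    b_few = rec("u", "b", "V01", 0.1, traj={"N-N-N": 1.0, "S-N-N": 2.0})
    assert trajectory_response_correlation(a, b_few) is None


def test_trajectory_correlation_null_centered(rng):
    rs = []
    for _ in range(500):
        ta = {f"k{i}": rng.standard_normal() for i in range(6)}
        tb = {f"k{i}": rng.standard_normal() for i in range(6)}
        rs.append(
            trajectory_response_correlation(
                rec("u", "a", "V00", 0, traj=ta), rec("u", "b", "V01", 0, traj=tb)
            )
        )
    assert abs(np.mean(rs)) < 0.05


# ---------------------------------------------------------------------------
# dip statistic


def dip_lp_oracle(values):
    """Dip by brute force over mode placements: the smallest sup-band
    radius admitting a nondecreasing convex-then-concave CDF, allowing
    an atom at the mode (including exactly at a data value), via LP."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    uniq, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    nu = len(uniq)
    span = uniq[-1] - uniq[0] if uniq[-1] > uniq[0] else 1.0
    knots = np.concatenate([[uniq[0] - 10 * span], uniq, [uniq[-1] + 10 * span]])
    m = len(knots)
    # variables: u_0..u_{m-1}, a (right limit at an atom knot, else unused), t
    nv = m + 2
    ia, it = m, m + 1
    best = np.inf

    def solve(mode_seg, atom_knot):
        """One LP: either a peak-slope segment, or an atom at a knot."""
        A_ub, b_ub = [], []

        def left_val(i):  # variable index holding the value right of knot i
            return ia if (atom_knot is not None and i == atom_knot) else i

        def slope_row(i):  # slope of segment (i, i+1)
            row = np.zeros(nv)
            h = knots[i + 1] - knots[i]
            row[i + 1] += 1 / h
            row[left_val(i)] -= 1 / h
            return row

        # band constraints at data knots: right limit >= c_j/n - t on
        # the value right of the knot; left limit <= (c_j - k_j)/n + t
        for j in range(nu):
            i = j + 1
            row = np.zeros(nv)
            row[left_val(i)] = -1
            row[it] = -1
            A_ub.append(row)
            b_ub.append(-(cum[j] / n))
            row = np.zeros(nv)
            row[i] = 1
            row[it] = -1
            A_ub.append(row)
            b_ub.append((cum[j] - counts[j]) / n)
        # monotone segments; atom jump u_k <= a
        for i in range(m - 1):
            A_ub.append(-slope_row(i))
            b_ub.append(0.0)
        if atom_knot is not None:
            row = np.zeros(nv)
            row[atom_knot] = 1
            row[ia] = -1
            A_ub.append(row)
            b_ub.append(0.0)
        # slope pattern: nondecreasing before the mode, nonincreasing after
        for i in range(m - 2):
            if atom_knot is not None:
                before = i + 1 <= atom_knot - 1  # both segments left of atom
                after = i >= atom_knot  # both right of atom
            else:
                before = i + 1 <= mode_seg
                after = i >= mode_seg
            if before:
                A_ub.append(slope_row(i) - slope_row(i + 1))
                b_ub.append(0.0)
            if after:
                A_ub.append(slope_row(i + 1) - slope_row(i))
                b_ub.append(0.0)
        A_eq = np.zeros((2, nv))
        A_eq[0, 0] = 1.0  # u at far-left knot = 0
        A_eq[1, m - 1] = 1.0  # u at far-right knot = 1
        b_eq = [0.0, 1.0]
        c = np.zeros(nv)
        c[it] = 1.0
        bounds = [(0, 1)] * (nv - 1) + [(0, 1)]
        res = linprog(
            c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), A_eq=A_eq, b_eq=b_eq,
            bounds=bounds, method="highs",
        )
        return res.fun if res.success else np.inf

    for mode_seg in range(m - 1):
        best = min(best, solve(mode_seg, None))
    for k in range(1, m - 1):  # atom at a data knot
        best = min(best, solve(None, k))
    return best


def test_dip_two_point_sample_matches_lp_oracle():
    assert dip_statistic(np.array([0.0, 1.0])) == pytest.approx(
        dip_lp_oracle([0.0, 1.0]), abs=1e-6
    )
    assert dip_statistic(np.array([0.0, 1.0])) == pytest.approx(0.25, abs=1e-6)


@pytest.mark.parametrize("n", [3, 4, 5, 7])
def test_dip_matches_lp_oracle_random_samples(n, rng):
    for _ in range(6):
        x = rng.uniform(0, 1, n)
        assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-6)


def test_dip_matches_lp_oracle_bimodal_small():
    x = np.array([0.0, 0.05, 0.1, 0.9, 0.95, 1.0])
    d = dip_statistic(x)
    assert d == pytest.approx(dip_lp_oracle(x), abs=1e-6)
    assert d > dip_statistic(np.linspace(0, 1, 6))


def test_dip_lower_bound_half_over_n(rng):
    for n in (2, 5, 20, 100):
        x = rng.uniform(0, 1, n)
        assert dip_statistic(x) >= 1 / (2 * n) - 1e-9


def test_dip_test_calibration_on_unimodal():
    rng = np.random.default_rng(3)
    ok = 0
    for r in range(8):
        d, p = dip_test(rng.standard_normal(500), n_boot=300, seed=r)
        ok += p > 0.05
    assert ok >= 7


def test_dip_test_power_on_separated_mixture():
    rng = np.random.default_rng(4)
    for r in range(4):
        x = np.concatenate([rng.normal(-3, 1, 250), rng.normal(3, 1, 250)])
        d, p = dip_test(x, n_boot=300, seed=r)
        assert p < 0.01


def test_dip_test_requires_four_points():
    with pytest.raises(DataError):
        dip_test([0.0, 1.0, 2.0])
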