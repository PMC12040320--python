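"""Ratemap computation and the field-detection rule sequence."""

import numpy as np
import pandas as pd
import pytest

from placerep.errors import DataError
from placerep.maze import build_standard_maze
from placerep.ratemaps import (
    RateMap,
    RateMapParams,
    assign_regions,
    compute_ratemap,
    detect_fields,
    exclude_interneurons,
)


def make_ratemap(geometry, rate_fn, unit="t"):
    """Hand-constructed ratemap: rate_fn(yc, xc) -> Hz at bin centers,
    valid on all walkable bins with unit occupancy."""
    shape = geometry.grid_shape
    bs = geometry.bin_size_cm
    rows, cols = np.indices(shape)
    rate = rate_fn((rows + 0.5) * bs, (cols + 0.5) * bs)
    rate = np.where(geometry.walkable_mask, rate, np.nan)
    occ = np.where(geometry.walkable_mask, 1.0, 0.0)
    return RateMap(
        rate=rate,
        occupancy=occ,
        bin_size_cm=bs,
        sigma_bins=1.5,
        speed_threshold_cm_s=1.5,
        unit_id=unit,
    )


def gaussian_bump(cx, cy, peak, sigma):
    return lambda yc, xc: peak * np.exp(-((xc - cx) ** 2 + (yc - cy) ** 2) / (2 * sigma**2))


def saddle_height_bruteforce(rate, p1, p2):
    """Max threshold at which the two peaks remain 8-connected: the
    max-min barrier between them (independent of the watershed path)."""
    from scipy.ndimage import label

    finite = np.nan_to_num(rate, nan=-np.inf)
    levels = np.unique(finite[np.isfinite(finite)])
    best = -np.inf
    for thr in levels[::-1]:
        lab, _ = label(finite >= thr, structure=np.ones((3, 3)))
        if lab[p1] and lab[p1] == lab[p2]:
            best = thr
            break
    return best


@pytest.fixture(scope="module")
def geom():
    return build_standard_maze()


# ---------------------------------------------------------------------------
# compute_ratemap


def test_homogeneous_poisson_mean_rate(geom, rng):
    """Uniform-ish sampling of a 5 Hz homogeneous unit gives a ~5 Hz map."""
    from placerep.synthetic import GroundTruthCell, generate_spikes, simulate_trajectory

    track, _ = simulate_trajectory(geom, duration_s=1200.0, seed=20)
    cell = GroundTruthCell(unit_id="h", fields=[], baseline_rate_hz=5.0)
    spikes = generate_spikes(track, [cell], geom, seed=21)["h"]
    rm = compute_ratemap(track, spikes, geom, unit_id="h")
    occ = rm.occupancy[rm.valid]
    mean = np.sum(rm.rate[rm.valid] * occ) / occ.sum()
    assert mean == pytest.approx(5.0, rel=0.10)


def test_zero_spikes_zero_rate(geom):
    from placerep.synthetic import simulate_trajectory

    track, _ = simulate_trajectory(geom, duration_s=300.0, seed=22)
    rm = compute_ratemap(track, np.array([]), geom)
    assert np.all(rm.rate[rm.valid] == 0)
    assert np.isnan(rm.rate[~geom.walkable_mask]).all()


def test_all_slow_samples_raise(geom):
    t = np.arange(0, 10, 1 / 30)
    track = pd.DataFrame({"t": t, "x": np.full_like(t, 4.0), "y": np.full_like(t, 30.0)})
    with pytest.raises(DataError):
        compute_ratemap(track, np.array([1.0]), geom)


def test_zero_occupancy_bins_invalid_not_zero(geom):
    from placerep.synthetic import simulate_trajectory

    track, _ = simulate_trajectory(geom, duration_s=60.0, seed=23)
    rm = compute_ratemap(track, np.array([]), geom)
    unvisited_walkable = geom.walkable_mask & (rm.occupancy == 0)
    if unvisited_walkable.any():
        assert np.isnan(rm.rate[unvisited_walkable]).all()


# ---------------------------------------------------------------------------
# exclude_interneurons


def test_interneuron_exclusion_rule():
    kept, excl = exclude_interneurons(
        [("a", 10.0), ("b", 1.0), ("c", 10**0.6), ("d", 4.1)]
    )
    assert excl == ["a", "d"]  # log10(10)=1 > 0.6; log10(4.1) ~ 0.613
    assert kept == ["b", "c"]  # boundary 10^0.6 kept (strict inequality)
    with pytest.raises(DataError):
        exclude_interneurons([("z", 0.0)])


# ---------------------------------------------------------------------------
# detect_fields


def test_single_bump_one_field(geom):
    a = geom.alley("V11").rect
    rm = make_ratemap(geom, gaussian_bump(a.center[0], a.center[1], 8.0, 4.0))
    fields = detect_fields(rm, geom)
    assert len(fields) == 1
    f = fields[0]
    pk_row, pk_col = f.peak_bin
    assert geom.region_grid[pk_row, pk_col] != ""
    assert f.peak_rate_hz == pytest.approx(8.0, rel=0.05)
    # true center bin is a member
    cbin = geom.bin_of(*a.center)
    assert any((b == cbin).all() for b in f.bins)


def test_subthreshold_peak_rejected(geom):
    a = geom.alley("V11").rect
    rm = make_ratemap(geom, gaussian_bump(a.center[0], a.center[1], 0.5, 6.0))
    assert detect_fields(rm, geom) == []


def test_tiny_area_rejected(geom):
    """A peak whose 20%-contour covers < 1% of walkable bins is dropped."""
    a = geom.alley("V11").rect
    rm = make_ratemap(geom, gaussian_bump(a.center[0], a.center[1], 8.0, 1.0))
    params = RateMapParams()
    n_above = np.sum(np.nan_to_num(rm.rate) >= 0.2 * 8.0)
    assert n_above < params.min_area_frac * geom.n_bins_walkable
    assert detect_fields(rm, geom) == []


def two_bump_map(geom, peak2=6.0, sep_sigma=3.0):
    """Two bumps along the middle horizontal corridor."""
    c1 = geom.alley("H01").rect.center
    c2 = geom.alley("H11").rect.center
    f1 = gaussian_bump(c1[0], c1[1], 8.0, sep_sigma)
    f2 = gaussian_bump(c2[0], c2[1], peak2, sep_sigma)
    return make_ratemap(geom, lambda yc, xc: f1(yc, xc) + f2(yc, xc)), c1, c2


def test_watershed_splits_deep_saddle(geom):
    """Two bumps with a saddle below 75% of the larger peak become two
    fields; the implied boundary rate matches the brute-force barrier."""
    rm, c1, c2 = two_bump_map(geom, peak2=6.0, sep_sigma=3.0)
    p1 = geom.bin_of(*c1)
    p2 = geom.bin_of(*c2)
    saddle = saddle_height_bruteforce(rm.rate, p1, p2)
    assert saddle <= 0.75 * np.nanmax(rm.rate)
    fields = detect_fields(rm, geom)
    assert len(fields) == 2
    peaks = sorted(f.peak_rate_hz for f in fields)
    assert peaks[1] == pytest.approx(8.0, rel=0.1)


def test_watershed_keeps_shallow_saddle(geom):
    """When the saddle exceeds 75% of the larger peak the merged field
    is kept."""
    rm, c1, c2 = two_bump_map(geom, peak2=8.0, sep_sigma=11.0)
    p1 = geom.bin_of(*c1)
    p2 = geom.bin_of(*c2)
    saddle = saddle_height_bruteforce(rm.rate, p1, p2)
    assert saddle > 0.75 * np.nanmax(rm.rate)
    fields = detect_fields(rm, geom)
    assert len(fields) == 1


def test_detection_translation_equivariant(geom):
    """On an unmasked map, shifting by whole bins shifts field
    boundaries identically."""

    def open_map(cy):
        shape = geom.grid_shape
        bs = geom.bin_size_cm
        rows, cols = np.indices(shape)
        rate = gaussian_bump(30.0, cy, 8.0, 5.0)((rows + 0.5) * bs, (cols + 0.5) * bs)
        return RateMap(
            rate=rate,
            occupancy=np.ones(shape),
            bin_size_cm=bs,
            sigma_bins=1.5,
            speed_threshold_cm_s=1.5,
        )

    shift_bins = 3
    f1 = detect_fields(open_map(30.0), geom)
    f2 = detect_fields(open_map(30.0 + shift_bins * geom.bin_size_cm), geom)
    assert len(f1) == len(f2) == 1
    b1 = {(r + shift_bins, c) for r, c in map(tuple, f1[0].bins)}
    b2 = {tuple(b) for b in f2[0].bins}
    assert b1 == b2


def test_detection_deterministic(geom):
    rm, _, _ = two_bump_map(geom)
    fa = detect_fields(rm, geom)
    fb = detect_fields(rm, geom)
    assert [f.field_id for f in fa] == [f.field_id for f in fb]
    for x, y in zip(fa, fb):
        assert np.array_equal(x.bins, y.bins)


# ---------------------------------------------------------------------------
# assign_regions


def field_from_bins(geom, rm, bins):
    from placerep.ratemaps import PlaceField

    bins = np.asarray(bins)
    rates = rm.rate[bins[:, 0], bins[:, 1]]
    k = int(np.nanargmax(rates))
    return PlaceField(
        unit_id="t",
        field_id="t-f0",
        bins=bins,
        peak_bin=tuple(bins[k]),
        peak_rate_hz=float(rates[k]),
        summed_rate=float(np.nansum(rates)),
    )


def test_field_inside_one_vertical_alley(geom):
    rm = make_ratemap(geom, lambda yc, xc: np.ones_like(xc))
    bins = geom.region_bins("V11")
    f = assign_regions(field_from_bins(geom, rm, bins), geom, rm)
    assert f.region_memberships == ["V11"]
    assert set(f.orientation_portions) == {"vertical"}


def test_thirty_percent_overlap_rule(geom):
    """Full coverage of one alley plus a sliver of a neighbor keeps only
    the first."""
    rm = make_ratemap(geom, lambda yc, xc: np.ones_like(xc))
    v11 = geom.region_bins("V11")
    inter = geom.region_bins("I11")  # neighbor region, take ~10% of it
    k = max(1, int(0.10 * len(inter)))
    bins = np.vstack([v11, inter[:k]])
    f = assign_regions(field_from_bins(geom, rm, bins), geom, rm)
    assert f.region_memberships == ["V11"]


def test_twenty_five_percent_rate_share_rule(geom):
    """A field straddling two alleys with a 60/40 rate split keeps both;
    with a 90/10 split only the dominant alley remains."""
    b1 = geom.region_bins("H01")
    b2 = geom.region_bins("H11")
    bins = np.vstack([b1, b2])

    def make(split):
        rate = np.zeros(geom.grid_shape)
        rate[b1[:, 0], b1[:, 1]] = split / len(b1)
        rate[b2[:, 0], b2[:, 1]] = (1 - split) / len(b2)
        rm = RateMap(
            rate=np.where(geom.walkable_mask, rate, np.nan),
            occupancy=np.ones(geom.grid_shape),
            bin_size_cm=geom.bin_size_cm,
            sigma_bins=1.5,
            speed_threshold_cm_s=1.5,
        )
        return assign_regions(field_from_bins(geom, rm, bins), geom, rm)

    f_60 = make(0.60)
    assert sorted(f_60.region_memberships) == ["H01", "H11"]
    f_90 = make(0.90)
    assert f_90.region_memberships == ["H01"]


def test_orientation_portions_split_and_recombine(geom):
    """A field spanning a vertical and a horizontal alley yields one
    portion per orientation with the member bins of that orientation."""
    bv = geom.region_bins("V11")
    bh = geom.region_bins("H01")
    rm = make_ratemap(geom, lambda yc, xc: np.ones_like(xc))
    f = assign_regions(field_from_bins(geom, rm, np.vstack([bv, bh])), geom, rm)
    assert set(f.orientation_portions) == {"vertical", "horizontal"}
    assert len(f.orientation_portions["vertical"]) == len(bv)
    assert len(f.orientation_portions["horizontal"]) == len(bh)
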