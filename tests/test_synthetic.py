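"""Synthetic session generator: behavior, cells, spikes, determinism."""

import numpy as np
import pytest
from scipy import stats

from placerep.errors import ConfigurationError
from placerep.maze import HORIZONTAL, VERTICAL
from placerep.synthetic import (
    DriftSpec,
    PopulationParams,
    TrajectoryParams,
    frame_directions,
    generate_place_cells,
    generate_spikes,
    simulate_pass_table,
    simulate_trajectory,
)


def test_trajectory_sample_count_and_monotone_time(geometry):
    track, _ = simulate_trajectory(geometry, duration_s=120.0, frame_rate_hz=30.0, seed=0)
    assert len(track) == 120 * 30
    assert np.all(np.diff(track["t"]) > 0)


def test_positions_on_or_near_walkable(geometry):
    from placerep.maze import region_lookup_array

    track, _ = simulate_trajectory(geometry, duration_s=300.0, seed=1)
    reg = region_lookup_array(geometry, track["x"].to_numpy(), track["y"].to_numpy())
    assert np.mean(reg == "") < 0.05  # jitter may nudge a few samples off


def test_reward_replacement_respects_graph_distance(geometry):
    """Every replacement site is >= 2 alleys from the site it replaces,
    verified with the breadth-first alley-graph oracle."""
    track, rewards = simulate_trajectory(geometry, duration_s=900.0, seed=2)
    history = track.attrs["reward_site_history"]
    assert len(history) >= 10
    for _, old, new in history:
        assert geometry.alley_graph_distance(old, new) >= 2
    assert track.attrs["initial_primed_sites"] == 2
    assert all(aid in {a.id for a in geometry.alleys} for _, aid in rewards)


def test_trajectory_deterministic(geometry):
    t1, r1 = simulate_trajectory(geometry, duration_s=60.0, seed=7)
    t2, r2 = simulate_trajectory(geometry, duration_s=60.0, seed=7)
    assert t1.equals(t2) and r1 == r2
    t3, _ = simulate_trajectory(geometry, duration_s=60.0, seed=8)
    assert not t1.equals(t3)


def test_turnaround_fraction_configurable(geometry):
    """Per-entry turnaround rate (no merge) matches the configured one."""
    from placerep.traversals import PassParams, alley_traversals

    for target in (0.05, 0.25):
        track, _ = simulate_trajectory(
            geometry,
            duration_s=1800.0,
            params=TrajectoryParams(turnaround_prob=target, lateral_jitter_cm=0.0),
            seed=3,
        )
        travs = alley_traversals(track, geometry, params=PassParams(merge_gap_s=0.0))
        frac = np.mean([not p.complete for p in travs])
        assert abs(frac - target) < 0.05


def test_rotation_bias_recovered(geometry):
    """Clockwise-circulation bias is recovered from pass directions."""
    from placerep.synthetic import clockwise_direction
    from placerep.traversals import PassParams, alley_traversals

    for bias in (0.5, 0.7):
        track, _ = simulate_trajectory(
            geometry,
            duration_s=1800.0,
            params=TrajectoryParams(rotation_bias=bias, lateral_jitter_cm=0.0),
            seed=4,
        )
        travs = [
            p
            for p in alley_traversals(track, geometry, params=PassParams(merge_gap_s=0.0))
            if p.complete
        ]
        cw = np.mean([p.direction == clockwise_direction(geometry, p.alley_id) for p in travs])
        assert abs(cw - bias) < 0.05


def test_duration_must_be_positive(geometry):
    with pytest.raises(ConfigurationError):
        simulate_trajectory(geometry, duration_s=0.0)


# ---------------------------------------------------------------------------
# cells


def test_alignment_strength_one_aligns_all_alley_fields(geometry):
    cells = generate_place_cells(
        geometry,
        PopulationParams(
            n_cells=30, p_multi_field=1.0, alignment_strength=1.0, p_intersection_field=0.0
        ),
        seed=4,
    )
    for c in cells:
        oris = {f.orientation for f in c.fields}
        assert len(oris) == 1
        assert 2 <= len(c.fields) <= 7


def test_alignment_strength_zero_uniform_over_alleys(geometry):
    """Host-alley draws should be indistinguishable from uniform over
    the 17 alleys (9 vertical : 8 horizontal)."""
    cells = generate_place_cells(
        geometry,
        PopulationParams(
            n_cells=700,
            p_multi_field=1.0,
            alignment_strength=0.0,
            p_intersection_field=0.0,
        ),
        seed=5,
    )
    oris = [f.orientation for c in cells for f in c.fields]
    assert len(oris) >= 2000
    n_v = oris.count(VERTICAL)
    stat, p = stats.chisquare(
        [n_v, len(oris) - n_v],
        [len(oris) * 9 / 17, len(oris) * 8 / 17],
    )
    assert p > 0.01


def test_field_centers_on_walkable(geometry):
    cells = generate_place_cells(geometry, PopulationParams(n_cells=15), seed=6)
    from placerep.maze import region_lookup

    for c in cells:
        for f in c.fields:
            assert region_lookup(geometry, *f.center) == f.region_id
            assert f.peak_rate_hz > 0
            assert all(g > 0 for g in f.directional_gain.values())


# ---------------------------------------------------------------------------
# spikes


def test_zero_rate_gives_zero_spikes(geometry):
    track, _ = simulate_trajectory(geometry, duration_s=60.0, seed=0)
    from placerep.synthetic import GroundTruthCell

    silent = GroundTruthCell(unit_id="z", fields=[], baseline_rate_hz=0.0)
    spikes = generate_spikes(track, [silent], geometry, seed=0)
    assert spikes["z"].size == 0


def test_constant_rate_poisson_count(geometry):
    """lambda = 5 Hz for 1000 s: count within 5000 +/- 4*sqrt(5000)."""
    track, _ = simulate_trajectory(geometry, duration_s=1000.0, seed=1)
    from placerep.synthetic import GroundTruthCell

    unit = GroundTruthCell(unit_id="c", fields=[], baseline_rate_hz=5.0)
    spikes = generate_spikes(track, [unit], geometry, seed=9)["c"]
    assert abs(len(spikes) - 5000) < 4 * np.sqrt(5000)
    assert np.all(np.diff(spikes) >= 0)
    assert spikes[0] >= 0 and spikes[-1] <= 1000.0


def test_directional_gain_recovered_from_passes(geometry):
    """A gain-2 field fires ~2x more per pass in its preferred direction."""
    from placerep.synthetic import GroundTruthCell, GroundTruthField
    from placerep.traversals import alley_traversals

    track, _ = simulate_trajectory(
        geometry, duration_s=3600.0, params=TrajectoryParams(lateral_jitter_cm=0.0), seed=10
    )
    alley = geometry.alley("V11")
    cell = GroundTruthCell(
        unit_id="g",
        fields=[
            GroundTruthField(
                center=alley.rect.center,
                scale_cm=3.5,
                peak_rate_hz=20.0,
                region_id="V11",
                orientation=VERTICAL,
                directional_gain={"N": 2.0},
            )
        ],
        baseline_rate_hz=0.0,
    )
    spikes = generate_spikes(track, [cell], geometry, seed=11)["g"]
    travs = [p for p in alley_traversals(track, geometry) if p.alley_id == "V11" and p.complete]
    counts = {"N": [], "S": []}
    for p in travs:
        k = np.sum((spikes >= p.t_in) & (spikes <= p.t_out))
        counts[p.direction].append(k / max(p.t_out - p.t_in, 1e-9))
    assert min(len(counts["N"]), len(counts["S"])) >= 40
    ratio = np.mean(counts["N"]) / np.mean(counts["S"])
    assert abs(ratio - 2.0) < 0.3  # within 15%


def test_spike_generation_deterministic(geometry):
    track, _ = simulate_trajectory(geometry, duration_s=120.0, seed=3)
    cells = generate_place_cells(geometry, PopulationParams(n_cells=5), seed=3)
    s1 = generate_spikes(track, cells, geometry, seed=5)
    s2 = generate_spikes(track, cells, geometry, seed=5)
    for u in s1:
        assert np.array_equal(s1[u], s2[u])


def test_rate_reconstruction_from_spikes(geometry):
    """Binning spikes by position recovers the ground-truth rate surface."""
    from placerep.ratemaps import compute_ratemap
    from placerep.synthetic import GroundTruthCell, GroundTruthField, rate_on_track

    track, _ = simulate_trajectory(geometry, duration_s=1800.0, seed=12)
    fields = [
        GroundTruthField(
            center=geometry.alley(a).rect.center,
            scale_cm=3.5,
            peak_rate_hz=10.0,
            region_id=a,
            orientation=geometry.orientation_of(a),
        )
        for a in ("V00", "V21", "H12")
    ]
    cell = GroundTruthCell(unit_id="r", fields=fields, baseline_rate_hz=0.05)
    spikes = generate_spikes(track, [cell], geometry, seed=13)["r"]
    rm = compute_ratemap(track, spikes, geometry, unit_id="r")

    # ground-truth rate per bin at bin centers
    bs = geometry.bin_size_cm
    rows, cols = np.nonzero(rm.valid)
    xc = (cols + 0.5) * bs
    yc = (rows + 0.5) * bs
    truth = np.full(len(rows), 0.05)
    for f in fields:
        d2 = (xc - f.center[0]) ** 2 + (yc - f.center[1]) ** 2
        truth += f.peak_rate_hz * np.exp(-d2 / (2 * f.scale_cm**2))
    est = rm.rate[rows, cols]
    assert stats.pearsonr(truth, est)[0] > 0.9


# ---------------------------------------------------------------------------
# pass-level generator and drift envelopes


def test_drift_families_bounded_and_shaped():
    t = np.linspace(0, 3600, 500)
    assert np.all(DriftSpec().value(t, 3600) == 1)
    lin = DriftSpec(family="linear", lo=0.5, hi=1.5).value(t, 3600)
    assert lin[0] == pytest.approx(0.5) and lin[-1] == pytest.approx(1.5)
    dec = DriftSpec(family="exp_decay", onset_s=600, tau_s=900).value(t, 3600)
    assert dec[0] == pytest.approx(0.1) and dec[-1] < 0.1
    sin = DriftSpec(family="sinusoid", depth=0.5).value(t, 3600)
    assert np.all(sin > 0) and np.all(sin <= 1.5 + 1e-12)
    with pytest.raises(ConfigurationError):
        DriftSpec(family="bogus").value(t, 3600)


def test_simulate_pass_table_gain_and_balance():
    tb = simulate_pass_table(n_per_direction=300, gain=2.0, seed=0)
    assert len(tb) == 600
    assert np.all(np.diff(tb["t"]) >= 0)
    m_n = tb.loc[tb["direction"] == "N", "norm_rate"].mean()
    m_s = tb.loc[tb["direction"] == "S", "norm_rate"].mean()
    assert m_n / m_s == pytest.approx(2.0, rel=0.15)


def test_frame_directions_labels_match_motion(geometry):
    track, _ = simulate_trajectory(
        geometry, duration_s=300.0, params=TrajectoryParams(lateral_jitter_cm=0.0), seed=14
    )
    dirs = frame_directions(geometry, track)
    assert set(np.unique(dirs)) <= {"", "N", "E", "S", "W"}
    assert np.mean(dirs != "") > 0.3  # most time is spent inside alleys
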