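"""Self-contained validation benchmarks on synthetic data.

Each function generates its own inputs from a seed, runs one slice of
the analysis chain, and returns the quantity a validation run checks:
detection precision/recall on a full simulated session, GLM power and
type-I rates on pass-level tables, drift detection and population-
vector decay, and decoding calibration. Shared by the test suite and
the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoding import linear_position_decode, rf_direction_decode
from .directionality import glm_direction_lrt
from .maze import MazeGeometry, build_standard_maze
from .ratemaps import RateMapParams, compute_ratemap, detect_fields, running_speed
from .synthetic import (
    DriftSpec,
    PopulationParams,
    simulate_pass_table,
    simulate_session,
)
from .temporal import TIME_GLM_ALPHA, glm_time_lrt, pv_window_correlation


def detection_precision_recall(
    seed: int = 42,
    duration_s: float = 3600.0,
    n_cells: int = 20,
    min_peak_hz: float = 3.0,
    geometry: MazeGeometry | None = None,
) -> dict:
    """Field-detection recall and precision for strong fields.

    A ground-truth field counts as strong when its drift-averaged peak
    is >= ``min_peak_hz``. A strong truth is recalled when a detected
    field of the same unit contains its center bin or peaks within the
    truth's 1-Hz radius; a strong detection (detected peak >=
    ``min_peak_hz``) is correct when it matches any truth the same way.
    """
    geom = geometry or build_standard_maze()
    params = RateMapParams()
    session, cells = simulate_session(
        geom, duration_s=duration_s, population_params=PopulationParams(n_cells=n_cells),
        seed=seed,
    )
    track = session.track_frame()
    speed = running_speed(track)
    dur = session.duration_s
    tgrid = np.linspace(0, dur, 200)
    bs = geom.bin_size_cm
    tp = fn = n_det = n_ok = 0
    for c in cells:
        rm = compute_ratemap(
            track, session.spikes[c.unit_id], geom, params, unit_id=c.unit_id, speed=speed
        )
        dets = detect_fields(rm, geom, params)
        truths = []
        for f in c.fields:
            eff = f.peak_rate_hz * float(np.mean(f.drift.value(tgrid, dur)))
            r1 = f.scale_cm * np.sqrt(2 * np.log(max(eff, 1.001))) / bs
            truths.append((geom.bin_of(*f.center), eff, r1))

        def matches(det, truth):
            cb, _, r1 = truth
            inside = any((b == cb).all() for b in det.bins)
            near = np.hypot(det.peak_bin[0] - cb[0], det.peak_bin[1] - cb[1]) <= max(r1, 3.0)
            return inside or near

        for truth in truths:
            if truth[1] < min_peak_hz:
                continue
            hit = any(matches(d, truth) for d in dets)
            tp += hit
            fn += not hit
        for d in dets:
            if d.peak_rate_hz < min_peak_hz:
                continue
            n_det += 1
            n_ok += any(matches(d, t) for t in truths)
    return {
        "recall": tp / max(tp + fn, 1),
        "precision": n_ok / max(n_det, 1),
        "n_true_strong": tp + fn,
        "n_detected_strong": n_det,
    }


def direction_glm_rates(
    n_reps: int = 500,
    gain: float = 1.0,
    n_per_direction: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated fields where the direction LRT rejects."""
    hits = 0
    for r in range(n_reps):
        tb = simulate_pass_table(
            n_per_direction=n_per_direction, gain=gain, seed=seed * n_reps + r
        )
        hits += glm_direction_lrt(tb).p < alpha
    return hits / n_reps


def time_glm_power(
    n_reps: int = 100,
    n_per_direction: int = 30,
    half_life_s: float = 900.0,
    seed: int = 0,
) -> float:
    """Power of the time LRT against an exponential-decay envelope."""
    drift = DriftSpec(family="exp_decay", onset_s=0.0, tau_s=half_life_s / np.log(2))
    hits = 0
    for r in range(n_reps):
        tb = simulate_pass_table(
            n_per_direction=n_per_direction, drift=drift, seed=seed * n_reps + r
        )
        hits += glm_time_lrt(tb).p < TIME_GLM_ALPHA
    return hits / n_reps


def pv_slope_negative_fraction(
    n_seeds: int = 20,
    n_units: int = 30,
    n_passes: int = 200,
    duration_s: float = 3600.0,
    seed: int = 0,
) -> float:
    """Fraction of simulated drifting populations with a negative
    population-vector lag slope."""
    negative = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * n_seeds + k)
        tables = {}
        for u in range(n_units):
            t = np.sort(rng.uniform(0, duration_s, n_passes))
            drift = DriftSpec(
                family="linear", lo=rng.uniform(0.2, 1.8), hi=rng.uniform(0.2, 1.8)
            )
            v = rng.uniform(0.5, 2.0) * drift.value(t, duration_s)
            v = v + 0.1 * rng.standard_normal(n_passes)
            tables[f"u{u}"] = pd.DataFrame({"t": t, "norm_rate": v})
        res = pv_window_correlation(tables, duration_s)
        negative += res["slope"] < 0
    return negative / n_seeds


def _rf_population(rng, n_passes, n_units, gain):
    labels = np.array(["N", "S"] * (n_passes // 2), dtype=object)
    rng.shuffle(labels)
    pref = rng.random(n_units) < 0.5
    X = rng.gamma(4.0, 0.25, size=(n_passes, n_units))
    for u in range(n_units):
        X[labels == ("N" if pref[u] else "S"), u] *= gain
    return X, labels


def rf_significant_fraction(
    n_seeds: int = 20,
    gain: float = 1.0,
    n_passes: int = 80,
    n_units: int = 12,
    n_trees: int = 100,
    n_shuffles: int = 20,
    n_naive: int = 200,
    seed: int = 0,
) -> float:
    """Fraction of populations the conjunctive shuffle+naive rule calls
    significant (false-positive rate when gain = 1)."""
    sig = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * n_seeds + k)
        X, labels = _rf_population(rng, n_passes, n_units, gain)
        res = rf_direction_decode(
            X,
            labels,
            n_trees=n_trees,
            n_shuffles=n_shuffles,
            n_naive=n_naive,
            seed=seed * n_seeds + k,
        )
        sig += res.significant
    return sig / n_seeds


def position_decode_margin(
    seed: int = 77,
    duration_s: float = 900.0,
    n_cells: int = 18,
    n_rotations: int = 15,
    n_shuffles: int = 15,
    geometry: MazeGeometry | None = None,
) -> dict:
    """Median test r^2 of the position decoder vs its circular-shuffle
    95th percentile on a standard synthetic session."""
    geom = geometry or build_standard_maze()
    session, _ = simulate_session(
        geom,
        duration_s=duration_s,
        population_params=PopulationParams(
            n_cells=n_cells, p_drifting=0.0, peak_rate_range_hz=(8.0, 15.0)
        ),
        seed=seed,
    )
    res = linear_position_decode(
        session.spikes,
        session.track_frame(),
        n_rotations=n_rotations,
        n_shuffles=n_shuffles,
        seed=seed,
    )
    return {
        "median_test_r2": res.median_test_r2(),
        "shuffle_95th": res.shuffle_95th,
        "median_train_r2": float(np.median(res.train_r2)),
    }
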