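"""Synthetic city-block maze sessions with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: rectilinear foraging over the 17-alley/12-intersection maze,
pseudorandom two-site reward with the >=2-alley replacement rule, place
cells with 1-7 Gaussian fields (optionally aligned by alley orientation),
per-field directional gain, and slow per-field temporal rate envelopes.
Spikes are drawn from an inhomogeneous Poisson process discretized at the
camera frame rate. Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .maze import (
    DIRECTION_PAIRS,
    HORIZONTAL,
    POSITIVE_DIRECTION,
    VERTICAL,
    MazeGeometry,
    region_lookup_array,
)

# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class TrajectoryParams:
    """Behavioral knobs for the random walk on the maze graph.

    Speeds are drawn once per alley traversal. ``turnaround_prob`` is the
    probability that an alley entry exits through the same end.
    ``reward_attraction`` biases alley choice toward the nearer primed
    reward site. ``rotation_bias`` sets the probability that the next
    alley entry continues clockwise circulation around the platform; it
    is the flow-conserving way to bias direction sampling in a closed
    maze (a fixed per-alley direction preference cannot persist because
    every crossing must eventually be matched by a return).
    """

    speed_mean_cm_s: float = 22.0
    speed_sd_cm_s: float = 7.0
    turnaround_prob: float = 0.12
    reward_attraction: float = 0.3
    rotation_bias: float = 0.5  # P(next entry continues clockwise circulation)
    backtrack_weight: float = 0.05  # damping on re-entering the alley just left
    lateral_jitter_cm: float = 0.5
    min_reward_replacement_distance: int = 2


@dataclass
class DriftSpec:
    """Slow multiplicative rate envelope for one field.

    Families: ``constant`` (value 1), ``linear`` (ramp from ``lo`` to
    ``hi`` over the session), ``exp_decay`` (rise at ``onset_s`` then
    exponential decay with ``tau_s``), ``sinusoid`` (period ``period_s``,
    modulation depth ``depth``).
    """

    family: str = "constant"
    lo: float = 1.0
    hi: float = 1.0
    onset_s: float = 0.0
    tau_s: float = 900.0
    period_s: float = 1200.0
    depth: float = 0.5
    phase: float = 0.0

    def value(self, t: np.ndarray, duration_s: float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "constant":
            return np.ones_like(t)
        if self.family == "linear":
            frac = np.clip(t / duration_s, 0.0, 1.0)
            return self.lo + (self.hi - self.lo) * frac
        if self.family == "exp_decay":
            out = np.where(t < self.onset_s, 0.1, np.exp(-(t - self.onset_s) / self.tau_s))
            return np.clip(out, 0.05, None)
        if self.family == "sinusoid":
            return 1.0 + self.depth * np.sin(2 * np.pi * t / self.period_s + self.phase)
        raise ConfigurationError(f"unknown drift family: {self.family!r}")


@dataclass
class GroundTruthField:
    center: tuple[float, float]  # cm
    scale_cm: float  # Gaussian sigma
    peak_rate_hz: float
    region_id: str  # host alley or intersection
    orientation: str | None  # VERTICAL/HORIZONTAL for alleys, None otherwise
    directional_gain: dict[str, float] = field(default_factory=dict)  # per direction
    drift: DriftSpec = field(default_factory=DriftSpec)


@dataclass
class GroundTruthCell:
    unit_id: str
    fields: list[GroundTruthField]
    baseline_rate_hz: float = 0.05


@dataclass
class PopulationParams:
    """Defaults describe a typical recorded population: ~20 cells per
    session, a majority of multi-fielded (repeating) cells with 2-7
    fields biased toward alleys of one orientation, modest directional
    gains and slow drift on a subset of fields."""

    n_cells: int = 20
    p_multi_field: float = 0.65
    fields_per_cell_weights: tuple[float, ...] = (0.35, 0.25, 0.2, 0.1, 0.07, 0.03)
    # ^ weights for 2..7 fields, used for multi-field cells (index 0 -> 2 fields)
    alignment_strength: float = 0.8
    p_intersection_field: float = 0.1
    peak_rate_range_hz: tuple[float, float] = (4.0, 12.0)
    field_scale_range_cm: tuple[float, float] = (2.5, 4.5)
    baseline_rate_hz: float = 0.05
    p_directional: float = 0.5
    directional_gain: float = 2.0
    drift_families: tuple[str, ...] = ("constant", "linear", "exp_decay", "sinusoid")
    p_drifting: float = 0.4
    max_placement_retries: int = 50


@dataclass
class SessionRecording:
    """One recorded (or simulated) session."""

    t: np.ndarray  # s, strictly increasing, fixed frame rate
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    spikes: dict[str, np.ndarray]  # unit id -> sorted spike times (s)
    rewards: list[tuple[float, str]]  # (timestamp s, alley id)
    geometry: MazeGeometry
    frame_rate_hz: float = 30.0
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.frame_rate_hz

    def track_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y})


# ---------------------------------------------------------------------------
# trajectory


def _pick_new_reward_site(rng, geometry, old_site, other_site, min_distance):
    candidates = [
        a.id
        for a in geometry.alleys
        if a.id != other_site
        and geometry.alley_graph_distance(a.id, old_site) >= min_distance
    ]
    if not candidates:
        raise SimulationError(
            f"no alley is >= {min_distance} alleys from {old_site!r}; maze too small"
        )
    return candidates[rng.integers(len(candidates))]


def simulate_trajectory(
    geometry: MazeGeometry,
    duration_s: float = 3600.0,
    frame_rate_hz: float = 30.0,
    params: TrajectoryParams | None = None,
    seed: int = 0,
):
    """Random walk on the maze graph rendered to per-frame positions.

    Returns ``(track, rewards)`` where track is a DataFrame (t, x, y) and
    rewards a list of (timestamp, alley id). Two reward sites are primed
    at all times; a visited site is replaced by one at graph distance >=
    ``min_reward_replacement_distance`` alleys.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration must be positive")
    params = params or TrajectoryParams()
    rng = np.random.default_rng(seed)

    inter_of = {a.id: geometry.intersections_of_alley(a.id) for a in geometry.alleys}
    alleys_at = {i.id: geometry.alleys_at_intersection(i.id) for i in geometry.intersections}
    centers = {rid: geometry.region_rect(rid).center for rid in geometry.region_ids}

    alley_ids = [a.id for a in geometry.alleys]
    primed = list(rng.choice(alley_ids, size=2, replace=False))
    # Precompute alley-to-alley graph distances for the attraction bias.
    dist = {
        a: {b: geometry.alley_graph_distance(a, b) for b in alley_ids} for a in alley_ids
    }

    t_now = 0.0
    node = geometry.intersections[rng.integers(len(geometry.intersections))].id
    way_t, way_x, way_y = [0.0], [centers[node][0]], [centers[node][1]]
    rewards: list[tuple[float, str]] = []
    site_history: list[tuple[float, str, str]] = []  # (t, replaced, new site)

    def extend(p_from, p_to, speed):
        nonlocal t_now
        d = float(np.hypot(p_to[0] - p_from[0], p_to[1] - p_from[1]))
        t_now += max(d, 1e-6) / speed
        way_t.append(t_now)
        way_x.append(p_to[0])
        way_y.append(p_to[1])

    prev_alley: str | None = None
    while t_now < duration_s:
        options = alleys_at[node]
        weights = np.ones(len(options))
        clockwise = np.zeros(len(options), dtype=bool)
        for k, aid in enumerate(options):
            implied = _implied_direction(geometry, aid, node, inter_of[aid])
            clockwise[k] = implied == clockwise_direction(geometry, aid)
            if aid == prev_alley and len(options) > 1:
                weights[k] *= params.backtrack_weight
        if params.reward_attraction > 0 and rng.random() < params.reward_attraction:
            # favor the option closest (in alley-graph distance) to a primed site
            d_opt = [min(dist[aid][p] for p in primed) for aid in options]
            best = min(d_opt)
            weights = weights * np.array([3.0 if d == best else 0.5 for d in d_opt])
        # circulation bias: give the clockwise-consistent options a total
        # probability mass of rotation_bias (flow-conserving direction bias)
        if clockwise.any() and (~clockwise).any():
            w_cw = weights[clockwise].sum()
            w_ccw = weights[~clockwise].sum()
            weights[clockwise] *= params.rotation_bias / w_cw
            weights[~clockwise] *= (1 - params.rotation_bias) / w_ccw
        weights = weights / weights.sum()
        alley = options[rng.choice(len(options), p=weights)]

        speed = max(3.0, rng.normal(params.speed_mean_cm_s, params.speed_sd_cm_s))
        ends = inter_of[alley]
        far = ends[0] if ends[1] == node else ends[1] if len(ends) > 1 else node
        turnaround = rng.random() < params.turnaround_prob

        extend(centers[node], centers[alley], speed)
        if alley in primed:  # reward delivered at the lickport (alley center)
            rewards.append((t_now, alley))
            other = primed[0] if primed[1] == alley else primed[1]
            new_site = _pick_new_reward_site(
                rng, geometry, alley, other, params.min_reward_replacement_distance
            )
            site_history.append((t_now, alley, new_site))
            primed = [other, new_site]
        if turnaround or far == node:
            extend(centers[alley], centers[node], speed)
        else:
            extend(centers[alley], centers[far], speed)
            node = far
        prev_alley = alley

    n_frames = int(round(duration_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    x = np.interp(t, way_t, way_x)
    y = np.interp(t, way_t, way_y)
    if params.lateral_jitter_cm > 0:
        x = x + rng.normal(0, params.lateral_jitter_cm, n_frames)
        y = y + rng.normal(0, params.lateral_jitter_cm, n_frames)
        x = np.clip(x, 0, geometry.platform.x1 - 1e-6)
        y = np.clip(y, 0, geometry.platform.y1 - 1e-6)
    track = pd.DataFrame({"t": t, "x": x, "y": y})
    track.attrs["reward_site_history"] = site_history
    track.attrs["initial_primed_sites"] = 2
    return track, [r for r in rewards if r[0] <= duration_s]


def clockwise_direction(geometry: MazeGeometry, alley_id: str) -> str:
    """Travel direction through an alley consistent with clockwise
    circulation around the platform center (image coordinates, y down):
    east along the top, south on the right, west along the bottom, north
    on the left."""
    a = geometry.alley(alley_id)
    mx, my = geometry.platform.center
    cx, cy = a.rect.center
    if a.orientation == VERTICAL:
        return "S" if cx > mx else "N"
    return "E" if cy < my else "W"


def _implied_direction(geometry, alley_id, entry_intersection, ends):
    """Direction of a straight-through traversal entered from one end."""
    a = geometry.alley(alley_id)
    (ex, ey) = geometry.region_rect(entry_intersection).center
    (cx, cy) = a.rect.center
    if a.orientation == VERTICAL:
        return "S" if ey < cy else "N"
    return "E" if ex < cx else "W"


# ---------------------------------------------------------------------------
# cells


def generate_place_cells(
    geometry: MazeGeometry,
    params: PopulationParams | None = None,
    seed: int = 0,
) -> list[GroundTruthCell]:
    """Draw a ground-truth population of place cells.

    With ``alignment_strength`` s, each alley field of a multi-fielded
    cell lands in the cell's preferred orientation with probability s and
    uniformly over all alleys otherwise; s=1 therefore aligns every alley
    field and s=0 scatters fields uniformly over alleys.
    """
    params = params or PopulationParams()
    if params.n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    v_alleys = [a.id for a in geometry.alleys if a.orientation == VERTICAL]
    h_alleys = [a.id for a in geometry.alleys if a.orientation == HORIZONTAL]
    all_alleys = v_alleys + h_alleys
    inter_ids = [i.id for i in geometry.intersections]

    cells = []
    for ci in range(params.n_cells):
        if rng.random() < params.p_multi_field:
            w = np.asarray(params.fields_per_cell_weights, dtype=float)
            n_fields = int(2 + rng.choice(len(w), p=w / w.sum()))
        else:
            n_fields = 1
        preferred = VERTICAL if rng.random() < 0.5 else HORIZONTAL
        used: set[str] = set()
        fields = []
        for _ in range(n_fields):
            region = None
            for _ in range(params.max_placement_retries):
                if rng.random() < params.p_intersection_field:
                    cand = inter_ids[rng.integers(len(inter_ids))]
                elif rng.random() < params.alignment_strength:
                    pool = v_alleys if preferred == VERTICAL else h_alleys
                    cand = pool[rng.integers(len(pool))]
                else:
                    cand = all_alleys[rng.integers(len(all_alleys))]
                if cand not in used:
                    region = cand
                    break
            if region is None:
                raise SimulationError(
                    f"could not place field {len(fields)} of cell {ci} after "
                    f"{params.max_placement_retries} retries"
                )
            used.add(region)
            orientation = geometry.orientation_of(region)
            cx, cy = geometry.region_rect(region).center
            gain = {}
            if orientation is not None and rng.random() < params.p_directional:
                d_pos, d_neg = DIRECTION_PAIRS[orientation]
                pref = d_pos if rng.random() < 0.5 else d_neg
                gain[pref] = params.directional_gain
            if rng.random() < params.p_drifting:
                fam = params.drift_families[rng.integers(len(params.drift_families))]
                drift = _random_drift(rng, fam)
            else:
                drift = DriftSpec()
            fields.append(
                GroundTruthField(
                    center=(cx, cy),
                    scale_cm=float(rng.uniform(*params.field_scale_range_cm)),
                    peak_rate_hz=float(rng.uniform(*params.peak_rate_range_hz)),
                    region_id=region,
                    orientation=orientation,
                    directional_gain=gain,
                    drift=drift,
                )
            )
        cells.append(
            GroundTruthCell(
                unit_id=f"u{ci:03d}", fields=fields, baseline_rate_hz=params.baseline_rate_hz
            )
        )
    return cells


def _random_drift(rng, family: str) -> DriftSpec:
    if family == "constant":
        return DriftSpec()
    if family == "linear":
        lo, hi = sorted(rng.uniform(0.3, 1.7, size=2))
        if rng.random() < 0.5:
            lo, hi = hi, lo
        return DriftSpec(family="linear", lo=lo, hi=hi)
    if family == "exp_decay":
        return DriftSpec(
            family="exp_decay",
            onset_s=float(rng.uniform(0, 900)),
            tau_s=float(rng.uniform(600, 1800)),
        )
    if family == "sinusoid":
        return DriftSpec(
            family="sinusoid",
            period_s=float(rng.uniform(800, 2000)),
            depth=float(rng.uniform(0.3, 0.7)),
            phase=float(rng.uniform(0, 2 * np.pi)),
        )
    raise ConfigurationError(f"unknown drift family: {family!r}")


# ---------------------------------------------------------------------------
# spikes


def frame_directions(geometry: MazeGeometry, track: pd.DataFrame) -> np.ndarray:
    """Pass-level travel direction per frame.

    Each contiguous run of frames inside one alley is labeled with the
    overall direction of travel across that run (sign of net displacement
    along the alley axis); frames outside alleys get ''.
    """
    regions = region_lookup_array(geometry, track["x"].to_numpy(), track["y"].to_numpy())
    out = np.full(len(track), "", dtype=object)
    x = track["x"].to_numpy()
    y = track["y"].to_numpy()
    i = 0
    n = len(track)
    while i < n:
        rid = regions[i]
        if rid and geometry.is_alley(rid):
            j = i
            while j + 1 < n and regions[j + 1] == rid:
                j += 1
            if geometry.orientation_of(rid) == VERTICAL:
                d = "S" if y[j] >= y[i] else "N"
            else:
                d = "E" if x[j] >= x[i] else "W"
            out[i : j + 1] = d
            i = j + 1
        else:
            i += 1
    return out


def rate_on_track(
    cell: GroundTruthCell,
    track: pd.DataFrame,
    directions: np.ndarray,
    duration_s: float,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of a cell along the trajectory."""
    x = track["x"].to_numpy()
    y = track["y"].to_numpy()
    t = track["t"].to_numpy()
    lam = np.full(len(track), cell.baseline_rate_hz, dtype=float)
    for f in cell.fields:
        d2 = (x - f.center[0]) ** 2 + (y - f.center[1]) ** 2
        g = f.peak_rate_hz * np.exp(-d2 / (2 * f.scale_cm**2))
        if f.directional_gain:
            gain = np.ones(len(track))
            for d, v in f.directional_gain.items():
                gain[directions == d] = v
            g = g * gain
        g = g * f.drift.value(t, duration_s)
        lam += g
    return lam


def generate_spikes(
    track: pd.DataFrame,
    cells: list[GroundTruthCell],
    geometry: MazeGeometry,
    frame_rate_hz: float = 30.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Inhomogeneous-Poisson spike trains, discretized per camera frame.

    The rate is held constant within each frame (33.3 ms at 30 Hz); spike
    counts are Poisson draws per frame with times jittered uniformly
    within the frame. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    t = track["t"].to_numpy()
    duration = float(t[-1] - t[0]) + dt
    directions = frame_directions(geometry, track)
    spikes: dict[str, np.ndarray] = {}
    for cell in cells:
        lam = rate_on_track(cell, track, directions, duration)
        counts = rng.poisson(lam * dt)
        idx = np.repeat(np.arange(len(t)), counts)
        times = t[idx] + rng.uniform(0, dt, size=idx.size)
        spikes[cell.unit_id] = np.sort(times)
    return spikes


def simulate_session(
    geometry: MazeGeometry,
    duration_s: float = 3600.0,
    frame_rate_hz: float = 30.0,
    trajectory_params: TrajectoryParams | None = None,
    population_params: PopulationParams | None = None,
    seed: int = 0,
) -> tuple[SessionRecording, list[GroundTruthCell]]:
    """Full synthetic session: trajectory + cells + spikes + rewards."""
    track, rewards = simulate_trajectory(
        geometry, duration_s, frame_rate_hz, trajectory_params, seed=seed
    )
    cells = generate_place_cells(geometry, population_params, seed=seed + 1)
    spikes = generate_spikes(track, cells, geometry, frame_rate_hz, seed=seed + 2)
    rec = SessionRecording(
        t=track["t"].to_numpy(),
        x=track["x"].to_numpy(),
        y=track["y"].to_numpy(),
        spikes=spikes,
        rewards=rewards,
        geometry=geometry,
        frame_rate_hz=frame_rate_hz,
        meta={"seed": seed, "duration_s": duration_s},
    )
    return rec, cells


# ---------------------------------------------------------------------------
# pass-level generator (for statistics calibration)


def simulate_pass_table(
    n_per_direction: int = 40,
    orientation: str = VERTICAL,
    gain: float = 1.0,
    drift: DriftSpec | None = None,
    duration_s: float = 3600.0,
    noise: str = "poisson",
    spikes_per_pass: float = 5.0,
    noise_shape: float = 8.0,
    prev_next_gain: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-pass table of normalized rates for one field portion.

    Pass times are uniform over the session; directions are balanced with
    ``n_per_direction`` passes each. The normalized rate of a pass has
    mean ``gain_dir * drift(t) * prev/next gains`` (1 in the unpreferred
    direction under no drift). The default noise model is pure counting
    statistics — a pass collects Poisson(spikes_per_pass * mean) spikes
    against a fixed expectation of ``spikes_per_pass``, which is what a
    field with no behavioral modulation produces; ``noise='gamma'``
    (shape ``noise_shape``) adds over-dispersed pass-to-pass variability
    instead. Columns match what the GLM/Mann-Whitney layer expects:
    t, direction, prev_direction, next_direction, norm_rate.
    """
    rng = np.random.default_rng(seed)
    d_pos, d_neg = DIRECTION_PAIRS[orientation]
    n = 2 * n_per_direction
    t = np.sort(rng.uniform(0, duration_s, n))
    dirs = np.array([d_pos, d_neg] * n_per_direction, dtype=object)
    rng.shuffle(dirs)
    prev_dirs = np.array([d_pos if rng.random() < 0.5 else d_neg for _ in range(n)], dtype=object)
    next_dirs = np.array([d_pos if rng.random() < 0.5 else d_neg for _ in range(n)], dtype=object)
    drift = drift or DriftSpec()
    mean = np.ones(n)
    mean[dirs == d_pos] *= gain
    mean[prev_dirs == d_pos] *= prev_next_gain[0]
    mean[next_dirs == d_pos] *= prev_next_gain[1]
    mean = mean * drift.value(t, duration_s)
    if noise == "poisson":
        rates = rng.poisson(spikes_per_pass * mean) / spikes_per_pass
    elif noise == "gamma":
        rates = rng.gamma(noise_shape, mean / noise_shape)
    else:
        raise ConfigurationError(f"unknown noise model {noise!r}")
    df = pd.DataFrame(
        {
            "t": t,
            "direction": dirs,
            "prev_direction": prev_dirs,
            "next_direction": next_dirs,
            "norm_rate": rates,
        }
    )
    df.attrs["orientation"] = orientation
    df.attrs["portion_id"] = f"sim-{seed}"
    return df


def ground_truth_to_json(cells: list[GroundTruthCell]) -> list[dict]:
    return [asdict(c) for c in cells]
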