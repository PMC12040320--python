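"""Alley/field pass segmentation, direction labels, and normalized rates.

A pass is a run of consecutive in-boundary camera frames; exits shorter
than 2 s are merged into the same pass. A kept pass must contain at least
two interior points at depth >= 5% of the shorter of the boundary's
length (y-extent) or width (x-extent). Passes are labeled with the
overall direction of travel (entry end -> exit end); same-end passes are
turnarounds and marked incomplete. Rewarded and incomplete passes are
excluded from rate analyses, and a field needs at least two clean passes
in each direction to be analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DataError
from .maze import DIRECTION_PAIRS, HORIZONTAL, VERTICAL, MazeGeometry, Rect
from .ratemaps import PlaceField, RateMap


@dataclass
class PassParams:
    merge_gap_s: float = 2.0
    min_interior_points: int = 2
    depth_frac: float = 0.05


@dataclass
class Pass:
    """One filtered traversal through an alley or field portion."""

    boundary_id: str  # alley id or field portion id
    i0: int  # first frame index (inclusive)
    i1: int  # last frame index (inclusive)
    t_in: float
    t_out: float
    direction: str | None = None
    complete: bool = True
    rewarded: bool = False
    norm_rate: float | None = None
    raw_rate_hz: float | None = None
    alley_id: str | None = None
    frame_indices: np.ndarray = dc_field(default_factory=lambda: np.empty(0, int))


# ---------------------------------------------------------------------------
# segmentation


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def segment_passes(
    track: pd.DataFrame,
    in_boundary: np.ndarray,
    depth: np.ndarray,
    min_dim_cm: float,
    boundary_id: str = "",
    params: PassParams | None = None,
) -> list[Pass]:
    """Segment a boolean in-boundary trace into passes.

    ``depth`` gives, per frame, the distance (cm) from the position to
    the nearest boundary edge (only meaningful on in-boundary frames).
    Bouts separated by less than ``merge_gap_s`` are merged; a pass needs
    >= 2 in-boundary points of which >= 2 lie at depth >=
    ``depth_frac * min_dim_cm``.
    """
    params = params or PassParams()
    t = track["t"].to_numpy()
    runs = _runs(np.asarray(in_boundary, dtype=bool))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1]] < params.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = []
    need_depth = params.depth_frac * min_dim_cm
    for s, e in merged:
        frames = np.arange(s, e + 1)
        frames = frames[np.asarray(in_boundary, dtype=bool)[frames]]
        if frames.size < params.min_interior_points:
            continue
        if int((depth[frames] >= need_depth).sum()) < params.min_interior_points:
            continue
        out.append(
            Pass(
                boundary_id=boundary_id,
                i0=int(frames[0]),
                i1=int(frames[-1]),
                t_in=float(t[frames[0]]),
                t_out=float(t[frames[-1]]),
                frame_indices=frames,
            )
        )
    return out


def rect_depth(track: pd.DataFrame, rect: Rect) -> tuple[np.ndarray, np.ndarray]:
    """(in_boundary, depth) per frame for a rectangular boundary."""
    x = track["x"].to_numpy()
    y = track["y"].to_numpy()
    inside = (x >= rect.x0) & (x < rect.x1) & (y >= rect.y0) & (y < rect.y1)
    depth = np.minimum.reduce([x - rect.x0, rect.x1 - x, y - rect.y0, rect.y1 - y])
    return inside, np.where(inside, depth, -np.inf)


def bins_depth(
    track: pd.DataFrame, bins: np.ndarray, bin_size_cm: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """(in_boundary, depth, min_dim) for a bin-set boundary.

    Depth is the Euclidean distance to the nearest non-member ("border")
    bin center minus half a bin, clipped at 0. The minimum dimension is
    the shorter of the y-extent (length) and x-extent (width) of the set.
    """
    x = track["x"].to_numpy()
    y = track["y"].to_numpy()
    rows = np.floor(y / bin_size_cm).astype(int)
    cols = np.floor(x / bin_size_cm).astype(int)
    member = {tuple(b) for b in bins}
    inside = np.fromiter(
        ((r, c) in member for r, c in zip(rows, cols)), dtype=bool, count=len(rows)
    )
    # edge bins: member bins with a non-member 4-neighbor
    edge = []
    for r, c in member:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in member:
                edge.append((r, c))
                break
    edge_arr = np.array(edge, dtype=float) if edge else np.array(bins, dtype=float)
    ecx = (edge_arr[:, 1] + 0.5) * bin_size_cm
    ecy = (edge_arr[:, 0] + 0.5) * bin_size_cm
    depth = np.full(len(x), -np.inf)
    idx = np.nonzero(inside)[0]
    if idx.size:
        d2 = (x[idx, None] - ecx[None, :]) ** 2 + (y[idx, None] - ecy[None, :]) ** 2
        depth[idx] = np.sqrt(d2.min(axis=1))
    length = (bins[:, 0].max() - bins[:, 0].min() + 1) * bin_size_cm  # y-extent
    width = (bins[:, 1].max() - bins[:, 1].min() + 1) * bin_size_cm  # x-extent
    return inside, depth, float(min(length, width))


# ---------------------------------------------------------------------------
# direction labels


def label_direction(p: Pass, alley_id: str, geometry: MazeGeometry, track: pd.DataFrame) -> Pass:
    """Label a pass with travel direction from entry end to exit end.

    The entrances of an alley are its two short ends; entry/exit ends are
    the ends nearest the first/last frame. Same-end passes are
    turnarounds (complete=False, direction None).
    """
    alley = geometry.alley(alley_id)
    x = track["x"].to_numpy()
    y = track["y"].to_numpy()
    r = alley.rect
    if alley.orientation == VERTICAL:
        ends = {"north": r.y0, "south": r.y1}
        pos_in = y[p.i0]
        pos_out = y[p.i1]
    else:
        ends = {"west": r.x0, "east": r.x1}
        pos_in = x[p.i0]
        pos_out = x[p.i1]
    names = list(ends)
    entry = min(names, key=lambda nm: abs(pos_in - ends[nm]))
    exit_ = min(names, key=lambda nm: abs(pos_out - ends[nm]))
    p.alley_id = alley_id
    if entry == exit_:
        p.complete = False
        p.direction = None
        return p
    p.complete = True
    if alley.orientation == VERTICAL:
        p.direction = "S" if exit_ == "south" else "N"
    else:
        p.direction = "E" if exit_ == "east" else "W"
    return p


def alley_traversals(
    track: pd.DataFrame,
    geometry: MazeGeometry,
    rewards: list[tuple[float, str]] | None = None,
    params: PassParams | None = None,
) -> list[Pass]:
    """All labeled passes through every alley, time-ordered."""
    rewards = rewards or []
    out: list[Pass] = []
    for alley in geometry.alleys:
        inside, depth = rect_depth(track, alley.rect)
        min_dim = min(alley.rect.width, alley.rect.height)
        for p in segment_passes(track, inside, depth, min_dim, alley.id, params):
            label_direction(p, alley.id, geometry, track)
            p.rewarded = any(
                aid == alley.id and p.t_in <= t <= p.t_out for t, aid in rewards
            )
            out.append(p)
    out.sort(key=lambda p: p.t_in)
    return out


def filter_passes(
    passes: list[Pass],
    min_per_direction: int = 2,
    keep_rewarded: bool = False,
) -> tuple[list[Pass], bool]:
    """Drop incomplete (and, by default, rewarded) passes.

    Returns (kept passes, excluded flag); the flag is set when fewer than
    ``min_per_direction`` passes remain in either direction.
    """
    kept = [p for p in passes if p.complete and (keep_rewarded or not p.rewarded)]
    dirs = [p.direction for p in kept]
    counts = {d: dirs.count(d) for d in set(dirs)}
    excluded = len(counts) < 2 or min(counts.values()) < min_per_direction
    return kept, excluded


# ---------------------------------------------------------------------------
# normalized pass rates


def normalized_pass_rate(
    p: Pass,
    spike_times: np.ndarray,
    session_ratemap: RateMap,
    track: pd.DataFrame,
    restrict_bins: np.ndarray | None = None,
) -> tuple[float | None, float]:
    """Mean over visited bins of the single-pass rate divided by the
    session rate.

    The single-pass ratemap is the unsmoothed spikes/occupancy on bins
    visited during the pass (optionally restricted to a field portion's
    bins); bins with zero session rate are excluded from the mean.
    Returns (normalized rate or None if undefined, raw mean rate in Hz).
    """
    t = track["t"].to_numpy()
    bs = session_ratemap.bin_size_cm
    frames = p.frame_indices if p.frame_indices.size else np.arange(p.i0, p.i1 + 1)
    rows = np.floor(track["y"].to_numpy()[frames] / bs).astype(int)
    cols = np.floor(track["x"].to_numpy()[frames] / bs).astype(int)
    dt = float(np.median(np.diff(t)))

    if restrict_bins is not None:
        member = {tuple(b) for b in restrict_bins}
        sel = np.fromiter(
            ((r, c) in member for r, c in zip(rows, cols)), dtype=bool, count=len(rows)
        )
        frames, rows, cols = frames[sel], rows[sel], cols[sel]
    if frames.size == 0:
        return None, 0.0

    shape = session_ratemap.rate.shape
    occ = np.zeros(shape)
    np.add.at(occ, (rows, cols), dt)
    spike_times = np.asarray(spike_times, dtype=float)
    in_span = spike_times[(spike_times >= t[frames[0]]) & (spike_times <= t[frames[-1]] + dt)]
    sf = np.clip(np.searchsorted(t, in_span, side="right") - 1, 0, len(t) - 1)
    frame_set = set(frames.tolist())
    sf = np.array([i for i in sf if i in frame_set], dtype=int)
    counts = np.zeros(shape)
    if sf.size:
        srows = np.floor(track["y"].to_numpy()[sf] / bs).astype(int)
        scols = np.floor(track["x"].to_numpy()[sf] / bs).astype(int)
        np.add.at(counts, (srows, scols), 1.0)

    visited = occ > 0
    sess = session_ratemap.rate
    usable = visited & np.isfinite(sess) & (sess > 0)
    total_time = occ[visited].sum()
    raw = float(counts[visited].sum() / total_time) if total_time > 0 else 0.0
    if not usable.any():
        return None, raw
    pass_rate = counts[usable] / occ[usable]
    return float(np.mean(pass_rate / sess[usable])), raw


def build_field_pass_table(
    portion_id: str,
    orientation: str,
    portion_bins: np.ndarray,
    portion_alley_ids: list[str],
    travs: list[Pass],
    spike_times: np.ndarray,
    session_ratemap: RateMap,
    track: pd.DataFrame,
    keep_rewarded: bool = False,
    min_per_direction: int = 2,
    min_portion_points: int = 2,
) -> pd.DataFrame | None:
    """Per-pass table (t, direction, prev/next direction, norm_rate) for
    one orientation portion of a field.

    Field passes inherit direction/rewarded labels from the alley
    traversal they occur in; the previous/next directions come from the
    neighboring complete traversals in the session sequence. Returns
    None when the portion fails the two-passes-per-direction rule.
    """
    if orientation not in DIRECTION_PAIRS:
        raise DataError(f"portion orientation must be vertical/horizontal, got {orientation!r}")
    complete_seq = [p for p in travs if p.complete]
    rows = []
    member = {tuple(b) for b in portion_bins}
    bs = session_ratemap.bin_size_cm
    xg = track["x"].to_numpy()
    yg = track["y"].to_numpy()
    for k, p in enumerate(travs):
        if p.alley_id not in portion_alley_ids or not p.complete:
            continue
        if p.rewarded and not keep_rewarded:
            continue
        frames = p.frame_indices
        rr = np.floor(yg[frames] / bs).astype(int)
        cc = np.floor(xg[frames] / bs).astype(int)
        sel = np.fromiter(((r, c) in member for r, c in zip(rr, cc)), dtype=bool, count=len(rr))
        if int(sel.sum()) < min_portion_points:
            continue
        norm, raw = normalized_pass_rate(
            p, spike_times, session_ratemap, track, restrict_bins=portion_bins
        )
        if norm is None:
            continue
        seq_idx = complete_seq.index(p) if p in complete_seq else None
        prev_d = complete_seq[seq_idx - 1].direction if seq_idx and seq_idx > 0 else None
        next_d = (
            complete_seq[seq_idx + 1].direction
            if seq_idx is not None and seq_idx + 1 < len(complete_seq)
            else None
        )
        rows.append(
            {
                "t": p.t_in,
                "direction": p.direction,
                "prev_direction": prev_d,
                "next_direction": next_d,
                "norm_rate": norm,
                "raw_rate_hz": raw,
                "alley": p.alley_id,
                "rewarded": p.rewarded,
            }
        )
    if not rows:
        return None
    df = pd.DataFrame(rows).sort_values("t").reset_index(drop=True)
    d_pos, d_neg = DIRECTION_PAIRS[orientation]
    n_pos = int((df["direction"] == d_pos).sum())
    n_neg = int((df["direction"] == d_neg).sum())
    if min(n_pos, n_neg) < min_per_direction:
        return None
    df.attrs["portion_id"] = portion_id
    df.attrs["orientation"] = orientation
    df.attrs["alleys"] = list(portion_alley_ids)
    return df
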