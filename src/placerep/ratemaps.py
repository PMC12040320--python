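"""Occupancy-normalized ratemaps and place-field detection.

Detection follows a fixed sequence: speed filtering (1.5 cm/s), binning
(10 px = 2.1 cm), Gaussian smoothing (1.5 bins), peak finding with a 4-bin
(40 px) minimum separation, 8-connected border expansion down to 20% of
the peak, size (>=1% of walkable bins) and rate (>=1 Hz peak) thresholds,
iterative watershed splitting accepted only when both parts pass the
thresholds and the inter-part boundary stays at or below 75% of the larger
peak, and a post-watershed rule keeping fields whose 95th-percentile bin
rate is >=1 Hz. Putative interneurons (log10 mean rate > 0.6) are dropped
before detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import DataError
from .maze import HORIZONTAL, VERTICAL, MazeGeometry


@dataclass
class RateMapParams:
    bin_px: int = 10
    sigma_bins: float = 1.5
    speed_threshold_cm_s: float = 1.5
    min_peak_distance_bins: int = 4  # 40 px at 10 px/bin
    expansion_stop_frac: float = 0.20
    min_area_frac: float = 0.01
    min_peak_rate_hz: float = 1.0
    watershed_boundary_frac: float = 0.75
    post_watershed_pctl: float = 95.0
    post_watershed_rate_hz: float = 1.0
    interneuron_log10_rate: float = 0.6
    oversized_area_frac: float = 0.15  # QC flag only


@dataclass
class RateMap:
    """Binned, occupancy-normalized, smoothed firing-rate grid.

    ``rate`` is NaN on invalid bins (off-track or zero occupancy);
    ``occupancy`` is seconds per bin after speed filtering.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    bin_size_cm: float
    sigma_bins: float
    speed_threshold_cm_s: float
    unit_id: str = ""

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.rate)

    def mean_rate(self) -> float:
        """Occupancy-weighted session mean rate over valid bins."""
        v = self.valid
        occ = self.occupancy[v]
        return float(np.sum(self.rate[v] * occ) / np.sum(occ))


@dataclass
class PlaceField:
    unit_id: str
    field_id: str
    bins: np.ndarray  # (k, 2) [row, col]
    peak_bin: tuple[int, int]
    peak_rate_hz: float
    summed_rate: float
    region_memberships: list[str] = dc_field(default_factory=list)
    orientation_portions: dict[str, np.ndarray] = dc_field(default_factory=dict)
    portion_alleys: dict[str, list[str]] = dc_field(default_factory=dict)
    qc_flags: list[str] = dc_field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.bins[:, 0], self.bins[:, 1]] = True
        return m

    def centroid(self) -> tuple[float, float]:
        return (float(self.bins[:, 0].mean()), float(self.bins[:, 1].mean()))


# ---------------------------------------------------------------------------
# speed and ratemaps


def running_speed(track: pd.DataFrame, smooth_sigma_frames: float = 2.0) -> np.ndarray:
    """Speed (cm/s) by centered finite difference of smoothed position."""
    t = track["t"].to_numpy()
    if len(t) < 3:
        raise DataError("track too short to estimate speed")
    x = gaussian_filter1d(track["x"].to_numpy(), smooth_sigma_frames)
    y = gaussian_filter1d(track["y"].to_numpy(), smooth_sigma_frames)
    dx = np.gradient(x, t)
    dy = np.gradient(y, t)
    return np.hypot(dx, dy)


def compute_ratemap(
    track: pd.DataFrame,
    spike_times: np.ndarray,
    geometry: MazeGeometry,
    params: RateMapParams | None = None,
    unit_id: str = "",
    speed: np.ndarray | None = None,
) -> RateMap:
    """Speed-filtered, smoothed, occupancy-normalized 2D ratemap.

    Samples below the running-speed threshold are excluded from both the
    spike counts and the occupancy. Smoothing is applied to counts and
    occupancy separately before division, restricted to walkable bins.
    """
    params = params or RateMapParams()
    if speed is None:
        speed = running_speed(track)
    fast = speed >= params.speed_threshold_cm_s
    if not fast.any():
        raise DataError("no track samples at or above the speed threshold")

    t = track["t"].to_numpy()
    dt = float(np.median(np.diff(t)))
    bs = geometry.bin_size_cm
    shape = geometry.grid_shape
    rows = np.floor(track["y"].to_numpy() / bs).astype(int)
    cols = np.floor(track["x"].to_numpy() / bs).astype(int)
    inb = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    sel = fast & inb

    occ = np.zeros(shape)
    np.add.at(occ, (rows[sel], cols[sel]), dt)

    spike_times = np.asarray(spike_times, dtype=float)
    frame_idx = np.clip(np.searchsorted(t, spike_times, side="right") - 1, 0, len(t) - 1)
    keep = sel[frame_idx]
    counts = np.zeros(shape)
    np.add.at(counts, (rows[frame_idx[keep]], cols[frame_idx[keep]]), 1.0)

    walk = geometry.walkable_mask
    sm_occ = gaussian_filter(occ * walk, params.sigma_bins)
    sm_counts = gaussian_filter(counts * walk, params.sigma_bins)
    rate = np.full(shape, np.nan)
    valid = walk & (occ > 0) & (sm_occ > 0)
    rate[valid] = sm_counts[valid] / sm_occ[valid]
    return RateMap(
        rate=rate,
        occupancy=occ,
        bin_size_cm=bs,
        sigma_bins=params.sigma_bins,
        speed_threshold_cm_s=params.speed_threshold_cm_s,
        unit_id=unit_id,
    )


def exclude_interneurons(
    units: list[tuple[str, float]], log10_threshold: float = 0.6
) -> tuple[list[str], list[str]]:
    """Split units into (kept, excluded) by session mean rate.

    A unit is excluded when log10(mean rate) strictly exceeds the
    threshold (0.6, i.e. mean rate above ~3.98 Hz); the boundary case is
    kept.
    """
    kept, excluded = [], []
    for unit, mean_rate in units:
        if mean_rate <= 0:
            raise DataError(f"unit {unit!r} has non-positive mean rate {mean_rate}")
        (excluded if np.log10(mean_rate) > log10_threshold else kept).append(unit)
    return kept, excluded


# ---------------------------------------------------------------------------
# field detection


def _grow_region(rate: np.ndarray, peak: tuple[int, int], stop_frac: float,
                 claimed: np.ndarray) -> np.ndarray:
    """8-connected region growing; a bin joins while its rate is at or
    above ``stop_frac`` of the seed peak rate."""
    shape = rate.shape
    thresh = stop_frac * rate[peak]
    mask = np.zeros(shape, dtype=bool)
    stack = [peak]
    mask[peak] = True
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1] and not mask[rr, cc]:
                    v = rate[rr, cc]
                    if np.isfinite(v) and v >= thresh and not claimed[rr, cc]:
                        mask[rr, cc] = True
                        stack.append((rr, cc))
    return mask


def _passes_thresholds(rate, mask, n_walkable, params) -> bool:
    vals = rate[mask]
    if mask.sum() < params.min_area_frac * n_walkable:
        return False
    return float(np.nanmax(vals)) >= params.min_peak_rate_hz


def _in_field_maxima(rate, mask) -> list[tuple[int, int]]:
    """All local maxima inside a field, in deterministic order
    (descending rate, then row-major)."""
    masked = np.where(mask, np.nan_to_num(rate, nan=-np.inf), -np.inf)
    coords = peak_local_max(masked, min_distance=1, exclude_border=False)
    coords = [tuple(c) for c in coords if mask[tuple(c)]]
    coords.sort(key=lambda c: (-rate[c], c[0], c[1]))
    return coords


def _boundary_rate(rate, part_a, part_b) -> float:
    """Saddle height between two parts: the highest rate on bins of one
    part 8-adjacent to the other (the watershed ridge)."""
    from scipy.ndimage import binary_dilation

    st = np.ones((3, 3), dtype=bool)
    touch = (binary_dilation(part_a, st) & part_b) | (binary_dilation(part_b, st) & part_a)
    vals = rate[touch]
    vals = vals[np.isfinite(vals)]
    return float(vals.max()) if vals.size else np.inf


def _watershed_pair(rate, mask, p1, p2):
    """Two-marker watershed split of a field; returns (part1, part2)."""
    markers = np.zeros(rate.shape, dtype=int)
    markers[p1] = 1
    markers[p2] = 2
    filled = np.where(np.isnan(rate), 0.0, rate)
    labels = watershed(-filled, markers=markers, mask=mask, connectivity=2)
    return labels == 1, labels == 2


def _split_field(rate, mask, n_walkable, params):
    """Iterative watershed split; returns list of accepted sub-masks."""
    maxima = _in_field_maxima(rate, mask)
    if len(maxima) < 2:
        return [mask]
    for i in range(len(maxima)):
        for j in range(i + 1, len(maxima)):
            p1, p2 = maxima[i], maxima[j]
            part_a, part_b = _watershed_pair(rate, mask, p1, p2)
            if not part_a.any() or not part_b.any():
                continue
            if not (
                _passes_thresholds(rate, part_a, n_walkable, params)
                and _passes_thresholds(rate, part_b, n_walkable, params)
            ):
                continue
            larger_peak = max(rate[p1], rate[p2])
            if _boundary_rate(rate, part_a, part_b) > params.watershed_boundary_frac * larger_peak:
                continue
            return _split_field(rate, part_a, n_walkable, params) + _split_field(
                rate, part_b, n_walkable, params
            )
    return [mask]


def detect_fields(
    ratemap: RateMap,
    geometry: MazeGeometry,
    params: RateMapParams | None = None,
) -> list[PlaceField]:
    """Detect place fields on a ratemap (see module docstring for the
    rule sequence). Returns fields sorted by descending peak rate."""
    params = params or RateMapParams()
    rate = ratemap.rate
    n_walkable = geometry.n_bins_walkable
    occupied = ratemap.valid

    filled = np.where(occupied, rate, -np.inf)
    peaks = peak_local_max(
        filled,
        min_distance=params.min_peak_distance_bins,
        exclude_border=False,
        threshold_abs=1e-12,
    )
    peaks = [tuple(p) for p in peaks if occupied[tuple(p)]]
    peaks.sort(key=lambda p: (-rate[p], p[0], p[1]))

    claimed = np.zeros(rate.shape, dtype=bool)
    candidate_masks = []
    for p in peaks:
        if claimed[p]:
            continue
        mask = _grow_region(rate, p, params.expansion_stop_frac, claimed)
        if not _passes_thresholds(rate, mask, n_walkable, params):
            continue
        candidate_masks.append(mask)
        claimed |= mask

    fields: list[PlaceField] = []
    for mask in candidate_masks:
        for sub in _split_field(rate, mask, n_walkable, params):
            vals = rate[sub]
            if np.nanpercentile(vals, params.post_watershed_pctl) < params.post_watershed_rate_hz:
                continue
            bins = np.argwhere(sub)
            flat = np.nan_to_num(rate, nan=-np.inf).copy()
            flat[~sub] = -np.inf
            pk = np.unravel_index(np.argmax(flat), rate.shape)
            f = PlaceField(
                unit_id=ratemap.unit_id,
                field_id="",
                bins=bins,
                peak_bin=(int(pk[0]), int(pk[1])),
                peak_rate_hz=float(rate[pk]),
                summed_rate=float(np.nansum(vals)),
            )
            if len(bins) > params.oversized_area_frac * n_walkable:
                f.qc_flags.append("oversized")
            fields.append(f)
    fields.sort(key=lambda f: (-f.peak_rate_hz, f.peak_bin))
    for k, f in enumerate(fields):
        f.field_id = f"{ratemap.unit_id}-f{k}"
    return fields


# ---------------------------------------------------------------------------
# region assignment


def assign_regions(
    field: PlaceField,
    geometry: MazeGeometry,
    ratemap: RateMap,
    min_region_overlap: float = 0.30,
    min_rate_share: float = 0.25,
) -> PlaceField:
    """Assign a field to maze regions and build orientation portions.

    A field is present in a region when it covers >= 30% of the region's
    bins; when several regions qualify, each is kept only if its bins
    carry >= 25% of the field's summed rate. Alley memberships are then
    regrouped into vertical/horizontal orientation portions (the bins of
    the field inside alleys of that orientation).
    """
    fmask = field.mask(geometry.grid_shape)
    rate = ratemap.rate
    candidates: list[tuple[str, np.ndarray, float]] = []
    for rid in geometry.region_ids:
        rb = geometry.region_bins(rid)
        if len(rb) == 0:
            continue
        overlap = fmask[rb[:, 0], rb[:, 1]]
        if overlap.sum() >= min_region_overlap * len(rb):
            ob = rb[overlap]
            share = float(np.nansum(rate[ob[:, 0], ob[:, 1]])) / max(field.summed_rate, 1e-12)
            candidates.append((rid, ob, share))

    if len(candidates) > 1:
        kept = [c for c in candidates if c[2] >= min_rate_share]
        if not kept:  # no region carries enough rate: flag, keep best
            field.qc_flags.append("no_dominant_region")
            kept = [max(candidates, key=lambda c: c[2])]
        candidates = kept
    if not candidates:
        field.qc_flags.append("no_qualifying_region")
        field.region_memberships = []
        field.orientation_portions = {}
        return field

    field.region_memberships = [c[0] for c in candidates]
    portions: dict[str, list[np.ndarray]] = {}
    portion_alleys: dict[str, list[str]] = {}
    for rid, ob, _ in candidates:
        ori = geometry.orientation_of(rid)
        if ori is None:
            continue
        portions.setdefault(ori, []).append(ob)
        portion_alleys.setdefault(ori, []).append(rid)
    field.orientation_portions = {
        ori: np.unique(np.vstack(blocks), axis=0) for ori, blocks in portions.items()
    }
    field.portion_alleys = portion_alleys
    return field


def field_orientation_labels(fields: list[PlaceField], geometry: MazeGeometry) -> list[str]:
    """One location-type label per (field, membership type): 'vertical',
    'horizontal' or 'intersection', from region memberships."""
    labels = []
    for f in fields:
        types = set()
        for rid in f.region_memberships:
            ori = geometry.orientation_of(rid)
            types.add(ori if ori is not None else "intersection")
        # a field overlapping both orientations contributes each type once
        labels.extend(sorted(t for t in types))
    return labels


def primary_location_type(field: PlaceField, geometry: MazeGeometry) -> str | None:
    """Dominant location type of a field: the type (vertical/horizontal/
    intersection) whose member regions hold the most field bins."""
    if not field.region_memberships:
        return None
    counts: dict[str, int] = {}
    fmask_bins = {tuple(b) for b in field.bins}
    for rid in field.region_memberships:
        ori = geometry.orientation_of(rid)
        t = ori if ori is not None else "intersection"
        rb = geometry.region_bins(rid)
        k = sum(1 for b in rb if tuple(b) in fmask_bins)
        counts[t] = counts.get(t, 0) + k
    order = {VERTICAL: 0, HORIZONTAL: 1, "intersection": 2}
    return max(sorted(counts, key=lambda t: order[t]), key=lambda t: counts[t])
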