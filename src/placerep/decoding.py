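"""Population decoding of travel direction and position.

Direction: a random forest classifies the direction of each alley pass
from the population vector of per-unit normalized pass rates, separately
for vertical and horizontal alleys; the out-of-bag (OOB) accuracy is the
performance metric. Significance is conjunctive: the empirical OOB must
exceed the 95th percentile of BOTH a label-shuffle null and a naive
classifier that guesses labels in proportion to their session-wide
sampling frequencies (so class imbalance alone cannot pass).

Position: spike trains are convolved with a Gaussian kernel (sigma = 25
camera frames by default) into firing-probability features, standardized,
and fed to a linear regression predicting x and y separately. Train and
test epochs alternate (8000/1000 samples) with 500-sample buffers so the
convolution cannot leak across the split; the window boundaries are
circularly rotated to estimate performance variability, and the null
circularly shifts position against the features. The temporal variant
trains on one 10000-sample window and tests on all other windows,
summarizing performance decay with Spearman correlations before/after
the training window.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, DataError


@dataclass
class DirectionDecodeResult:
    orientation: str
    oob_accuracy: float
    shuffle_null: np.ndarray
    naive_null: np.ndarray
    n_passes: int
    n_units: int

    @property
    def significant(self) -> bool:
        """Conjunctive rule: above the 95th percentile of both nulls."""
        return self.oob_accuracy > np.percentile(self.shuffle_null, 95) and (
            self.oob_accuracy > np.percentile(self.naive_null, 95)
        )


@dataclass
class PositionDecodeResult:
    train_r2: np.ndarray  # (n_rotations, 2) for x and y
    test_r2: np.ndarray
    shuffle_95th: float
    sigma_frames: float
    window: dict = dc_field(default_factory=dict)

    def median_test_r2(self) -> float:
        return float(np.median(self.test_r2))


# ---------------------------------------------------------------------------
# direction


def naive_classifier_null(labels, n_iter: int = 1000, seed: int = 0) -> np.ndarray:
    """Accuracy distribution of a classifier guessing each trial's label
    in proportion to the empirical label frequencies."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise DataError("need >= 1 label")
    classes, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    rng = np.random.default_rng(seed)
    acc = np.empty(n_iter)
    for i in range(n_iter):
        guess = rng.choice(classes, size=labels.size, p=p)
        acc[i] = np.mean(guess == labels)
    return acc


def rf_direction_decode(
    features: np.ndarray,
    labels,
    orientation: str = "",
    n_trees: int = 1000,
    n_shuffles: int = 200,
    n_naive: int = 1000,
    seed: int = 0,
) -> DirectionDecodeResult:
    """Random-forest direction decoding from per-pass population vectors.

    ``features`` is (n_passes, n_units) of normalized pass rates;
    ``labels`` the pass directions. OOB accuracy is the metric; the
    shuffle null refits the forest on permuted labels.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if len(np.unique(y)) < 2:
        raise DataError("need >= 2 direction classes to decode")
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError("features must be (n_passes, n_units) aligned with labels")
    rng = np.random.default_rng(seed)

    def oob(Xm, ym, rs):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=True,
            random_state=rs,
            n_jobs=1,
        )
        rf.fit(Xm, ym.astype(str))
        return float(rf.oob_score_)

    emp = oob(X, y, int(rng.integers(2**31)))
    shuffle_null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffle_null[s] = oob(X, rng.permutation(y), int(rng.integers(2**31)))
    naive = naive_classifier_null(y, n_iter=n_naive, seed=int(rng.integers(2**31)))
    return DirectionDecodeResult(
        orientation=orientation,
        oob_accuracy=emp,
        shuffle_null=shuffle_null,
        naive_null=naive,
        n_passes=X.shape[0],
        n_units=X.shape[1],
    )


# ---------------------------------------------------------------------------
# position


def spike_probability_features(
    spikes: dict[str, np.ndarray],
    t: np.ndarray,
    sigma_frames: float = 25.0,
) -> np.ndarray:
    """Per-frame Gaussian-convolved spike counts, one column per unit.

    The kernel is truncated at 4 sigma; frames are camera frames.
    """
    n = len(t)
    units = sorted(spikes)
    feats = np.zeros((n, len(units)))
    dt = float(np.median(np.diff(t)))
    for k, u in enumerate(units):
        st = np.asarray(spikes[u], dtype=float)
        idx = np.clip(np.searchsorted(t, st, side="right") - 1, 0, n - 1)
        counts = np.bincount(idx, minlength=n).astype(float)
        feats[:, k] = gaussian_filter1d(counts, sigma_frames, truncate=4.0)
    return feats


def _window_masks(n: int, train: int, test: int, buffer: int, offset: int):
    """Alternating train/test masks with buffers, circular at offset."""
    cycle = train + buffer + test + buffer
    if n < cycle:
        raise ConfigurationError(
            f"session of {n} frames shorter than one train/test cycle ({cycle})"
        )
    pos = (np.arange(n) - offset) % cycle
    train_mask = pos < train
    test_mask = (pos >= train + buffer) & (pos < train + buffer + test)
    return train_mask, test_mask


def linear_position_decode(
    spikes: dict[str, np.ndarray],
    track: pd.DataFrame,
    sigma_frames: float = 25.0,
    train: int = 8000,
    test: int = 1000,
    buffer: int = 500,
    n_rotations: int = 1000,
    n_shuffles: int = 100,
    min_shift_s: float = 10.0,
    frame_rate_hz: float = 30.0,
    seed: int = 0,
) -> PositionDecodeResult:
    """Linear regression position decoding with rotating windows.

    Per rotation, the train/test window pattern is circularly shifted by
    a uniform offset; r^2 is computed on pooled train and pooled test
    frames for x and y separately. The null circularly shifts the
    position trace against the features (shift uniform in
    [min_shift_s, duration - min_shift_s]) and records the median test
    r^2 per shift; the 95th percentile of that distribution is reported.
    """
    t = track["t"].to_numpy()
    n = len(t)
    feats = StandardScaler().fit_transform(spike_probability_features(spikes, t, sigma_frames))
    pos = np.column_stack([track["x"].to_numpy(), track["y"].to_numpy()])
    rng = np.random.default_rng(seed)

    def decode(features, target, offsets):
        out = np.empty((len(offsets), 2, 2))  # rotation x (train/test) x (x/y)
        for i, off in enumerate(offsets):
            tr, te = _window_masks(n, train, test, buffer, off)
            reg = LinearRegression().fit(features[tr], target[tr])
            pred_tr = reg.predict(features[tr])
            pred_te = reg.predict(features[te])
            for d in range(2):
                out[i, 0, d] = r2_score(target[tr][:, d], pred_tr[:, d])
                out[i, 1, d] = r2_score(target[te][:, d], pred_te[:, d])
        return out

    cycle = train + buffer + test + buffer
    offsets = rng.integers(0, cycle, size=n_rotations)
    perf = decode(feats, pos, offsets)

    min_shift = int(min_shift_s * frame_rate_hz)
    null_meds = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shift = int(rng.integers(min_shift, n - min_shift))
        rolled = np.roll(pos, shift, axis=0)
        off = int(rng.integers(0, cycle))
        res = decode(feats, rolled, [off])
        null_meds[s] = np.median(res[0, 1, :])
    return PositionDecodeResult(
        train_r2=perf[:, 0, :],
        test_r2=perf[:, 1, :],
        shuffle_95th=float(np.percentile(null_meds, 95)) if n_shuffles else np.nan,
        sigma_frames=sigma_frames,
        window={"train": train, "test": test, "buffer": buffer},
    )


def sliding_window_decode(
    spikes: dict[str, np.ndarray],
    track: pd.DataFrame,
    sigma_frames: float = 25.0,
    train: int = 10000,
    test: int = 1000,
    buffer: int = 1000,
) -> dict:
    """Temporal decoding: train on each window, test on all others.

    The session is partitioned into consecutive blocks of ``train``
    frames separated by ``buffer``; within the remainder, consecutive
    ``test`` windows are evaluated. Returns per-training-window test
    performance against window time, and Spearman correlations of
    performance vs time before (expected positive under drift) and after
    (expected negative) the training window.
    """
    t = track["t"].to_numpy()
    n = len(t)
    if n < train + 2 * (test + buffer):
        raise ConfigurationError("session too short for sliding-window decoding")
    feats = StandardScaler().fit_transform(spike_probability_features(spikes, t, sigma_frames))
    pos = np.column_stack([track["x"].to_numpy(), track["y"].to_numpy()])

    train_starts = list(range(0, n - train + 1, train + buffer))
    results = []
    for ts in train_starts:
        tr = np.zeros(n, dtype=bool)
        tr[ts : ts + train] = True
        reg = LinearRegression().fit(feats[tr], pos[tr])
        wins = []
        s = 0
        while s + test <= n:
            if s + test <= ts - buffer or s >= ts + train + buffer:
                sel = np.zeros(n, dtype=bool)
                sel[s : s + test] = True
                pred = reg.predict(feats[sel])
                r2 = np.mean(
                    [r2_score(pos[sel][:, d], pred[:, d]) for d in range(2)]
                )
                wins.append((s + test / 2, float(r2)))
            s += test
        times = np.array([w[0] for w in wins])
        perfs = np.array([w[1] for w in wins])
        pre = times < ts
        post = times > ts + train
        rho_pre = (
            float(stats.spearmanr(times[pre], perfs[pre])[0]) if pre.sum() >= 2 else np.nan
        )
        rho_post = (
            float(stats.spearmanr(times[post], perfs[post])[0]) if post.sum() >= 2 else np.nan
        )
        results.append(
            {
                "train_start": ts,
                "window_times": times,
                "window_r2": perfs,
                "spearman_pre": rho_pre,
                "spearman_post": rho_post,
            }
        )
    return {
        "per_window": results,
        "median_spearman_pre": float(
            np.nanmedian([r["spearman_pre"] for r in results])
        ),
        "median_spearman_post": float(
            np.nanmedian([r["spearman_post"] for r in results])
        ),
    }


def subgroup_position_compare(
    spikes: dict[str, np.ndarray],
    track: pd.DataFrame,
    repeating_ids: list[str],
    non_repeating_ids: list[str],
    n_rotations: int = 20,
    n_downsamples: int = 10,
    seed: int = 0,
    **decode_kwargs,
) -> dict:
    """Repeating-minus-non-repeating position decoding difference.

    The larger group is downsampled to the smaller group's size
    ``n_downsamples`` times per rotation; mean test r^2 per group is
    differenced (repeating - non-repeating).
    """
    if not repeating_ids or not non_repeating_ids:
        raise ConfigurationError("both unit groups must be non-empty")
    rng = np.random.default_rng(seed)
    k = min(len(repeating_ids), len(non_repeating_ids))
    diffs = []
    for _ in range(n_downsamples):
        rep = list(rng.choice(repeating_ids, size=k, replace=False))
        non = list(rng.choice(non_repeating_ids, size=k, replace=False))
        # both groups share the rotation offsets, so identical groups
        # give exactly zero difference
        draw_seed = int(rng.integers(2**31))
        res_r = linear_position_decode(
            {u: spikes[u] for u in rep},
            track,
            n_rotations=n_rotations,
            n_shuffles=0,
            seed=draw_seed,
            **decode_kwargs,
        )
        res_n = linear_position_decode(
            {u: spikes[u] for u in non},
            track,
            n_rotations=n_rotations,
            n_shuffles=0,
            seed=draw_seed,
            **decode_kwargs,
        )
        diffs.append(res_r.median_test_r2() - res_n.median_test_r2())
    return {"differences": np.array(diffs), "mean_difference": float(np.mean(diffs))}
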