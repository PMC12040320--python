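"""Repeating-cell classification and the orientation alignment score.

A repeating cell has two or more fields in a common location type
(vertical alley, horizontal alley, or intersection); violations of the
pattern (e.g. an extra field elsewhere) are not penalized.

The orientation alignment score (OAS) quantifies, for a multi-fielded
cell, how aligned its alley fields are relative to how aligned they
could possibly be. With n alley fields and a majority orientation count
m, the alignment ratio is m/n; this ratio is located in the ordered list
of achievable ratios for n fields (k/n for k from ceil(n/2) to n) and
its 1-based rank is divided by the list length. A cell with 6 fields, 4
of them vertical, has ratio 4/6 ~ 0.67, list [0.5, 0.67, 0.83, 1.0],
and OAS 2/4 = 0.5. The population test compares the mean OAS of
multi-fielded cells against a shuffle that permutes the pooled
orientation labels across cells while preserving each cell's field
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil

import numpy as np

from .errors import DataError
from .maze import HORIZONTAL, VERTICAL

INTERSECTION = "intersection"
LOCATION_TYPES = (VERTICAL, HORIZONTAL, INTERSECTION)


@dataclass
class CellFieldSummary:
    unit_id: str
    orientations: list[str]  # per-field location-type labels
    repeating: bool
    repeat_types: list[str]
    n_alley_fields: int
    alignment_ratio: float | None  # None when < 2 alley fields
    oas: float | None
    orientation_bias: float | None


def classify_repeating(orientations: list[str]) -> tuple[bool, list[str]]:
    """True iff >= 2 fields share a location type; also the types that
    repeat."""
    for o in orientations:
        if o not in LOCATION_TYPES:
            raise DataError(f"unknown location type {o!r}")
    types = [t for t in LOCATION_TYPES if orientations.count(t) >= 2]
    return bool(types), types


def possible_alignment_ratios(n_fields: int) -> list[Fraction]:
    """Achievable majority ratios k/n, k from ceil(n/2) to n, ascending.

    Even n bottoms out at 1/2; odd n at ((n+1)/2)/n.
    """
    if n_fields < 2:
        raise DataError("alignment ratios are defined for >= 2 alley fields")
    return [Fraction(k, n_fields) for k in range(ceil(n_fields / 2), n_fields + 1)]


def alignment_ratio(orientations: list[str]) -> Fraction:
    """Majority-orientation count over total, for alley fields only."""
    alley = [o for o in orientations if o in (VERTICAL, HORIZONTAL)]
    if len(alley) < 2:
        raise DataError("alignment ratio needs >= 2 alley fields")
    n_v = alley.count(VERTICAL)
    return Fraction(max(n_v, len(alley) - n_v), len(alley))


def oas(orientations: list[str]) -> float:
    """Orientation alignment score in (0, 1] (see module docstring)."""
    alley = [o for o in orientations if o in (VERTICAL, HORIZONTAL)]
    if len(alley) < 2:
        raise DataError("OAS is defined for cells with >= 2 alley fields")
    ratios = possible_alignment_ratios(len(alley))
    r = alignment_ratio(alley)
    rank = ratios.index(r) + 1  # exact rational comparison, no rounding
    return rank / len(ratios)


def orientation_bias_score(orientations: list[str]) -> float:
    """Max fields sharing an orientation over total alley fields."""
    alley = [o for o in orientations if o in (VERTICAL, HORIZONTAL)]
    if not alley:
        raise DataError("orientation bias needs >= 1 alley field")
    n_v = alley.count(VERTICAL)
    return max(n_v, len(alley) - n_v) / len(alley)


def summarize_cell(unit_id: str, orientations: list[str]) -> CellFieldSummary:
    repeating, types = classify_repeating(orientations)
    alley = [o for o in orientations if o in (VERTICAL, HORIZONTAL)]
    multi = len(alley) >= 2
    return CellFieldSummary(
        unit_id=unit_id,
        orientations=list(orientations),
        repeating=repeating,
        repeat_types=types,
        n_alley_fields=len(alley),
        alignment_ratio=float(alignment_ratio(orientations)) if multi else None,
        oas=oas(orientations) if multi else None,
        orientation_bias=orientation_bias_score(orientations) if alley else None,
    )


def oas_population_test(
    cell_orientations: dict[str, list[str]],
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Mean OAS of multi-fielded cells against an orientation-shuffle null.

    The shuffle pools all alley-field orientation labels, permutes them,
    and re-deals to cells preserving each cell's alley-field count, so
    the total and per-cell field counts are exactly conserved. The mean
    null OAS per shuffle forms the null distribution; the empirical mean
    is compared one-sided to its (1 - alpha) percentile.
    """
    counts = {}
    labels = []
    for unit, oris in cell_orientations.items():
        alley = [o for o in oris if o in (VERTICAL, HORIZONTAL)]
        if len(alley) >= 2:
            counts[unit] = len(alley)
            labels.extend(alley)
    if not counts:
        raise DataError("no multi-fielded cell with >= 2 alley fields")
    observed = float(np.mean([oas([o for o in cell_orientations[u]]) for u in counts]))

    rng = np.random.default_rng(seed)
    labels = np.array(labels, dtype=object)
    null = np.empty(n_shuffles)
    sizes = list(counts.values())
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        vals, pos = [], 0
        for k in sizes:
            vals.append(oas(list(perm[pos : pos + k])))
            pos += k
        null[s] = np.mean(vals)
    pct = float(np.percentile(null, 100 * (1 - alpha))) if n_shuffles else np.nan
    p = float((np.sum(null >= observed) + 1) / (n_shuffles + 1)) if n_shuffles else np.nan
    return {
        "mean_oas": observed,
        "null": null,
        "null_95th": pct,
        "p": p,
        "significant": bool(n_shuffles) and observed > pct,
        "n_cells": len(counts),
    }
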