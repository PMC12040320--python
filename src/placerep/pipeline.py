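"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis chain: ratemaps -> interneuron
exclusion -> field detection -> region assignment -> alley traversals ->
per-portion pass tables -> repetition scoring -> directionality ->
field pairs -> temporal dynamics -> (optional) decoding. Every stage is
deterministic given the config seeds; results are plain dict/DataFrame
bundles that serialize to CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import directionality as dirmod
from . import pairs as pairmod
from . import repetition as repmod
from . import temporal as tempmod
from .maze import HORIZONTAL, VERTICAL, MazeGeometry
from .ratemaps import (
    PlaceField,
    RateMap,
    RateMapParams,
    assign_regions,
    compute_ratemap,
    detect_fields,
    exclude_interneurons,
    primary_location_type,
    running_speed,
)
from .synthetic import SessionRecording
from .traversals import alley_traversals, build_field_pass_table


@dataclass
class PipelineConfig:
    ratemap: RateMapParams = dc_field(default_factory=RateMapParams)
    keep_rewarded: bool = False
    min_passes_per_direction: int = 2
    spline_df: int = 3
    alpha_direction: float = 0.05 / 2  # Bonferroni over two orientations
    alpha_time: float = tempmod.TIME_GLM_ALPHA
    n_oas_shuffles: int = 1000
    n_corridor_shuffles: int = 1000
    n_pv_windows: int = 6
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def run_pipeline(session: SessionRecording, config: PipelineConfig | None = None) -> dict:
    """Run detection and statistics on a session; returns a results dict.

    Keys: ratemaps, fields, cell_summaries, oas_test, pass_tables,
    directionality, pairs (DataFrame), pair_stats, time_glm, pv.
    """
    config = config or PipelineConfig()
    geom = session.geometry
    track = session.track_frame()
    speed = running_speed(track)
    duration = session.duration_s

    # -- ratemaps and interneuron exclusion -----------------------------
    ratemaps: dict[str, RateMap] = {}
    mean_rates = []
    for unit, st in session.spikes.items():
        rm = compute_ratemap(track, st, geom, config.ratemap, unit_id=unit, speed=speed)
        ratemaps[unit] = rm
        mean_rates.append((unit, max(len(st) / duration, 1e-9)))
    kept_units, excluded_units = exclude_interneurons(
        mean_rates, config.ratemap.interneuron_log10_rate
    )

    # -- field detection -------------------------------------------------
    fields: list[PlaceField] = []
    for unit in kept_units:
        for f in detect_fields(ratemaps[unit], geom, config.ratemap):
            assign_regions(f, geom, ratemaps[unit])
            fields.append(f)

    # -- repetition -------------------------------------------------------
    cell_oris: dict[str, list[str]] = {}
    for f in fields:
        loc = primary_location_type(f, geom)
        if loc is not None:
            cell_oris.setdefault(f.unit_id, []).append(loc)
    summaries = [repmod.summarize_cell(u, o) for u, o in sorted(cell_oris.items())]
    oas_test = None
    if any(s.oas is not None for s in summaries):
        oas_test = repmod.oas_population_test(
            cell_oris, n_shuffles=config.n_oas_shuffles, seed=config.seed
        )

    # -- traversals and pass tables --------------------------------------
    travs = alley_traversals(track, geom, session.rewards)
    pass_tables: dict[str, pd.DataFrame] = {}
    portion_meta: dict[str, dict] = {}
    for f in fields:
        for ori, bins in f.orientation_portions.items():
            pid = f"{f.field_id}-{ori[0]}"
            tb = build_field_pass_table(
                pid,
                ori,
                bins,
                f.portion_alleys[ori],
                travs,
                session.spikes[f.unit_id],
                ratemaps[f.unit_id],
                track,
                keep_rewarded=config.keep_rewarded,
                min_per_direction=config.min_passes_per_direction,
            )
            if tb is not None:
                pass_tables[pid] = tb
                portion_meta[pid] = {
                    "unit": f.unit_id,
                    "field": f.field_id,
                    "alleys": f.portion_alleys[ori],
                    "centroid": f.centroid(),
                    "repeating": None,
                }

    # -- directionality ---------------------------------------------------
    dir_results = {
        pid: dirmod.analyze_field_portion(tb, config.spline_df)
        for pid, tb in pass_tables.items()
    }

    # -- pairs ------------------------------------------------------------
    records = []
    for pid, tb in pass_tables.items():
        res = dir_results[pid]
        if res.di is None:
            continue
        meta = portion_meta[pid]
        from .maze import POSITIVE_DIRECTION

        n_pos = int((tb["direction"] == POSITIVE_DIRECTION[tb.attrs["orientation"]]).sum())
        records.append(
            pairmod.FieldRecord(
                unit_id=meta["unit"],
                portion_id=pid,
                orientation=tb.attrs["orientation"],
                alley_id=meta["alleys"][0],
                di=res.di,
                n_pos=n_pos,
                n_neg=len(tb) - n_pos,
                centroid_bins=meta["centroid"],
                trajectory_means=pairmod.trajectory_means_from_table(tb),
            )
        )
    pairs = pairmod.build_field_pairs(records, geom)
    pair_stats: dict = {}
    same = [p for p in pairs if p.same_corridor]
    diff = [p for p in pairs if not p.same_corridor]
    if len(same) >= 3 and len(diff) >= 3:
        pair_stats["same"] = pairmod.pair_direction_correlation(same)
        pair_stats["different"] = pairmod.pair_direction_correlation(diff)
        pair_stats["shuffle"] = pairmod.corridor_shuffle_test(
            pairs, n_shuffles=config.n_corridor_shuffles, seed=config.seed
        )

    # -- temporal ---------------------------------------------------------
    time_glm = {}
    for pid, tb in pass_tables.items():
        try:
            time_glm[pid] = tempmod.glm_time_lrt(tb, config.spline_df)
        except Exception:
            continue
    unit_tables = {}
    for pid, tb in pass_tables.items():
        unit_tables.setdefault(portion_meta[pid]["unit"], []).append(tb)
    merged = {
        u: pd.concat(ts, ignore_index=True) for u, ts in unit_tables.items()
    }
    pv = None
    if len(merged) >= 2:
        pv = tempmod.pv_window_correlation(merged, duration, config.n_pv_windows)

    return {
        "ratemaps": ratemaps,
        "kept_units": kept_units,
        "excluded_units": excluded_units,
        "fields": fields,
        "cell_summaries": summaries,
        "oas_test": oas_test,
        "traversals": travs,
        "pass_tables": pass_tables,
        "directionality": dir_results,
        "pairs": pairmod.pairs_to_frame(pairs),
        "pair_objects": pairs,
        "pair_stats": pair_stats,
        "time_glm": time_glm,
        "pv": pv,
        "config": config,
    }


def write_results(results: dict, outdir: str | Path) -> None:
    """Write the report files of a results bundle as CSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "unit": s.unit_id,
            "n_fields": len(s.orientations),
            "n_vertical": s.orientations.count(VERTICAL),
            "n_horizontal": s.orientations.count(HORIZONTAL),
            "alignment_ratio": s.alignment_ratio,
            "oas": s.oas,
            "repeating": s.repeating,
        }
        for s in results["cell_summaries"]
    ]
    pd.DataFrame(rows).to_csv(outdir / "cells.csv", index=False)

    drows = []
    for pid, r in results["directionality"].items():
        drows.append(
            {
                "portion": pid,
                "orientation": r.orientation,
                "n_passes": r.n_passes,
                "U": r.u_stat,
                "p_mw": r.p_mw,
                "abs_delta": r.abs_delta,
                "di": r.di,
                "lrt_stat": r.glm.lrt_stat if r.glm else None,
                "p_lrt": r.glm.p if r.glm else None,
                "rmse_base": r.glm.rmse_base if r.glm else None,
                "rmse_dir": r.glm.rmse_alt if r.glm else None,
                "flags": ";".join(r.flags),
            }
        )
    pd.DataFrame(drows).to_csv(outdir / "directionality.csv", index=False)
    results["pairs"].to_csv(outdir / "pairs.csv", index=False)

    summary = {
        "n_units_kept": len(results["kept_units"]),
        "n_units_excluded": results["excluded_units"],
        "n_fields": len(results["fields"]),
        "n_pass_tables": len(results["pass_tables"]),
    }
    if results["oas_test"] is not None:
        ot = results["oas_test"]
        summary["oas"] = {
            "mean": ot["mean_oas"],
            "null_95th": ot["null_95th"],
            "significant": ot["significant"],
        }
    if results["pv"] is not None:
        summary["pv_lag_slope"] = results["pv"]["slope"]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
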