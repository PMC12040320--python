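"""Reading and writing session recordings as plain CSV/JSON files.

A session on disk is: track.csv (t,x,y), spikes.csv (unit,t),
rewards.csv (t,alley), geometry.json, and provenance.json (seed and
parameter metadata). Everything is diffable text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .maze import MazeGeometry
from .synthetic import SessionRecording


def write_session(session: SessionRecording, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session.track_frame().to_csv(outdir / "track.csv", index=False)
    rows = [
        {"unit": u, "t": t} for u in sorted(session.spikes) for t in session.spikes[u]
    ]
    pd.DataFrame(rows, columns=["unit", "t"]).to_csv(outdir / "spikes.csv", index=False)
    pd.DataFrame(session.rewards, columns=["t", "alley"]).to_csv(
        outdir / "rewards.csv", index=False
    )
    (outdir / "geometry.json").write_text(session.geometry.to_json())
    (outdir / "provenance.json").write_text(
        json.dumps({"frame_rate_hz": session.frame_rate_hz, **session.meta}, indent=1)
    )


def read_session(indir: str | Path, allow_missing_rewards: bool = False) -> SessionRecording:
    indir = Path(indir)
    track_path = indir / "track.csv"
    if not track_path.exists():
        raise DataError(f"missing {track_path}")
    track = pd.read_csv(track_path)
    for col in ("t", "x", "y"):
        if col not in track.columns:
            raise DataError(f"{track_path}: missing column {col!r}")
    t = track["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{track_path}: timestamps not strictly increasing")

    geometry = MazeGeometry.from_json((indir / "geometry.json").read_text())

    spikes_df = pd.read_csv(indir / "spikes.csv")
    spikes: dict[str, np.ndarray] = {}
    if len(spikes_df):
        for unit, grp in spikes_df.groupby("unit"):
            st = np.sort(grp["t"].to_numpy(float))
            if st.size and (st[0] < t[0] or st[-1] > t[-1] + 1.0):
                raise DataError(f"unit {unit!r}: spike outside track time span")
            spikes[str(unit)] = st

    rewards_path = indir / "rewards.csv"
    if rewards_path.exists():
        rw = pd.read_csv(rewards_path)
        rewards = [(float(r.t), str(r.alley)) for r in rw.itertuples()]
    elif allow_missing_rewards:
        rewards = []
    else:
        raise DataError(f"missing {rewards_path} (pass allow_missing_rewards to accept)")

    prov = {}
    if (indir / "provenance.json").exists():
        prov = json.loads((indir / "provenance.json").read_text())
    frame_rate = prov.pop("frame_rate_hz", 1.0 / float(np.median(np.diff(t))))
    return SessionRecording(
        t=t,
        x=track["x"].to_numpy(float),
        y=track["y"].to_numpy(float),
        spikes=spikes,
        rewards=rewards,
        geometry=geometry,
        frame_rate_hz=float(frame_rate),
        meta=prov,
    )
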