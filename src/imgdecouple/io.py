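"""File formats: per-event CSV + JSON sidecar, feature tables, manifests.

Event CSV columns: ``time_s,lin_x_g,lin_y_g,lin_z_g,gyro_x_rads,
gyro_y_rads,gyro_z_rads`` with a strictly increasing uniform time column
(t = 0 at the trigger).  The JSON sidecar carries identifiers, sampling
metadata, sensor orientation, lever arm, proximity readings, the quality
grade and the coupling label.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .features import ALL_FEATURES, FeatureVector
from .signals import ChannelSignal, ProximityTrace, RawImgRecord, UNKNOWN
from .simulate import SimulatedEvent

EVENT_COLUMNS = ["time_s", "lin_x_g", "lin_y_g", "lin_z_g",
                 "gyro_x_rads", "gyro_y_rads", "gyro_z_rads"]


def write_event(record: RawImgRecord, csv_path) -> None:
    """Write one event as CSV plus a ``.json`` sidecar next to it."""
    csv_path = Path(csv_path)
    t = record.lin[0].time_s
    df = pd.DataFrame({
        "time_s": t,
        "lin_x_g": record.lin[0].samples,
        "lin_y_g": record.lin[1].samples,
        "lin_z_g": record.lin[2].samples,
        "gyro_x_rads": record.gyro[0].samples,
        "gyro_y_rads": record.gyro[1].samples,
        "gyro_z_rads": record.gyro[2].samples,
    })
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "event_id": record.event_id,
        "device_id": record.device_id,
        "sample_rate_hz": record.sample_rate,
        "trigger_index": record.trigger_index,
        "orientation": record.orientation.ravel().tolist(),
        "lever_arm_m": record.lever_arm_r.tolist(),
        "quality": record.quality,
        "label": record.label,
        "proximity": None,
    }
    if record.proximity is not None:
        p = record.proximity
        sidecar["proximity"] = {"pre": p.pre, "mid": p.mid, "post": p.post,
                                "series": p.series}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_event(csv_path) -> RawImgRecord:
    """Read an event CSV and its JSON sidecar back into a record."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"event CSV missing columns: {missing}")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    fs = float(meta["sample_rate_hz"])
    ti = int(meta["trigger_index"])
    dt = np.diff(df["time_s"].to_numpy())
    if np.any(dt <= 0) or not np.allclose(dt, 1.0 / fs, rtol=1e-6):
        raise AlignmentError("time column must increase uniformly at 1/fs")
    chans = [ChannelSignal(df[c].to_numpy(), fs, ti) for c in EVENT_COLUMNS[1:]]
    prox = None
    if meta.get("proximity"):
        p = meta["proximity"]
        prox = ProximityTrace(pre=p["pre"], post=p["post"], mid=p.get("mid"),
                              series=[tuple(s) for s in p["series"]] if p.get("series") else None)
    return RawImgRecord(
        lin=tuple(chans[:3]), gyro=tuple(chans[3:]),
        event_id=meta["event_id"], device_id=meta.get("device_id", ""),
        orientation=np.asarray(meta["orientation"], dtype=float).reshape(3, 3),
        lever_arm_r=np.asarray(meta["lever_arm_m"], dtype=float),
        proximity=prox, quality=meta.get("quality"),
        label=meta.get("label") or UNKNOWN,
    )


def write_dataset(events: List[SimulatedEvent], out_dir) -> Path:
    """Write event CSVs/sidecars plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ev in events:
        write_event(ev.record, out_dir / f"{ev.record.event_id}.csv")
        s = ev.scenario
        rows.append({
            "event_id": ev.record.event_id,
            "label": ev.record.label,
            "peak_lin_g": s.peak_lin_g,
            "lin_duration_ms": s.lin_duration_ms,
            "dir_x": s.direction[0], "dir_y": s.direction[1], "dir_z": s.direction[2],
            "ang_vel_peak": s.ang_vel_peak,
            "artifact_onset_ms": s.artifact.onset_ms if s.artifact else "",
            "artifact_freq_hz": s.artifact.freq_hz if s.artifact else "",
            "artifact_amplitude_ratio": s.artifact.amplitude_ratio if s.artifact else "",
            "seed": ev.seed,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(in_dir) -> List[RawImgRecord]:
    """Read every event CSV (with sidecar) in a directory, sorted by id."""
    in_dir = Path(in_dir)
    records = []
    for csv_path in sorted(in_dir.glob("*.csv")):
        if csv_path.name == "manifest.csv" or not csv_path.with_suffix(".json").exists():
            continue
        records.append(read_event(csv_path))
    return records


def write_feature_table(fvs: List[FeatureVector], path,
                        labels: Optional[List[str]] = None) -> None:
    """Feature CSV: ``event_id,f1,...,f7,label`` (empty when not computed)."""
    rows = []
    for i, fv in enumerate(fvs):
        row = {"event_id": fv.event_id}
        for fid in ALL_FEATURES:
            v = getattr(fv, fid)
            row[fid] = v if v is not None else ""
        row["label"] = labels[i] if labels else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"event_id": str})
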