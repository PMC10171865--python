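"""Readers/writers for label-image series and long-format measurement tables.

On-disk layout of a series directory (also accepted: a bare multi-page
TIFF of labels):

    labels.tif            multi-page integer TIFF, one page per frame
    channel_<name>.tif    optional co-registered channels, same pages
    manifest.json         frame indices, channel names, calibration

Measurement tables are long-format CSV (UTF-8, comma, "." decimal, header
mandatory): one row per (entity, frame, variable, channel) with columns
``entity_kind, entity_id, frame, variable, value, channel, embryo_id,
genotype``. Junction ids are serialized as "a|b" with a < b.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datamodel import (
    Calibration,
    CellTrack,
    FormatError,
    Frame,
    IntegrityError,
    JunctionTrack,
    SegmentedFrameSeries,
    junction_key,
)

__all__ = [
    "read_series",
    "write_series",
    "write_tables",
    "read_tables",
    "tracks_to_table",
]

TABLE_COLUMNS = [
    "entity_kind",
    "entity_id",
    "frame",
    "variable",
    "value",
    "channel",
    "embryo_id",
    "genotype",
]


def _junction_id_str(jid: tuple[int, int]) -> str:
    a, b = junction_key(*jid)
    return f"{a}|{b}"


def parse_junction_id(s: str) -> tuple[int, int]:
    a, b = s.split("|")
    return junction_key(int(a), int(b))


def write_series(series: SegmentedFrameSeries, path: str | Path) -> Path:
    """Write a series directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels = np.stack([fr.labels for fr in series.frames])
    tifffile.imwrite(
        path / "labels.tif", labels.astype(np.int32), photometric="minisblack"
    )
    for name in series.channel_names:
        stack = np.stack([fr.channels[name] for fr in series.frames])
        tifffile.imwrite(
            path / f"channel_{name}.tif",
            stack.astype(np.float32),
            photometric="minisblack",
        )
    manifest = {
        "frame_indices": [fr.frame_index for fr in series.frames],
        "channels": series.channel_names,
        "calibration": asdict(series.calibration),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_series(
    path: str | Path, calibration: Calibration | None = None
) -> SegmentedFrameSeries:
    """Read a series directory or a bare multi-page label TIFF.

    A calibration given explicitly overrides the manifest's. Labels are
    left untouched (no relabelling).
    """
    path = Path(path)
    if path.is_dir():
        manifest = json.loads((path / "manifest.json").read_text())
        labels = tifffile.imread(path / "labels.tif")
        frame_indices = manifest["frame_indices"]
        channel_names = manifest.get("channels", [])
        if calibration is None:
            calibration = Calibration(**manifest["calibration"])
        channels = {
            name: tifffile.imread(path / f"channel_{name}.tif")
            for name in channel_names
        }
    else:
        if calibration is None:
            raise FormatError("a bare TIFF requires an explicit calibration")
        labels = tifffile.imread(path)
        frame_indices = list(range(labels.shape[0] if labels.ndim == 3 else 1))
        channels = {}

    if labels.ndim == 2:
        labels = labels[None]
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError(f"label data must be integer, got {labels.dtype}")
    if len(frame_indices) != labels.shape[0]:
        raise FormatError(
            f"manifest lists {len(frame_indices)} frames, TIFF has {labels.shape[0]}"
        )
    if any(b <= a for a, b in zip(frame_indices, frame_indices[1:])):
        raise FormatError(f"non-monotone frame indices: {frame_indices}")
    for name, stack in channels.items():
        if stack.ndim == 2:
            channels[name] = stack = stack[None]
        if stack.shape != labels.shape:
            raise FormatError(
                f"channel {name!r} shape {stack.shape} != labels {labels.shape}"
            )

    frames = [
        Frame(
            frame_index=fi,
            labels=labels[i],
            channels={name: channels[name][i] for name in channels},
        )
        for i, fi in enumerate(frame_indices)
    ]
    return SegmentedFrameSeries(frames=frames, calibration=calibration)


def _check_unique(df: pd.DataFrame, what: str) -> None:
    keys = ["entity_kind", "entity_id", "frame", "variable", "channel"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise IntegrityError(f"duplicate {what} table key: {first}")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise IntegrityError(f"non-finite values in {what} table")


def tracks_to_table(
    cell_tracks: dict[int, CellTrack] | None = None,
    junction_tracks: dict[tuple[int, int], JunctionTrack] | None = None,
    embryo_id: str = "e0",
    genotype: str = "",
) -> pd.DataFrame:
    """Flatten tracks into the long measurement-table format."""
    rows: list[tuple] = []
    for tr in (cell_tracks or {}).values():
        for f in tr.frames:
            r = tr.records[f]
            for var, val in [
                ("area_um2", r.area_um2),
                ("centroid_x_um", r.centroid_um[0]),
                ("centroid_y_um", r.centroid_um[1]),
                ("elongation_index", r.elongation_index),
                ("elongation_angle_deg", r.elongation_angle_deg),
                ("junction_count", float(r.junction_count)),
                ("border_touching", float(r.border_touching)),
            ]:
                rows.append(("cell", str(tr.cell_id), f, var, val, "", embryo_id, genotype))
    for jt in (junction_tracks or {}).values():
        jid = _junction_id_str(jt.junction_id)
        for f in jt.frames:
            r = jt.records[f]
            rows.append(("junction", jid, f, "length_um", r.length_um, "", embryo_id, genotype))
            rows.append(
                ("junction", jid, f, "orientation_deg", r.orientation_deg, "", embryo_id, genotype)
            )
            rows.append(
                ("junction", jid, f, "pixel_count", float(r.pixel_count), "", embryo_id, genotype)
            )
            for chan, val in r.intensity.items():
                rows.append(
                    ("junction", jid, f, "mean_intensity", val, chan, embryo_id, genotype)
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_tables(
    cell_tracks: dict[int, CellTrack],
    junction_tracks: dict[tuple[int, int], JunctionTrack],
    path: str | Path,
    calibration: Calibration | None = None,
    embryo_id: str = "e0",
    genotype: str = "",
) -> dict[str, Path]:
    """Emit cells.csv / junctions.csv plus a calibration JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table = tracks_to_table(cell_tracks, junction_tracks, embryo_id, genotype)
    cells = table[table.entity_kind == "cell"]
    junctions = table[table.entity_kind == "junction"]
    _check_unique(cells, "cell")
    _check_unique(junctions, "junction")
    out = {
        "cells": path / "cells.csv",
        "junctions": path / "junctions.csv",
    }
    cells.to_csv(out["cells"], index=False)
    junctions.to_csv(out["junctions"], index=False)
    if calibration is not None:
        sidecar = path / "calibration.json"
        sidecar.write_text(json.dumps(asdict(calibration), indent=2))
        out["calibration"] = sidecar
    return out


def read_tables(path: str | Path) -> tuple[pd.DataFrame, Calibration | None]:
    """Read cells.csv + junctions.csv back into one long table."""
    path = Path(path)
    parts = []
    for name in ("cells.csv", "junctions.csv"):
        f = path / name
        if f.exists():
            df = pd.read_csv(f, dtype={"entity_id": str}, keep_default_na=False)
            if not df.empty:
                parts.append(df)
    if not parts:
        raise FileNotFoundError(f"no cells.csv/junctions.csv under {path}")
    table = pd.concat(parts, ignore_index=True)
    _check_unique(table, "measurement")
    calib = None
    sidecar = path / "calibration.json"
    if sidecar.exists():
        calib = Calibration(**json.loads(sidecar.read_text()))
    return table, calib
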