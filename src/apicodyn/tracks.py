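"""Assemble per-cell and per-junction time series from a frame series.

Tracking itself is assumed done upstream (stable labels); this module
only collects per-frame measurements into contiguous tracks, bridging
one-frame dropouts by linear interpolation (flagged ``bridged``) and
splitting on longer gaps with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import (
    CellRecord,
    CellTrack,
    JunctionRecord,
    JunctionTrack,
    SegmentedFrameSeries,
)
from .geometry import extract_cells, extract_junctions, measure_junction_intensity

__all__ = ["build_tracks"]


def _segments(frames: list[int]) -> list[list[int]]:
    """Split a sorted frame list into runs separated by gaps >= 2 frames
    (one-frame gaps stay within a run; they are bridged later)."""
    runs: list[list[int]] = [[frames[0]]]
    for f in frames[1:]:
        if f - runs[-1][-1] <= 2:
            runs[-1].append(f)
        else:
            runs.append([f])
    return runs


def _bridge_cell(rec0: CellRecord, rec1: CellRecord, frame: int) -> CellRecord:
    t = (frame - rec0.frame) / (rec1.frame - rec0.frame)
    lerp = lambda a, b: a + t * (b - a)
    return CellRecord(
        frame=frame,
        area_um2=lerp(rec0.area_um2, rec1.area_um2),
        centroid_um=(
            lerp(rec0.centroid_um[0], rec1.centroid_um[0]),
            lerp(rec0.centroid_um[1], rec1.centroid_um[1]),
        ),
        elongation_index=lerp(rec0.elongation_index, rec1.elongation_index),
        elongation_angle_deg=rec0.elongation_angle_deg,
        neighbor_ids=rec0.neighbor_ids,
        junction_count=rec0.junction_count,
        border_touching=rec0.border_touching or rec1.border_touching,
        bridged=True,
    )


def _bridge_junction(
    rec0: JunctionRecord, rec1: JunctionRecord, frame: int
) -> JunctionRecord:
    t = (frame - rec0.frame) / (rec1.frame - rec0.frame)
    lerp = lambda a, b: a + t * (b - a)
    return JunctionRecord(
        frame=frame,
        length_um=lerp(rec0.length_um, rec1.length_um),
        orientation_deg=rec0.orientation_deg,
        pixel_count=rec0.pixel_count,
        intensity={
            ch: lerp(v, rec1.intensity.get(ch, v)) for ch, v in rec0.intensity.items()
        },
        bridged=True,
    )


def build_tracks(
    series: SegmentedFrameSeries,
    min_junction_pixels: int = 2,
    intensity_width_px: int = 3,
) -> tuple[dict[int, CellTrack], dict[tuple[int, int], JunctionTrack]]:
    """Measure every frame and assemble tracks.

    Returns (cell tracks keyed by label, junction tracks keyed by the
    unordered member pair). A junction track persists while its member
    pair shares a boundary. Cells reappearing after a gap of two or more
    frames are split: the first segment keeps the label as its track id,
    later segments get fresh ids above the maximum label (warned). For a
    junction pair with several segments the longest is kept (warned).
    """
    cell_obs: dict[int, dict[int, CellRecord]] = {}
    junc_obs: dict[tuple[int, int], dict[int, JunctionRecord]] = {}
    for frame in series.frames:
        f = frame.frame_index
        for cg in extract_cells(frame, series.calibration, min_junction_pixels):
            cell_obs.setdefault(cg.cell_id, {})[f] = CellRecord(
                frame=f,
                area_um2=cg.area_um2,
                centroid_um=cg.centroid_um,
                elongation_index=cg.elongation_index,
                elongation_angle_deg=cg.elongation_angle_deg,
                neighbor_ids=cg.neighbor_ids,
                junction_count=cg.junction_count,
                border_touching=cg.border_touching,
            )
        for jg in extract_junctions(frame, series.calibration, min_junction_pixels):
            intens = {
                ch: measure_junction_intensity(frame, ch, jg, intensity_width_px)
                for ch in frame.channels
            }
            junc_obs.setdefault(jg.members, {})[f] = JunctionRecord(
                frame=f,
                length_um=jg.length_um,
                orientation_deg=jg.orientation_deg,
                pixel_count=jg.pixel_count,
                intensity=intens,
            )

    max_label = max(cell_obs, default=0)
    next_id = max_label + 1
    cell_tracks: dict[int, CellTrack] = {}
    for cid in sorted(cell_obs):
        obs = cell_obs[cid]
        runs = _segments(sorted(obs))
        if len(runs) > 1:
            warnings.warn(
                f"cell {cid} reappears after a >=2-frame gap; "
                f"split into {len(runs)} tracks",
                stacklevel=2,
            )
        for k, run in enumerate(runs):
            records: dict[int, CellRecord] = {}
            for f0, f1 in zip(run, run[1:]):
                records[f0] = obs[f0]
                if f1 - f0 == 2:  # one-frame dropout: bridge it
                    records[f0 + 1] = _bridge_cell(obs[f0], obs[f1], f0 + 1)
            records[run[-1]] = obs[run[-1]]
            tid = cid if k == 0 else next_id
            if k > 0:
                next_id += 1
            cell_tracks[tid] = CellTrack(cell_id=tid, records=records)

    junction_tracks: dict[tuple[int, int], JunctionTrack] = {}
    for jid in sorted(junc_obs):
        obs = junc_obs[jid]
        runs = _segments(sorted(obs))
        if len(runs) > 1:
            warnings.warn(
                f"junction {jid} has {len(runs)} presence segments; "
                "keeping the longest",
                stacklevel=2,
            )
            runs = [max(runs, key=len)]
        run = runs[0]
        records: dict[int, JunctionRecord] = {}
        for f0, f1 in zip(run, run[1:]):
            records[f0] = obs[f0]
            if f1 - f0 == 2:
                records[f0 + 1] = _bridge_junction(obs[f0], obs[f1], f0 + 1)
        records[run[-1]] = obs[run[-1]]
        junction_tracks[jid] = JunctionTrack(junction_id=jid, records=records)
    return cell_tracks, junction_tracks
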