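"""Ingression events: detection, isolated/clustered classification with
the 30-min adjacency rule, streak-domain ingression rates, and track
displacement summaries.

An ingression event is a tracked cell whose label disappears before the
final movie frame while not touching the image border. Two events join
one cluster when the cells were adjacent neighbors and their ingression
times differ by less than the 30-min window ("clustered"); connected
components under this rule define clusters, size 1 being isolated. The
boundary is strict: events exactly 30 min apart are isolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datamodel import Calibration, CellTrack

__all__ = [
    "IngressionEvent",
    "detect_ingressions",
    "classify_event_clusters",
    "ingression_rate_per_hour",
    "RateSummary",
    "track_displacement",
]


@dataclass
class IngressionEvent:
    cell_id: int
    frame: int                      # last present frame
    time_min: float
    last_centroid_um: tuple[float, float]
    in_streak_domain: bool | None = None
    cluster_id: int | None = None
    cluster_size: int = 1


def _in_streak(x_um: float, calibration: Calibration) -> bool | None:
    if calibration.midline_x_um is None:
        return None
    return abs(x_um - calibration.midline_x_um) <= calibration.streak_halfwidth_um


def detect_ingressions(
    cell_tracks: dict[int, CellTrack],
    series_last_frame: int,
    calibration: Calibration,
) -> list[IngressionEvent]:
    """One event per track that ends by label disappearance before the
    final frame with its last record off the image border; tracks running
    to the movie end or exiting at the border are censored."""
    events: list[IngressionEvent] = []
    for cid in sorted(cell_tracks):
        tr = cell_tracks[cid]
        last = tr.last_frame
        if last >= series_last_frame:
            continue
        rec = tr.records[last]
        if rec.border_touching:
            continue
        events.append(
            IngressionEvent(
                cell_id=cid,
                frame=last,
                time_min=calibration.time_min(last),
                last_centroid_um=rec.centroid_um,
                in_streak_domain=_in_streak(rec.centroid_um[0], calibration),
            )
        )
    return events


def _were_adjacent(
    tracks: dict[int, CellTrack], a: int, b: int, mode: str
) -> bool:
    ta, tb = tracks.get(a), tracks.get(b)
    if ta is None or tb is None:
        return False
    common = sorted(set(ta.records) & set(tb.records), reverse=True)
    if not common:
        return False
    if mode == "last_common":
        common = common[:1]
    return any(b in ta.records[f].neighbor_ids for f in common)


def classify_event_clusters(
    events: list[IngressionEvent],
    cell_tracks: dict[int, CellTrack],
    window_min: float = 30.0,
    adjacency: str = "ever",
) -> list[IngressionEvent]:
    """Assign cluster ids/sizes in place (and return the events).

    Two events are linked when |Δt| < window (strict, so neighbors
    ingressing >= 30 min apart stay isolated) and the cells were adjacent
    neighbors. Adjacency defaults to "ever" — the cells shared a junction
    at some frame where both existed — because a fully constricted cell
    routinely loses its last-frame contacts during the final collapse;
    "last_common" restricts the check to the latest frame both cells
    exist. Cluster membership is the transitive closure; classification
    is order-independent.
    """
    if adjacency not in ("ever", "last_common"):
        raise ValueError(f"adjacency must be 'ever' or 'last_common', got {adjacency!r}")
    g = nx.Graph()
    g.add_nodes_from(ev.cell_id for ev in events)
    by_id = {ev.cell_id: ev for ev in events}
    evs = sorted(events, key=lambda e: (e.time_min, e.cell_id))
    for i, ea in enumerate(evs):
        for eb in evs[i + 1 :]:
            if eb.time_min - ea.time_min >= window_min:
                break
            if _were_adjacent(cell_tracks, ea.cell_id, eb.cell_id, adjacency):
                g.add_edge(ea.cell_id, eb.cell_id)
    for k, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: min(c))
    ):
        for cid in comp:
            by_id[cid].cluster_id = k
            by_id[cid].cluster_size = len(comp)
    return events


def cluster_size_fractions(events: list[IngressionEvent]) -> dict[int, float]:
    """Fraction of ingressing cells in clusters of each size."""
    if not events:
        return {}
    sizes = np.array([ev.cluster_size for ev in events])
    return {int(s): float((sizes == s).mean()) for s in np.unique(sizes)}


@dataclass
class RateSummary:
    mean: float
    sem: float
    per_window: list[float]
    n_windows: int


def ingression_rate_per_hour(
    events: list[IngressionEvent],
    cell_tracks: dict[int, CellTrack],
    calibration: Calibration,
    series_last_frame: int,
    domain: str = "streak",
    window_min: float = 60.0,
) -> RateSummary:
    """Fraction of domain cells ingressing per hour.

    For each sliding 60-min window (stepping one frame at a time), the
    rate is (# events in the window and domain) / (# cells present in the
    domain at the window start); reported as mean ± s.e.m. across
    windows. The streak domain is |x - midline| <= half-width (~40 µm
    total by default).
    """
    if domain not in ("streak", "all"):
        raise ValueError(f"domain must be 'streak' or 'all', got {domain!r}")
    if domain == "streak" and calibration.midline_x_um is None:
        raise ValueError("streak domain requires calibration.midline_x_um")
    dt = calibration.frame_interval_min
    total_min = series_last_frame * dt
    if total_min < window_min:
        raise ValueError(
            f"need >= {window_min} min of observation, have {total_min}"
        )

    def in_domain(x: float) -> bool:
        return domain == "all" or bool(_in_streak(x, calibration))

    rates: list[float] = []
    f = 0
    while f * dt + window_min <= total_min + 1e-9:
        t0 = f * dt
        n_present = 0
        for tr in cell_tracks.values():
            rec = tr.records.get(f)
            if rec is not None and in_domain(rec.centroid_um[0]):
                n_present += 1
        n_events = sum(
            1
            for ev in events
            if t0 <= ev.time_min < t0 + window_min and in_domain(ev.last_centroid_um[0])
        )
        if n_present > 0:
            rates.append(n_events / n_present)
        f += 1
    arr = np.array(rates)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return RateSummary(
        mean=float(arr.mean()), sem=sem, per_window=rates, n_windows=len(arr)
    )


def track_displacement(
    cell_tracks: dict[int, CellTrack], calibration: Calibration
) -> dict[int, dict[str, float]]:
    """Per-cell path length, net displacement, and midline convergence
    (positive = moved toward the midline) in µm."""
    out: dict[int, dict[str, float]] = {}
    for cid, tr in cell_tracks.items():
        frames = tr.frames
        if len(frames) < 2:
            continue
        pts = np.array([tr.records[f].centroid_um for f in frames])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        net = float(np.linalg.norm(pts[-1] - pts[0]))
        conv = np.nan
        if calibration.midline_x_um is not None:
            m = calibration.midline_x_um
            conv = float(abs(pts[0, 0] - m) - abs(pts[-1, 0] - m))
        out[cid] = {
            "path_length_um": float(steps.sum()),
            "net_displacement_um": net,
            "convergence_um": conv,
        }
    return out
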