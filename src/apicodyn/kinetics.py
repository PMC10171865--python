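"""Constriction kinetics: rate series, pulse detection, period detection,
phase statistics and junction-shrinkage asynchrony.

The signed rate convention is positive = contraction/shrinkage:
rate(t) = (value(t-1) - value(t)) / frame interval, so an area series in
µm² over 5-min frames yields rates in µm²/min. A constriction pulse is a
maximal run of frames whose contraction rate exceeds a reference
threshold built as mean + k·SD of pooled reference-cell contraction rates
(k = 1 by default; on gastrulating epiblast this reference construction
gives ~0.7 µm²/min). Pulse magnitude is the maximum rate within the
pulse. Rates are not smoothed; smoothing is used only inside
constriction-period detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CellTrack, JunctionTrack

__all__ = [
    "RateSeries",
    "PulseThreshold",
    "Pulse",
    "ConstrictionAnnotation",
    "rate_series",
    "reference_threshold",
    "pool_contraction_rates",
    "detect_pulses",
    "detect_constriction_period",
    "phase_time_fractions",
    "PhaseFractions",
    "annotate_constriction",
    "junction_shrinkage_by_phase",
    "junction_length_correlation",
]


@dataclass
class RateSeries:
    """Signed per-frame change series; rate[i] belongs to frame
    first_frame + 1 + i (the frame the step ends on)."""

    entity_id: object
    first_frame: int
    rates: np.ndarray
    frame_interval_min: float
    unit: str = "um2_per_min"

    @property
    def frames(self) -> np.ndarray:
        return self.first_frame + 1 + np.arange(len(self.rates))

    def __len__(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class PulseThreshold:
    reference_mean: float
    reference_sd: float
    k: float = 1.0

    @property
    def threshold(self) -> float:
        return self.reference_mean + self.k * self.reference_sd


@dataclass
class Pulse:
    start_frame: int
    end_frame: int  # inclusive
    magnitude: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class PhaseFractions:
    contracting: float
    expanding: float
    stable: float
    mean_contraction_rate: float
    mean_expansion_rate: float


@dataclass
class ConstrictionAnnotation:
    cell_id: int
    constriction_start_frame: int | None
    ingression_frame: int | None
    pulses: list[Pulse] = field(default_factory=list)
    stable_frames: list[int] = field(default_factory=list)
    mean_constriction_rate: float = float("nan")
    fractions: PhaseFractions | None = None
    censored: bool = False
    unclassifiable: bool = False


def rate_series(
    values: np.ndarray | list[float],
    frame_interval_min: float,
    entity_id: object = None,
    first_frame: int = 0,
    unit: str = "um2_per_min",
) -> RateSeries:
    """Signed rate series: rate(t) = (value(t-1) - value(t)) / Δt."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"need >= 2 frames for a rate series, got {values.size}")
    rates = (values[:-1] - values[1:]) / frame_interval_min
    return RateSeries(
        entity_id=entity_id,
        first_frame=first_frame,
        rates=rates,
        frame_interval_min=frame_interval_min,
        unit=unit,
    )


def pool_contraction_rates(series: list[RateSeries]) -> np.ndarray:
    """Pooled positive (contraction) rates across reference cells."""
    pool = np.concatenate([s.rates for s in series]) if series else np.array([])
    return pool[pool > 0]


def reference_threshold(reference_rates: np.ndarray, k: float = 1.0) -> PulseThreshold:
    """Pulse threshold = mean + k × sample SD of pooled reference
    contraction rates (k = 1 reproduces the mean-plus-one-SD rule)."""
    r = np.asarray(reference_rates, dtype=float)
    if r.size == 0:
        raise ValueError("empty reference rate pool")
    if r.size < 10:
        raise ValueError(f"need >= 10 reference rate samples, got {r.size}")
    return PulseThreshold(
        reference_mean=float(r.mean()),
        reference_sd=float(r.std(ddof=1)),
        k=k,
    )


def detect_pulses(
    rates: RateSeries | np.ndarray,
    threshold: PulseThreshold | float,
    merge_gap: int = 0,
) -> list[Pulse]:
    """Maximal runs of frames with rate > threshold; runs separated by at
    most ``merge_gap`` sub-threshold frames are merged. Magnitude is the
    maximum rate within the pulse."""
    if isinstance(rates, RateSeries):
        arr = rates.rates
        offset = rates.first_frame + 1
    else:
        arr = np.asarray(rates, dtype=float)
        offset = 0
    thr = threshold.threshold if isinstance(threshold, PulseThreshold) else float(threshold)
    above = arr > thr
    pulses: list[Pulse] = []
    i = 0
    n = len(arr)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if pulses and (i - (pulses[-1].end_frame - offset) - 1) <= merge_gap:
            prev = pulses[-1]
            prev.end_frame = j + offset
            prev.magnitude = float(
                max(prev.magnitude, arr[i : j + 1].max())
            )
        else:
            pulses.append(
                Pulse(
                    start_frame=i + offset,
                    end_frame=j + offset,
                    magnitude=float(arr[i : j + 1].max()),
                )
            )
        i = j + 1
    return pulses


def detect_constriction_period(
    cell_track: CellTrack,
    series_last_frame: int,
    smoothing_window: int = 3,
    reexpansion_tol_um2: float = 0.5,
    min_total_decline_frac: float = 0.5,
) -> ConstrictionAnnotation:
    """Locate the constriction period of a cell that ends by ingression.

    The ingression frame is the track's last present frame; the start is
    the latest frame s such that the moving-average area never rises
    above area(s) + tolerance within [s, end] and the total decline over
    [s, end] is at least ``min_total_decline_frac`` × area(s). Tracks
    ending at the movie end or while touching the border are censored.
    """
    frames, areas = cell_track.area_series()
    last = int(frames[-1])
    censored = last >= series_last_frame or cell_track.records[last].border_touching
    ann = ConstrictionAnnotation(
        cell_id=cell_track.cell_id,
        constriction_start_frame=None,
        ingression_frame=None if censored else last,
        censored=censored,
    )
    if censored:
        return ann
    w = max(int(smoothing_window), 1)
    pad = w // 2
    padded = np.concatenate([np.full(pad, areas[0]), areas, np.full(pad, areas[-1])])
    ma = np.convolve(padded, np.ones(w) / w, mode="valid")
    # suffix maximum of the smoothed area
    suffix_max = np.maximum.accumulate(ma[::-1])[::-1]
    peak = float(ma.max())
    start = None
    for i in range(len(frames) - 2, -1, -1):
        at_peak = ma[i] >= peak - reexpansion_tol_um2
        no_reexpansion = suffix_max[i] <= ma[i] + reexpansion_tol_um2
        declines = (areas[i] - areas[-1]) >= min_total_decline_frac * areas[i]
        if at_peak and no_reexpansion and declines:
            start = int(frames[i])
            break  # latest qualifying frame
    if start is None:
        ann.unclassifiable = True
    else:
        ann.constriction_start_frame = start
    return ann


def phase_time_fractions(
    rates: RateSeries | np.ndarray,
    window: tuple[int, int] | None = None,
    epsilon: float = 0.0,
) -> PhaseFractions:
    """Time fractions spent contracting (> ε), expanding (< -ε) and stable
    (|rate| <= ε), with the mean contraction and expansion rates. The
    window is an inclusive frame range filtering a RateSeries."""
    if isinstance(rates, RateSeries):
        arr = rates.rates
        if window is not None:
            sel = (rates.frames >= window[0]) & (rates.frames <= window[1])
            arr = arr[sel]
    else:
        arr = np.asarray(rates, dtype=float)
        if window is not None:
            arr = arr[window[0] : window[1] + 1]
    if arr.size == 0:
        raise ValueError("empty rate window")
    contracting = arr > epsilon
    expanding = arr < -epsilon
    stable = ~contracting & ~expanding
    pos = arr[contracting]
    neg = arr[expanding]
    return PhaseFractions(
        contracting=float(contracting.mean()),
        expanding=float(expanding.mean()),
        stable=float(stable.mean()),
        mean_contraction_rate=float(pos.mean()) if pos.size else 0.0,
        mean_expansion_rate=float(np.abs(neg).mean()) if neg.size else 0.0,
    )


def annotate_constriction(
    cell_track: CellTrack,
    threshold: PulseThreshold | float,
    series_last_frame: int,
    frame_interval_min: float,
    merge_gap: int = 0,
    **period_kwargs,
) -> ConstrictionAnnotation:
    """Full annotation: period bounds, pulses, stable frames, mean
    constriction rate ((area(start) - area(end)) / duration) and phase
    fractions over the period."""
    ann = detect_constriction_period(cell_track, series_last_frame, **period_kwargs)
    if ann.censored or ann.unclassifiable:
        return ann
    frames, areas = cell_track.area_series()
    sel = frames >= ann.constriction_start_frame
    rs = rate_series(
        areas[sel],
        frame_interval_min,
        entity_id=cell_track.cell_id,
        first_frame=ann.constriction_start_frame,
    )
    ann.pulses = detect_pulses(rs, threshold, merge_gap)
    pulse_frames = {
        f for p in ann.pulses for f in range(p.start_frame, p.end_frame + 1)
    }
    ann.stable_frames = [int(f) for f in rs.frames if f not in pulse_frames]
    duration = (ann.ingression_frame - ann.constriction_start_frame) * frame_interval_min
    if duration > 0:
        ann.mean_constriction_rate = float((areas[sel][0] - areas[-1]) / duration)
    ann.fractions = phase_time_fractions(rs)
    return ann


def _phase_intervals(ann: ConstrictionAnnotation) -> list[tuple[str, int, int]]:
    """(name, first_frame, last_frame) for pulse_1, stable_1, pulse_2, …
    Stable phase k spans the frames strictly between pulses k and k+1."""
    out: list[tuple[str, int, int]] = []
    for k, p in enumerate(ann.pulses, start=1):
        out.append((f"pulse_{k}", p.start_frame, p.end_frame))
        if k < len(ann.pulses):
            nxt = ann.pulses[k]
            if nxt.start_frame > p.end_frame + 1:
                out.append((f"stable_{k}", p.end_frame + 1, nxt.start_frame - 1))
    return out


def junction_shrinkage_by_phase(
    junction_tracks: dict[tuple[int, int], JunctionTrack] | list[JunctionTrack],
    annotation: ConstrictionAnnotation,
    frame_interval_min: float,
) -> pd.DataFrame:
    """Mean junction shrinkage rate (µm/min) per constriction phase.

    Rows = junctions, columns = pulse_1, stable_1, pulse_2, …; a junction
    absent in a phase yields NaN, not zero.
    """
    if not annotation.pulses:
        raise ValueError("annotation has no pulses")
    tracks = (
        list(junction_tracks.values())
        if isinstance(junction_tracks, dict)
        else junction_tracks
    )
    phases = _phase_intervals(annotation)
    rows = {}
    for jt in tracks:
        frames, lengths = jt.length_series()
        rs = rate_series(
            lengths, frame_interval_min, first_frame=int(frames[0]), unit="um_per_min"
        ) if len(frames) >= 2 else None
        vals = {}
        for name, f0, f1 in phases:
            if rs is None:
                vals[name] = np.nan
                continue
            sel = (rs.frames >= f0) & (rs.frames <= f1)
            vals[name] = float(rs.rates[sel].mean()) if sel.any() else np.nan
        rows["|".join(map(str, jt.junction_id))] = vals
    return pd.DataFrame.from_dict(rows, orient="index")[
        [name for name, *_ in phases]
    ]


def junction_length_correlation(
    junction_tracks: dict[tuple[int, int], JunctionTrack] | list[JunctionTrack],
    method: str = "pearson",
    min_common_frames: int = 3,
) -> pd.DataFrame:
    """Pairwise correlation of junction length time series over common
    frames (diagonal 1; pairs with < 3 common frames or zero variance are
    NaN)."""
    tracks = (
        list(junction_tracks.values())
        if isinstance(junction_tracks, dict)
        else junction_tracks
    )
    if len(tracks) < 2:
        raise ValueError("need >= 2 junction tracks")
    names = ["|".join(map(str, jt.junction_id)) for jt in tracks]
    series = {}
    for name, jt in zip(names, tracks):
        frames, lengths = jt.length_series()
        series[name] = pd.Series(lengths, index=frames)
    df = pd.DataFrame(series)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            common = df[[a, b]].dropna()
            if len(common) < min_common_frames:
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            xa, xb = common[a].to_numpy(), common[b].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                warnings.warn(f"zero-variance length series in pair ({a}, {b})")
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            if method == "pearson":
                r = float(np.corrcoef(xa, xb)[0, 1])
            elif method == "spearman":
                r = float(
                    np.corrcoef(
                        pd.Series(xa).rank().to_numpy(), pd.Series(xb).rank().to_numpy()
                    )[0, 1]
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            out.loc[a, b] = out.loc[b, a] = r
    return out
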