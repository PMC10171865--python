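"""Programmed apical-constriction dynamics on the synthetic mesh.

Ingressing cells follow a programmed rate schedule — 2–4 constriction
pulses separated by stable phases — realized geometrically by contracting
scheduled junction edges of the shared-vertex mesh, so neighbors absorb
the freed area and the label disappears at the ingression frame.
Non-ingressing cells oscillate with ~zero mean rate via sinusoidal vertex
motion. Every programmed event is echoed in a :class:`GroundTruth` so
downstream detectors can be scored against it.

Default magnitudes realize the study conditions this generator emulates:
initial apical areas of 20–80 µm² (mean ≈ 45), 5-min frames, mean pulse
magnitude 1.4 µm²/min with peaks capped at 4.6, reference-cell oscillation
whose pooled contraction rates have mean + 1 SD ≈ 0.7 µm²/min, ingression
within roughly 25–90 min, and a 48/37/11/4% isolated/pair/triplet/quadruplet
event mix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..datamodel import Calibration, Frame, SegmentedFrameSeries, junction_key
from .mesh import Tissue, TissueMesh

__all__ = [
    "DynamicsParams",
    "PulseTruth",
    "CellTruth",
    "GroundTruth",
    "constriction_schedule",
    "oscillation_rates",
    "sample_area_schedules",
    "simulate_dynamics",
]

# Per-frame rate bands (µm²/min). Stable phases stay clear of the 0.7
# pulse threshold; pulse shoulder frames stay above it for peak >= 1.
STABLE_RATE_MEAN = 0.12
STABLE_RATE_SD = 0.18
STABLE_RATE_LO = -0.45
STABLE_RATE_HI = 0.58
SHOULDER_LO = 0.82
SHOULDER_HI = 0.97

# Reference (non-ingressing) oscillation: per-cell sinusoid amplitude
# drawn uniformly, plus white measurement-like noise. Pooled positive
# rates then have mean + 1 SD ~= 0.7 µm²/min.
OSC_AMP_RANGE = (0.15, 1.1)
OSC_NOISE_SD = 0.12
OSC_PERIOD_RANGE_MIN = (20.0, 50.0)


@dataclass
class DynamicsParams:
    """Knobs of the programmed dynamics (units: µm², µm²/min, minutes)."""

    n_frames: int = 30
    frame_interval_min: float = 5.0
    ingressing_fraction: float = 0.44    # of streak-domain cells per hour
    pulse_count_range: tuple[int, int] = (2, 4)
    pulse_magnitude_mean: float = 1.4
    pulse_magnitude_sd: float = 0.35
    pulse_magnitude_min: float = 1.0
    pulse_magnitude_max: float = 4.6
    max_pulse_len_frames: int = 5
    stable_gap_frames: tuple[int, int] = (1, 2)
    oscillation_amp_range: tuple[float, float] = OSC_AMP_RANGE
    # cluster-size mix of ingression events, by fraction of ingressing
    # cells: isolated / pairs / triplets / quadruplets; or an explicit
    # plan {cluster_size: group_count} that overrides both the mix and
    # ingressing_fraction (unplaceable plans raise)
    cluster_mix: tuple[float, float, float, float] = (0.48, 0.37, 0.11, 0.04)
    cluster_plan: dict[int, int] | None = None
    # keep groups non-adjacent so the 30-min rule recovers the plan
    # exactly; disable for dense runs where only the event rate matters
    cluster_halo: bool = True
    cluster_gap_range_min: tuple[float, float] = (5.0, 25.0)
    streak_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulse_magnitude_mean <= 0 or self.pulse_magnitude_min <= 0:
            raise ValueError("pulse magnitudes must be positive")
        if not 0 <= self.ingressing_fraction <= 1:
            raise ValueError("ingressing_fraction must be in [0, 1]")
        lo, hi = self.pulse_count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad pulse_count_range {self.pulse_count_range}")
        if abs(sum(self.cluster_mix) - 1) > 1e-6:
            raise ValueError("cluster_mix must sum to 1")


@dataclass
class PulseTruth:
    start: int          # frame offset within the constriction period
    stop: int           # inclusive
    magnitude: float    # µm²/min, max programmed rate within the pulse
    junctions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CellTruth:
    cell_id: int
    constriction_start_frame: int
    ingression_frame: int
    cluster_id: int
    cluster_size: int
    pulses: list[PulseTruth]
    area_series_um2: list[float]       # programmed area at each present frame
    first_frame: int = 0


@dataclass
class GroundTruth:
    """Machine-readable record of every programmed event."""

    cells: dict[int, CellTruth]
    reference_cells: list[int]
    junction_lengths_um: dict[tuple[int, int], dict[int, float]] = field(
        default_factory=dict
    )
    painted_junction_means: dict[str, dict[tuple[int, int], float]] = field(
        default_factory=dict
    )
    params: dict = field(default_factory=dict)

    @property
    def ingressing_cells(self) -> list[int]:
        return sorted(self.cells)

    def to_json(self, path: str | Path) -> None:
        def _key(k):
            return f"{k[0]}|{k[1]}" if isinstance(k, tuple) else str(k)

        payload = {
            "cells": {str(c): asdict(t) for c, t in self.cells.items()},
            "reference_cells": self.reference_cells,
            "junction_lengths_um": {
                _key(j): series for j, series in self.junction_lengths_um.items()
            },
            "painted_junction_means": {
                ch: {_key(j): v for j, v in means.items()}
                for ch, means in self.painted_junction_means.items()
            },
            "params": self.params,
        }
        def _default(o):
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return list(o)

        Path(path).write_text(json.dumps(payload, indent=1, default=_default))


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    draws = rng.normal(mean, sd, size)
    bad = (draws < lo) | (draws > hi)
    while np.any(bad):
        draws = np.where(bad, rng.normal(mean, sd, size), draws)
        bad = (draws < lo) | (draws > hi)
    return draws


def constriction_schedule(
    rng: np.random.Generator,
    area0_um2: float,
    params: DynamicsParams | None = None,
    n_max: int | None = None,
) -> tuple[np.ndarray, list[PulseTruth]]:
    """Programmed per-frame contraction rates for one ingressing cell.

    Returns (rates µm²/min, pulses). The schedule consumes the cell's
    initial area down to a sub-pixel remnant: 2–4 pulses whose shoulder
    frames sit at 82–97% of the peak magnitude, separated by stable
    phases of small (occasionally negative) rates, mimicking ratchet-like
    constriction. ``n_max`` caps the period length (never beyond the
    ~90-min ingression-completion window); magnitudes are scaled up
    (within the observed 4.6 µm²/min ceiling) when the budget would not
    otherwise fit.
    """
    p = params or DynamicsParams()
    dt = p.frame_interval_min
    cap = max(3, int(round(90.0 / dt)))
    n_max = cap if n_max is None else min(n_max, cap)
    area_end = float(np.clip(0.06 * area0_um2, 0.5, 3.0))
    budget = area0_um2 - area_end
    lo, hi = p.pulse_count_range
    n_pulses = int(rng.integers(lo, hi + 1))
    mags = _truncnorm(
        rng, p.pulse_magnitude_mean, p.pulse_magnitude_sd,
        p.pulse_magnitude_min, p.pulse_magnitude_max, n_pulses,
    )
    # drop pulses that cannot fit a small cell's budget
    while n_pulses > 2 and float(mags[:n_pulses].sum()) * dt > 0.9 * budget:
        n_pulses -= 1
    mags = np.asarray(mags[:n_pulses], dtype=float)
    if mags.sum() * dt > 0.9 * budget:
        mags *= 0.9 * budget / (mags.sum() * dt)

    glo, ghi = p.stable_gap_frames
    gap_lens = [int(rng.integers(glo, ghi + 1)) for _ in range(n_pulses - 1)]
    if n_max is not None:
        # the minimal layout (single-frame pulses + gaps) must fit
        while n_pulses + sum(gap_lens) > n_max:
            if any(g > 1 for g in gap_lens):
                gap_lens[int(np.argmax(gap_lens))] = 1
            elif n_pulses > 1:
                n_pulses -= 1
                mags = mags[:n_pulses]
                gap_lens = gap_lens[: max(0, n_pulses - 1)]
            else:
                break
    pulse_profiles: list[list[float]] = [[float(m)] for m in mags]

    def consumption() -> float:
        tot = sum(sum(prof) for prof in pulse_profiles)
        tot += sum(gap_lens) * STABLE_RATE_MEAN
        return tot * dt

    def total_frames() -> int:
        return sum(len(pr) for pr in pulse_profiles) + sum(gap_lens)

    # grow pulses (shoulder frames), then stable frames, until the area
    # budget is nearly consumed
    order = list(rng.permutation(n_pulses))
    extra_stable = 0
    while budget - consumption() > 3.0:
        if n_max is not None and total_frames() + extra_stable + 1 > n_max:
            break
        grown = False
        for k in order:
            if len(pulse_profiles[k]) < p.max_pulse_len_frames:
                shoulder = float(mags[k]) * rng.uniform(SHOULDER_LO, SHOULDER_HI)
                if budget - consumption() > shoulder * dt - 2.0:
                    if rng.random() < 0.5:
                        pulse_profiles[k].insert(0, shoulder)
                    else:
                        pulse_profiles[k].append(shoulder)
                    grown = True
                    break
        if not grown:
            extra_stable += 1
            if extra_stable * STABLE_RATE_MEAN * dt > budget - consumption():
                break

    if n_max is not None and total_frames() + extra_stable > n_max:
        extra_stable = max(0, n_max - total_frames())
        # scale magnitudes so the capped schedule still consumes the budget
        cons = consumption() + extra_stable * STABLE_RATE_MEAN * dt
        if cons < budget:
            scale = min(budget / cons, p.pulse_magnitude_max / float(mags.max()))
            mags = mags * scale
            pulse_profiles = [
                [r * scale for r in prof] for prof in pulse_profiles
            ]

    # assemble: [P1][G1][P2]...[Pp] + extra stable frames distributed into
    # gaps / trailing positions
    slots: list[tuple[str, int]] = []
    for k in range(n_pulses):
        slots.append(("pulse", k))
        if k < n_pulses - 1:
            slots.append(("gap", gap_lens[k]))
    trail = extra_stable
    rates: list[float] = []
    pulses: list[PulseTruth] = []
    for kind, v in slots:
        if kind == "pulse":
            start = len(rates)
            rates.extend(pulse_profiles[v])
            pulses.append(
                PulseTruth(start=start, stop=len(rates) - 1, magnitude=float(max(pulse_profiles[v])))
            )
        else:
            extra_here = 0
            if trail > 0:
                extra_here = int(rng.integers(0, trail + 1))
                trail -= extra_here
            for _ in range(v + extra_here):
                rates.append(
                    float(
                        np.clip(
                            rng.normal(STABLE_RATE_MEAN, STABLE_RATE_SD),
                            STABLE_RATE_LO,
                            STABLE_RATE_HI,
                        )
                    )
                )
    for _ in range(trail):
        rates.append(
            float(
                np.clip(
                    rng.normal(STABLE_RATE_MEAN, STABLE_RATE_SD),
                    STABLE_RATE_LO,
                    STABLE_RATE_HI,
                )
            )
        )

    # exact-budget fix-up on stable frames so the final area lands in
    # (0.3, 6) µm²; stable frames stay inside their sub-threshold band
    rates_arr = np.array(rates)
    pulse_idx = np.zeros(len(rates_arr), dtype=bool)
    for pu in pulses:
        pulse_idx[pu.start : pu.stop + 1] = True
    stable_idx = np.flatnonzero(~pulse_idx)
    # frame-capped schedules (late ingression slots): scale pulse frames
    # up, toward the observed 4.6 µm²/min ceiling, to consume the budget
    deficit = area0_um2 - area_end - dt * rates_arr.sum()
    if deficit > 3.0 and n_max is not None and len(rates_arr) >= n_max:
        cur = rates_arr[pulse_idx].sum()
        if cur > 0:
            scale = (cur + deficit / dt) / cur
            rates_arr[pulse_idx] = np.minimum(
                rates_arr[pulse_idx] * scale, p.pulse_magnitude_max
            )
        deficit = area0_um2 - area_end - dt * rates_arr.sum()
        if deficit > 0 and len(stable_idx):
            rates_arr[stable_idx] = np.minimum(
                rates_arr[stable_idx] + deficit / (dt * len(stable_idx)),
                STABLE_RATE_HI,
            )
    for _ in range(50):
        a_end = area0_um2 - dt * rates_arr.sum()
        if 0.3 < a_end < 6.0:
            break
        resid = a_end - area_end  # positive: still too much area left
        if len(stable_idx):
            adj = resid / (dt * len(stable_idx))
            rates_arr[stable_idx] = np.clip(
                rates_arr[stable_idx] + adj, STABLE_RATE_LO, STABLE_RATE_HI
            )
        else:
            # no stable frames: nudge shoulder frames, preserving peaks
            for pu in pulses:
                seg = slice(pu.start, pu.stop + 1)
                prof = rates_arr[seg]
                if len(prof) > 1:
                    peak = np.argmax(prof)
                    bump = resid / (dt * max(1, len(prof) - 1))
                    prof += bump
                    prof[peak] = pu.magnitude
                    rates_arr[seg] = np.clip(prof, 0.72 * pu.magnitude, pu.magnitude)
                else:
                    new_m = float(
                        np.clip(prof[0] + resid / dt, p.pulse_magnitude_min * 0.6,
                                p.pulse_magnitude_max)
                    )
                    rates_arr[seg] = new_m
                    pu.magnitude = new_m
                break
    for pu in pulses:
        pu.magnitude = float(rates_arr[pu.start : pu.stop + 1].max())
    return rates_arr, pulses


def oscillation_rates(
    rng: np.random.Generator,
    n: int,
    frame_interval_min: float = 5.0,
    amp_range: tuple[float, float] = OSC_AMP_RANGE,
    noise_sd: float = OSC_NOISE_SD,
) -> np.ndarray:
    """Per-frame signed area rates (µm²/min) of a non-ingressing cell:
    a random-phase sinusoid plus white noise, zero mean by construction."""
    amp = rng.uniform(*amp_range)
    period = rng.uniform(*OSC_PERIOD_RANGE_MIN)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) * frame_interval_min
    return amp * np.sin(2 * np.pi * t / period + phase) + rng.normal(0, noise_sd, n)


def sample_area_schedules(
    n_cells: int,
    params: DynamicsParams | None = None,
    seed: int | np.random.Generator = 0,
    pre_frames: int = 4,
    area_range_um2: tuple[float, float] = (20.0, 80.0),
) -> list[CellTruth]:
    """Analytic fast path: programmed area series for ``n_cells``
    ingressing cells, without rasterization.

    Initial areas are uniform on 20–80 µm². The returned ground truth
    carries the full area series (pre-constriction oscillation included)
    so detectors can be scored at scale.
    """
    p = params or DynamicsParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = p.frame_interval_min
    out: list[CellTruth] = []
    for cid in range(1, n_cells + 1):
        a0 = rng.uniform(*area_range_um2)
        rates, pulses = constriction_schedule(rng, a0, p)
        pre = oscillation_rates(rng, pre_frames, dt, (0.1, 0.4), 0.08)
        areas = [a0 + dt * pre[i:].sum() for i in range(pre_frames)] + [a0]
        for r in rates:
            areas.append(areas[-1] - r * dt)
        out.append(
            CellTruth(
                cell_id=cid,
                constriction_start_frame=pre_frames,
                ingression_frame=len(areas) - 1,
                cluster_id=cid,
                cluster_size=1,
                pulses=pulses,
                area_series_um2=[float(a) for a in areas],
            )
        )
    return out


# ---------------------------------------------------------------------------
# cluster planning on the mesh


def plan_clusters(
    mesh: TissueMesh,
    candidates: list[int],
    sizes: list[int],
    rng: np.random.Generator,
    halo: bool = True,
    strict: bool = False,
) -> list[list[int]]:
    """Pick groups of mutually adjacent cells realizing the requested
    group sizes. With ``halo`` members of different groups are never
    adjacent, so the 30-min rule recovers the plan exactly. With
    ``strict`` an unplaceable group raises instead of being skipped."""
    g = mesh.adjacency_graph().subgraph(candidates).copy()
    groups: list[list[int]] = []
    available = set(g.nodes)
    for size in sorted(sizes, reverse=True):
        placed = None
        for start in sorted(available, key=lambda c: rng.random()):
            # grow a connected group by BFS within available cells
            group = [start]
            frontier = [start]
            while len(group) < size and frontier:
                nxt = [
                    nb
                    for f in frontier
                    for nb in g.neighbors(f)
                    if nb in available and nb not in group
                ]
                if not nxt:
                    break
                pick = nxt[int(rng.integers(len(nxt)))]
                group.append(pick)
                frontier.append(pick)
            if len(group) == size:
                placed = group
                break
        if placed is None:
            if strict:
                raise ValueError(
                    f"cluster plan unrealizable: no room for a group of "
                    f"size {size} on the mesh adjacency"
                )
            continue  # mesh too fragmented for this size; skip
        groups.append(placed)
        remove = set(placed)
        if halo:  # also remove the neighborhood: groups never adjacent
            for c in placed:
                remove.update(g.neighbors(c))
        available -= remove
    return groups


def _sizes_from_mix(
    n_ingress: int, mix: tuple[float, float, float, float]
) -> list[int]:
    sizes: list[int] = []
    remaining = n_ingress
    for size, frac in ((4, mix[3]), (3, mix[2]), (2, mix[1])):
        count = int(round(frac * n_ingress / size))
        sizes.extend([size] * count)
        remaining -= size * count
    sizes.extend([1] * max(0, remaining))
    return sizes


# ---------------------------------------------------------------------------
# geometric realization


def _contract_edges(
    mesh: TissueMesh,
    base: np.ndarray,
    edge_keys: list[tuple[int, int]],
    s: float,
) -> None:
    """Move the endpoints of each edge a fraction ``s`` of the way toward
    the edge midpoint (positions taken from ``base``). Vertices shared by
    several scheduled edges receive the average of their targets."""
    targets: dict[int, list[np.ndarray]] = {}
    for key in edge_keys:
        vi, vj = mesh.edges[key]
        mid = 0.5 * (base[vi] + base[vj])
        for v in (vi, vj):
            targets.setdefault(v, []).append(base[v] + s * (mid - base[v]))
    for v, tgts in targets.items():
        mesh.vertices[v] = np.mean(tgts, axis=0)


def _contract_toward_centroid(
    mesh: TissueMesh, base: np.ndarray, label: int, s: float
) -> None:
    loop = mesh.cells[label]
    cen = base[loop].mean(axis=0)
    for v in loop:
        mesh.vertices[v] = base[v] + s * (cen - base[v])


MAX_EDGE_CONTRACTION = 0.85  # junctions shrink but never fully collapse,
# so a constricting cell keeps contact with all its neighbors to the end


def _drive_cell_to_area(
    mesh: TissueMesh,
    label: int,
    target_area: float,
    edge_keys: list[tuple[int, int]],
) -> None:
    """Bisection on the contraction parameter so the cell polygon hits the
    target area; falls back to whole-cell centroid contraction when the
    scheduled edges alone cannot release enough area."""
    base = mesh.vertices.copy()
    if mesh.area(label) <= target_area:
        return

    def area_at(s: float, mode: str) -> float:
        mesh.vertices[:] = base
        if mode == "edges":
            _contract_edges(mesh, base, edge_keys, s)
        else:
            _contract_toward_centroid(mesh, base, label, s)
        return mesh.area(label)

    mode = "edges" if edge_keys else "centroid"
    s_max = MAX_EDGE_CONTRACTION if mode == "edges" else 1.0
    if mode == "edges" and area_at(s_max, "edges") > target_area:
        # scheduled edges exhausted: leave them contracted and finish with
        # a centroid contraction from that state
        base = mesh.vertices.copy()
        mode = "centroid"
        s_max = 1.0
    lo, hi = 0.0, s_max
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if area_at(mid, mode) > target_area:
            lo = mid
        else:
            hi = mid
    area_at(hi, mode)


def simulate_dynamics(
    tissue: Tissue, params: DynamicsParams | None = None
) -> tuple[SegmentedFrameSeries, GroundTruth]:
    """Simulate a tracked label-image series with programmed ingressions.

    Ingressing cells are chosen in the streak domain (when
    ``params.streak_only`` and the calibration has a midline), grouped per
    the cluster mix, and given constriction schedules ending at their
    planned ingression frames; non-ingressing cells oscillate. Returns the
    rasterized series and the ground truth of every programmed event.
    """
    p = params or DynamicsParams()
    rng = np.random.default_rng(p.seed)
    mesh = tissue.mesh
    calib = Calibration(
        pixel_size_um=tissue.calibration.pixel_size_um,
        frame_interval_min=p.frame_interval_min,
        midline_x_um=tissue.calibration.midline_x_um,
        streak_halfwidth_um=tissue.calibration.streak_halfwidth_um,
    )
    dt = p.frame_interval_min
    labels_all = sorted(mesh.cells)

    # border cells are censored downstream and, having an unshared field
    # edge, cannot hand their area to a neighbor — never ingress them
    interior = [c for c in labels_all if c not in mesh.border_cells()]
    if p.streak_only and calib.midline_x_um is not None:
        candidates = [
            c
            for c in interior
            if abs(mesh.centroid(c)[0] - calib.midline_x_um)
            <= calib.streak_halfwidth_um
        ]
    else:
        candidates = interior
    movie_hours = (p.n_frames - 1) * dt / 60.0
    if p.cluster_plan is not None:
        sizes = [s for s, count in sorted(p.cluster_plan.items())
                 for _ in range(count)]
        strict = True
    else:
        n_ingress = int(
            round(p.ingressing_fraction * len(candidates) * min(1.0, movie_hours))
        )
        sizes = _sizes_from_mix(n_ingress, p.cluster_mix)
        strict = False
    groups = plan_clusters(
        mesh, candidates, sizes, rng, halo=p.cluster_halo, strict=strict
    )

    # ingression times: first and last ~25 min of the movie are kept
    # event-free so every 60-min window sees the same event set
    t_total = (p.n_frames - 1) * dt
    t_lo, t_hi = min(25.0, 0.3 * t_total), max(t_total - 25.0, 0.4 * t_total)
    truth_cells: dict[int, CellTruth] = {}
    schedules: dict[int, tuple[int, np.ndarray, list[PulseTruth]]] = {}
    for gid, group in enumerate(groups):
        base_t = rng.uniform(t_lo, t_hi)
        times = [base_t]
        for _ in group[1:]:
            gap = rng.uniform(*p.cluster_gap_range_min)
            times.append(min(times[-1] + gap, t_hi))
        for cid, t_ing in zip(group, times):
            f_ing = int(np.clip(round(t_ing / dt), 3, p.n_frames - 2))
            a0 = mesh.area(cid)
            n_period_max = f_ing  # must start at frame >= 0
            rates, pulses = constriction_schedule(rng, a0, p, n_max=n_period_max)
            f_start = f_ing - len(rates)
            # per-pulse junction schedule: partition this cell's junctions
            edges = mesh.cell_edges(cid)
            perm = [edges[i] for i in rng.permutation(len(edges))]
            for k, pu in enumerate(pulses):
                pu.junctions = sorted(perm[k :: len(pulses)])
            areas = [float(a0)]
            for r in rates:
                areas.append(areas[-1] - r * dt)
            truth_cells[cid] = CellTruth(
                cell_id=cid,
                constriction_start_frame=f_start,
                ingression_frame=f_ing,
                cluster_id=gid,
                cluster_size=len(group),
                pulses=pulses,
                area_series_um2=areas,
            )
            schedules[cid] = (f_start, rates, pulses)

    ingressing = set(schedules)
    reference = [c for c in labels_all if c not in ingressing]

    # oscillation assignment: vertices incident to any ingressing cell
    # stay parked (pre-period) / driven (period); the rest breathe
    frozen_vertices: set[int] = set()
    for cid in ingressing:
        frozen_vertices.update(mesh.cells[cid])
    osc = {}
    for v in range(len(mesh.vertices)):
        if v in frozen_vertices:
            continue
        osc[v] = (
            rng.uniform(0.08, 0.35),                      # µm amplitude
            rng.uniform(*OSC_PERIOD_RANGE_MIN),           # min period
            rng.uniform(0, 2 * np.pi),                    # phase
            rng.uniform(0, 2 * np.pi),                    # direction
        )

    base_positions = mesh.vertices.copy()
    truth = GroundTruth(
        cells=truth_cells,
        reference_cells=reference,
        params={"dynamics": asdict(p)},
    )
    tracked_junctions = {
        key for cid in ingressing for key in mesh.cell_edges(cid)
    }
    frames: list[Frame] = []
    gone: set[int] = set()
    for f in range(p.n_frames):
        t = f * dt
        # breathe the free vertices about their base positions
        for v, (amp, period, phase, ang) in osc.items():
            d = amp * np.sin(2 * np.pi * t / period + phase)
            mesh.vertices[v] = base_positions[v] + d * np.array(
                [np.cos(ang), np.sin(ang)]
            )
        # drive constricting cells (deterministic label order)
        for cid in sorted(schedules):
            f_start, rates, pulses = schedules[cid]
            f_ing = truth_cells[cid].ingression_frame
            if f <= f_start or f > f_ing or cid in gone:
                continue
            k = f - f_start - 1  # index into the rate schedule
            target = truth_cells[cid].area_series_um2[k + 1]
            active = [pu for pu in pulses if pu.start <= k <= pu.stop]
            edge_keys = active[0].junctions if active else []
            edge_keys = [e for e in edge_keys if e in mesh.edges]
            _drive_cell_to_area(mesh, cid, target, edge_keys)
        for key in tracked_junctions:
            vi, vj = mesh.edges[key]
            a, b = key
            if a in gone or b in gone:
                continue
            truth.junction_lengths_um.setdefault(key, {})[f] = float(
                np.linalg.norm(mesh.vertices[vi] - mesh.vertices[vj])
            )
        labels = mesh.rasterize(calib.pixel_size_um, exclude=gone)
        frames.append(Frame(frame_index=f, labels=labels))
        for cid in sorted(ingressing - gone):
            # ingression_frame is the LAST present frame; the label is
            # absent from the next frame on
            if f >= truth_cells[cid].ingression_frame:
                gone.add(cid)
    series = SegmentedFrameSeries(frames=frames, calibration=calib)
    return series, truth
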