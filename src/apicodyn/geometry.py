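"""Per-frame cell and junction geometry from tracked label images.

Conventions (documented once, used everywhere):

* image row/column convert to µm via the pixel size; the origin sits at
  the top-left pixel center and x is the column axis (y points down);
* angles are degrees from the +x axis folded to [0, 180), since junction
  and nematic orientations are axial quantities;
* a junction's skeleton is the set of pixels 8-adjacent to exactly one
  other label; pixels adjacent to two or more other labels are tricellular
  vertices and belong to no junction;
* cells touching the image border are flagged (their geometry is
  censored) and excluded from per-cell statistics by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .datamodel import Calibration, Frame, junction_key

__all__ = [
    "CellGeometry",
    "JunctionGeometry",
    "extract_cells",
    "extract_junctions",
    "measure_junction_intensity",
    "measure_medial_intensity",
    "MeasurementError",
]

_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class MeasurementError(ValueError):
    pass


@dataclass
class CellGeometry:
    cell_id: int
    area_um2: float
    centroid_um: tuple[float, float]
    elongation_index: float
    elongation_angle_deg: float
    neighbor_ids: frozenset[int]
    junction_count: int
    border_touching: bool
    angle_unstable: bool = False  # near-degenerate axes (round cell)


@dataclass
class JunctionGeometry:
    members: tuple[int, int]
    skeleton_rc: np.ndarray = field(repr=False)  # (n, 2) row/col pixels
    length_um: float = 0.0
    orientation_deg: float = 0.0

    @property
    def pixel_count(self) -> int:
        return len(self.skeleton_rc)


def _neighbor_structure(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stack of 8 shifted label images (edges padded with the pixel's own
    label so the image border creates no phantom neighbors), and the count
    of distinct labels different from the pixel's own."""
    h, w = labels.shape
    stack = np.empty((8, h, w), dtype=labels.dtype)
    for i, (dr, dc) in enumerate(_SHIFTS):
        shifted = labels.copy()
        rs = slice(max(dr, 0), h + min(dr, 0))
        rd = slice(max(-dr, 0), h + min(-dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        cd = slice(max(-dc, 0), w + min(-dc, 0))
        shifted[rd, cd] = labels[rs, cs]
        stack[i] = shifted
    own = labels[None]
    others = np.where(stack == own, own, stack)
    srt = np.sort(others, axis=0)
    distinct = np.ones(srt.shape, dtype=bool)
    distinct[1:] = srt[1:] != srt[:-1]
    n_other = distinct.sum(axis=0) - 1  # own label always counted once
    return stack, n_other


def _boundary_pairs(labels: np.ndarray):
    """Per-pixel unique other-label (where exactly one), the tricellular
    vertex mask, and the raw shifted stack."""
    stack, n_other = _neighbor_structure(labels)
    own = labels[None]
    vertex_mask = n_other >= 2
    single = n_other == 1
    other = np.where(stack != own, stack, 0).max(axis=0)
    return single, other, vertex_mask, stack


def extract_cells(
    frame: Frame, calibration: Calibration, min_junction_pixels: int = 2
) -> list[CellGeometry]:
    """One geometry record per positive label present in the frame.

    Elongation comes from the eigen-decomposition of the second central
    area moments: with a >= b the equivalent-ellipse semi-axes, the index
    is (a - b)/(a + b) — 0 for a disc, -> 1 for a line — and the angle is
    the major-axis direction.
    """
    labels = frame.labels
    px = calibration.pixel_size_um
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    junctions = extract_junctions(frame, calibration, min_pixels=min_junction_pixels)
    neighbor_map: dict[int, set[int]] = {int(i): set() for i in ids}
    jcount: dict[int, int] = {int(i): 0 for i in ids}
    for j in junctions:
        a, b = j.members
        if a > 0 and b > 0:
            neighbor_map[a].add(b)
            neighbor_map[b].add(a)
        for m in (a, b):
            if m > 0:
                jcount[m] += 1

    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border]).tolist())

    slices = ndimage.find_objects(labels)
    out: list[CellGeometry] = []
    for lab in ids:
        lab = int(lab)
        sl = slices[lab - 1]
        mask = labels[sl] == lab
        rr, cc = np.nonzero(mask)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        n = rr.size
        x = cc * px
        y = rr * px
        cx, cy = float(x.mean()), float(y.mean())
        # second central moments (+ pixel self-variance so a 1-px cell is
        # a tiny square, not a point)
        dx, dy = x - cx, y - cy
        sxx = float(np.dot(dx, dx) / n) + px**2 / 12.0
        syy = float(np.dot(dy, dy) / n) + px**2 / 12.0
        sxy = float(np.dot(dx, dy) / n)
        cov = np.array([[sxx, sxy], [sxy, syy]])
        evals, evecs = np.linalg.eigh(cov)
        l2, l1 = max(evals[0], 0.0), max(evals[1], 0.0)
        a, b = np.sqrt(l1), np.sqrt(l2)
        index = float((a - b) / (a + b)) if (a + b) > 0 else 0.0
        vx, vy = evecs[:, 1]
        angle = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
        unstable = (l1 - l2) / max(l1, 1e-30) < 1e-3
        out.append(
            CellGeometry(
                cell_id=lab,
                area_um2=n * px**2,
                centroid_um=(cx, cy),
                elongation_index=index,
                elongation_angle_deg=angle,
                neighbor_ids=frozenset(neighbor_map[lab]),
                junction_count=jcount[lab],
                border_touching=lab in border_labels,
                angle_unstable=unstable,
            )
        )
    return out


def _geodesic_length_px(rc: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Approximate geodesic length (in px) of a pixel chain: the longest
    shortest path through the 8-connected pixel graph (double Dijkstra
    sweep), plus one pixel for the endpoint extent."""
    n = len(rc)
    if n == 1:
        return 1.0, rc[0], rc[0]
    order = np.lexsort((rc[:, 1], rc[:, 0]))
    rc = rc[order]
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(rc)}
    rows, cols, w = [], [], []
    for i, (r, c) in enumerate(rc):
        for dr, dc in _SHIFTS:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None and j > i:
                rows.append(i)
                cols.append(j)
                w.append(np.hypot(dr, dc))
    g = coo_matrix((w, (rows, cols)), shape=(n, n))
    d0 = dijkstra(g, directed=False, indices=0)
    finite = np.where(np.isfinite(d0))[0]
    far = int(finite[np.argmax(d0[finite])])
    d1 = dijkstra(g, directed=False, indices=far)
    finite = np.where(np.isfinite(d1))[0]
    end = int(finite[np.argmax(d1[finite])])
    return float(d1[end]) + 1.0, rc[far], rc[end]


def extract_junctions(
    frame: Frame, calibration: Calibration, min_pixels: int = 2
) -> list[JunctionGeometry]:
    """Junction skeletons, lengths and orientations for one frame.

    The skeleton of junction {L, M} collects pixels of either member
    adjacent (8-connectivity) to exactly the other label. Length is the
    calibrated geodesic length of the one-sided skeleton chain (the side
    of the smaller label, falling back to the other side), orientation the
    axial direction of the chord between the chain endpoints. Junctions
    with fewer than ``min_pixels`` skeleton pixels are dropped.
    """
    labels = frame.labels
    px = calibration.pixel_size_um
    single, other, _vertex, _ = _boundary_pairs(labels)
    rr, cc = np.nonzero(single)
    own = labels[rr, cc]
    oth = other[rr, cc]
    out: list[JunctionGeometry] = []
    if rr.size == 0:
        return out
    lo = np.minimum(own, oth)
    hi = np.maximum(own, oth)
    order = np.lexsort((cc, rr, hi, lo))
    lo, hi, rr, cc, own = lo[order], hi[order], rr[order], cc[order], own[order]
    breaks = np.flatnonzero((np.diff(lo) != 0) | (np.diff(hi) != 0)) + 1
    for seg in np.split(np.arange(len(lo)), breaks):
        a, b = int(lo[seg[0]]), int(hi[seg[0]])
        rc = np.column_stack([rr[seg], cc[seg]])
        if len(rc) < max(min_pixels, 1):
            continue
        side = rc[own[seg] == a]
        if len(side) == 0:
            side = rc
        length_px, p0, p1 = _geodesic_length_px(side)
        dx = float(p1[1] - p0[1])
        dy = float(p1[0] - p0[0])
        if dx == 0 and dy == 0:
            ang = 0.0
        else:
            ang = float(np.degrees(np.arctan2(dy, dx)) % 180.0)
        out.append(
            JunctionGeometry(
                members=junction_key(a, b),
                skeleton_rc=rc,
                length_um=length_px * px,
                orientation_deg=ang,
            )
        )
    return out


def _band_mask(
    labels: np.ndarray, junction: JunctionGeometry, width_px: int
) -> np.ndarray:
    """Junction band: the skeleton dilated to ``width_px``, clipped to the
    two member cells (plus boundary). Tricellular vertices and pixels at
    least as close to another junction's skeleton are excluded, so bands
    of neighboring junctions never overlap."""
    a, b = junction.members
    mask = np.zeros(labels.shape, dtype=bool)
    rc = junction.skeleton_rc
    mask[rc[:, 0], rc[:, 1]] = True
    r = max((width_px - 1) // 2, 0)
    single, other, vertex, _ = _boundary_pairs(labels)
    own_pair = np.zeros(labels.shape, dtype=bool)
    lo, hi = junction.members
    own_pair[single] = (np.minimum(labels, other)[single] == lo) & (
        np.maximum(labels, other)[single] == hi
    )
    foreign = (single & ~own_pair) | vertex
    if r:
        mask = ndimage.binary_dilation(mask, iterations=r)
        foreign = ndimage.binary_dilation(foreign, iterations=r)
        mask &= ~(foreign & ~own_pair)
    member = (labels == a) | (labels == b)
    return mask & member & ~vertex


def measure_junction_intensity(
    frame: Frame,
    channel: str,
    junction: JunctionGeometry,
    width_px: int = 3,
) -> float:
    """Mean channel intensity over the junction's band (default 3 px wide,
    ~500 nm at the default pixel size)."""
    if channel not in frame.channels:
        raise MeasurementError(f"channel {channel!r} not present in frame")
    band = _band_mask(frame.labels, junction, width_px)
    if not band.any():
        raise MeasurementError(f"empty band for junction {junction.members}")
    return float(frame.channels[channel][band].mean())


def measure_medial_intensity(
    frame: Frame,
    channel: str,
    cell_id: int,
    erosion_px: int = 3,
) -> float:
    """Mean channel intensity over the cell's medial (cytoplasmic) pool:
    the cell mask eroded by ``erosion_px`` so junction bands are excluded.
    If erosion empties the cell, falls back to pixels not adjacent to any
    other label and warns."""
    if channel not in frame.channels:
        raise MeasurementError(f"channel {channel!r} not present in frame")
    mask = frame.labels == cell_id
    if not mask.any():
        raise KeyError(f"cell {cell_id} absent from frame {frame.frame_index}")
    core = ndimage.binary_erosion(mask, iterations=erosion_px) if erosion_px else mask
    if not core.any():
        _, n_other = _neighbor_structure(frame.labels)
        core = mask & (n_other == 0)
        if not core.any():
            core = mask
        warnings.warn(
            f"cell {cell_id}: erosion by {erosion_px} px emptied the mask; "
            "medial pool fell back to non-boundary pixels",
            stacklevel=2,
        )
    return float(frame.channels[channel][core].mean())
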