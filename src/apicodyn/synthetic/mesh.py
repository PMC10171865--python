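"""Polygonal epithelium stand-in: Lloyd-relaxed Voronoi mesh + rasterizer.

The tissue is a shared-vertex polygon mesh: each cell is a loop of vertex
indices into one mutable vertex array, and each cell-cell junction is the
edge (vertex pair) of the Voronoi ridge between the two seeds. Moving a
vertex deforms every incident cell consistently, so the mesh remains a
partition of the field under any vertex motion — the property the dynamics
simulator relies on to let neighbors absorb the area freed by a
constricting cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from skimage.draw import polygon as draw_polygon

from ..datamodel import Calibration, Frame, SegmentedFrameSeries, junction_key

__all__ = ["TissueMesh", "Tissue", "generate_tissue"]


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    cx = ((x + xs) * cross).sum() / (6 * a)
    cy = ((y + ys) * cross).sum() / (6 * a)
    return np.array([cx, cy])


@dataclass
class TissueMesh:
    """Shared-vertex polygon partition of a rectangular field (µm units)."""

    vertices: np.ndarray                       # (n_v, 2), mutable positions
    cells: dict[int, list[int]]                # label -> vertex-index loop
    edges: dict[tuple[int, int], tuple[int, int]]  # (labA,labB) -> (vi,vj)
    field_size_um: tuple[float, float]         # (width, height)

    def polygon(self, label: int) -> np.ndarray:
        return self.vertices[self.cells[label]]

    def area(self, label: int) -> float:
        return abs(_shoelace(self.polygon(label)))

    def centroid(self, label: int) -> np.ndarray:
        return _polygon_centroid(self.polygon(label))

    def edge_length(self, a: int, b: int) -> float:
        vi, vj = self.edges[junction_key(a, b)]
        return float(np.linalg.norm(self.vertices[vi] - self.vertices[vj]))

    def cell_edges(self, label: int) -> list[tuple[int, int]]:
        """Junction keys of one cell, in deterministic (sorted) order."""
        return sorted(k for k in self.edges if label in k)

    def neighbors(self, label: int) -> set[int]:
        return {a if b == label else b for a, b in self.cell_edges(label)}

    def adjacency_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        g.add_edges_from(self.edges)
        return g

    def cell_vertex_set(self, label: int) -> set[int]:
        return set(self.cells[label])

    def border_cells(self, tol: float = 1e-6) -> set[int]:
        """Cells whose polygon touches the field boundary."""
        w, h = self.field_size_um
        out = set()
        for label, loop in self.cells.items():
            pts = self.vertices[loop]
            if (
                (pts[:, 0] < tol).any()
                or (pts[:, 1] < tol).any()
                or (pts[:, 0] > w - tol).any()
                or (pts[:, 1] > h - tol).any()
            ):
                out.add(label)
        return out

    def rasterize(
        self, pixel_size_um: float, exclude: set[int] | frozenset[int] = frozenset()
    ) -> np.ndarray:
        """Label image of the current vertex positions.

        Pixel (row r, col c) has its center at (x, y) = (c, r) × pixel size
        (origin at the top-left pixel center). Cells in ``exclude`` are not
        drawn; their pixels are filled by the nearest drawn label so the
        partition stays gapless after an ingression.
        """
        w_um, h_um = self.field_size_um
        shape = (int(round(h_um / pixel_size_um)), int(round(w_um / pixel_size_um)))
        canvas = np.zeros(shape, dtype=np.int32)
        for label in sorted(self.cells):
            if label in exclude:
                continue
            pts = self.polygon(label)
            rr, cc = draw_polygon(
                pts[:, 1] / pixel_size_um, pts[:, 0] / pixel_size_um, shape
            )
            free = canvas[rr, cc] == 0
            canvas[rr[free], cc[free]] = label
        if (canvas == 0).any() and (canvas != 0).any():
            _, (ir, ic) = ndimage.distance_transform_edt(
                canvas == 0, return_indices=True
            )
            canvas = canvas[ir, ic]
        return canvas


@dataclass
class Tissue:
    """A generated tissue: mesh plus the calibration used to rasterize it."""

    mesh: TissueMesh
    calibration: Calibration
    seed_points_um: np.ndarray = field(repr=False, default=None)

    def to_series(self, frame_index: int = 0) -> SegmentedFrameSeries:
        labels = self.mesh.rasterize(self.calibration.pixel_size_um)
        return SegmentedFrameSeries(
            frames=[Frame(frame_index=frame_index, labels=labels)],
            calibration=self.calibration,
        )


def _voronoi_with_mirrors(points: np.ndarray, w: float, h: float) -> Voronoi:
    """Voronoi of the points plus their reflections across the 4 field
    edges, which bounds every original cell inside the field rectangle."""
    mirrors = [
        points * [-1, 1],                 # left edge x=0
        points * [1, -1],                 # top edge y=0
        np.column_stack([2 * w - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * h - points[:, 1]]),
    ]
    return Voronoi(np.vstack([points] + mirrors))


def _lloyd(points: np.ndarray, w: float, h: float, iters: int) -> np.ndarray:
    for _ in range(iters):
        vor = _voronoi_with_mirrors(points, w, h)
        new = points.copy()
        for i in range(len(points)):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:  # pragma: no cover - mirrors prevent this
                continue
            new[i] = _polygon_centroid(vor.vertices[region])
        points = np.clip(new, [1e-6, 1e-6], [w - 1e-6, h - 1e-6])
    return points


def build_mesh(points: np.ndarray, w: float, h: float) -> TissueMesh:
    """Build the shared-vertex mesh from seed points (one cell per seed,
    label = seed index + 1)."""
    n = len(points)
    vor = _voronoi_with_mirrors(points, w, h)
    used: dict[int, int] = {}
    cells: dict[int, list[int]] = {}
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        loop = []
        for v in region:
            if v not in used:
                used[v] = len(used)
            loop.append(used[v])
        pts = vor.vertices[region]
        if _shoelace(pts) < 0:
            loop = loop[::-1]
        cells[i + 1] = loop
    vertices = np.empty((len(used), 2))
    for old, newi in used.items():
        vertices[newi] = vor.vertices[old]
    edges: dict[tuple[int, int], tuple[int, int]] = {}
    for (pa, pb), (va, vb) in zip(vor.ridge_points, vor.ridge_vertices):
        if pa < n and pb < n and va != -1 and vb != -1 and va in used and vb in used:
            edges[junction_key(pa + 1, pb + 1)] = (used[va], used[vb])
    vertices = np.clip(vertices, [0.0, 0.0], [w, h])
    return TissueMesh(vertices=vertices, cells=cells, edges=edges, field_size_um=(w, h))


def generate_tissue(
    n_cells: int,
    field_size_um: tuple[float, float] | None = None,
    mean_area_um2: float = 45.0,
    pixel_size_um: float = 0.17,
    frame_interval_min: float = 5.0,
    lloyd_iters: int = 1,
    seed: int | np.random.Generator = 0,
) -> Tissue:
    """Generate a one-frame synthetic epithelium.

    The field defaults to a square sized so the mean apical area is
    ``mean_area_um2`` (default 45 µm², within the 20–80 µm² range of
    gastrulating epiblast cells). One Lloyd iteration keeps a natural,
    epithelium-like spread of cell areas; more iterations homogenize it.
    """
    if n_cells < 3:
        raise ValueError(f"n_cells must be >= 3, got {n_cells}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if field_size_um is None:
        side = float(np.sqrt(n_cells * mean_area_um2))
        field_size_um = (side, side)
    w, h = field_size_um
    if w * h < n_cells * 4 * pixel_size_um**2 * 9:
        raise ValueError(
            f"field {field_size_um} µm too small for {n_cells} cells at "
            f"{pixel_size_um} µm/px"
        )
    pts = np.column_stack([rng.uniform(0, w, n_cells), rng.uniform(0, h, n_cells)])
    pts = _lloyd(pts, w, h, lloyd_iters)
    mesh = build_mesh(pts, w, h)
    calib = Calibration(
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
        midline_x_um=w / 2.0,
    )
    return Tissue(mesh=mesh, calibration=calib, seed_points_um=pts)
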