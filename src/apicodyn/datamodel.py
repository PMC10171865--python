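"""Core domain types for segmented epithelial time-lapse analysis.

The pipeline consumes tracked label-image series: one integer label image
per time point, where a given positive label identifies the same cell in
every frame it appears in, plus optional co-registered fluorescence
channels. Label 0 is reserved for exterior/background. All physical
quantities are expressed in micrometres and minutes via a
:class:`Calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Calibration",
    "Frame",
    "SegmentedFrameSeries",
    "CellRecord",
    "CellTrack",
    "JunctionRecord",
    "JunctionTrack",
    "FormatError",
    "IntegrityError",
    "junction_key",
]

EXTERIOR = 0  # reserved background label


class FormatError(ValueError):
    """Raised when on-disk data violates the series contract."""


class IntegrityError(ValueError):
    """Raised when measurement tables violate uniqueness/finiteness."""


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of a recording.

    Parameters
    ----------
    pixel_size_um : float
        Micrometres per pixel (> 0).
    frame_interval_min : float
        Minutes per frame (> 0).
    midline_x_um : float, optional
        Horizontal position of the tissue midline (x = column axis) in µm.
        Required for streak-domain statistics.
    streak_halfwidth_um : float
        Half-width of the streak domain in µm; the default 20 defines a
        40 µm region centred on the midline.
    """

    pixel_size_um: float
    frame_interval_min: float
    midline_x_um: float | None = None
    streak_halfwidth_um: float = 20.0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_min > 0:
            raise ValueError(
                f"frame_interval_min must be > 0, got {self.frame_interval_min}"
            )
        if not self.streak_halfwidth_um > 0:
            raise ValueError(
                f"streak_halfwidth_um must be > 0, got {self.streak_halfwidth_um}"
            )

    def time_min(self, frame_index: int) -> float:
        """Time of a 0-based frame index in minutes."""
        return frame_index * self.frame_interval_min


@dataclass
class Frame:
    """One time point: a label image plus named intensity channels."""

    frame_index: int
    labels: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.frame_index < 0:
            raise FormatError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.labels.ndim != 2:
            raise FormatError("label image must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label image must be integer, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise FormatError("negative labels are not allowed")
        for name, chan in self.channels.items():
            if chan.shape != self.labels.shape:
                raise FormatError(
                    f"channel {name!r} shape {chan.shape} != label shape "
                    f"{self.labels.shape}"
                )
            if np.nanmin(chan) < 0:
                raise FormatError(f"channel {name!r} has negative intensities")


@dataclass
class SegmentedFrameSeries:
    """Tracked label-image series with calibration; the canonical input.

    Invariants: all grids in a frame share one shape; frame indices are
    strictly increasing; a positive label means the same tracked cell in
    every frame where it appears.
    """

    frames: list[Frame]
    calibration: Calibration

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        last = -1
        shape = None
        for fr in self.frames:
            fr.validate()
            if fr.frame_index <= last:
                raise FormatError(
                    f"frame indices must be strictly increasing "
                    f"({fr.frame_index} after {last})"
                )
            last = fr.frame_index
            if shape is None:
                shape = fr.labels.shape
            elif fr.labels.shape != shape:
                raise FormatError(
                    f"frame {fr.frame_index} shape {fr.labels.shape} != {shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].labels.shape

    @property
    def channel_names(self) -> list[str]:
        return sorted(self.frames[0].channels) if self.frames else []

    def labels_present(self) -> set[int]:
        out: set[int] = set()
        for fr in self.frames:
            out.update(np.unique(fr.labels).tolist())
        out.discard(EXTERIOR)
        return out


def junction_key(a: int, b: int) -> tuple[int, int]:
    """Canonical unordered key of a cell pair (may include the exterior 0)."""
    if a == b:
        raise ValueError(f"junction members must be distinct, got ({a}, {b})")
    return (a, b) if a < b else (b, a)


@dataclass
class CellRecord:
    """Per-frame geometry of one cell."""

    frame: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y) in µm, image coordinates
    elongation_index: float
    elongation_angle_deg: float
    neighbor_ids: frozenset[int]
    junction_count: int
    border_touching: bool
    bridged: bool = False  # filled across a one-frame tracking dropout


@dataclass
class CellTrack:
    """Contiguous per-cell time series of geometry records."""

    cell_id: int
    records: dict[int, CellRecord]  # frame -> record

    @property
    def first_frame(self) -> int:
        return min(self.records)

    @property
    def last_frame(self) -> int:
        return max(self.records)

    @property
    def frames(self) -> list[int]:
        return sorted(self.records)

    def area_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(frames, areas in µm²) over the track's presence."""
        fr = np.array(self.frames)
        return fr, np.array([self.records[f].area_um2 for f in fr])

    def ever_border_touching(self) -> bool:
        return any(r.border_touching for r in self.records.values())


@dataclass
class JunctionRecord:
    """Per-frame geometry and intensity of one cell-cell junction."""

    frame: int
    length_um: float
    orientation_deg: float
    pixel_count: int
    intensity: dict[str, float] = field(default_factory=dict)
    bridged: bool = False


@dataclass
class JunctionTrack:
    """Per-junction time series; the id is an unordered cell-label pair."""

    junction_id: tuple[int, int]
    records: dict[int, JunctionRecord]

    @property
    def first_frame(self) -> int:
        return min(self.records)

    @property
    def last_frame(self) -> int:
        return max(self.records)

    @property
    def frames(self) -> list[int]:
        return sorted(self.records)

    def length_series(self) -> tuple[np.ndarray, np.ndarray]:
        fr = np.array(self.frames)
        return fr, np.array([self.records[f].length_um for f in fr])
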