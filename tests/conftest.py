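import warnings

import numpy as np
import pytest

from apicodyn.datamodel import Calibration, Frame, SegmentedFrameSeries
from apicodyn.synthetic import (
    DynamicsParams,
    generate_tissue,
    simulate_dynamics,
)
from apicodyn import tracks as trk

CAL = Calibration(pixel_size_um=0.17, frame_interval_min=5.0)


@pytest.fixture(scope="session")
def calibration():
    return CAL


@pytest.fixture(scope="session")
def tissue():
    return generate_tissue(36, seed=11)


@pytest.fixture(scope="session")
def dynamics_run(tissue):
    """One small simulated movie with ingressions, shared across tests."""
    params = DynamicsParams(n_frames=24, ingressing_fraction=0.3, seed=42)
    series, truth = simulate_dynamics(tissue, params)
    return series, truth


@pytest.fixture(scope="session")
def dynamics_tracks(dynamics_run):
    series, _ = dynamics_run
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return trk.build_tracks(series)


def label_frame(labels: np.ndarray, frame_index: int = 0, **channels) -> Frame:
    return Frame(
        frame_index=frame_index,
        labels=np.asarray(labels, dtype=np.int32),
        channels={k: np.asarray(v, dtype=float) for k, v in channels.items()},
    )


def single_frame_series(labels: np.ndarray, calibration=CAL, **channels):
    return SegmentedFrameSeries(
        frames=[label_frame(labels, 0, **channels)], calibration=calibration
    )


def disc_labels(radius_px: int = 40, pad: int = 6) -> np.ndarray:
    n = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius_px + pad
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2).astype(np.int32)


def hex_tissue(n_side: int = 4, seed: int = 0):
    """Near-regular hexagonal tissue from a honeycomb seed lattice."""
    from apicodyn.synthetic.mesh import build_mesh, Tissue

    spacing = 7.0
    pts = []
    for i in range(n_side):
        for j in range(n_side):
            x = spacing * (j + 0.5 * (i % 2)) + spacing / 2
            y = spacing * i * np.sqrt(3) / 2 + spacing / 2
            pts.append((x, y))
    pts = np.array(pts)
    w = pts[:, 0].max() + spacing / 2
    h = pts[:, 1].max() + spacing / 2
    mesh = build_mesh(pts, w, h)
    return Tissue(mesh=mesh, calibration=CAL, seed_points_um=pts)
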