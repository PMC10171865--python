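"""Painted fluorescence channels with controllable junctional structure.

Per-junction mean loadings are drawn from a two-group latent model that
emulates the observed organization of apical proteins: an
"actomyosin-like" group (M) and a "Crumbs-complex-like" group (C) share
one latent activity per junction, with the two groups anti-correlated on
high-intensity junctions only — so their pooled correlation is near zero
until low-intensity junctions are filtered out, when the reciprocal
enrichment appears. A "control" group paints a planar-polarized channel
(Celsr1-like) whose intensity follows cos 2(θ - axis), and a "uniform"
group paints a homogeneous membrane marker.

Channels are rasterized as 3-px junction bands over a medial
(cytoplasmic) baseline, optionally blurred and Poisson-noised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from ..datamodel import Frame, SegmentedFrameSeries
from ..geometry import _band_mask, extract_junctions

__all__ = ["ChannelSpec", "ChannelModel", "sample_junction_loadings", "paint_channels"]

GROUPS = ("actomyosin", "crumbs", "control", "uniform")

# high-intensity anti-correlated arm: I/base = ARM_LO + ARM_SPAN * x with
# x the shared activity (or 1 - x for the opposing group); low junctions
# draw independently from LOW_RANGE. With a top-tertile high set these
# constants put the pooled (unfiltered) correlation near zero while the
# filtered correlation is strongly negative.
ARM_LO = 0.3
ARM_SPAN = 1.7
LOW_RANGE = (0.25, 0.85)


@dataclass(frozen=True)
class ChannelSpec:
    group: str = "uniform"
    junctional_base: float = 10.0
    medial_base: float = 2.0
    noise_sd: float = 0.05          # multiplicative per-junction channel noise
    polarity_axis_deg: float = 90.0  # control group only
    polarity_amplitude: float = 0.0  # 0 => expected polarity magnitude 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown channel group {self.group!r}; one of {GROUPS}")
        if self.junctional_base < 0 or self.medial_base < 0:
            raise ValueError("baselines must be >= 0")
        if not 0 <= self.polarity_amplitude <= 1:
            raise ValueError("polarity_amplitude must be in [0, 1]")


@dataclass
class ChannelModel:
    channels: dict[str, ChannelSpec]
    high_quantile: float = 2 / 3     # junction-strength cut for the "high" set
    blur_sigma_px: float = 0.0
    noise: str = "none"              # none | poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0 < self.high_quantile < 1:
            raise ValueError("high_quantile must be in (0, 1)")


def sample_junction_loadings(
    model: ChannelModel,
    junctions: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-junction mean loadings for every channel of the model.

    ``junctions`` needs columns junction_id and orientation_deg. Returns
    the input plus one loading column per channel. One latent strength
    and one latent activity are shared by all channels, producing
    positive within-group and negative between-group correlation on the
    high-strength junctions.
    """
    rng = rng or np.random.default_rng(model.seed)
    n = len(junctions)
    strength = rng.uniform(0, 1, n)
    activity = rng.uniform(0, 1, n)
    high = strength > np.quantile(strength, model.high_quantile) if n else strength > 1
    out = junctions.copy()
    theta = np.radians(out["orientation_deg"].to_numpy(dtype=float))
    for name, spec in model.channels.items():
        base = spec.junctional_base
        if spec.group == "uniform":
            load = np.full(n, base, dtype=float)
        elif spec.group == "control":
            mod = 1.0 + spec.polarity_amplitude * np.cos(
                2 * (theta - np.radians(spec.polarity_axis_deg))
            )
            load = base * mod
        else:
            x = activity if spec.group == "actomyosin" else 1.0 - activity
            arm = base * (ARM_LO + ARM_SPAN * x)
            low = base * rng.uniform(*LOW_RANGE, n)
            load = np.where(high, arm, low)
        if spec.noise_sd > 0:
            load = load * np.clip(1.0 + rng.normal(0, spec.noise_sd, n), 0.05, None)
        out[name] = load
    return out


def paint_channels(
    series: SegmentedFrameSeries,
    model: ChannelModel,
    width_px: int = 3,
) -> tuple[SegmentedFrameSeries, dict[str, dict[tuple[int, int], float]]]:
    """Paint the model's channels onto every frame of the series.

    Junction bands (``width_px``, ~500 nm at the default pixel size)
    carry the per-junction loading, cell interiors the medial baseline;
    the image is then blurred and noised per the model. Loadings are
    drawn once per junction pair, so they are stable across frames.
    Returns the painted series plus the ground-truth painted mean per
    channel and junction.
    """
    rng = np.random.default_rng(model.seed)
    geoms = {}
    for frame in series.frames:
        for jg in extract_junctions(frame, series.calibration, min_pixels=1):
            geoms.setdefault(jg.members, jg)
    jdf = pd.DataFrame(
        {
            "junction_id": [f"{a}|{b}" for a, b in sorted(geoms)],
            "orientation_deg": [geoms[k].orientation_deg for k in sorted(geoms)],
        }
    )
    loadings = sample_junction_loadings(model, jdf, rng)
    loading_by_pair = {
        pair: {name: float(loadings[name].iloc[i]) for name in model.channels}
        for i, pair in enumerate(sorted(geoms))
    }
    truth = {
        name: {pair: vals[name] for pair, vals in loading_by_pair.items()}
        for name in model.channels
    }

    new_frames = []
    for frame in series.frames:
        juncs = extract_junctions(frame, series.calibration, min_pixels=1)
        chans: dict[str, np.ndarray] = {}
        for name, spec in model.channels.items():
            img = np.zeros(frame.labels.shape, dtype=float)
            img[frame.labels > 0] = spec.medial_base
            for jg in juncs:
                band = _band_mask(frame.labels, jg, width_px)
                img[band] = loading_by_pair[jg.members][name]
            if model.blur_sigma_px > 0:
                img = ndimage.gaussian_filter(img, model.blur_sigma_px)
            if model.noise == "poisson":
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            chans[name] = img
        new_frames.append(
            Frame(
                frame_index=frame.frame_index,
                labels=frame.labels,
                channels={**frame.channels, **chans},
            )
        )
    painted = SegmentedFrameSeries(frames=new_frames, calibration=series.calibration)
    return painted, truth
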