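"""Fixed-tissue junctional quantifications: intensity normalization,
per-cell anisotropy (sample SD and Max/Min ratio of junction means),
planar-polarity nematics, 15° orientation binning, and pairwise channel
correlation with the low-intensity junction filter.

Input is a *junction intensity table*: one row per junction × channel
with columns ``embryo_id, junction_id, cell_a, cell_b, channel,
intensity, length_um, orientation_deg`` (cell 0 marks the exterior;
exterior junctions are excluded from per-cell statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import JunctionTrack

__all__ = [
    "junction_table",
    "normalize_intensities",
    "cell_anisotropy",
    "cell_anisotropy_table",
    "AnisotropyRecord",
    "planar_polarity",
    "PolarityNematic",
    "polarity_table",
    "mean_polarity",
    "bin_by_orientation",
    "channel_pair_correlation",
]

TABLE_COLUMNS = [
    "embryo_id",
    "junction_id",
    "cell_a",
    "cell_b",
    "channel",
    "intensity",
    "length_um",
    "orientation_deg",
]


def junction_table(
    junction_tracks: dict[tuple[int, int], JunctionTrack],
    frame: int = 0,
    embryo_id: str = "e0",
) -> pd.DataFrame:
    """Flatten one frame of junction tracks into the intensity table."""
    rows = []
    for (a, b), jt in sorted(junction_tracks.items()):
        rec = jt.records.get(frame)
        if rec is None:
            continue
        for chan, val in rec.intensity.items():
            rows.append(
                (embryo_id, f"{a}|{b}", a, b, chan, val, rec.length_um,
                 rec.orientation_deg)
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def normalize_intensities(
    table: pd.DataFrame,
    mode: str = "embryo_mean",
    medial: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalize junction intensities per channel.

    ``embryo_mean``: divide by the embryo's grand mean junctional
    intensity; ``cohort_mean``: divide by the grand mean pooled over all
    embryos (both genotypes); ``medial``: divide each junction by its own
    cells' medial (cytoplasmic) intensity — junctions between two cells
    use the mean of the two medial values (``medial`` needs columns
    embryo_id, cell_id, channel, intensity).
    """
    out = table.copy()
    out["intensity"] = out["intensity"].astype(float)
    if mode == "embryo_mean":
        for (emb, chan), grp in table.groupby(["embryo_id", "channel"]):
            norm = grp["intensity"].mean()
            if norm == 0:
                raise ValueError(f"zero mean junctional intensity in embryo {emb!r}, "
                                 f"channel {chan!r}")
            out.loc[grp.index, "intensity"] = grp["intensity"] / norm
    elif mode == "cohort_mean":
        for chan, grp in table.groupby("channel"):
            norm = grp["intensity"].mean()
            if norm == 0:
                raise ValueError(f"zero cohort mean for channel {chan!r}")
            out.loc[grp.index, "intensity"] = grp["intensity"] / norm
    elif mode == "medial":
        if medial is None:
            raise ValueError("medial mode requires the medial intensity table")
        med = medial.set_index(["embryo_id", "cell_id", "channel"])["intensity"]
        vals = []
        for _, row in table.iterrows():
            ms = []
            for cell in (row.cell_a, row.cell_b):
                if cell == 0:
                    continue
                key = (row.embryo_id, cell, row.channel)
                if key in med.index:
                    ms.append(float(med.loc[key]))
            if not ms:
                raise ValueError(
                    f"no medial value for junction {row.junction_id} "
                    f"(embryo {row.embryo_id!r})"
                )
            m = float(np.mean(ms))
            if m == 0:
                raise ValueError(
                    f"zero medial normalizer for cell(s) of junction "
                    f"{row.junction_id} in embryo {row.embryo_id!r}"
                )
            vals.append(row.intensity / m)
        out["intensity"] = vals
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


@dataclass
class AnisotropyRecord:
    cell_id: int
    channel: str
    n_junctions: int
    sd: float
    max_min_ratio: float


def cell_anisotropy(intensities: np.ndarray | list[float]) -> tuple[float, float]:
    """(sample SD, Max/Min ratio) of one cell's junction mean intensities."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 retained junctions, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("non-positive junction intensity; ratio undefined")
    return float(x.std(ddof=1)), float(x.max() / x.min())


def _cell_junctions(table: pd.DataFrame) -> pd.DataFrame:
    """Long view keyed by (embryo, cell, channel) with one row per
    junction of that cell; exterior junctions (cell 0) dropped."""
    a = table[table.cell_a != 0].rename(columns={"cell_a": "cell_id"}).drop(columns="cell_b")
    b = table[table.cell_b != 0].rename(columns={"cell_b": "cell_id"}).drop(columns="cell_a")
    return pd.concat([a, b], ignore_index=True)


def cell_anisotropy_table(
    table: pd.DataFrame, min_junctions: int = 3
) -> pd.DataFrame:
    """Per-cell anisotropy for every channel: sample SD across the cell's
    junction mean intensities and the Max/Min ratio. Cells with fewer
    than ``min_junctions`` retained junctions, or any non-positive
    intensity, are excluded."""
    cj = _cell_junctions(table)
    rows = []
    for (emb, cell, chan), grp in cj.groupby(["embryo_id", "cell_id", "channel"]):
        x = grp["intensity"].to_numpy(dtype=float)
        if x.size < min_junctions or np.any(x <= 0):
            continue
        sd, ratio = cell_anisotropy(x)
        rows.append((emb, cell, chan, x.size, sd, ratio))
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "cell_id", "channel", "n_junctions", "sd",
                 "max_min_ratio"],
    )


@dataclass
class PolarityNematic:
    cell_id: int
    channel: str
    magnitude: float
    axis_deg: float
    axis_defined: bool


def planar_polarity(
    intensities: np.ndarray,
    lengths_um: np.ndarray,
    orientations_deg: np.ndarray,
) -> tuple[float, float, bool]:
    """Weighted nematic order parameter of one cell's junctions.

    Q = Σ w_j exp(2iθ_j) / Σ w_j with weights w_j = I_j × L_j; returns
    (|Q|, ½ arg Q folded to [0, 180), axis-defined flag). |Q| = 0 for
    uniform intensity on a centrally symmetric cell; |Q| = 1 when all
    weight lies on one axis.
    """
    w = np.asarray(intensities, dtype=float) * np.asarray(lengths_um, dtype=float)
    if np.all(w == 0):
        return 0.0, 0.0, False
    theta = np.radians(np.asarray(orientations_deg, dtype=float))
    q = np.sum(w * np.exp(2j * theta)) / w.sum()
    mag = float(abs(q))
    if mag < 1e-6:
        return mag, 0.0, False
    axis = float(np.degrees(np.angle(q)) / 2.0 % 180.0)
    return mag, axis, True


def polarity_table(table: pd.DataFrame, min_junctions: int = 3) -> pd.DataFrame:
    """Per-cell planar-polarity nematics for every channel."""
    cj = _cell_junctions(table)
    rows = []
    for (emb, cell, chan), grp in cj.groupby(["embryo_id", "cell_id", "channel"]):
        if len(grp) < min_junctions:
            continue
        mag, axis, ok = planar_polarity(
            grp["intensity"].to_numpy(),
            grp["length_um"].to_numpy(),
            grp["orientation_deg"].to_numpy(),
        )
        rows.append((emb, cell, chan, len(grp), mag, axis, ok))
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "cell_id", "channel", "n_junctions", "magnitude",
                 "axis_deg", "axis_defined"],
    )


def mean_polarity(pol: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Population-mean nematic per channel: average of the per-cell
    nematic vectors (magnitude, axis). Vanishes when cell polarities are
    randomly oriented — the symmetry check for an unpolarized channel."""
    out = {}
    for chan, grp in pol.groupby("channel"):
        q = np.mean(
            grp["magnitude"].to_numpy()
            * np.exp(2j * np.radians(grp["axis_deg"].to_numpy()))
        )
        out[chan] = (float(abs(q)), float(np.degrees(np.angle(q)) / 2.0 % 180.0))
    return out


def bin_by_orientation(
    table: pd.DataFrame, bin_deg: float = 15.0, channel: str | None = None
) -> pd.DataFrame:
    """Mean junction intensity per orientation bin ([0,15), …, [165,180);
    half-open, so a junction at exactly 15° falls in [15, 30)). Empty
    bins are reported with NaN mean and count 0."""
    df = table if channel is None else table[table.channel == channel]
    edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
    idx = np.digitize(df["orientation_deg"].to_numpy(), edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = df[idx == b]
        rows.append(
            (edges[b], edges[b + 1],
             float(sel["intensity"].mean()) if len(sel) else np.nan,
             len(sel))
        )
    return pd.DataFrame(rows, columns=["bin_lo_deg", "bin_hi_deg", "mean_intensity", "n"])


def _minmax_per_embryo(
    table: pd.DataFrame, channels: tuple[str, str], robust: bool = True
) -> pd.DataFrame:
    """Wide per-junction frame with both channels min-max scaled to [0,1]
    per embryo (1st–99th percentile by default, to resist hot pixels)."""
    df = table[table.channel.isin(channels)]
    wide = df.pivot_table(
        index=["embryo_id", "junction_id", "cell_a", "cell_b"],
        columns="channel",
        values="intensity",
    ).dropna().reset_index()
    for chan in channels:
        scaled = np.empty(len(wide))
        for emb, grp in wide.groupby("embryo_id"):
            x = grp[chan].to_numpy(dtype=float)
            lo, hi = (np.percentile(x, [1, 99]) if robust else (x.min(), x.max()))
            if hi <= lo:
                raise ValueError(f"degenerate channel {chan!r} in embryo {emb!r}")
            scaled[wide.embryo_id == emb] = np.clip((x - lo) / (hi - lo), 0, 1)
        wide[chan] = scaled
    return wide


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("degenerate (constant) channel; correlation undefined")
        return float("nan")
    if method == "spearman":
        x = pd.Series(x).rank().to_numpy()
        y = pd.Series(y).rank().to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    return float(np.corrcoef(x, y)[0, 1])


def channel_pair_correlation(
    table: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    filter_low: float | None = None,
    group_by_cell: bool = False,
    method: str = "pearson",
    robust_minmax: bool = True,
    min_pooled: int = 10,
    min_per_cell: int = 5,
):
    """Correlation of two channels' junction intensities.

    Both channels are min-max normalized to [0, 1] per embryo. With
    ``filter_low`` = q, junctions whose max across the two channels is at
    or below the q-quantile of that max are removed — the filter that
    reveals reciprocal (anti-correlated) enrichment confined to
    high-intensity junctions. Returns pooled r, or the per-cell r
    distribution (DataFrame) when ``group_by_cell``.
    """
    wide = _minmax_per_embryo(table, (channel_a, channel_b), robust_minmax)
    if filter_low is not None:
        mx = wide[[channel_a, channel_b]].max(axis=1)
        wide = wide[mx > mx.quantile(filter_low)]
    if not group_by_cell:
        if len(wide) < min_pooled:
            raise ValueError(
                f"only {len(wide)} junctions after filtering (need >= {min_pooled})"
            )
        return _corr(
            wide[channel_a].to_numpy(), wide[channel_b].to_numpy(), method
        )
    cj = pd.concat(
        [
            wide[wide.cell_a != 0].rename(columns={"cell_a": "cell_id"}),
            wide[wide.cell_b != 0].rename(columns={"cell_b": "cell_id"}),
        ],
        ignore_index=True,
    )
    rows = []
    for (emb, cell), grp in cj.groupby(["embryo_id", "cell_id"]):
        if len(grp) < min_per_cell:
            continue
        rows.append(
            (emb, cell, len(grp),
             _corr(grp[channel_a].to_numpy(), grp[channel_b].to_numpy(), method))
        )
    return pd.DataFrame(rows, columns=["embryo_id", "cell_id", "n_junctions", "r"])
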