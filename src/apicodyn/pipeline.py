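"""Pipeline orchestration: simulate → measure → kinetics → events →
anisotropy from one config, with deterministic seed fan-out and full
parameter echo.

The config is a plain mapping (usually loaded from YAML). Every numeric
default is echoed to ``config_echo.yaml`` in the output directory, so a
run is reproducible from its artifacts alone. One global seed is fanned
out to per-stage child seeds via ``numpy.random.SeedSequence(seed).spawn``,
so stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anisotropy as aniso
from . import events as ev
from . import io as adio
from . import kinetics as kin
from . import tracks as trk
from .datamodel import Calibration
from .synthetic import (
    ChannelModel,
    ChannelSpec,
    DynamicsParams,
    generate_tissue,
    paint_channels,
    simulate_dynamics,
)

__all__ = ["default_config", "run", "stage_seeds", "MissingArtifactError"]

log = logging.getLogger("apicodyn")


class MissingArtifactError(FileNotFoundError):
    """A stage dependency (an earlier stage's output file) is missing."""


def default_config() -> dict:
    """Full default config; houses the pipeline's standard constants
    (5-min frames, k = 1 threshold, 30-min event window, 40-µm streak
    domain, 3-px intensity lines, 15° orientation bins)."""
    return {
        "seed": 0,
        "stages": ["simulate", "measure", "kinetics", "events", "anisotropy"],
        "calibration": {
            "pixel_size_um": 0.17,
            "frame_interval_min": 5.0,
            "streak_halfwidth_um": 20.0,
        },
        "simulate": {
            "n_cells": 36,
            "mean_area_um2": 45.0,
            "n_frames": 24,
            "ingressing_fraction": 0.3,
            "channels": {},  # name -> ChannelSpec kwargs
            "blur_sigma_px": 0.0,
            "noise": "none",
        },
        "measure": {"min_junction_pixels": 2, "intensity_width_px": 3},
        "kinetics": {
            "threshold_k": 1.0,
            "merge_gap": 0,
            "smoothing_window": 3,
            "reexpansion_tol_um2": 0.5,
            "min_total_decline_frac": 0.5,
        },
        "events": {"window_min": 30.0, "domain": "streak"},
        "anisotropy": {
            "normalization": "embryo_mean",
            "bin_deg": 15.0,
            "filter_low_quantile": 0.5,
            "method": "pearson",
            "pairs": [],  # [[channel_a, channel_b], ...]
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from the global seed."""
    names = ["simulate", "channels", "measure", "kinetics", "events", "anisotropy"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {stage!r} needs missing artifact: {path}"
        )
    return path


def run(config: dict | None = None, out_dir: str | Path = "apicodyn_run") -> Path:
    """Run the configured stages; returns the artifact directory.

    Deterministic under a fixed seed: re-running with the same config
    reproduces all CSV outputs byte-identically.
    """
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seeds = stage_seeds(int(cfg["seed"]))
    stages = cfg["stages"]
    calib = Calibration(**cfg["calibration"])
    dt = calib.frame_interval_min

    if "simulate" in stages:
        scfg = cfg["simulate"]
        log.info("simulate: n_cells=%d n_frames=%d seed=%d",
                 scfg["n_cells"], scfg["n_frames"], seeds["simulate"])
        tissue = generate_tissue(
            scfg["n_cells"],
            mean_area_um2=scfg["mean_area_um2"],
            pixel_size_um=calib.pixel_size_um,
            frame_interval_min=dt,
            seed=seeds["simulate"],
        )
        params = DynamicsParams(
            n_frames=scfg["n_frames"],
            frame_interval_min=dt,
            ingressing_fraction=scfg["ingressing_fraction"],
            seed=seeds["simulate"],
        )
        series, truth = simulate_dynamics(tissue, params)
        if scfg["channels"]:
            model = ChannelModel(
                channels={
                    name: ChannelSpec(**kw) for name, kw in scfg["channels"].items()
                },
                blur_sigma_px=scfg["blur_sigma_px"],
                noise=scfg["noise"],
                seed=seeds["channels"],
            )
            series, painted = paint_channels(series, model)
            truth.painted_junction_means = painted
        adio.write_series(series, out / "series")
        truth.to_json(out / "ground_truth.json")

    if "measure" in stages:
        mcfg = cfg["measure"]
        series = adio.read_series(_require(out / "series", "measure"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cell_tracks, junction_tracks = trk.build_tracks(
                series,
                min_junction_pixels=mcfg["min_junction_pixels"],
                intensity_width_px=mcfg["intensity_width_px"],
            )
        adio.write_tables(cell_tracks, junction_tracks, out / "tables",
                          calibration=series.calibration)
        log.info("measure: %d cell tracks, %d junction tracks",
                 len(cell_tracks), len(junction_tracks))

    if {"kinetics", "events"} & set(stages):
        series = adio.read_series(_require(out / "series", "kinetics"))
        _require(out / "tables" / "cells.csv", "kinetics")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cell_tracks, junction_tracks = trk.build_tracks(series)
        last_frame = series.frames[-1].frame_index

    if "kinetics" in stages:
        kcfg = cfg["kinetics"]
        ingress_ids = [
            cid for cid, tr in cell_tracks.items()
            if tr.last_frame < last_frame and not tr.records[tr.last_frame].border_touching
        ]
        ref_series = [
            kin.rate_series(tr.area_series()[1], dt, entity_id=cid)
            for cid, tr in cell_tracks.items()
            if cid not in ingress_ids and not tr.ever_border_touching()
        ]
        pool = kin.pool_contraction_rates(ref_series)
        threshold = kin.reference_threshold(pool, k=kcfg["threshold_k"])
        log.info("kinetics: threshold %.3f um2/min (mean %.3f sd %.3f, k=%g)",
                 threshold.threshold, threshold.reference_mean,
                 threshold.reference_sd, threshold.k)
        ann_rows, pulse_rows = [], []
        for cid in ingress_ids:
            ann = kin.annotate_constriction(
                cell_tracks[cid], threshold, last_frame, dt,
                merge_gap=kcfg["merge_gap"],
                smoothing_window=kcfg["smoothing_window"],
                reexpansion_tol_um2=kcfg["reexpansion_tol_um2"],
                min_total_decline_frac=kcfg["min_total_decline_frac"],
            )
            if ann.censored or ann.unclassifiable:
                ann_rows.append((cid, np.nan, np.nan, 0, np.nan, np.nan, np.nan,
                                 ann.censored, ann.unclassifiable))
                continue
            fr = ann.fractions
            ann_rows.append(
                (cid, ann.constriction_start_frame, ann.ingression_frame,
                 len(ann.pulses), ann.mean_constriction_rate,
                 fr.contracting, fr.expanding, ann.censored, ann.unclassifiable)
            )
            for k, pu in enumerate(ann.pulses, start=1):
                pulse_rows.append(
                    (cid, k, pu.start_frame, pu.end_frame, pu.magnitude)
                )
        pd.DataFrame(
            ann_rows,
            columns=["cell_id", "start_frame", "ingression_frame", "n_pulses",
                     "mean_constriction_rate", "frac_contracting",
                     "frac_expanding", "censored", "unclassifiable"],
        ).to_csv(out / "annotations.csv", index=False)
        pd.DataFrame(
            pulse_rows,
            columns=["cell_id", "pulse", "start_frame", "end_frame",
                     "magnitude_um2_min"],
        ).to_csv(out / "pulses.csv", index=False)
        with (out / "threshold.json").open("w") as fh:
            json.dump(
                {"mean": threshold.reference_mean, "sd": threshold.reference_sd,
                 "k": threshold.k, "threshold": threshold.threshold}, fh, indent=2,
            )

    if "events" in stages:
        ecfg = cfg["events"]
        calib_run = series.calibration
        events = ev.detect_ingressions(cell_tracks, last_frame, calib_run)
        ev.classify_event_clusters(events, cell_tracks, window_min=ecfg["window_min"])
        pd.DataFrame(
            [
                (e.cell_id, e.time_min, e.last_centroid_um[0], e.last_centroid_um[1],
                 e.in_streak_domain, e.cluster_id, e.cluster_size)
                for e in events
            ],
            columns=["cell_id", "time_min", "x_um", "y_um", "in_streak",
                     "cluster_id", "cluster_size"],
        ).to_csv(out / "events.csv", index=False)
        summary: dict = {
            "n_events": len(events),
            "cluster_size_fractions": ev.cluster_size_fractions(events),
        }
        total_min = last_frame * dt
        if total_min >= 60.0:
            rate = ev.ingression_rate_per_hour(
                events, cell_tracks, calib_run, last_frame, domain=ecfg["domain"]
            )
            summary["ingression_rate_per_hour"] = {
                "mean": rate.mean, "sem": rate.sem, "n_windows": rate.n_windows
            }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("events: %d ingressions", len(events))

    if "anisotropy" in stages:
        acfg = cfg["anisotropy"]
        series = adio.read_series(_require(out / "series", "anisotropy"))
        _require(out / "tables" / "junctions.csv", "anisotropy")
        if not series.channel_names:
            log.info("anisotropy: no channels painted; stage skipped")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, junction_tracks = trk.build_tracks(series)
            table = aniso.junction_table(junction_tracks, frame=series.frames[0].frame_index)
            table = table[(table.cell_a != 0) & (table.cell_b != 0)]
            norm = aniso.normalize_intensities(table, acfg["normalization"])
            aniso.cell_anisotropy_table(norm).to_csv(out / "anisotropy.csv", index=False)
            pol = aniso.polarity_table(norm)
            pol.to_csv(out / "polarity.csv", index=False)
            bins = pd.concat(
                [
                    aniso.bin_by_orientation(norm, acfg["bin_deg"], channel=ch)
                    .assign(channel=ch)
                    for ch in series.channel_names
                ]
            )
            bins.to_csv(out / "orientation_bins.csv", index=False)
            corrs = {}
            for pair in acfg["pairs"]:
                a, b = pair
                corrs[f"{a}:{b}"] = {
                    "unfiltered_r": aniso.channel_pair_correlation(
                        table, a, b, filter_low=None, method=acfg["method"]
                    ),
                    "filtered_r": aniso.channel_pair_correlation(
                        table, a, b, filter_low=acfg["filter_low_quantile"],
                        method=acfg["method"],
                    ),
                }
            (out / "correlations.json").write_text(json.dumps(corrs, indent=2))
            log.info("anisotropy: %d cells, %d pairs", pol.cell_id.nunique(),
                     len(corrs))
    return out
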