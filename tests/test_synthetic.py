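"""Generator contracts: determinism, area bookkeeping, programmed-event
ground truth, and the statistical structure of painted channels."""

import numpy as np
import pandas as pd
import pytest

from apicodyn import kinetics
from apicodyn.synthetic import (
    ChannelModel,
    ChannelSpec,
    DynamicsParams,
    constriction_schedule,
    generate_tissue,
    oscillation_rates,
    paint_channels,
    sample_area_schedules,
    sample_junction_loadings,
    simulate_dynamics,
)

from conftest import CAL


def test_same_seed_is_pixel_identical():
    a = generate_tissue(20, seed=7).to_series().frames[0].labels
    b = generate_tissue(20, seed=7).to_series().frames[0].labels
    np.testing.assert_array_equal(a, b)


def test_three_collinear_seeds_still_tile():
    t = generate_tissue(3, field_size_um=(20.0, 20.0), seed=0)
    labels = t.to_series().frames[0].labels
    assert set(np.unique(labels)) == {1, 2, 3}


def test_mean_area_matches_field_partition():
    t = generate_tissue(100, seed=3)
    labels = t.to_series().frames[0].labels
    px2 = t.calibration.pixel_size_um**2
    areas = np.bincount(labels.ravel())[1:] * px2
    field_area = labels.size * px2
    assert areas.mean() == pytest.approx(field_area / 100, rel=0.05)


def test_too_small_field_rejected():
    with pytest.raises(ValueError):
        generate_tissue(100, field_size_um=(1.0, 1.0))


def test_no_ingressions_means_no_label_loss():
    t = generate_tissue(12, seed=5)
    series, truth = simulate_dynamics(
        t, DynamicsParams(n_frames=8, ingressing_fraction=0.0, seed=1)
    )
    assert truth.cells == {}
    first = set(np.unique(series.frames[0].labels))
    for fr in series.frames[1:]:
        assert set(np.unique(fr.labels)) == first


def test_total_labelled_area_is_conserved(dynamics_run):
    """Neighbors absorb every freed pixel: no holes, no leaks."""
    series, _ = dynamics_run
    counts = [(fr.labels > 0).sum() for fr in series.frames]
    assert len(set(counts)) == 1


def test_labels_disappear_exactly_at_ingression(dynamics_run):
    series, truth = dynamics_run
    for cid, ct in truth.cells.items():
        present = [f.frame_index for f in series.frames if (f.labels == cid).any()]
        assert max(present) == ct.ingression_frame
        assert min(present) == 0


def test_programmed_three_pulse_recovery_through_pipeline():
    """One isolated ingressing cell with pulses 1.0/1.5/2.0 µm²/min:
    measured rates show 3 supra-threshold runs, magnitudes within 15%."""
    from apicodyn.synthetic.dynamics import (
        CellTruth,
        GroundTruth,
        PulseTruth,
        _drive_cell_to_area,
    )
    from apicodyn import tracks as trk

    t = generate_tissue(30, seed=21)
    mesh = t.mesh
    interior = sorted(set(mesh.cells) - mesh.border_cells())
    cid = next(c for c in interior if mesh.area(c) > 40)
    a0 = mesh.area(cid)
    # schedule: P(1.0) g P(1.5) g P(2.0) then drain
    mags = [1.0, 1.5, 2.0]
    rates = []
    pulses = []
    for k, m in enumerate(mags):
        pulses.append(PulseTruth(start=len(rates), stop=len(rates), magnitude=m))
        rates.append(m)
        rates.append(0.2)
    areas = [a0]
    for r in rates:
        areas.append(areas[-1] - 5.0 * r)
    edges = mesh.cell_edges(cid)
    for k, target in enumerate(areas[1:]):
        sched = edges[k % len(edges) : k % len(edges) + 2]
        _drive_cell_to_area(mesh, cid, target, sched)
        img = mesh.rasterize(CAL.pixel_size_um)
        measured = (img == cid).sum() * CAL.pixel_size_um**2
        assert measured == pytest.approx(target, abs=0.6)
    meas_areas = []
    mesh2 = generate_tissue(30, seed=21).mesh  # fresh copy for the movie
    frames = []
    from apicodyn.datamodel import Frame, SegmentedFrameSeries

    for k, target in enumerate(areas):
        if k > 0:
            sched = edges[(k - 1) % len(edges) : (k - 1) % len(edges) + 2]
            _drive_cell_to_area(mesh2, cid, target, sched)
        frames.append(Frame(frame_index=k, labels=mesh2.rasterize(CAL.pixel_size_um)))
    series = SegmentedFrameSeries(frames=frames, calibration=CAL)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cell_tracks, _ = trk.build_tracks(series)
    _, meas = cell_tracks[cid].area_series()
    rs = kinetics.rate_series(meas, 5.0)
    detected = kinetics.detect_pulses(rs, 0.7)
    assert len(detected) == 3
    for det, prog in zip(detected, mags):
        assert det.magnitude == pytest.approx(prog, rel=0.15)


def test_schedule_consumes_area_budget():
    rng = np.random.default_rng(0)
    for a0 in (20.0, 45.0, 80.0):
        rates, pulses = constriction_schedule(rng, a0)
        a_end = a0 - 5.0 * rates.sum()
        assert 0.2 < a_end < 6.5
        assert 2 <= len(pulses) <= 4 or a0 <= 25
        for pu in pulses:
            assert pu.magnitude == pytest.approx(
                rates[pu.start : pu.stop + 1].max()
            )
        # pulses disjoint and ordered
        for p1, p2 in zip(pulses, pulses[1:]):
            assert p1.stop < p2.start


def test_balanced_oscillation_population_mean():
    rng = np.random.default_rng(9)
    means = [oscillation_rates(rng, 24).mean() for _ in range(100)]
    assert abs(np.mean(means)) < 0.05


def test_cluster_plan_members_are_adjacent(dynamics_run):
    _, truth = dynamics_run
    groups: dict[int, list[int]] = {}
    for cid, ct in truth.cells.items():
        groups.setdefault(ct.cluster_id, []).append(cid)
    from conftest import generate_tissue as _  # noqa: F401

    for members in groups.values():
        sizes = {truth.cells[c].cluster_size for c in members}
        assert sizes == {len(members)}


def _loading_table(seed: int, n: int = 300) -> pd.DataFrame:
    model = ChannelModel(
        channels={
            "myosin": ChannelSpec(group="actomyosin"),
            "myosin2": ChannelSpec(group="actomyosin"),
            "crumbs": ChannelSpec(group="crumbs"),
        },
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    jdf = pd.DataFrame(
        {
            "junction_id": [f"{i}|{i+1}" for i in range(n)],
            "orientation_deg": rng.uniform(0, 180, n),
        }
    )
    return sample_junction_loadings(model, jdf, rng)


def test_two_group_latent_structure():
    df = _loading_table(0, n=2000)
    hi = df[["myosin", "crumbs"]].max(axis=1) > df[["myosin", "crumbs"]].max(axis=1).median()
    r_all = np.corrcoef(df.myosin, df.crumbs)[0, 1]
    r_hi = np.corrcoef(df.myosin[hi], df.crumbs[hi])[0, 1]
    r_within = np.corrcoef(df.myosin, df.myosin2)[0, 1]
    assert abs(r_all) < 0.25          # unfiltered ~ 0
    assert r_hi < -0.3                # filtered strongly negative
    assert r_within > 0.5             # within-group positive


def test_painted_uniform_channel_measures_exactly(tissue):
    series = tissue.to_series()
    model = ChannelModel(
        channels={"mem": ChannelSpec(group="uniform", junctional_base=7.0,
                                     medial_base=7.0, noise_sd=0.0)},
        blur_sigma_px=0.0,
        noise="none",
        seed=0,
    )
    painted, truth = paint_channels(series, model)
    assert set(truth["mem"].values()) == {7.0}
    chan = painted.frames[0].channels["mem"]
    inside = painted.frames[0].labels > 0
    assert np.all(chan[inside] == 7.0)


def test_polarized_control_has_axis_and_zero_amplitude_is_flat():
    df_rows = []
    rng = np.random.default_rng(4)
    jdf = pd.DataFrame(
        {"junction_id": [str(i) for i in range(500)],
         "orientation_deg": rng.uniform(0, 180, 500)}
    )
    for amp in (0.0, 0.6):
        model = ChannelModel(
            channels={"celsr": ChannelSpec(group="control", polarity_axis_deg=90.0,
                                           polarity_amplitude=amp, noise_sd=0.0)},
            seed=1,
        )
        load = sample_junction_loadings(model, jdf, np.random.default_rng(1))
        df_rows.append(load)
    flat, polar = df_rows
    assert flat["celsr"].std() == pytest.approx(0.0, abs=1e-12)
    near_axis = np.abs(jdf.orientation_deg - 90) < 15
    off_axis = np.minimum(jdf.orientation_deg, 180 - jdf.orientation_deg) < 15
    assert polar["celsr"][near_axis].mean() > polar["celsr"][off_axis].mean()


def test_explicit_cluster_plan_is_realized():
    t = generate_tissue(40, seed=2)
    params = DynamicsParams(n_frames=20, cluster_plan={1: 2, 2: 1, 3: 1}, seed=3)
    _, truth = simulate_dynamics(t, params)
    sizes = sorted(ct.cluster_size for ct in truth.cells.values())
    assert sizes == [1, 1, 2, 2, 3, 3, 3]


def test_unrealizable_cluster_plan_raises():
    t = generate_tissue(12, seed=2)
    params = DynamicsParams(n_frames=20, cluster_plan={4: 20}, seed=3)
    with pytest.raises(ValueError, match="unrealizable"):
        simulate_dynamics(t, params)


def test_unknown_channel_group_rejected():
    with pytest.raises(ValueError):
        ChannelSpec(group="nonsense")
    with pytest.raises(ValueError):
        ChannelModel(channels={}, noise="salt-and-pepper")
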