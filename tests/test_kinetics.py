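"""Rate series, thresholds, pulse and period detection, phase fractions,
and junction-shrinkage statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apicodyn import kinetics
from apicodyn.datamodel import CellRecord, CellTrack, JunctionRecord, JunctionTrack


def _cell_track(areas, first=0, border=False):
    return CellTrack(
        cell_id=1,
        records={
            first + i: CellRecord(
                frame=first + i,
                area_um2=float(a),
                centroid_um=(0.0, 0.0),
                elongation_index=0.0,
                elongation_angle_deg=0.0,
                neighbor_ids=frozenset(),
                junction_count=6,
                border_touching=border,
            )
            for i, a in enumerate(areas)
        },
    )


def _junction_track(jid, lengths, first=0):
    return JunctionTrack(
        junction_id=jid,
        records={
            first + i: JunctionRecord(
                frame=first + i, length_um=float(l), orientation_deg=0.0,
                pixel_count=10,
            )
            for i, l in enumerate(lengths)
        },
    )


def test_rate_series_arithmetic():
    rs = kinetics.rate_series([50.0, 48.0, 45.0, 45.0], 5.0)
    np.testing.assert_allclose(rs.rates, [0.4, 0.6, 0.0])


def test_rate_series_signs_and_errors():
    assert np.all(kinetics.rate_series([1.0, 1.0, 1.0], 5.0).rates == 0)
    assert np.all(kinetics.rate_series([1.0, 2.0, 4.0], 5.0).rates < 0)
    with pytest.raises(ValueError):
        kinetics.rate_series([1.0], 5.0)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(1.0, 500.0), min_size=2, max_size=40),
    st.floats(0.5, 20.0),
)
def test_telescoping_identity(values, dt):
    """Σ rate(t) × Δt = value(first) - value(last), exactly."""
    rs = kinetics.rate_series(values, dt)
    assert rs.rates.sum() * dt == pytest.approx(values[0] - values[-1], abs=1e-9)


def test_reference_threshold_arithmetic():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 200)
    x = 0.3 + 0.4 * (x - x.mean()) / x.std(ddof=1)  # mean .3, sample SD .4
    thr = kinetics.reference_threshold(x, k=1.0)
    assert thr.threshold == pytest.approx(0.7, abs=1e-12)
    assert kinetics.reference_threshold(x, k=0.0).threshold == pytest.approx(0.3)
    with pytest.raises(ValueError):
        kinetics.reference_threshold(np.array([]))


def test_reference_threshold_monte_carlo():
    """Draws from normal(0.3, 0.4²) reproduce the ~0.7 µm²/min rule."""
    rng = np.random.default_rng(123)
    draws = rng.normal(0.3, 0.4, 1000)
    thr = kinetics.reference_threshold(draws)
    se = 0.4 * np.sqrt(1 / 1000 + 1 / (2 * (1000 - 1)))  # s.e. of mean + of SD
    assert thr.threshold == pytest.approx(0.7, abs=3 * (se * 2))


def test_detect_pulses_example():
    pulses = kinetics.detect_pulses(
        np.array([0.2, 0.9, 1.2, 0.3, 0.8, 0.1]), 0.7
    )
    assert [(p.start_frame, p.end_frame, p.magnitude) for p in pulses] == [
        (1, 2, 1.2),
        (4, 4, 0.8),
    ]
    assert kinetics.detect_pulses(np.array([0.1, 0.2]), 0.7) == []


def test_detect_pulses_merge_gap():
    rates = np.array([1.0, 0.1, 1.0])
    assert len(kinetics.detect_pulses(rates, 0.7, merge_gap=0)) == 2
    merged = kinetics.detect_pulses(rates, 0.7, merge_gap=1)
    assert len(merged) == 1 and merged[0].magnitude == 1.0


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(-2, 4), min_size=3, max_size=60), st.floats(0, 1.5))
def test_threshold_monotonicity(rates, bump):
    """Raising the threshold shrinks the supra-threshold frame set (a run
    may split, so the pulse COUNT is not monotone — e.g. [2,1,2] with
    thresholds 0.5 vs 1.5 — but every frame in a higher-threshold pulse
    lies in some lower-threshold pulse)."""
    lo = kinetics.detect_pulses(np.array(rates), 0.5)
    hi = kinetics.detect_pulses(np.array(rates), 0.5 + bump)
    lo_frames = {f for p in lo for f in range(p.start_frame, p.end_frame + 1)}
    hi_frames = {f for p in hi for f in range(p.start_frame, p.end_frame + 1)}
    assert hi_frames <= lo_frames


def test_pulse_partition_is_disjoint_and_complete():
    areas = np.concatenate([[60.0], 60 - np.cumsum([1, 6, 7, 1, 5, 6, 1, 30])])
    track = _cell_track(areas)
    ann = kinetics.annotate_constriction(track, 0.7, series_last_frame=20,
                                         frame_interval_min=5.0)
    pulse_frames = {
        f for p in ann.pulses for f in range(p.start_frame, p.end_frame + 1)
    }
    assert pulse_frames.isdisjoint(ann.stable_frames)
    period_frames = set(range(ann.constriction_start_frame + 1,
                              ann.ingression_frame + 1))
    assert pulse_frames | set(ann.stable_frames) == period_frames


def test_period_detection_strict_decline_starts_at_first_frame():
    track = _cell_track(np.linspace(50, 2, 10))
    ann = kinetics.detect_constriction_period(track, series_last_frame=30)
    assert not ann.censored
    assert ann.constriction_start_frame == 0
    assert ann.ingression_frame == 9


def test_period_detection_flat_then_decline():
    areas = np.concatenate([np.full(10, 50.0), np.linspace(50, 2, 12)[1:]])
    track = _cell_track(areas)
    ann = kinetics.detect_constriction_period(
        track, series_last_frame=40, smoothing_window=3
    )
    assert abs(ann.constriction_start_frame - 9) <= 1  # onset ± half-window


def test_period_detection_censoring():
    track = _cell_track(np.linspace(50, 10, 10))
    ann = kinetics.detect_constriction_period(track, series_last_frame=9)
    assert ann.censored and ann.ingression_frame is None
    border = _cell_track(np.linspace(50, 10, 10), border=True)
    ann2 = kinetics.detect_constriction_period(border, series_last_frame=30)
    assert ann2.censored


def test_phase_time_fractions_examples():
    pf = kinetics.phase_time_fractions(np.array([1.0, -1.0, 1.0, -1.0]))
    assert (pf.contracting, pf.expanding, pf.stable) == (0.5, 0.5, 0.0)
    assert pf.mean_contraction_rate == 1.0 and pf.mean_expansion_rate == 1.0
    pf2 = kinetics.phase_time_fractions(np.array([0.4, 0.6, 0.0]))
    assert (pf2.contracting, pf2.expanding, pf2.stable) == pytest.approx(
        (2 / 3, 0.0, 1 / 3)
    )
    with pytest.raises(ValueError):
        kinetics.phase_time_fractions(np.array([]))


def test_nonigressing_cells_contract_half_the_time():
    from apicodyn.synthetic import oscillation_rates

    rng = np.random.default_rng(6)
    fracs = [
        kinetics.phase_time_fractions(oscillation_rates(rng, 24)).contracting
        for _ in range(100)
    ]
    assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)


def test_junction_shrinkage_by_phase_example():
    """One junction shrinking 0.5 µm/frame only during pulse 1."""
    ann = kinetics.ConstrictionAnnotation(
        cell_id=1, constriction_start_frame=0, ingression_frame=6,
        pulses=[kinetics.Pulse(1, 2, 1.0), kinetics.Pulse(5, 5, 1.0)],
    )
    lengths = [5.0, 4.5, 4.0, 4.0, 4.0, 4.0, 4.0]
    jt = _junction_track((1, 2), lengths)
    out = kinetics.junction_shrinkage_by_phase({(1, 2): jt}, ann, 5.0)
    assert list(out.columns) == ["pulse_1", "stable_1", "pulse_2"]
    assert out.loc["1|2", "pulse_1"] == pytest.approx(0.1)
    assert out.loc["1|2", "stable_1"] == pytest.approx(0.0)
    assert out.loc["1|2", "pulse_2"] == pytest.approx(0.0)


def test_junction_created_mid_period_yields_missing():
    ann = kinetics.ConstrictionAnnotation(
        cell_id=1, constriction_start_frame=0, ingression_frame=6,
        pulses=[kinetics.Pulse(1, 2, 1.0), kinetics.Pulse(5, 5, 1.0)],
    )
    late = _junction_track((1, 3), [4.0, 3.5, 3.0], first=4)
    out = kinetics.junction_shrinkage_by_phase([late], ann, 5.0)
    assert np.isnan(out.loc["1|3", "pulse_1"])
    assert out.loc["1|3", "pulse_2"] == pytest.approx(0.1)


def test_scheduled_junctions_shrink_fastest_in_their_pulse(dynamics_run,
                                                           dynamics_tracks):
    series, truth = dynamics_run
    _, junction_tracks = dynamics_tracks
    checked = 0
    for cid, ct in truth.cells.items():
        if ct.cluster_size > 1:
            continue
        ann = kinetics.ConstrictionAnnotation(
            cell_id=cid,
            constriction_start_frame=ct.constriction_start_frame,
            ingression_frame=ct.ingression_frame,
            pulses=[
                kinetics.Pulse(
                    ct.constriction_start_frame + 1 + pu.start,
                    ct.constriction_start_frame + 1 + pu.stop,
                    pu.magnitude,
                )
                for pu in ct.pulses
            ],
        )
        cell_juncs = {
            k: jt for k, jt in junction_tracks.items() if cid in k and 0 not in k
        }
        if len(cell_juncs) < 3:
            continue
        table = kinetics.junction_shrinkage_by_phase(cell_juncs, ann, 5.0)
        for k, pu in enumerate(ct.pulses, start=1):
            col = f"pulse_{k}"
            sched = [f"{a}|{b}" for a, b in pu.junctions if f"{a}|{b}" in table.index]
            others = [j for j in table.index if j not in sched]
            if not sched or not others:
                continue
            med_sched = np.nanmedian(table.loc[sched, col])
            med_other = np.nanmedian(table.loc[others, col])
            if np.isnan(med_sched) or np.isnan(med_other):
                continue
            checked += 1
            assert med_sched >= med_other - 0.02
    assert checked >= 3


def test_correlation_matrix_identities_and_oracle():
    a = _junction_track((1, 2), [5, 4, 3, 2, 1])
    b = _junction_track((1, 3), [5, 4, 3, 2, 1])
    m = kinetics.junction_length_correlation([a, b])
    assert m.loc["1|2", "1|3"] == pytest.approx(1.0)
    refl = _junction_track((1, 4), [1, 2, 3, 4, 5])
    m2 = kinetics.junction_length_correlation([a, refl])
    assert m2.loc["1|2", "1|4"] == pytest.approx(-1.0)
    rng = np.random.default_rng(0)
    xs = [_junction_track((1, k), rng.uniform(1, 9, 8)) for k in range(2, 6)]
    m3 = kinetics.junction_length_correlation(xs)
    for i in range(2, 6):
        for j in range(i + 1, 6):
            x = np.array([xs[i - 2].records[f].length_um for f in range(8)])
            y = np.array([xs[j - 2].records[f].length_um for f in range(8)])
            # textbook formula, computed independently
            r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert m3.loc[f"1|{i}", f"1|{j}"] == pytest.approx(r, abs=1e-12)


def test_correlation_zero_variance_is_missing():
    a = _junction_track((1, 2), [5, 4, 3, 2])
    const = _junction_track((1, 3), [2, 2, 2, 2])
    with pytest.warns(UserWarning, match="zero-variance"):
        m = kinetics.junction_length_correlation([a, const])
    assert np.isnan(m.loc["1|2", "1|3"])
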