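"""Normalization, anisotropy parameters, polarity nematics, orientation
bins and channel-pair correlation with the low-intensity filter."""

import numpy as np
import pandas as pd
import pytest

from apicodyn import anisotropy as an


def _table(rows):
    return pd.DataFrame(rows, columns=an.TABLE_COLUMNS)


def _junc(jid, a, b, chan, inten, length=3.0, theta=0.0, emb="e0"):
    return (emb, jid, a, b, chan, inten, length, theta)


def test_embryo_mean_normalization():
    t = _table([_junc(f"j{i}", 1, 2, "c", v) for i, v in enumerate([2, 4, 6])])
    out = an.normalize_intensities(t, "embryo_mean")
    assert sorted(out.intensity) == [0.5, 1.0, 1.5]


def test_medial_normalization_uses_mean_of_members():
    t = _table([_junc("j0", 1, 2, "c", 8.0)])
    medial = pd.DataFrame(
        [("e0", 1, "c", 2.0), ("e0", 2, "c", 2.0)],
        columns=["embryo_id", "cell_id", "channel", "intensity"],
    )
    out = an.normalize_intensities(t, "medial", medial=medial)
    assert out.intensity.iloc[0] == pytest.approx(4.0)


def test_cohort_normalizer_pools_embryos():
    rows = [_junc(f"a{i}", 1, 2, "c", 5.0, emb="e0") for i in range(4)]
    rows += [_junc(f"b{i}", 1, 2, "c", 10.0, emb="e1") for i in range(4)]
    out = an.normalize_intensities(_table(rows), "cohort_mean")
    np.testing.assert_allclose(
        sorted(set(np.round(out.intensity, 12))), [5 / 7.5, 10 / 7.5]
    )


def test_zero_normalizer_raises():
    t = _table([_junc("j0", 1, 2, "c", 0.0)])
    with pytest.raises(ValueError, match="zero"):
        an.normalize_intensities(t, "embryo_mean")


def test_anisotropy_fixture_values():
    sd, ratio = an.cell_anisotropy([2.0, 4.0, 8.0])
    assert sd == pytest.approx(3.05505, abs=1e-4)   # sample SD
    assert ratio == pytest.approx(4.0)
    sd0, ratio0 = an.cell_anisotropy([5.0, 5.0, 5.0, 5.0])
    assert (sd0, ratio0) == (0.0, 1.0)
    with pytest.raises(ValueError):
        an.cell_anisotropy([1.0, 2.0])
    with pytest.raises(ValueError):
        an.cell_anisotropy([1.0, 0.0, 2.0])


def test_anisotropy_table_excludes_sparse_and_nonpositive_cells():
    rows = [_junc(f"j{i}", 1, 2 + i, "c", v) for i, v in enumerate([2, 4, 8])]
    rows += [_junc("k0", 9, 10, "c", 0.0), _junc("k1", 9, 11, "c", 1.0),
             _junc("k2", 9, 12, "c", 2.0)]
    out = an.cell_anisotropy_table(_table(rows))
    assert set(out.cell_id) == {1}  # cell 9 has a zero; others < 3 junctions
    assert out.sd.iloc[0] == pytest.approx(3.05505, abs=1e-4)


def test_polarity_regular_hexagon_is_zero():
    theta = np.array([0.0, 60.0, 120.0, 0.0, 60.0, 120.0])
    mag, axis, ok = an.planar_polarity(
        np.ones(6), np.ones(6), theta
    )
    assert mag == pytest.approx(0.0, abs=1e-12)
    assert not ok


def test_polarity_single_axis_is_one():
    mag, axis, ok = an.planar_polarity(
        np.array([1.0, 1.0]), np.array([2.0, 2.0]), np.array([0.0, 0.0])
    )
    assert mag == pytest.approx(1.0) and axis == pytest.approx(0.0) and ok


def test_polarity_matches_complex_sum_oracle():
    rng = np.random.default_rng(3)
    I = rng.uniform(1, 5, 7)
    L = rng.uniform(0.5, 4, 7)
    th = rng.uniform(0, 180, 7)
    mag, axis, _ = an.planar_polarity(I, L, th)
    w = I * L
    q = (w * np.exp(2j * np.radians(th))).sum() / w.sum()
    assert mag == pytest.approx(abs(q), abs=1e-12)
    assert axis == pytest.approx(np.degrees(np.angle(q)) / 2 % 180, abs=1e-9)


def test_polarity_magnitude_bounded_and_scale_invariant():
    rng = np.random.default_rng(8)
    for _ in range(20):
        I = rng.uniform(0.1, 9, 6)
        L = rng.uniform(0.1, 9, 6)
        th = rng.uniform(0, 180, 6)
        mag, axis, _ = an.planar_polarity(I, L, th)
        assert 0.0 <= mag <= 1.0
        mag2, axis2, _ = an.planar_polarity(I * 13.7, L, th)
        assert mag2 == pytest.approx(mag) and axis2 == pytest.approx(axis)


def test_scale_invariance_of_anisotropy_ratio_and_correlation():
    x = np.array([2.0, 4.0, 8.0, 5.0])
    sd1, r1 = an.cell_anisotropy(x)
    sd2, r2 = an.cell_anisotropy(x * 3.0)
    assert r2 == pytest.approx(r1)              # Max/Min is scale-free
    assert sd2 / np.mean(x * 3) == pytest.approx(sd1 / np.mean(x))


def test_orientation_bins_half_open():
    rows = [
        _junc("j0", 1, 2, "c", 1.0, theta=7.0),
        _junc("j1", 1, 3, "c", 2.0, theta=15.0),
        _junc("j2", 1, 4, "c", 3.0, theta=179.9),
    ]
    out = an.bin_by_orientation(_table(rows))
    assert len(out) == 12
    assert out.loc[out.bin_lo_deg == 0.0, "n"].iloc[0] == 1
    assert out.loc[out.bin_lo_deg == 15.0, "n"].iloc[0] == 1  # 15° -> [15,30)
    assert out.loc[out.bin_lo_deg == 165.0, "n"].iloc[0] == 1
    assert out.n.sum() == 3


def test_polarized_channel_peaks_in_axis_bin():
    rng = np.random.default_rng(5)
    theta = rng.uniform(0, 180, 400)
    inten = 10.0 * (1 + 0.6 * np.cos(2 * np.radians(theta - 90.0)))
    rows = [
        _junc(f"j{i}", 1, 2, "celsr", float(v), theta=float(t))
        for i, (v, t) in enumerate(zip(inten, theta))
    ]
    out = an.bin_by_orientation(_table(rows))
    best = out.loc[out.mean_intensity.idxmax()]
    assert best.bin_lo_deg <= 90.0 < best.bin_hi_deg or best.bin_lo_deg == 75.0


def _pair_table(f, n=60, emb="e0"):
    rng = np.random.default_rng(0)
    a = rng.uniform(1, 9, n)
    rows = []
    for i, x in enumerate(a):
        rows.append(_junc(f"j{i}", 1, 2, "A", float(x), emb=emb))
        rows.append(_junc(f"j{i}", 1, 2, "B", float(f(x)), emb=emb))
    return _table(rows)


def test_proportional_channels_correlate_perfectly():
    t = _pair_table(lambda x: 2 * x)
    assert an.channel_pair_correlation(t, "A", "B") == pytest.approx(1.0)
    assert an.channel_pair_correlation(t, "A", "B", filter_low=0.5) == pytest.approx(1.0)


def test_reflected_channel_is_anticorrelated():
    t = _pair_table(lambda x: 10 - x)
    assert an.channel_pair_correlation(t, "A", "B") == pytest.approx(-1.0)


def test_degenerate_channel_warns_nan():
    t = _pair_table(lambda x: 5.0)
    with pytest.raises(ValueError, match="degenerate"):
        an.channel_pair_correlation(t, "A", "B")


def test_filter_reveals_reciprocal_enrichment():
    """Anti-correlation confined to high-intensity junctions: pooled r is
    near zero until the low-intensity filter is applied."""
    from apicodyn.synthetic import ChannelModel, ChannelSpec, sample_junction_loadings

    signs_ok = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        jdf = pd.DataFrame(
            {"junction_id": [f"{i}|{i+1}" for i in range(240)],
             "orientation_deg": rng.uniform(0, 180, 240)}
        )
        model = ChannelModel(
            channels={"M": ChannelSpec(group="actomyosin"),
                      "M2": ChannelSpec(group="actomyosin"),
                      "C": ChannelSpec(group="crumbs")},
            seed=seed,
        )
        load = sample_junction_loadings(model, jdf, rng)
        rows = []
        for _, r in load.iterrows():
            i = int(r.junction_id.split("|")[0])
            for chan in ("M", "M2", "C"):
                rows.append(_junc(r.junction_id, i, i + 1, chan, float(r[chan])))
        t = _table(rows)
        r_unf = an.channel_pair_correlation(t, "M", "C")
        r_fil = an.channel_pair_correlation(t, "M", "C", filter_low=0.5)
        r_within = an.channel_pair_correlation(t, "M", "M2", filter_low=0.5)
        if r_fil < 0 and r_within > 0 and abs(r_unf) < abs(r_fil):
            signs_ok += 1
    assert signs_ok >= 19


def test_raster_painted_channels_recover_correlation_signs(tissue):
    """End-to-end: paint channels on the rasterized tissue, measure
    junction intensities through the geometry pipeline, and recover the
    anti-/within-group correlation signs."""
    import warnings

    from apicodyn import tracks as trk
    from apicodyn.synthetic import ChannelModel, ChannelSpec, paint_channels

    series = tissue.to_series()
    model = ChannelModel(
        channels={"M": ChannelSpec(group="actomyosin"),
                  "M2": ChannelSpec(group="actomyosin"),
                  "C": ChannelSpec(group="crumbs")},
        blur_sigma_px=0.0,
        noise="none",
        seed=12,
    )
    painted, truth = paint_channels(series, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, junction_tracks = trk.build_tracks(painted)
    table = an.junction_table(junction_tracks)
    table = table[(table.cell_a != 0) & (table.cell_b != 0)]
    # measured means match the painted ground truth on clean images
    merged = 0
    for _, row in table[table.channel == "M"].iterrows():
        pair = tuple(sorted((row.cell_a, row.cell_b)))
        if pair in truth["M"]:
            assert row.intensity == pytest.approx(truth["M"][pair], rel=0.01)
            merged += 1
    assert merged > 30
    r_fil = an.channel_pair_correlation(table, "M", "C", filter_low=0.5)
    r_within = an.channel_pair_correlation(table, "M", "M2", filter_low=0.5)
    assert r_fil < 0 < r_within


def test_group_by_cell_returns_distribution():
    rng = np.random.default_rng(2)
    rows = []
    for cell in (1, 2, 3):
        for i in range(8):
            x = rng.uniform(1, 9)
            rows.append(_junc(f"c{cell}j{i}", cell, 50 + i, "A", x))
            rows.append(_junc(f"c{cell}j{i}", cell, 50 + i, "B", 2 * x + rng.normal(0, 0.1)))
    out = an.channel_pair_correlation(_table(rows), "A", "B", group_by_cell=True)
    assert set(out.cell_id) == {1, 2, 3}
    assert (out.r > 0.9).all()


def test_mean_polarity_vanishes_for_random_axes():
    rng = np.random.default_rng(11)
    rows = []
    for cell in range(60):
        th0 = rng.uniform(0, 180)
        for j in range(6):
            theta = (th0 + 30 * j) % 180
            inten = 3.0 * (1 + 0.5 * np.cos(2 * np.radians(theta - th0)))
            rows.append(
                _junc(f"c{cell}j{j}", cell + 1, 200 + cell * 6 + j, "c",
                      float(inten), theta=float(theta))
            )
    pol = an.polarity_table(_table(rows))
    mags = pol.magnitude
    assert (mags > 0.1).all()                     # every cell is polarized
    mag, _ = an.mean_polarity(pol)["c"]
    assert mag < 0.06                             # but axes are random
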