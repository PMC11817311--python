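import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_diff_chain, brute_extrema
from scribepd.dynamic_features import (
    IN_AIR,
    ON_SURFACE,
    count_local_extrema,
    kinematic_features,
    pressure_features,
    segment,
)


class TestSegmentation:
    def test_simple_mask_and_runs(self, make_recording):
        rec = make_recording([0.0, 1.0, 1.0, 0.0])
        mask = segment(rec)
        assert mask.on_surface.tolist() == [False, True, True, False]
        assert len(mask.runs_on) == 1
        assert len(mask.runs_air) == 2

    def test_all_on_surface(self, make_recording):
        rec = make_recording([1.0, 1.0, 1.0], z=[0.0, 0.0, 0.0])
        mask = segment(rec)
        assert len(mask.runs_on) == 1
        assert len(mask.runs_air) == 0

    def test_all_in_air_is_valid_but_warned(self, make_recording, caplog):
        rec = make_recording([0.0, 0.0, 0.0])
        with caplog.at_level("WARNING"):
            mask = segment(rec)
        assert mask.n_on == 0
        assert "no on-surface" in caplog.text

    def test_runs_cover_all_indices(self, hc_recording, hc_mask):
        covered = np.zeros(hc_recording.n, dtype=int)
        for s in hc_mask.runs_on + hc_mask.runs_air:
            covered[s] += 1
        assert np.all(covered == 1)


class TestPressureFeatures:
    def test_constant_pressure_has_no_changes(self, make_recording):
        rec = make_recording(np.full(180, 0.5), z=np.zeros(180))
        fm = pressure_features(rec, segment(rec))
        assert np.allclose(fm.vectors["pressure.dp"], 0.0)
        assert fm.scalars["pressure.ncp.dp"] == 0
        assert fm.scalars["pressure.rncp.dp"] == 0

    def test_difference_chain_matches_stated_formulas(self, make_recording):
        rec = make_recording([0.1, 0.3, 0.2, 0.4], z=np.zeros(4), fs=180.0)
        fm = pressure_features(rec, segment(rec))
        assert np.allclose(fm.vectors["pressure.dp"], [0.2, -0.1, 0.2])
        assert np.allclose(fm.vectors["pressure.d1"], [36.0, -18.0, 36.0])

    def test_sinusoid_extrema_match_exhaustive_scan(self, make_recording):
        k = 3
        t = np.linspace(0, 1, 360, endpoint=False)
        p = 0.5 + 0.3 * np.sin(2 * np.pi * k * t)
        rec = make_recording(p, z=np.zeros(len(p)))
        fm = pressure_features(rec, segment(rec))
        assert brute_extrema(p) == 2 * k
        for name, order in (("dp", 1), ("d1", 1), ("d2", 2)):
            derived = brute_diff_chain(p, 1.0, order)
            assert fm.scalars[f"pressure.ncp.{name}"] == brute_extrema(derived)

    def test_too_few_on_surface_samples_rejected(self, make_recording):
        rec = make_recording([0.5, 0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError, match="4 samples"):
            pressure_features(rec, segment(rec))

    def test_cardinality(self, pressure_fm):
        assert pressure_fm.n_vectors == 5
        assert pressure_fm.n_scalars == 6


class TestKinematicFeatures:
    def test_constant_position_trajectory(self, make_recording):
        n = 10
        rec = make_recording(np.full(n, 0.5), x=np.full(n, 3.0),
                             y=np.full(n, 4.0), z=np.zeros(n))
        fm = kinematic_features(rec, segment(rec), ON_SURFACE)
        assert np.allclose(fm.vectors["kin_on.r.base"], 5.0)
        assert np.allclose(fm.vectors["kin_on.di.base"], 0.0)
        assert np.allclose(fm.vectors["kin_on.di.vel"], 0.0)

    def test_unit_staircase_displacement(self, make_recording):
        x = np.arange(5.0)
        rec = make_recording(np.full(5, 0.5), x=x, y=np.zeros(5),
                             z=np.zeros(5), fs=1.0)
        fm = kinematic_features(rec, segment(rec), ON_SURFACE)
        assert np.allclose(fm.vectors["kin_on.di.base"], 1.0)
        assert fm.scalars["kin_on.ncv.di"] == 0

    def test_cardinalities(self, kin_on_fm, kin_air_fm):
        assert kin_on_fm.n_vectors == 24 and kin_on_fm.n_scalars == 24
        assert kin_air_fm.n_vectors == 28 and kin_air_fm.n_scalars == 28
        assert any(n.startswith("kin_air.dz") for n in kin_air_fm.vectors)
        assert not any(n.startswith("kin_on.dz") for n in kin_on_fm.vectors)

    def test_azimuth_differences_wrap_across_zero(self, make_recording):
        n = 6
        rec = make_recording(np.full(n, 0.5), z=np.zeros(n))
        rec.azimuth = np.array([356.0, 358.0, 0.0, 2.0, 4.0, 6.0])
        fm = kinematic_features(rec, segment(rec), ON_SURFACE)
        assert np.allclose(fm.vectors["kin_on.daz.base"], 2.0)

    def test_translation_invariance_of_differences_but_not_r(
            self, make_recording):
        rng = np.random.default_rng(0)
        n = 30
        x = np.cumsum(rng.normal(size=n)) + 50
        y = np.cumsum(rng.normal(size=n)) + 80
        rec = make_recording(np.full(n, 0.5), x=x, y=y, z=np.zeros(n))
        shifted = make_recording(np.full(n, 0.5), x=x + 100, y=y - 40,
                                 z=np.zeros(n))
        a = kinematic_features(rec, segment(rec), ON_SURFACE)
        b = kinematic_features(shifted, segment(shifted), ON_SURFACE)
        for name in ("kin_on.di.base", "kin_on.dx.base", "kin_on.dy.base"):
            assert np.allclose(a.vectors[name], b.vectors[name])
        assert not np.allclose(a.vectors["kin_on.r.base"],
                               b.vectors["kin_on.r.base"])

    def test_velocity_tiers_scale_linearly_with_fs(self, make_recording):
        rng = np.random.default_rng(1)
        n = 40
        x = np.cumsum(rng.normal(size=n))
        lo = make_recording(np.full(n, 0.5), x=x, z=np.zeros(n), fs=100.0)
        hi = make_recording(np.full(n, 0.5), x=x, z=np.zeros(n), fs=200.0)
        a = kinematic_features(lo, segment(lo), ON_SURFACE)
        b = kinematic_features(hi, segment(hi), ON_SURFACE)
        assert np.allclose(2.0 * a.vectors["kin_on.dx.vel"],
                           b.vectors["kin_on.dx.vel"])
        assert np.allclose(4.0 * a.vectors["kin_on.dx.acc"],
                           b.vectors["kin_on.dx.acc"])

    def test_requested_class_absent_is_an_error(self, make_recording):
        rec = make_recording(np.zeros(8))
        with pytest.raises(ValueError, match="no on_surface"):
            kinematic_features(rec, segment(rec), ON_SURFACE)

    def test_differences_never_cross_pen_lifts(self, make_recording):
        # two runs with a large positional jump between them: the jump
        # must not appear in any difference vector
        p = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        x = np.where(np.arange(14) < 7, 0.0, 1000.0) + np.arange(14)
        rec = make_recording(p, x=x)
        fm = kinematic_features(rec, segment(rec), ON_SURFACE)
        assert np.abs(fm.vectors["kin_on.dx.base"]).max() < 10


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=6, max_size=100),
       st.sampled_from([60.0, 180.0]))
def test_derivative_chain_matches_brute_force(values, fs):
    """Forward-difference tiers agree with an explicit loop oracle."""
    p = np.abs(np.asarray(values)) / 101.0 + 0.1  # valid positive pressure
    n = len(p)
    from scribepd.io_formats import TabletRecording
    rec = TabletRecording("h", x=np.arange(n, dtype=float), y=np.zeros(n),
                          z=np.zeros(n), azimuth=np.full(n, 10.0),
                          altitude=np.full(n, 45.0), pressure=p, fs=fs)
    fm = pressure_features(rec, segment(rec))
    for name, order in (("dp", 0), ("d1", 1), ("d2", 2), ("d3", 3)):
        expect = brute_diff_chain(np.diff(p) if order == 0 else p,
                                  fs, 0 if order == 0 else order)
        assert np.allclose(fm.vectors[f"pressure.{name}"], expect, atol=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(-5, 5), min_size=3, max_size=60))
def test_extrema_counter_matches_exhaustive_scan(values):
    assert count_local_extrema(np.asarray(values, float)) == brute_extrema(values)
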