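"""Wing cross-section geometry: generators, smoothing, rasterization, file I/O."""

import math

import numpy as np
import pytest

import wingflow as wf
from wingflow.errors import (
    GeometryError,
    InvalidParameterError,
    PlacementError,
    ProfileParseError,
)
from wingflow.profiles import (
    _camber_thickness,
    _cap_thickness,
    _scanline_minmax,
    _spine_polygon,
)


def thickness_profile(profile, n=4096):
    """Brute-force chordwise thickness scan (oracle for vein-bump counting)."""
    return _camber_thickness(profile, n=n)


class TestGenerators:
    @pytest.mark.parametrize(
        "maker",
        [
            lambda: wf.make_flat_plate(4.0, 0.0125),
            lambda: wf.make_ellipse(4.0, 0.125),
            lambda: wf.make_corrugated(4.0, wf.CorrugationSpec()),
            lambda: wf.smooth_profile(
                wf.make_corrugated(4.0, wf.CorrugationSpec()), 0.8
            ),
        ],
        ids=["plate", "ellipse", "corrugated", "smoothed"],
    )
    def test_generator_invariants(self, maker):
        p = maker()
        assert p.chord == pytest.approx(4.0)
        xs = np.concatenate([lp[:, 0] for lp in p.loops])
        assert xs.max() - xs.min() == pytest.approx(4.0, rel=1e-9)
        assert p.area > 0.0
        # construction re-validates closure and simplicity
        wf.WingProfile(p.loops, p.chord, p.name)

    def test_plate_dimensions(self):
        p = wf.make_flat_plate(4.0, 0.0125)
        xmin, xmax, ymin, ymax = p.bbox
        assert xmax - xmin == pytest.approx(4.0)
        assert ymax - ymin == pytest.approx(0.05, rel=1e-6)

    def test_plate_area_closed_form(self):
        # rectangle + semicircular caps: c*t - t^2 + pi t^2/4
        c, r = 4.0, 0.0125
        t = r * c
        expected = c * t - t * t + math.pi * t * t / 4.0
        p = wf.make_flat_plate(c, r)
        assert p.area == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0])
    def test_plate_invalid_thickness(self, bad):
        with pytest.raises(InvalidParameterError):
            wf.make_flat_plate(4.0, bad)

    def test_plate_invalid_chord(self):
        with pytest.raises(InvalidParameterError):
            wf.make_flat_plate(-4.0, 0.0125)

    def test_ellipse_dimensions(self):
        p = wf.make_ellipse(4.0, 0.125)
        xmin, xmax, ymin, ymax = p.bbox
        assert xmax - xmin == pytest.approx(4.0)
        assert ymax - ymin == pytest.approx(0.5, rel=1e-4)

    def test_ellipse_area_converges_to_pi_ab(self):
        errs = []
        for n in (128, 512):
            p = wf.make_ellipse(4.0, 0.125, n_points=n)
            errs.append(abs(p.area - math.pi * 2.0 * 0.25))
        assert errs[1] < errs[0] / 4.0
        assert errs[1] < 1e-3

    def test_ellipse_unit_ratio_is_circle(self):
        p = wf.make_ellipse(4.0, 1.0)
        radii = np.hypot(p.loops[0][:, 0], p.loops[0][:, 1])
        assert radii == pytest.approx(np.full_like(radii, 2.0))


class TestCorrugated:
    def test_zero_corrugation_is_flat_plate(self):
        spec = wf.CorrugationSpec(
            vein_amplitudes=(0.0,) * 8, vein_radius=0.00625, membrane_thickness=0.0125
        )
        cor = wf.make_corrugated(4.0, spec, n_points=600)
        plate = wf.make_flat_plate(4.0, 0.0125, n_points=600)
        assert np.allclose(cor.loops[0], plate.loops[0], atol=1e-12)

    def test_eight_thickness_maxima(self, default_corrugated):
        xq, _, thick = thickness_profile(default_corrugated)
        # local maxima above the membrane plateau, brute-force scan
        from scipy.signal import find_peaks

        idx, _ = find_peaks(thick, prominence=0.2 * (thick.max() - thick.min()))
        assert len(idx) == 8

    def test_determinism(self):
        spec = wf.CorrugationSpec(jitter=0.3, seed=7)
        a = wf.make_corrugated(4.0, spec)
        b = wf.make_corrugated(4.0, spec)
        assert all(np.array_equal(x, y) for x, y in zip(a.loops, b.loops))

    def test_seed_changes_jittered_geometry(self):
        a = wf.make_corrugated(4.0, wf.CorrugationSpec(jitter=0.3, seed=1))
        b = wf.make_corrugated(4.0, wf.CorrugationSpec(jitter=0.3, seed=2))
        assert not np.array_equal(a.loops[0], b.loops[0])

    def test_self_intersection_names_vein(self):
        # extreme corrugation: the membrane offset cusps at the interface
        # notch once the boundary is sampled finely enough to resolve it
        spec = wf.CorrugationSpec(
            vein_amplitudes=(0.1, -0.1, 0.1, -0.1, 0.1, -0.1, 0.1, -0.1),
        )
        with pytest.raises(GeometryError, match="vein node"):
            wf.make_corrugated(4.0, spec, n_points=4000)

    def test_amplitude_bound_enforced(self):
        with pytest.raises(InvalidParameterError):
            wf.CorrugationSpec(vein_amplitudes=(0.2,) * 8)

    def test_notch_position_bounds(self):
        with pytest.raises(InvalidParameterError):
            wf.CorrugationSpec(notch_position=1.5)


class TestSmoothing:
    def test_flat_plate_is_fixed_point(self, plate_section):
        s = wf.smooth_profile(plate_section, 0.8)
        _, cam0, th0 = _camber_thickness(plate_section)
        _, cam1, th1 = _camber_thickness(s)
        assert np.abs(cam1 - cam0).max() < 1e-4 * 4.0
        assert np.abs(th1 - th0).max() < 1e-3 * 4.0

    def test_corrugation_amplitude_strictly_reduced(self, default_corrugated):
        s = wf.smooth_profile(default_corrugated, 0.8)
        _, cam0, _ = _camber_thickness(default_corrugated)
        _, cam1, _ = _camber_thickness(s)
        assert np.abs(cam1).max() < np.abs(cam0).max()

    def test_window_larger_than_chord_rejected(self):
        p = wf.make_flat_plate(4.0, 0.0125)
        with pytest.raises(InvalidParameterError):
            wf.smooth_profile(p, 5.0)
        with pytest.raises(InvalidParameterError):
            wf.smooth_profile(p, 0.0)

    def test_idempotent_on_already_smooth_profile(self):
        # gentle single-mode camber, constant-thickness membrane: relief is
        # far coarser than the window, so smoothing must be a no-op twice over
        span = 4.0
        lo = 0.02 * span
        L = span - 2.0 * lo

        def cam(x):
            return 0.08 * np.cos(math.pi * np.clip(x - lo, 0, L) / L)

        def thk(x):
            return _cap_thickness(x, span, 0.05)

        p = wf.WingProfile((_spine_polygon(span, cam, thk, n_half=2000),), span)
        s1 = wf.smooth_profile(p, 0.8)
        s2 = wf.smooth_profile(s1, 0.8)
        dev = max(np.abs(a - b).max() for a, b in zip(s1.loops, s2.loops))
        assert dev < 1e-6 * span

    def test_chord_preserved(self, default_corrugated):
        s = wf.smooth_profile(default_corrugated, 0.8)
        assert s.chord == default_corrugated.chord


class TestRasterize:
    def test_ellipse_area_within_one_percent(self, ellipse_section):
        f = wf.rasterize(ellipse_section, (10.0, 5.0, 0.0), cell=0.05,
                         extents=(0.0, 20.0, 0.0, 10.0))
        area = f.sum() * 0.05**2
        assert area == pytest.approx(math.pi * 2.0 * 0.25, rel=0.01)
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_area_error_halves_with_cell_size(self, ellipse_section):
        exact = math.pi * 2.0 * 0.25
        errs = []
        for cell in (0.1, 0.05):
            f = wf.rasterize(ellipse_section, (10.0, 5.0, 0.0), cell=cell,
                             extents=(0.0, 20.0, 0.0, 10.0), n_sub=8)
            errs.append(abs(f.sum() * cell * cell - exact))
        assert errs[1] <= errs[0] / 2.0 + 1e-12

    def test_half_turn_symmetry(self, ellipse_section):
        kw = dict(cell=0.05, extents=(0.0, 20.0, 0.0, 10.0))
        f0 = wf.rasterize(ellipse_section, (10.0, 5.0, 0.0), **kw)
        f180 = wf.rasterize(ellipse_section, (10.0, 5.0, 180.0), **kw)
        assert np.abs(f0 - f180).max() < 1e-12

    def test_placement_outside_domain_rejected(self, plate_section):
        with pytest.raises(PlacementError):
            wf.rasterize(plate_section, (19.5, 5.0, 0.0), cell=0.05,
                         extents=(0.0, 20.0, 0.0, 10.0))


class TestProfileFiles:
    def test_round_trip(self, tmp_path, ellipse_section):
        path = tmp_path / "ellipse.txt"
        wf.save_profile(path, ellipse_section)
        back = wf.load_profile(path)
        assert back.chord == pytest.approx(ellipse_section.chord, rel=1e-8)
        assert np.allclose(back.loops[0], ellipse_section.loops[0], atol=1e-7)

    def test_two_point_loop_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0\n1 0\n")
        with pytest.raises(ProfileParseError, match="fewer than 3"):
            wf.load_profile(path)

    def test_figure_eight_rejected(self, tmp_path):
        path = tmp_path / "eight.txt"
        path.write_text("0 0\n1 1\n1 0\n0 1\n")
        with pytest.raises(ProfileParseError, match="self-intersect"):
            wf.load_profile(path)

    def test_parse_error_carries_line_number(self, tmp_path):
        path = tmp_path / "cols.txt"
        path.write_text("0 0\n1 0 99\n")
        with pytest.raises(ProfileParseError, match=":2:"):
            wf.load_profile(path)

    def test_multi_loop_round_trip(self, tmp_path):
        a = wf.make_ellipse(2.0, 0.5)
        b = wf.make_ellipse(1.5, 0.5).translated(3.0, 0.0)
        p = wf.WingProfile(a.loops + b.loops, chord=4.75, name="two-loops")
        path = tmp_path / "two.txt"
        wf.save_profile(path, p)
        back = wf.load_profile(path)
        assert len(back.loops) == 2

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("# header\n0 0\n2 0  # inline\n2 1\n0 1\n")
        p = wf.load_profile(path)
        assert p.chord == pytest.approx(2.0)


class TestWingProfileInvariants:
    def test_chord_mismatch_rejected(self):
        loop = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [0.0, 1.0]])
        with pytest.raises(GeometryError):
            wf.WingProfile((loop,), chord=3.0)

    def test_zero_area_rejected(self):
        loop = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(GeometryError):
            wf.WingProfile((loop,), chord=2.0)

    def test_pivot_is_mid_chord_on_camber(self, ellipse_section):
        assert ellipse_section.pivot() == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_scanline_recovers_rectangle(self):
        loop = np.array([[0.0, -1.0], [4.0, -1.0], [4.0, 1.0], [0.0, 1.0]])
        ys = _scanline_minmax([loop], np.array([1.0, 2.0, 3.0]))
        assert np.allclose(ys[0], -1.0)
        assert np.allclose(ys[1], 1.0)
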