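"""Curvature, torsion, smoothing, radius and tilt estimators.

Analytic oracles: a circle of radius r has κ = 1/r and τ = 0; a helix
x = (a·cos t, a·sin t, c·t) has κ = a/(a²+c²) and τ = c/(a²+c²);
mirroring flips the torsion sign only.
"""

import numpy as np
import pytest

from organgeo.centreline import Centreline, parameterize
from organgeo.diffgeo import (ScalarProfile, curvature_torsion, local_cubic_fit,
                              normalize_by_length, radius_profile,
                              smooth_profile, tilt_angle)
from organgeo.synthetic import generate_tube_mesh
from tests.conftest import helix_points, random_rotation


def interior(values, frac=0.2):
    n = len(values)
    return values[int(frac * n):int((1 - frac) * n)]


class TestLocalFit:
    def test_exact_cubic_reproduced(self):
        # coordinates that are exact cubics of the arclength coordinate:
        # the least-squares cubic fit recovers derivatives to machine precision
        from organgeo.centreline import ParamCurve

        s = np.linspace(0, 10, 200)
        pts = np.c_[1 + 2 * s + 3 * s**2 + 0.5 * s**3, 4 * s - s**2, 0.1 * s**3]
        p = ParamCurve(points=pts, s=s)
        s_star = 5.0
        fit = local_cubic_fit(p, s_star, delta=2.0)
        d1 = np.array([2 + 6 * s_star + 1.5 * s_star**2, 4 - 2 * s_star,
                       0.3 * s_star**2])
        d2 = np.array([6 + 3 * s_star, -2.0, 0.6 * s_star])
        d3 = np.array([3.0, 0.0, 0.6])
        np.testing.assert_allclose(fit.d1, d1, rtol=1e-8)
        np.testing.assert_allclose(fit.d2, d2, rtol=1e-8)
        np.testing.assert_allclose(fit.d3, d3, rtol=1e-7, atol=1e-8)

    def test_straight_line_zero_derivatives(self):
        pts = np.c_[np.linspace(0, 10, 100), np.zeros(100), np.zeros(100)]
        p = parameterize(Centreline(pts))
        fit = local_cubic_fit(p, 5.0, delta=1.0)
        np.testing.assert_allclose(fit.d2, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.d3, 0.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(fit.d1), 1.0, atol=1e-10)

    def test_helix_derivatives_match_analytic(self):
        a = c = 1.0
        p = parameterize(Centreline(helix_points(a, c, 1.0, 2000)))
        w = np.sqrt(a**2 + c**2)
        s_star = p.L / 2
        fit = local_cubic_fit(p, s_star, delta=0.02 * p.L)
        t = s_star / w  # parameter value at s*
        d1 = np.array([-a * np.sin(t), a * np.cos(t), c]) / w
        d2 = np.array([-a * np.cos(t), -a * np.sin(t), 0]) / w**2
        np.testing.assert_allclose(fit.d1, d1, atol=0.01)
        np.testing.assert_allclose(fit.d2, d2, atol=0.01 * np.linalg.norm(d2))

    def test_too_few_neighbours(self):
        pts = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        p = parameterize(Centreline(pts))
        with pytest.raises(ValueError, match="resample"):
            local_cubic_fit(p, 2.0, delta=0.5)


class TestCurvatureTorsion:
    def test_circle(self, circle_curve):
        kap, tau = curvature_torsion(circle_curve)
        assert np.median(kap.values) == pytest.approx(1 / 7.0, rel=0.01)
        assert np.nanmax(np.abs(interior(tau.values))) < 1e-3

    def test_helix_analytic(self):
        p = parameterize(Centreline(helix_points(1.0, 1.0, 1.0, 600)))
        kap, tau = curvature_torsion(p)
        assert np.median(interior(kap.values)) == pytest.approx(0.5, rel=0.01)
        assert np.nanmedian(interior(tau.values)) == pytest.approx(0.5, rel=0.01)

    def test_mirror_flips_torsion_sign(self):
        pts = helix_points(1.0, 1.0, 1.0, 600)
        k1, t1 = curvature_torsion(parameterize(Centreline(pts)))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        k2, t2 = curvature_torsion(parameterize(Centreline(mirrored)))
        np.testing.assert_allclose(k2.values, k1.values, atol=1e-9)
        np.testing.assert_allclose(t2.values, -t1.values, atol=1e-9)

    def test_rigid_motion_invariance(self):
        pts = helix_points(2.0, 0.5, 1.0, 500)
        R = random_rotation(7)
        k1, t1 = curvature_torsion(parameterize(Centreline(pts)))
        k2, t2 = curvature_torsion(
            parameterize(Centreline(pts @ R.T + np.array([3.0, 1.0, -4.0]))))
        np.testing.assert_allclose(k2.values, k1.values, atol=1e-8)
        np.testing.assert_allclose(t2.values, t1.values, atol=1e-8)

    def test_straight_line_torsion_undefined(self):
        pts = np.c_[np.linspace(0, 10, 200), np.zeros(200), np.zeros(200)]
        kap, tau = curvature_torsion(parameterize(Centreline(pts)))
        assert tau.undefined.all()
        assert np.all(kap.values < 1e-8)


class TestSmoothing:
    def grid_profile(self, values):
        return ScalarProfile(s=np.linspace(0, 1, len(values)), values=values)

    def test_constant_preserved(self):
        f = self.grid_profile(np.full(200, 3.7))
        np.testing.assert_allclose(smooth_profile(f).values, 3.7, atol=1e-9)

    def test_high_frequency_attenuated(self):
        t = np.arange(400)
        f = self.grid_profile(np.sin(2 * np.pi * 0.35 * t))  # 0.7 × Nyquist
        out = smooth_profile(f, cutoff=0.3)
        assert np.abs(interior(out.values)).max() < 0.1

    def test_low_frequency_preserved(self):
        t = np.arange(400)
        f = self.grid_profile(np.sin(2 * np.pi * 0.02 * t))  # 0.04 × Nyquist
        out = smooth_profile(f, cutoff=0.3)
        ratio = np.abs(interior(out.values)).max()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_short_profile_warns_unfiltered(self):
        f = self.grid_profile(np.arange(8.0))
        with pytest.warns(UserWarning, match="unfiltered"):
            out = smooth_profile(f)
        np.testing.assert_allclose(out.values, f.values)


class TestNormalize:
    def test_circle_normalized_curvature_is_2pi(self):
        for r in (1.0, 50.0):
            th = np.linspace(0, 2 * np.pi, 800, endpoint=False)
            p = parameterize(Centreline(np.c_[r * np.cos(th), r * np.sin(th),
                                              np.zeros_like(th)]))
            kap, _ = curvature_torsion(p)
            kn = normalize_by_length(kap, p.L)
            assert np.median(kn.values) == pytest.approx(2 * np.pi, rel=0.01)

    def test_scale_invariance(self):
        pts = helix_points(1.0, 1.0, 1.0, 500)
        p1 = parameterize(Centreline(pts))
        p3 = parameterize(Centreline(3 * pts))
        k1, _ = curvature_torsion(p1)
        k3, _ = curvature_torsion(p3)
        n1 = normalize_by_length(k1, p1.L)
        n3 = normalize_by_length(k3, p3.L)
        np.testing.assert_allclose(n3.values, n1.values, rtol=1e-6)

    def test_kind_guard(self):
        f = ScalarProfile(s=np.arange(5.0), values=np.ones(5), kind="intensity")
        with pytest.raises(ValueError):
            normalize_by_length(f, 10.0)
        with pytest.raises(ValueError):
            normalize_by_length(
                ScalarProfile(s=np.arange(5.0), values=np.ones(5), kind="curvature"),
                0.0)


class TestRadius:
    def test_straight_tube(self):
        n = 80
        line = Centreline(np.c_[np.linspace(0, 200, n), np.zeros(n), np.zeros(n)])
        mesh = generate_tube_mesh(line, 10.0, n_rings=80)
        prof = radius_profile(parameterize(line), mesh)
        np.testing.assert_allclose(prof.values, 10.0, rtol=0.01)

    def test_cone_taper_monotone(self):
        n = 100
        line = Centreline(np.c_[np.linspace(0, 400, n), np.zeros(n), np.zeros(n)])
        p = parameterize(line)
        taper = ScalarProfile(s=p.s, values=np.linspace(5.0, 20.0, n), kind="radius")
        mesh = generate_tube_mesh(p, taper, n_rings=100)
        prof = radius_profile(p, mesh)
        inner = interior(prof.values, 0.1)
        assert np.corrcoef(np.arange(len(inner)), inner)[0, 1] > 0.99
        assert inner[-1] > 2 * inner[0]

    def test_empty_mesh_rejected(self):
        from organgeo.proximity import SurfaceMesh

        with pytest.raises(ValueError):
            SurfaceMesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int))


class TestTilt:
    def test_collinear_subregion_zero(self):
        n = 100
        pts = np.c_[np.linspace(0, 100, n), np.sin(np.linspace(0, 2 * np.pi, n)),
                    np.zeros(n)]
        p = parameterize(Centreline(pts))
        sub = parameterize(Centreline(pts[20:80]))
        assert tilt_angle(p, sub) < 3.0

    def test_perpendicular_is_90(self):
        n = 200
        whole = np.c_[np.linspace(0, 100, n), 0.5 * np.sin(np.linspace(0, 4 * np.pi, n)),
                      np.zeros(n)]
        sub = np.c_[0.2 * np.sin(np.linspace(0, 4 * np.pi, n)),
                    np.linspace(0, 50, n), np.zeros(n)]
        ang = tilt_angle(parameterize(Centreline(whole)),
                         parameterize(Centreline(sub)))
        assert ang == pytest.approx(90.0, abs=2.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        whole = np.cumsum(np.abs(rng.normal(size=(60, 3))) + 0.05, axis=0)
        sub = whole[10:40]
        base = tilt_angle(parameterize(Centreline(whole)),
                          parameterize(Centreline(sub)))
        R = random_rotation(11)
        rot = tilt_angle(parameterize(Centreline(whole @ R.T)),
                         parameterize(Centreline(sub @ R.T)))
        assert rot == pytest.approx(base, abs=1e-6)

    def test_degenerate_cloud_rejected(self):
        n = 30
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circle = np.c_[np.cos(th), np.sin(th), np.zeros(n)]  # two equal eigenvalues
        line = np.c_[np.linspace(0, 1, n), np.zeros(n), np.zeros(n)]
        with pytest.raises(ValueError, match="principal axis"):
            tilt_angle(parameterize(Centreline(circle)),
                       parameterize(Centreline(line)))
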