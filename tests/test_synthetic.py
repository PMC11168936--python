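"""Generator contracts: determinism, ground-truth recoverability, guards."""

from dataclasses import replace

import numpy as np
import pytest

from organgeo.centreline import parameterize, subset_by_landmarks
from organgeo.diffgeo import curvature_torsion, radius_profile, tilt_angle
from organgeo.proximity import min_vertex_distances
from organgeo.synthetic import (CohortSpec, GeneratorParams, generate_centreline,
                                generate_cohort, generate_intensity_trace,
                                generate_organ_pair, generate_tube_mesh)
from tests.conftest import helix_points


def arc_centre_curvature(params, seed=1):
    """Curvature sampled at the centres of the full serpentine arcs."""
    c = generate_centreline(params, seed=seed)
    p = parameterize(c)
    kap, _ = curvature_torsion(p)
    b1 = 0.30 * p.L
    arc = 0.50 * p.L / (params.loop_count + 1)
    centres = [b1 + arc / 2 + (k + 0.5) * arc for k in range(params.loop_count)]
    return float(np.mean([kap.interp(x) for x in centres]))


class TestGenerateCentreline:
    def test_loop_curvature_matches_analytic_arc(self, noiseless_female):
        est = arc_centre_curvature(noiseless_female)
        assert est == pytest.approx(noiseless_female.loop_curvature_amp, rel=0.10)

    def test_seed_determinism(self, noiseless_female):
        p = replace(noiseless_female, noise_sd=2.0)
        c1 = generate_centreline(p, seed=42)
        c2 = generate_centreline(p, seed=42)
        np.testing.assert_array_equal(c1.points, c2.points)

    def test_zero_tilt_aligns_loop_axis(self, noiseless_female):
        p = replace(noiseless_female, loop_tilt_deg=0.0)
        pc = parameterize(generate_centreline(p, seed=1))
        sub = subset_by_landmarks(pc, "loop_start", "loop_end")
        assert tilt_angle(pc, sub) < 2.0

    def test_tilt_monotone_in_parameter(self, noiseless_female):
        angles = []
        for t in (0.0, 15.0, 30.0):
            pc = parameterize(generate_centreline(
                replace(noiseless_female, loop_tilt_deg=t), seed=1))
            sub = subset_by_landmarks(pc, "loop_start", "loop_end")
            angles.append(tilt_angle(pc, sub))
        assert angles[0] < angles[1] < angles[2]

    def test_total_length_realized(self, noiseless_female):
        pc = parameterize(generate_centreline(noiseless_female, seed=3))
        assert pc.L == pytest.approx(noiseless_female.total_length, rel=1e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="total_length"):
            generate_centreline(GeneratorParams(total_length=-5.0), 0)
        with pytest.raises(ValueError, match="stationary"):
            generate_centreline(GeneratorParams(ar_coeffs=(1.2,)), 0)


class TestGenerateCohort:
    def test_counts_and_sexes(self):
        cohort = generate_cohort(CohortSpec(n_per_group=1, seed=0))
        assert len(cohort) == 2
        assert sorted(cohort.metadata["sex"]) == ["female", "male"]

    def test_group_parameter_ordering(self):
        cohort = generate_cohort(CohortSpec(n_per_group=5, seed=1))
        m = cohort.metadata.groupby("sex")[["true_curvature_amp", "true_tilt_deg",
                                            "true_radius", "gut_length"]].mean()
        assert m.loc["female", "true_curvature_amp"] > m.loc["male", "true_curvature_amp"]
        assert m.loc["female", "true_tilt_deg"] < m.loc["male", "true_tilt_deg"]
        assert m.loc["female", "true_radius"] > m.loc["male", "true_radius"]
        assert m.loc["female", "gut_length"] > m.loc["male", "gut_length"]

    def test_curvature_ordering_recovered_downstream(self):
        from organgeo.diffgeo import normalize_by_length

        cohort = generate_cohort(CohortSpec(n_per_group=3, seed=2))
        means = {"female": [], "male": []}
        for c, row in cohort:
            p = parameterize(c)
            kap, _ = curvature_torsion(p)
            kn = normalize_by_length(kap, p.L)
            loop = (kap.s > 0.32 * p.L) & (kap.s < 0.78 * p.L)
            means[row["sex"]].append(np.mean(kn.values[loop]))
        assert np.mean(means["female"]) > np.mean(means["male"])

    def test_empty_batch_list_warns_single_batch(self):
        spec = CohortSpec(n_per_group=1, batch_labels=[], seed=3)
        with pytest.warns(UserWarning, match="single batch"):
            cohort = generate_cohort(spec)
        assert set(cohort.metadata["batch"]) == {"batch1"}


class TestTubeMesh:
    def test_helix_radius_round_trip(self):
        from organgeo.centreline import Centreline

        pts = helix_points(a=100.0, c=40.0, turns=2.0, n=400)
        p = parameterize(Centreline(pts))
        mesh = generate_tube_mesh(p, 8.0, n_rings=200)
        prof = radius_profile(p, mesh)
        assert np.median(prof.values) == pytest.approx(8.0, rel=0.1)

    def test_watertight(self, noiseless_female):
        pc = parameterize(generate_centreline(noiseless_female, seed=1))
        mesh = generate_tube_mesh(pc, 40.0, n_rings=120)
        assert mesh.as_trimesh().is_watertight

    def test_degenerate_inputs_rejected(self):
        from organgeo.centreline import ParamCurve

        zero = ParamCurve(points=np.zeros((4, 3)), s=np.zeros(4))
        with pytest.raises(ValueError, match="zero-length"):
            generate_tube_mesh(zero, 5.0)

    def test_tight_curvature_warns(self):
        from organgeo.centreline import Centreline

        th = np.linspace(0, np.pi, 100)
        arc = Centreline(np.c_[10 * np.cos(th), 10 * np.sin(th), np.zeros(100)])
        with pytest.warns(UserWarning, match="self-intersect"):
            generate_tube_mesh(arc, 9.0, n_rings=100)


class TestIntensityTrace:
    def test_zero_noise_equals_mean(self):
        p = GeneratorParams(ar_noise_sd=0.0, intensity_peak_pos=0.4)
        tr = generate_intensity_trace(300, p, seed=1)
        t = np.linspace(0, 1, 300)
        expected = 0.2 + np.exp(-0.5 * ((t - 0.4) / 0.08) ** 2)
        np.testing.assert_allclose(tr.values, expected, atol=1e-12)
        assert tr.anchor == 0.4

    def test_seeds_differ(self):
        p = GeneratorParams()
        t1 = generate_intensity_trace(200, p, seed=1)
        t2 = generate_intensity_trace(200, p, seed=2)
        assert not np.allclose(t1.values, t2.values)

    def test_lag1_autocorrelation_of_noise(self):
        p = GeneratorParams(ar_coeffs=(0.8,), ar_noise_sd=1.0)
        p0 = replace(p, ar_noise_sd=0.0)
        noise = (generate_intensity_trace(20000, p, seed=4).values
                 - generate_intensity_trace(20000, p0, seed=4).values)
        r1 = np.corrcoef(noise[:-1], noise[1:])[0, 1]
        assert r1 == pytest.approx(0.8, abs=0.02)

    def test_non_stationary_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            generate_intensity_trace(100, GeneratorParams(ar_coeffs=(0.6, 0.5)), 0)


class TestOrganPair:
    def test_sphere_gap_exact(self):
        m1, m2 = generate_organ_pair(2.0, "sphere", seed=0, radius=1.0)
        # unit spheres, centre distance 4 -> surface separation 2
        d = min_vertex_distances(m1, m2)
        assert d.min() == pytest.approx(2.0, abs=1e-9)

    def test_touching_spheres(self):
        m1, m2 = generate_organ_pair(0.0, "sphere", seed=1)
        assert min_vertex_distances(m1, m2).min() == pytest.approx(0.0, abs=1e-9)

    def test_box_gap_matches_brute_force(self):
        m1, m2 = generate_organ_pair(50.0, "box", seed=2)
        d = min_vertex_distances(m1, m2)
        brute = np.sqrt(((m1.vertices[:, None] - m2.vertices[None]) ** 2)
                        .sum(-1)).min(axis=1)
        np.testing.assert_allclose(d, brute, atol=1e-12)
        assert d.min() == pytest.approx(50.0, abs=1e-9)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            generate_organ_pair(-1.0, "sphere", 0)
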