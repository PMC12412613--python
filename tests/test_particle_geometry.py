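import math

import numpy as np
import pytest

from memclust.particle_geometry import (
    Particle,
    classify_edge_center,
    classify_symmetry,
    compare_distance_populations,
    delaunay_pairs,
    distance_stats,
    angle_density_map,
    interaction_angles,
    refine_particle,
    signed_protomer_angle,
    symmetrize,
    tilt_angle,
)
from memclust.synthetic_data import render_particle_patch


def regular_particle(center, nf=5, radius=2.2, phase_deg=0.0, heights=None):
    phis = np.deg2rad(phase_deg + 360.0 / nf * np.arange(nf))
    protomers = np.asarray(center) + radius * np.stack([np.cos(phis), np.sin(phis)], axis=1)
    if heights is None:
        heights = np.ones(nf)
    return Particle(
        center=np.asarray(center, float), nf=nf, protomers=protomers,
        protomer_heights=np.asarray(heights, float), isv=1.0,
    )


class TestRefineParticle:
    def test_center_recovery_from_offset_seed(self):
        patch = render_particle_patch(nf=5, phase_deg=13.0, pixel_size=0.25, size_px=41)
        frame = np.zeros((81, 81))
        frame[20:61, 20:61] = patch
        p = refine_particle(frame, (42.0, 38.0), nf=5, patch_radius=14)
        assert np.allclose(p.center, [40.0, 40.0], atol=0.5)
        assert p.isv > 0.99
        assert not p.low_confidence

    def test_translation_equivariance(self):
        patch = render_particle_patch(nf=5, phase_deg=31.0, pixel_size=0.25, size_px=41)
        f1 = np.zeros((101, 101))
        f1[20:61, 20:61] = patch
        f2 = np.roll(f1, (7, 4), axis=(0, 1))  # translate by (dy=7, dx=4)
        p1 = refine_particle(f1, (40.0, 40.0), nf=5, patch_radius=14)
        p2 = refine_particle(f2, (44.0, 47.0), nf=5, patch_radius=14)
        assert np.allclose(p2.center - p1.center, [4.0, 7.0], atol=0.3)

    def test_symmetrized_patch_is_invariant(self):
        patch = render_particle_patch(nf=4, phase_deg=22.0, pixel_size=0.25, size_px=41)
        sym = symmetrize(patch, (20.0, 20.0), 4)
        again = symmetrize(sym, (20.0, 20.0), 4)
        inner = (slice(8, 33), slice(8, 33))  # away from interpolation edges
        assert np.allclose(sym[inner], again[inner], atol=0.02)

    def test_noise_patch_low_isv(self, rng):
        vals = []
        for _ in range(10):
            p = refine_particle(
                rng.normal(0, 1, (41, 41)), (20.0, 20.0), nf=5,
                patch_radius=14, search_radius=1,
            )
            vals.append(p.isv)
            assert p.low_confidence
        assert abs(np.mean(vals)) < 0.25

    def test_protomer_phase_recovered(self):
        patch = render_particle_patch(nf=5, phase_deg=17.0, pixel_size=0.25, size_px=41)
        p = refine_particle(patch, (20.0, 20.0), nf=5, patch_radius=14)
        ang = np.degrees(np.arctan2(*(p.protomers - p.center).T[::-1]))
        assert np.allclose(np.sort(np.mod(ang, 72.0)), 17.0, atol=1.0)


class TestClassifySymmetry:
    def test_pentamer(self):
        nf, spacing = classify_symmetry(render_particle_patch(nf=5))
        assert nf == 5
        assert spacing == pytest.approx(72.0)

    def test_tetramer(self):
        nf, spacing = classify_symmetry(render_particle_patch(nf=4))
        assert nf == 4
        assert spacing == pytest.approx(90.0)

    @pytest.mark.parametrize("rot", [10.0, 33.0, 61.0])
    def test_rotation_invariance(self, rot):
        nf, _ = classify_symmetry(render_particle_patch(nf=5, phase_deg=rot))
        assert nf == 5

    def test_unclassifiable_noise(self, rng):
        nf, spacing = classify_symmetry(rng.normal(0, 1, (41, 41)))
        # either no dominant harmonic, or an arbitrary one; must not crash
        assert nf in (None, 4, 5, 6)


class TestTiltAngle:
    def test_flat_particle(self):
        p = regular_particle((0, 0))
        assert tilt_angle(p.protomers, p.protomer_heights) == pytest.approx(0.0)

    def test_analytic_ten_degrees(self):
        p = regular_particle((0, 0), radius=2.2)
        # heights on a plane tilted 10 deg about the x-axis
        heights = np.tan(np.radians(10.0)) * p.protomers[:, 1]
        assert tilt_angle(p.protomers, heights) == pytest.approx(10.0, abs=1e-9)

    def test_invariances(self):
        p = regular_particle((3, -2), phase_deg=28.0)
        heights = 0.3 * p.protomers[:, 0] + 0.1 * p.protomers[:, 1]
        w0 = tilt_angle(p.protomers, heights)
        assert tilt_angle(p.protomers, heights + 5.0) == pytest.approx(w0)
        # in-plane rotation of positions AND the height plane
        ang = np.radians(40.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        prot2 = (p.protomers - p.center) @ rot.T + p.center
        grad = rot @ np.array([0.3, 0.1])
        heights2 = grad[0] * prot2[:, 0] + grad[1] * prot2[:, 1]
        assert tilt_angle(prot2, heights2) == pytest.approx(w0, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            tilt_angle(pts, np.array([0.0, 1.0, 2.0]))

    def test_rendered_tilt_recovery(self):
        errs = []
        for tilt in (0.0, 10.0, 20.0, 30.0, 35.0):
            patch = render_particle_patch(
                nf=5, tilt_deg=tilt, tilt_axis_deg=40.0, phase_deg=9.0,
                protomer_height=3.0, pixel_size=0.2, size_px=61,
            )
            p = refine_particle(patch, (30.0, 30.0), nf=5, patch_radius=15, pixel_size=0.2)
            errs.append(abs(tilt_angle(p.protomers, p.protomer_heights) - tilt))
        assert np.mean(errs) < 2.0


class TestDelaunayPairs:
    def test_equilateral_triangle(self):
        parts = [regular_particle(c) for c in [(0, 0), (8, 0), (4, 8 * math.sqrt(3) / 2)]]
        pairs = delaunay_pairs(parts, d_max=10.0)
        assert len(pairs) == 3

    def test_collinear_chain(self):
        parts = [regular_particle((7.0 * i, 0.0)) for i in range(4)]
        pairs = delaunay_pairs(parts, d_max=10.0)
        assert len(pairs) == 3
        assert all(p.distance == pytest.approx(7.0, abs=0.1) for p in pairs)

    def test_single_particle_empty(self):
        assert delaunay_pairs([regular_particle((0, 0))], d_max=10.0) == []

    def test_oracle_equivalence(self, rng):
        from scipy.spatial import Delaunay

        pos = rng.uniform(0, 40, (20, 2))
        parts = [regular_particle(p) for p in pos]
        d_max = 12.0
        got = {
            tuple(sorted((round(p.particle_a.center[0], 6), round(p.particle_b.center[0], 6))))
            for p in delaunay_pairs(parts, d_max)
        }
        tri = Delaunay(pos)
        expected = set()
        for s in tri.simplices:
            for i in range(3):
                for j in range(i + 1, 3):
                    a, b = s[i], s[j]
                    if np.hypot(*(pos[a] - pos[b])) <= d_max:
                        expected.add(tuple(sorted((round(pos[a][0], 6), round(pos[b][0], 6)))))
        assert got == expected


class TestInteractionAngles:
    def test_protomer_on_connection_line(self):
        a = regular_particle((0, 0), phase_deg=0.0)
        b = regular_particle((8, 0), phase_deg=180.0)
        alpha, beta = interaction_angles(a, b)
        assert alpha == pytest.approx(0.0, abs=1e-9)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_clockwise_rotation_positive(self):
        # pentamer rotated 10 deg clockwise (y-up): protomer at math angle -10
        a = regular_particle((0, 0), phase_deg=-10.0)
        alpha = signed_protomer_angle(a.center, a.protomers, np.array([10.0, 0.0]), 5)
        assert alpha == pytest.approx(+10.0)

    def test_counterclockwise_negative(self):
        a = regular_particle((0, 0), phase_deg=+25.0)
        alpha = signed_protomer_angle(a.center, a.protomers, np.array([10.0, 0.0]), 5)
        assert alpha == pytest.approx(-25.0)

    def test_boundary_tie_resolves_positive(self):
        a = regular_particle((0, 0), phase_deg=36.0)  # exactly between protomers
        alpha = signed_protomer_angle(a.center, a.protomers, np.array([10.0, 0.0]), 5)
        assert abs(alpha) == pytest.approx(36.0)
        assert alpha == pytest.approx(+36.0)

    @pytest.mark.parametrize("nf,bound", [(5, 36.0), (4, 45.0)])
    def test_bound_never_exceeded(self, rng, nf, bound):
        for _ in range(300):
            phase = rng.uniform(0, 360)
            direction = rng.uniform(0, 360)
            other = 10.0 * np.array([np.cos(np.radians(direction)), np.sin(np.radians(direction))])
            a = regular_particle((0, 0), nf=nf, phase_deg=phase)
            alpha = signed_protomer_angle(a.center, a.protomers, other, nf)
            assert -bound < alpha <= bound + 1e-9

    def test_lattice_orientation_recovery_rms(self, rng):
        errs = []
        for _ in range(200):
            true = rng.uniform(-35.9, 35.9)
            direction = rng.uniform(0, 360)
            psi = np.radians(direction)
            other = np.array([np.cos(psi), np.sin(psi)]) * 8.0
            # protomer placed at math angle psi_deg - true (CW positive)
            a = regular_particle((0, 0), phase_deg=direction - true)
            alpha = signed_protomer_angle(a.center, a.protomers, other, 5)
            errs.append(alpha - true)
        assert np.sqrt(np.mean(np.square(errs))) < 3.0


class TestAngleDensityMap:
    def _pair(self, alpha, beta):
        a = regular_particle((0, 0))
        b = regular_particle((8, 0))
        from memclust.particle_geometry import NeighborPair

        return NeighborPair(a, b, 8.0, alpha, beta)

    def test_single_mode_peak_at_origin(self):
        pairs = [self._pair(0.0, 0.0)] * 20
        centers, dens = angle_density_map(pairs)
        assert dens.max() == 1.0
        i = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(centers[i[0]]) < 2.0 and abs(centers[i[1]]) < 2.0

    def test_uniform_pairs_near_flat(self, rng):
        pairs = [
            self._pair(rng.uniform(-36, 36), rng.uniform(-36, 36)) for _ in range(1000)
        ]
        _, dens = angle_density_map(pairs, bandwidth=6.0)
        assert dens.max() / max(dens.min(), 1e-12) < 2.0

    def test_symmetric_about_diagonal(self, rng):
        pairs = [
            self._pair(rng.uniform(-36, 36), rng.uniform(-36, 36)) for _ in range(100)
        ]
        _, dens = angle_density_map(pairs)
        assert np.allclose(dens, dens.T, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            angle_density_map([])


class TestDistanceStats:
    def test_gaussian_recovery(self, rng):
        d = rng.normal(7.8, 0.8, 200)
        st = distance_stats(d)
        assert st.peak == pytest.approx(7.8, abs=0.2)
        assert st.sd == pytest.approx(0.8, abs=0.2)
        assert st.n == 200

    def test_identical_distances(self):
        st = distance_stats(np.full(50, 7.0))
        assert st.peak == 7.0
        assert st.sd == 0.0

    def test_bimodal_flagged(self, rng):
        d = np.concatenate([rng.normal(6.0, 0.2, 150), rng.normal(10.0, 0.2, 150)])
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # non-convergence path also flags
            st = distance_stats(d)
        assert st.poor_fit

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            distance_stats(np.arange(5.0))

    def test_population_comparison(self, rng):
        d1 = rng.normal(6.7, 0.5, 80)
        d2 = rng.normal(7.8, 0.5, 80)
        assert compare_distance_populations(d1, d2) < 1e-6
        same = compare_distance_populations(d1, rng.normal(6.7, 0.5, 80))
        assert same > 1e-4


class TestClassifyEdgeCenter:
    def _contour(self, r=20.0, n=360):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return r * np.stack([np.cos(th), np.sin(th)], axis=1)

    def test_centroid_particle_is_center(self):
        p = regular_particle((0, 0))
        classify_edge_center([p], self._contour(), particle_diameter=4.4)
        assert p.location_class == "center"

    def test_touching_contour_is_edge(self):
        p = regular_particle((19.5, 0))
        classify_edge_center([p], self._contour(), particle_diameter=4.4)
        assert p.location_class == "edge"

    def test_known_ring_classified_exactly(self, rng):
        contour = self._contour(20.0)
        particles, truth = [], []
        for _ in range(40):
            r = rng.uniform(0, 19)
            th = rng.uniform(0, 2 * np.pi)
            particles.append(regular_particle((r * np.cos(th), r * np.sin(th))))
            truth.append("edge" if 20.0 - r <= 4.4 else "center")
        classify_edge_center(particles, contour, particle_diameter=4.4)
        got = [p.location_class for p in particles]
        assert got == truth
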