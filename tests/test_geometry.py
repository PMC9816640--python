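import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from spindlemorph import geometry, graph_io
from spindlemorph.geometry import (
    GeometryError,
    absolute_pole_distance,
    apply_z_correction,
    assign_polarity,
    endpoint_z_uniformity,
    interaction_area,
    interkinetochore_distance,
    kinetochore_center,
    kmts_per_fiber,
    minus_end_density,
    relative_position,
    spindle_angle,
    tortuosity,
)
from spindlemorph.graph_io import EndAnnotation, Kinetochore, MicrotubuleTrack, Pole
from spindlemorph.synthetic_spindle import GeneratorConfig, generate_spindle


def pole_at(x, pole_id="P1"):
    return Pole(pole_id, np.array([x, 0.0, 0.0]), np.array([x, 0.0, 200.0]))


class TestZCorrection:
    def test_expansion_factor(self, tiny_recon):
        tiny_recon.tracks[0].points[:, 2] = 1000.0
        out = apply_z_correction(tiny_recon, 300, 10, 2400)
        assert out.metadata["z_factor"] == pytest.approx(1.25)
        np.testing.assert_allclose(out.tracks[0].points[:, 2], 1250.0)
        # x, y untouched
        np.testing.assert_array_equal(out.tracks[0].points[:, :2], tiny_recon.tracks[0].points[:, :2])

    def test_identity_when_measured_matches(self, tiny_recon):
        out = apply_z_correction(tiny_recon, 300, 10, 3000)
        np.testing.assert_array_equal(out.tracks[0].points, tiny_recon.tracks[0].points)

    def test_nonpositive_inputs_rejected(self, tiny_recon):
        with pytest.raises(GeometryError):
            apply_z_correction(tiny_recon, 300, 10, 0)

    def test_round_trip_recovers_input(self, tiny_recon):
        tiny_recon.tracks[0].points[:, 2] = np.array([10.0, 20.0, 30.0])
        once = apply_z_correction(tiny_recon, 300, 10, 2400)
        back = apply_z_correction(once, 300, 10, 3000 * 3000 / 2400)
        np.testing.assert_allclose(back.tracks[0].points, tiny_recon.tracks[0].points, rtol=1e-12)


class TestPolarity:
    def test_kmt_associated_end_is_plus(self, tiny_recon):
        plus, minus = assign_polarity(tiny_recon.tracks[0], tiny_recon)
        np.testing.assert_array_equal(plus.position, tiny_recon.tracks[0].point_a)
        np.testing.assert_array_equal(minus.position, tiny_recon.tracks[0].point_b)

    def test_nonkmt_nearer_end_is_minus(self, tiny_recon):
        plus, minus = assign_polarity(tiny_recon.tracks[1], tiny_recon)
        # end_a at (-4000,500,0) is 1118 nm from P1; end_b at (0,1000,0) is ~5099
        np.testing.assert_array_equal(minus.position, tiny_recon.tracks[1].point_a)
        assert not minus.tie_flag

    def test_equidistant_tie_goes_to_end_a(self):
        t = MicrotubuleTrack("t", "non-KMT", None, np.array([[-1000.0, 0, 0], [1000.0, 0, 0]]))
        recon = graph_io.SpindleReconstruction(tracks=[t], poles=[pole_at(0.0)])
        plus, minus = assign_polarity(t, recon)
        assert minus.tie_flag
        np.testing.assert_array_equal(minus.position, t.point_a)

    @pytest.mark.parametrize("assoc_a,assoc_b", [(False, False), (True, True)])
    def test_kmt_with_wrong_association_count(self, assoc_a, assoc_b):
        t = MicrotubuleTrack(
            "t", "KMT", "f", np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            end_a=EndAnnotation(assoc_a), end_b=EndAnnotation(assoc_b),
        )
        recon = graph_io.SpindleReconstruction(tracks=[t], poles=[pole_at(0.0)])
        with pytest.raises(GeometryError, match="exactly one"):
            assign_polarity(t, recon)


class TestRelativePosition:
    def test_anchors_and_midpoint(self):
        pole = pole_at(0.0)
        ref = np.array([8000.0, 0, 0])
        assert relative_position(pole.mother, pole, ref) == pytest.approx(0.0)
        assert relative_position(ref, pole, ref) == pytest.approx(1.0)
        assert relative_position(np.array([4000.0, 0, 0]), pole, ref) == pytest.approx(0.5)

    def test_off_axis_projection(self):
        pole = pole_at(0.0)
        ref = np.array([8000.0, 0, 0])
        # perpendicular offset does not change D
        assert relative_position(np.array([4000.0, 999.0, -50.0]), pole, ref) == pytest.approx(0.5)

    def test_unclamped_outside_segment(self):
        pole = pole_at(0.0)
        ref = np.array([1000.0, 0, 0])
        assert relative_position(np.array([-500.0, 0, 0]), pole, ref) == pytest.approx(-0.5)
        assert relative_position(np.array([1500.0, 0, 0]), pole, ref) == pytest.approx(1.5)

    def test_zero_axis_rejected(self):
        pole = pole_at(0.0)
        with pytest.raises(GeometryError):
            relative_position(np.zeros(3), pole, pole.mother)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        end = rng.normal(0, 1000, 3)
        mother = rng.normal(0, 1000, 3)
        ref = mother + rng.normal(0, 1000, 3)
        if np.allclose(ref, mother):
            return
        d0 = relative_position(end, Pole("P", mother, mother + [1, 0, 0]), ref)
        R = Rotation.random(random_state=int(seed % 2**16)).as_matrix()
        shift = rng.normal(0, 5000, 3)
        d1 = relative_position(
            R @ end + shift, Pole("P", R @ mother + shift, R @ mother + shift + 1), R @ ref + shift
        )
        assert d1 == pytest.approx(d0, abs=1e-8)


class TestDistances:
    def test_at_mother_centriole(self):
        assert absolute_pole_distance(np.array([-5000.0, 0, 0]), [pole_at(-5000.0)]) == 0.0

    def test_three_four_five(self):
        assert absolute_pole_distance(np.array([3000.0, 4000.0, 0]), [pole_at(0.0)]) == pytest.approx(5000.0)

    def test_nearest_of_two_poles(self):
        poles = [pole_at(-5000.0, "P1"), pole_at(5000.0, "P2")]
        assert absolute_pole_distance(np.zeros(3), poles) == pytest.approx(5000.0)


class TestKinetochoreCenter:
    def make_recon(self, plus_positions):
        tracks, ids = [], []
        for i, pos in enumerate(plus_positions):
            pts = np.array([np.asarray(pos, float), np.asarray(pos, float) + [0, 0, -3000.0]])
            tracks.append(
                MicrotubuleTrack(f"t{i}", "KMT", "f", pts, end_a=EndAnnotation(True))
            )
            ids.append(f"t{i}")
        kin = Kinetochore("k", None, ids)
        recon = graph_io.SpindleReconstruction(
            tracks=tracks, poles=[pole_at(0.0)], kinetochores=[kin]
        )
        return kin, recon

    def test_single_kmt(self):
        kin, recon = self.make_recon([[7.0, 8.0, 9.0]])
        np.testing.assert_allclose(kinetochore_center(kin, recon), [7, 8, 9])

    def test_median_component_wise(self):
        kin, recon = self.make_recon([[0, 0, 0], [10, 1, 2], [100, 2, 4]])
        np.testing.assert_allclose(kinetochore_center(kin, recon), [10, 1, 2])

    def test_even_count_is_midpoint(self):
        kin, recon = self.make_recon([[0, 0, 0], [10, 4, 2]])
        np.testing.assert_allclose(kinetochore_center(kin, recon), [5, 2, 1])

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 7))
    def test_median_minimizes_l1_objective(self, seed, npts):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 10, (npts, 3)).round(1)
        kin, recon = self.make_recon(pts)
        center = kinetochore_center(kin, recon)
        obj = lambda c: np.abs(pts - c).sum(axis=0)
        base = obj(center)
        for _ in range(50):
            trial = center + rng.normal(0, 5, 3)
            assert np.all(base <= obj(trial) + 1e-9)

    def test_empty_kmt_list(self):
        kin, recon = self.make_recon([[0, 0, 0]])
        empty = Kinetochore("ke", None, [])
        with pytest.raises(GeometryError):
            kinetochore_center(empty, recon)


class TestInterkinetochore:
    def test_identical_centers_zero(self):
        tracks = []
        for i, kin_id in enumerate(["ka", "kb"]):
            pts = np.array([[1000.0, 0, 0], [1000.0, 0, -3000.0]])
            tracks.append(MicrotubuleTrack(f"t{i}", "KMT", kin_id, pts, end_a=EndAnnotation(True)))
        recon = graph_io.SpindleReconstruction(
            tracks=tracks,
            poles=[pole_at(0.0)],
            kinetochores=[Kinetochore("ka", "kb", ["t0"]), Kinetochore("kb", "ka", ["t1"])],
        )
        pair = tuple(recon.kinetochores)
        assert interkinetochore_distance(pair, recon) == 0.0

    def test_unit_conversion_1060nm(self):
        tracks = [
            MicrotubuleTrack("t0", "KMT", "ka", np.array([[0.0, 0, 0], [0, 0, -3000.0]]),
                             end_a=EndAnnotation(True)),
            MicrotubuleTrack("t1", "KMT", "kb", np.array([[1060.0, 0, 0], [1060.0, 0, 3000.0]]),
                             end_a=EndAnnotation(True)),
        ]
        recon = graph_io.SpindleReconstruction(
            tracks=tracks,
            poles=[pole_at(-5000.0)],
            kinetochores=[Kinetochore("ka", "kb", ["t0"]), Kinetochore("kb", "ka", ["t1"])],
        )
        assert interkinetochore_distance(tuple(recon.kinetochores), recon) == pytest.approx(1.06)

    def test_generated_cohort_mean(self):
        # ~200 sister pairs drawn with separation Normal(1.06, 0.21) µm
        cfg = GeneratorConfig(seed=123, n_fibers=400, kmt_rate=2.0, n_nonkmt=0)
        recon, truth = generate_spindle(cfg)
        d = truth.interkinetochore_um
        assert len(d) == 200
        se = 0.21 / np.sqrt(len(d))
        assert abs(d.mean() - 1.06) < 3 * se
        # realized geometry agrees with the recorded truth
        measured = [geometry.interkinetochore_distance(p, recon)
                    for p in geometry.sister_pairs(recon)]
        assert np.mean(measured) == pytest.approx(d.mean(), abs=0.05)


class TestKmtsPerFiber:
    def test_shared_fiber_counted(self):
        tracks = [
            MicrotubuleTrack(f"t{i}", "KMT", "fib", np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                             end_a=EndAnnotation(True))
            for i in range(3)
        ]
        recon = graph_io.SpindleReconstruction(tracks=tracks, poles=[pole_at(0.0)])
        assert kmts_per_fiber(recon).to_dict() == {"fib": 3}

    def test_no_kmts_empty(self, tiny_recon):
        tiny_recon.tracks = [t for t in tiny_recon.tracks if t.mt_class != "KMT"]
        assert kmts_per_fiber(tiny_recon).empty

    def test_zero_truncated_poisson_mean(self):
        lam = 9.0
        cfg = GeneratorConfig(seed=5, n_fibers=100, kmt_rate=lam, n_nonkmt=0)
        recon, _ = generate_spindle(cfg)
        counts = kmts_per_fiber(recon)
        assert len(counts) == 100
        truncated_mean = lam / (1 - np.exp(-lam))
        var = truncated_mean * (1 + lam - truncated_mean)
        se = np.sqrt(var / len(counts))
        assert abs(counts.mean() - truncated_mean) < 3 * se


class TestTortuosity:
    def test_collinear_is_one(self):
        assert tortuosity(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])) == pytest.approx(1.0)

    def test_right_angle_sqrt2(self):
        t = tortuosity(np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]]))
        assert t == pytest.approx(np.sqrt(2))

    def test_two_point_track(self):
        assert tortuosity(np.array([[0.0, 0, 0], [5, 5, 5]])) == pytest.approx(1.0)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(GeometryError):
            tortuosity(np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 0]]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_at_least_one_with_equality_iff_collinear(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (rng.integers(2, 8), 3))
        if np.linalg.norm(pts[-1] - pts[0]) < 1e-9:
            return
        t = tortuosity(pts)
        assert t >= 1.0 - 1e-12
        # collinear equally spaced points => exactly 1
        line = np.outer(np.linspace(0, 1, 5), rng.normal(0, 1, 3) + 2)
        assert tortuosity(line) == pytest.approx(1.0)


class TestDensity:
    def test_peak_recovery(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.05, 0.01, 10_000)
        curve = minus_end_density(d)
        assert abs(curve.peak_position - 0.05) < 0.005

    def test_symmetric_peak_at_half(self):
        # triangular point arrangement, exactly symmetric about 0.5
        d = np.concatenate([np.linspace(0.3, 0.7, 101), np.linspace(0.45, 0.55, 51)])
        curve = minus_end_density(d)
        step = curve.grid[1] - curve.grid[0]
        assert abs(curve.peak_position - 0.5) <= step + 1e-12

    def test_normalized_over_grid(self):
        rng = np.random.default_rng(1)
        curve = minus_end_density(rng.uniform(0, 1, 2000))
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=1e-3)

    def test_constant_data_rejected(self):
        with pytest.raises(GeometryError):
            minus_end_density(np.full(100, 0.3))


class TestInteractionArea:
    def test_default_fixed_bound(self):
        area = interaction_area()
        assert area.upper_bound == 0.2
        assert area.method == "fixed"

    def test_gaussian_closed_form(self):
        mu, sigma = 0.03, 0.05
        grid = np.linspace(-0.3, 1.0, 2000)
        dens = np.exp(-0.5 * ((grid - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        curve = geometry.DensityCurve(grid, dens, 0.1, mu)
        area = interaction_area(curve, method="density_derived")
        expected = mu + 2 * sigma * np.sqrt(2 * np.log(2))
        assert area.upper_bound == pytest.approx(expected, rel=1e-3)

    def test_narrow_peak_limit(self):
        mu = 0.05
        grid = np.linspace(-0.3, 1.0, 5000)
        for sigma in (0.02, 0.005):
            dens = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
            curve = geometry.DensityCurve(grid, dens, 0.1, mu)
            ub = interaction_area(curve, method="density_derived").upper_bound
            assert abs(ub - mu) < 3 * sigma  # upper bound -> mu as sigma -> 0

    def test_missing_curve_rejected(self):
        with pytest.raises(GeometryError):
            interaction_area(None, method="density_derived")


class TestAngles:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            ([1, 0, 0], [0, 1, 0], 90.0),
            ([1, 0, 0], [-1, 0, 0], 180.0),
            ([1, 1, 0], [2, 2, 0], 0.0),
        ],
    )
    def test_reference_angles(self, r1, r2, expected):
        assert spindle_angle([0, 0, 0], r1, r2) == pytest.approx(expected, abs=1e-5)

    def test_zero_ray_rejected(self):
        with pytest.raises(GeometryError):
            spindle_angle([1, 1, 1], [1, 1, 1], [2, 2, 2])


class TestZUniformity:
    def _recon_with_endpoint_z(self, zs):
        tracks = [
            MicrotubuleTrack(f"t{i}", "non-KMT", None,
                             np.array([[0.0, 0, z1], [100.0, 0, z2]]))
            for i, (z1, z2) in enumerate(zip(zs[::2], zs[1::2]))
        ]
        return graph_io.SpindleReconstruction(tracks=tracks, poles=[pole_at(0.0)])

    def test_uniform_low_cv(self):
        rng = np.random.default_rng(9)
        zs = rng.uniform(0, 3000, 10_000)
        recon = self._recon_with_endpoint_z(zs)
        res = endpoint_z_uniformity(recon, np.linspace(0, 3000, 11))
        assert res.cv < 0.1
        assert not res.flagged

    def test_point_mass_max_cv(self):
        zs = np.full(100, 150.0)
        recon = self._recon_with_endpoint_z(zs)
        res = endpoint_z_uniformity(recon, np.linspace(0, 3000, 11))
        assert res.cv == pytest.approx(np.sqrt(10 - 1))
        assert res.flagged

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        zs = rng.uniform(0, 3000, 60)
        recon = self._recon_with_endpoint_z(zs)
        res = endpoint_z_uniformity(recon, np.linspace(0, 3000, 4))
        assert res.counts.sum() == 2 * len(recon.tracks)

    def test_too_few_sections(self, tiny_recon):
        with pytest.raises(GeometryError):
            endpoint_z_uniformity(tiny_recon, np.array([0.0, 100.0]))
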