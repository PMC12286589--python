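"""Lattice construction, region classification, sampling and ray tracing."""

import math

import numpy as np
import pytest

from marrowdose.geometry import (
    GeometryError,
    GeometrySpec,
    RegionLabel as R,
    build_lattice,
)


class TestSpecValidation:
    def test_default_spec_consistency(self, default_spec):
        s = default_spec
        assert s.modeled_vessels == 225
        assert s.n_cells_total * s.vessels_per_cell == s.total_vessels
        assert s.vessel_scale == pytest.approx(40000 / 225)
        assert s.vessel_spacing_um == 120.0

    @pytest.mark.parametrize(
        "kw",
        [
            {"cell_inner_um": 700.0},  # inner > outer
            {"vessels_per_cell": 24},  # not a square
            {"modeled_grids": 8},
            {"vessel_radius_um": 55.0},  # shells overlap
            {"trab_surface_thickness_um": 20.0},  # thicker than half-wall
            {"total_vessels": 39999},
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(GeometryError):
            GeometrySpec(**kw)

    def test_json_roundtrip(self, tmp_path, default_spec):
        p = tmp_path / "spec.json"
        default_spec.to_json(p)
        assert GeometrySpec.from_json(p) == default_spec


class TestBuildLattice:
    def test_default_has_225_axes(self, full_model):
        assert len(full_model.vessel_axes_xy) == 225

    def test_minimal_single_axis_at_center(self, single_vessel_model):
        m = single_vessel_model
        assert len(m.vessel_axes_xy) == 1
        assert np.allclose(m.vessel_axes_xy[0], [315.0, 315.0])

    def test_nearest_neighbour_spacing(self, full_model):
        from scipy.spatial.distance import pdist

        d = pdist(full_model.vessel_axes_xy)
        assert d.min() == pytest.approx(600.0 / 5.0)

    def test_deterministic(self, default_spec):
        a = build_lattice(default_spec)
        b = build_lattice(default_spec)
        assert np.array_equal(a.vessel_axes_xy, b.vessel_axes_xy)


class TestClassifyPoint:
    def test_canonical_points(self, full_model):
        m = full_model
        c = m.cell_centers_xy[0]
        z = m.cell_center_z
        assert m.classify_point([c[0], c[1], z]) == R.BLOOD  # on an axis
        assert m.classify_point([c[0] + 25.0, c[1], z]) == R.PERIVASCULAR_HSC
        assert m.classify_point([c[0] + 45.0, c[1], z]) == R.RED_BONE_MARROW
        # 5 um into the bone wall (cavity face at x = 15)
        assert m.classify_point([10.0, c[1], z]) == R.TRABECULAR_SURFACE
        # 12 um deep
        assert m.classify_point([3.0, c[1], z]) == R.TRABECULAR_VOLUME

    def test_boundary_ties_inner(self, full_model):
        m = full_model
        c = m.cell_centers_xy[0]
        z = m.cell_center_z
        assert m.classify_point([c[0] + 20.0, c[1], z]) == R.PERIVASCULAR_HSC
        assert m.classify_point([c[0] + 30.0, c[1], z]) == R.RED_BONE_MARROW

    def test_out_of_bounds_rejected(self, full_model):
        with pytest.raises(GeometryError):
            full_model.classify_point([-5.0, 100.0, 100.0])


class TestRegionVolumes:
    def test_analytic_annulus_and_cylinder(self, full_model):
        """Shell and blood volumes equal the closed-form annulus/cylinder values."""
        s = full_model.spec
        n_vessels = s.modeled_vessels
        v_hsc, _ = full_model.region_volume(R.PERIVASCULAR_HSC)
        assert v_hsc == pytest.approx(
            n_vessels * math.pi * (30.0**2 - 20.0**2) * 600.0, rel=1e-12
        )
        v_blood, m_blood = full_model.region_volume(R.BLOOD)
        assert v_blood == pytest.approx(
            n_vessels * math.pi * 20.0**2 * 600.0, rel=1e-12
        )
        assert m_blood == pytest.approx(v_blood * 1e-12, rel=1e-12)  # 1 g/cm3

    def test_partition_sums_to_block(self, full_model):
        total = sum(full_model.region_volume(r)[0] for r in R)
        assert total == pytest.approx(full_model.total_volume_um3, rel=1e-12)

    def test_bone_mass_uses_bone_density(self, full_model):
        v, m = full_model.region_volume(R.TRABECULAR_VOLUME)
        assert m == pytest.approx(v * 1e-12 * 1.765, rel=1e-12)

    def test_monte_carlo_partition_agreement(self, full_model, rng):
        """Classified volume fractions of 1e5 uniform points match analytic
        fractions within 3 sigma binomial error."""
        n = 100_000
        pts = rng.random((n, 3)) * (full_model.block_max - full_model.block_min)
        labs = full_model.classify_points(pts)
        tot = full_model.total_volume_um3
        for r in R:
            p = full_model.region_volume(r)[0] / tot
            phat = (labs == int(r)).mean()
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < 3.5 * sigma, r


class TestSamplePoint:
    @pytest.mark.parametrize("region", list(R))
    def test_samples_classify_back(self, full_model, rng, region):
        pts = full_model.sample_points(region, 3000, rng)
        assert (full_model.classify_points(pts) == int(region)).all()

    def test_shell_mean_radius_matches_annulus(self, full_model, rng):
        """Empirical mean radius of uniform shell samples equals
        (2/3)(r2^3-r1^3)/(r2^2-r1^2)."""
        pts = full_model.sample_points(R.PERIVASCULAR_HSC, 40_000, rng)
        lxy, _ = full_model._local(pts)
        s = full_model.spec
        om = full_model._offset_max
        k = np.clip(np.round((lxy + om) / s.vessel_spacing_um), 0, s.vessels_side - 1)
        v = k * s.vessel_spacing_um - om
        r = np.hypot(lxy[:, 0] - v[:, 0], lxy[:, 1] - v[:, 1])
        expect = 2.0 / 3.0 * (30.0**3 - 20.0**3) / (30.0**2 - 20.0**2)
        assert r.mean() == pytest.approx(expect, abs=3.5 * r.std() / math.sqrt(len(r)))

    def test_fixed_seed_reproducible(self, full_model):
        a = full_model.sample_points(R.BLOOD, 50, np.random.default_rng(7))
        b = full_model.sample_points(R.BLOOD, 50, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_marrow_source_can_include_shell(self, full_model, rng):
        pts = full_model.sample_points(
            R.RED_BONE_MARROW, 4000, rng, marrow_includes_shell=True
        )
        labs = full_model.classify_points(pts)
        assert set(np.unique(labs)) <= {int(R.RED_BONE_MARROW), int(R.PERIVASCULAR_HSC)}
        assert (labs == int(R.PERIVASCULAR_HSC)).any()


class TestTraceSegments:
    def test_ray_along_vessel_axis_is_blood(self, full_model):
        c = full_model.cell_centers_xy[0]
        segs = full_model.trace_segments([c[0], c[1], 16.0], [0, 0, 1.0], 500.0)
        assert len(segs) == 1
        assert segs[0][0] == R.BLOOD
        assert segs[0][1] == pytest.approx(500.0, abs=1e-9)

    @pytest.mark.parametrize("b", [0.0, 5.0, 12.0, 19.0])
    def test_blood_chord_length(self, full_model, b):
        """Chord through one vessel at impact parameter b is 2*sqrt(r^2-b^2)."""
        c = full_model.cell_centers_xy[0]
        o = [c[0] - 55.0, c[1] + b, full_model.cell_center_z]
        segs = full_model.trace_segments(o, [1.0, 0, 0], 110.0)
        blood = sum(s for lab, s in segs if lab == R.BLOOD)
        assert blood == pytest.approx(2.0 * math.sqrt(20.0**2 - b**2), abs=1e-6)

    def test_length_conservation_random_rays(self, full_model, rng):
        for _ in range(60):
            o = rng.random(3) * (full_model.block_max - 2.0) + 1.0
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            length = rng.uniform(10.0, 2500.0)
            t_exit = min(
                max(
                    (full_model.block_min[k] - o[k]) / d[k],
                    (full_model.block_max[k] - o[k]) / d[k],
                )
                for k in range(3)
                if abs(d[k]) > 1e-14
            )
            segs = full_model.trace_segments(o, d, length)
            assert sum(s for _, s in segs) == pytest.approx(
                min(length, t_exit), abs=1e-9
            )

    def test_agreement_with_fine_step_oracle(self, full_model, rng):
        """Segment labels agree with a brute-force 0.1 um classification march."""
        for _ in range(100):
            o = rng.random(3) * (full_model.block_max - 2.0) + 1.0
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            segs = full_model.trace_segments(o, d, 200.0)
            total = sum(s for _, s in segs)
            ts = np.arange(0.05, total, 0.1)
            oracle = full_model.classify_points(o[None, :] + ts[:, None] * d[None, :])
            # reconstruct per-step labels from segments
            edges = np.cumsum([s for _, s in segs])
            idx = np.searchsorted(edges, ts, side="right")
            mine = np.array([int(segs[i][0]) for i in idx])
            # disagreements allowed only within 0.1 um of a boundary
            bad = mine != oracle
            if bad.any():
                dist_to_edge = np.min(
                    np.abs(ts[bad][:, None] - np.concatenate([[0.0], edges])[None, :]),
                    axis=1,
                )
                assert dist_to_edge.max() < 0.1

    def test_zero_direction_rejected(self, full_model):
        with pytest.raises(GeometryError):
            full_model.trace_segments([100.0, 100.0, 100.0], [0, 0, 0], 10.0)
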