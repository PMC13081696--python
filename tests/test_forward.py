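import numpy as np
import pytest

import oracles
from cerebmeg import (Channel, LeadField, SourceSpace, assemble_leadfield,
                      channel_gain, dipole_field_sphere, exclude_near_boundary,
                      export_leadfield, import_leadfield, make_sphere_mesh)
from cerebmeg.forward import _parse_gain_unit, distance_to_mesh

CENTER = np.zeros(3)


class TestDipoleFieldSphere:
    def test_radial_dipole_is_silent(self, rng):
        for _ in range(5):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            fp = rng.normal(size=3)
            fp = fp / np.linalg.norm(fp) * 0.12
            B = dipole_field_sphere(u * 0.07, u, fp, CENTER)
            assert np.linalg.norm(B) < 1e-28

    def test_linearity_in_moment(self):
        r0, fp = np.array([0, 0, 0.07]), np.array([0.02, 0.05, 0.09])
        B1 = dipole_field_sphere(r0, [1.0, 0, 0], fp, CENTER)
        B2 = dipole_field_sphere(r0, [2.0, 0, 0], fp, CENTER)
        assert np.allclose(B2, 2 * B1)
        Bsum = dipole_field_sphere(r0, [1.0, 1.0, 0], fp, CENTER)
        By = dipole_field_sphere(r0, [0, 1.0, 0], fp, CENTER)
        assert np.allclose(Bsum, B1 + By, rtol=1e-12)

    def test_matches_quadrature_oracle_for_tangential_dipoles(self, rng):
        for _ in range(5):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r0 = u * 0.07
            t = np.cross(u, rng.normal(size=3))
            t /= np.linalg.norm(t)
            fp = rng.normal(size=3)
            fp = fp / np.linalg.norm(fp) * 0.10
            B_oracle = oracles.geselowitz_field(r0, t, fp)[0]
            B = dipole_field_sphere(r0, t, fp, CENTER)
            assert np.linalg.norm(B - B_oracle) < 0.01 * np.linalg.norm(B_oracle)

    def test_oracle_error_shrinks_with_refinement(self):
        r0 = np.array([0.0, 0.0, 0.07])
        q = np.array([1.0, 0.0, 0.0])
        fp = np.array([0.03, 0.02, 0.10])
        B = dipole_field_sphere(r0, q, fp, CENTER)
        errs = [np.linalg.norm(oracles.geselowitz_field(r0, q, fp, lmax=l)[0] - B)
                for l in (10, 25, 60)]
        assert errs[0] > errs[1] > errs[2]

    def test_field_point_inside_conductor_rejected(self):
        with pytest.raises(ValueError):
            dipole_field_sphere([0, 0, 0.07], [1, 0, 0], [0, 0, 0.05], CENTER)

    def test_dipole_at_center_rejected(self):
        with pytest.raises(ValueError):
            dipole_field_sphere([0, 0, 0], [1, 0, 0], [0, 0, 0.1], CENTER)


class TestChannelGain:
    def test_orthogonal_pickup_reads_zero(self):
        r0 = np.array([0, 0, 0.07])
        q = np.array([1.0, 0, 0])
        fp = np.array([0.0, 0.04, 0.10])
        B = dipole_field_sphere(r0, q, fp, CENTER)
        perp = np.cross(B, [0.3, 0.5, 0.1])
        perp /= np.linalg.norm(perp)
        ch = Channel(kind="magnetometer", integration_points=fp[None],
                     integration_weights=[1.0], orientation=perp)
        assert abs(channel_gain(ch, r0, q, CENTER)) < 1e-9 * np.linalg.norm(B)

    def test_gradiometer_rejects_common_field(self):
        # both points collocated -> identical field -> zero difference
        fp = np.array([0.0, 0.04, 0.10])
        ch = Channel(kind="axial_gradiometer",
                     integration_points=np.array([fp, fp]),
                     integration_weights=[1.0, -1.0],
                     orientation=np.array([0.0, 0.0, 1.0]))
        g = channel_gain(ch, np.array([0, 0, 0.07]), np.array([1.0, 0, 0]), CENTER)
        assert g == pytest.approx(0.0, abs=1e-30)

    def test_square_loop_matches_point_for_far_source(self):
        r0 = np.array([0.0, 0.0, 0.05])
        q = np.array([1.0, 0.0, 0.0])
        center_pt = np.array([0.0, 0.10, 0.14])
        e = 0.0105
        pts = np.array([center_pt + np.array([dx, dy, 0.0])
                        for dx in (-e, e) for dy in (-e, e)])
        loop = Channel(kind="magnetometer", integration_points=pts,
                       integration_weights=np.full(4, 0.25),
                       orientation=np.array([0.0, 0.0, 1.0]))
        point = Channel(kind="magnetometer", integration_points=center_pt[None],
                        integration_weights=[1.0],
                        orientation=np.array([0.0, 0.0, 1.0]))
        g4 = channel_gain(loop, r0, q, CENTER)
        g1 = channel_gain(point, r0, q, CENTER)
        assert abs(g4 - g1) < 0.01 * abs(g1)


class TestAssembly:
    def _space(self, positions, normals):
        normals = np.asarray(normals, float)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
        return SourceSpace(positions=np.asarray(positions, float),
                           normals=normals, region="cortex")

    def _mag(self, pos, ori):
        ori = np.asarray(ori, float)
        return Channel(kind="magnetometer", integration_points=np.atleast_2d(pos),
                       integration_weights=[1.0],
                       orientation=ori / np.linalg.norm(ori))

    def test_single_pair_equals_channel_gain(self):
        space = self._space([[0, 0, 0.07]], [[1, 0, 0]])
        ch = self._mag([0, 0.03, 0.11], [0, 1, 1])
        lf = assemble_leadfield([ch], space, CENTER)
        assert lf.gain.shape == (1, 1)
        assert lf.gain[0, 0] == pytest.approx(
            channel_gain(ch, space.positions[0], space.normals[0], CENTER))

    def test_source_permutation_permutes_columns(self, rng):
        pos = np.array([[0, 0, 0.06], [0.02, 0, 0.05], [0, 0.03, 0.055]])
        nrm = rng.normal(size=(3, 3))
        space = self._space(pos, nrm)
        chans = [self._mag([0, 0.03, 0.11], [0, 1, 1]),
                 self._mag([0.05, 0, 0.10], [1, 0, 1])]
        lf = assemble_leadfield(chans, space, CENTER)
        perm = np.array([2, 0, 1])
        lf_p = assemble_leadfield(chans, space.subset(perm), CENTER)
        assert np.allclose(lf_p.gain, lf.gain[:, perm])

    def test_superposition_over_concatenated_spaces(self, rng):
        from cerebmeg import concatenate_spaces

        a = self._space([[0, 0, 0.06], [0.01, 0.01, 0.05]], rng.normal(size=(2, 3)))
        b = self._space([[0, -0.02, 0.05]], rng.normal(size=(1, 3)))
        chans = [self._mag([0, 0.03, 0.11], [0, 1, 1])]
        lf_ab = assemble_leadfield(chans, concatenate_spaces([a, b]), CENTER)
        lf_a = assemble_leadfield(chans, a, CENTER)
        lf_b = assemble_leadfield(chans, b, CENTER)
        assert np.allclose(lf_ab.gain, np.hstack([lf_a.gain, lf_b.gain]))

    def test_rotation_equivariance(self, rng):
        from scipy.spatial.transform import Rotation

        pos = np.array([[0.01, 0.02, 0.06], [-0.02, 0.01, 0.05]])
        nrm = rng.normal(size=(2, 3))
        space = self._space(pos, nrm)
        chans = [self._mag([0, 0.03, 0.11], [0.2, 1, 1]),
                 self._mag([0.05, 0, 0.10], [1, 0, 1])]
        lf = assemble_leadfield(chans, space, CENTER)
        R = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        space_r = self._space(pos @ R.T, nrm @ R.T)
        chans_r = [self._mag(np.asarray(c.integration_points[0]) @ R.T,
                             c.orientation @ R.T) for c in chans]
        lf_r = assemble_leadfield(chans_r, space_r, CENTER)
        assert np.allclose(lf_r.gain, lf.gain, rtol=1e-10)

    def test_radial_sources_nearly_silent_through_assembly(self, small_fixture):
        from cerebmeg import helmet_layout

        fx = small_fixture
        space = fx.cerebellum_space
        radial = space.positions / np.linalg.norm(space.positions, axis=1,
                                                  keepdims=True)
        radial_space = SourceSpace(positions=space.positions, normals=radial,
                                   region="cerebellum")
        array = helmet_layout(fx.scalp, n_sensors=20, sensor_type="opm",
                              standoff=0.005)
        lf_folded = assemble_leadfield(array, space, CENTER)
        lf_radial = assemble_leadfield(array, radial_space, CENTER)
        assert (np.abs(lf_radial.gain).max()
                < 1e-3 * np.abs(lf_folded.gain).max())

    def test_source_outside_conductor_rejected(self):
        space = self._space([[0, 0, 0.12]], [[1, 0, 0]])
        ch = self._mag([0, 0, 0.11], [0, 0, 1])
        with pytest.raises(ValueError):
            assemble_leadfield([ch], space, CENTER)


class TestBoundaryExclusion:
    def test_distant_sources_untouched(self):
        boundary = make_sphere_mesh(0.08, 2)
        pos = np.array([[0, 0, 0.05], [0.02, 0, 0.04]])
        space = SourceSpace(positions=pos, normals=np.tile([1.0, 0, 0], (2, 1)),
                            region="cortex")
        out = exclude_near_boundary(space, boundary, 0.003)
        assert np.array_equal(out.positions, space.positions)

    def test_infinite_threshold_empties_space(self):
        boundary = make_sphere_mesh(0.08, 1)
        space = SourceSpace(positions=np.array([[0, 0, 0.05]]),
                            normals=np.array([[1.0, 0, 0]]), region="cortex")
        with pytest.warns(UserWarning):
            out = exclude_near_boundary(space, boundary, np.inf)
        assert len(out) == 0

    def test_known_construction_survivor_count(self, rng):
        # 93 sources well inside, 7 placed ~2 mm from the boundary sphere
        boundary = make_sphere_mesh(0.08, 3)
        r_eff = np.linalg.norm(
            boundary.vertices[boundary.faces].mean(axis=1), axis=1).mean()
        dirs = rng.normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = np.full(100, 0.05)
        radii[:7] = r_eff - 0.002
        space = SourceSpace(positions=dirs * radii[:, None], normals=dirs,
                            region="cortex")
        out = exclude_near_boundary(space, boundary, 0.003)
        assert len(out) == 93
        assert np.all(np.linalg.norm(out.positions, axis=1) < 0.06)

    def test_distance_matches_analytic_sphere(self):
        boundary = make_sphere_mesh(0.08, 4)
        pts = np.array([[0, 0, 0.05], [0, 0.06, 0], [0.03, 0.03, 0.03]])
        d = distance_to_mesh(pts, boundary)
        analytic = 0.08 - np.linalg.norm(pts, axis=1)
        # mesh is inscribed in the sphere, so distances agree to mesh sag
        assert np.allclose(d, analytic, atol=2e-4)

    def test_open_boundary_rejected(self):
        from cerebmeg import make_folded_surface

        cap, _ = make_folded_surface(0.07, 0.0, 6, np.deg2rad(60), (0, 0, 1),
                                     seed=1, subdivision_level=2)
        space = SourceSpace(positions=np.array([[0, 0, 0.05]]),
                            normals=np.array([[1.0, 0, 0]]), region="cortex")
        with pytest.raises(ValueError):
            exclude_near_boundary(space, cap)


class TestImportExport:
    def _leadfield(self, rng):
        chans = [Channel(kind="magnetometer",
                         integration_points=np.array([[0, 0, 0.1 + 0.01 * i]]),
                         integration_weights=[1.0],
                         orientation=np.array([0.0, 0.0, 1.0]),
                         parent_sensor_id=i)
                 for i in range(3)]
        space = SourceSpace(positions=rng.uniform(-0.01, 0.01, (4, 3)),
                            normals=np.tile([0, 1.0, 0], (4, 1)), region="cortex")
        return LeadField(gain=rng.normal(size=(3, 4)) * 1e-6,
                         channel_meta=chans, source_meta=space)

    def test_hdf5_round_trip_bit_identical(self, rng, tmp_path):
        lf = self._leadfield(rng)
        path = tmp_path / "lf.h5"
        export_leadfield(lf, path)
        back = import_leadfield(path)
        assert np.array_equal(back.gain, lf.gain)
        assert back.model_tag == "imported"

    def test_truncated_file_raises_format_error(self, rng, tmp_path):
        lf = self._leadfield(rng)
        path = tmp_path / "lf.h5"
        export_leadfield(lf, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError):
            import_leadfield(path)

    def test_shape_mismatch_rejected(self, rng, tmp_path):
        lf = self._leadfield(rng)
        path = tmp_path / "lf.h5"
        export_leadfield(lf, path)
        with pytest.raises(ValueError):
            import_leadfield(path, channel_meta=lf.channel_meta[:2])

    def test_unit_algebra_rescales_to_si(self, rng, tmp_path):
        # 1 fT/(nA·m) = 1e-15 T / 1e-9 A·m = 1e-6 T/(A·m)
        assert _parse_gain_unit("T/(A·m)") == 1.0
        assert _parse_gain_unit("fT/(nA·m)") == pytest.approx(1e-6)
        gain = rng.normal(size=(2, 3))
        np.save(tmp_path / "lf.npy", gain)
        (tmp_path / "lf.json").write_text('{"units": "fT/(nA·m)"}')
        back = import_leadfield(tmp_path / "lf.npy")
        assert np.allclose(back.gain, gain * 1e-6)
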