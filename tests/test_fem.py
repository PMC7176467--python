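"""Complete-electrode-model forward solver, meshing and Jacobian checks."""

import numpy as np
import pytest

from eitshape import fem
from eitshape.shapes import Contour


def circle_contour(n=64, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(r * np.column_stack([np.cos(th), np.sin(th)]))


def thorax_contour(n=48):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 1 + 0.17 * np.cos(2 * th) + 0.05 * np.cos(3 * th + 0.5)
    return Contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))


@pytest.fixture(scope="module")
def disc_model():
    return fem.build_model(circle_contour(), max_area=0.01)


@pytest.fixture(scope="module")
def coarse_model():
    return fem.build_model(circle_contour(48), max_area=0.03)


class TestElectrodes:
    def test_unit_circle_arcs(self):
        c = circle_contour(256)
        es = fem.place_electrodes(c, count=16, coverage=0.5)
        P = es.perimeter
        widths = np.mod(es.arcs[:, 1] - es.arcs[:, 0], P)
        np.testing.assert_allclose(widths, P / 32, rtol=1e-12)
        centers = np.mod(es.arcs.mean(axis=1), P)
        np.testing.assert_allclose(np.sort(np.diff(np.sort(centers))),
                                   P / 16, rtol=1e-9)

    def test_arc_sum_equals_coverage(self):
        es = fem.place_electrodes(thorax_contour(), coverage=0.37)
        total = np.mod(es.arcs[:, 1] - es.arcs[:, 0], es.perimeter).sum()
        assert total == pytest.approx(0.37 * es.perimeter, rel=1e-9)

    def test_nonconvex_positions_match_arclength_oracle(self):
        c = thorax_contour(64)
        es = fem.place_electrodes(c, count=8, coverage=0.4)
        # brute-force cumulative arc-length search on a dense polyline
        dense = c.resample(20000).points
        seg = np.linalg.norm(np.diff(np.vstack([dense, dense[:1]]), axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        for s_center in es.arcs.mean(axis=1):
            i = np.searchsorted(cum, s_center % es.perimeter)
            expected = dense[min(i, len(dense) - 1)]
            got = c.point_at_arclength([s_center])[0]
            assert np.linalg.norm(got - expected) < 1e-3

    def test_rejects_bad_args(self):
        c = circle_contour()
        with pytest.raises(ValueError):
            fem.place_electrodes(c, count=1)
        with pytest.raises(ValueError):
            fem.place_electrodes(c, coverage=1.5)


class TestMesh:
    def test_area_and_quality(self, disc_model):
        mesh = disc_model.mesh
        A = mesh.element_areas
        assert np.all(A > 0)
        assert A.sum() == pytest.approx(np.pi, rel=5e-3)
        assert A.max() <= 0.01 * 2.5  # soft bound: graded mesh

    def test_every_electrode_has_two_edges(self, disc_model):
        labels = disc_model.mesh.boundary_edges[:, 2]
        for l in range(16):
            assert np.count_nonzero(labels == l) >= 2

    def test_thorax_mesh_area(self):
        c = thorax_contour()
        es = fem.place_electrodes(c)
        mesh = fem.build_mesh(c, es, max_area=0.01)
        assert mesh.element_areas.sum() == pytest.approx(c.area, rel=5e-3)

    def test_element_count_scales(self):
        c = circle_contour()
        es = fem.place_electrodes(c)
        n1 = fem.build_mesh(c, es, max_area=0.02).n_elements
        n2 = fem.build_mesh(c, es, max_area=0.005).n_elements
        assert n2 > 2.5 * n1


class TestPattern:
    def test_adjacent_16_has_208_channels(self):
        p = fem.adjacent_pattern(16)
        assert p.n_channels == 208
        for (a, b), meas in zip(p.drive_pairs, p.meas_pairs):
            assert len(meas) == 13
            for m in meas:
                assert not ({a, b} & set(m))

    def test_skip_pattern(self):
        p = fem.adjacent_pattern(16, skip=2)
        assert all((b - a) % 16 == 3 for a, b in p.drive_pairs)


class TestForward:
    def test_reciprocity(self, disc_model):
        fr = fem.solve_forward(disc_model)
        vmap = dict(zip(fr.channels, fr.v))
        drv = list(disc_model.pattern.drive_pairs)
        scale = np.abs(fr.v).max()
        n_checked = 0
        for (d, p, q), val in vmap.items():
            if (p, q) in drv:
                rec = vmap.get((drv.index((p, q)), *drv[d]))
                if rec is not None:
                    assert abs(val - rec) / scale < 1e-10
                    n_checked += 1
        assert n_checked > 100

    def test_conductivity_scaling(self, disc_model):
        # v(c*sigma) = v(sigma)/c holds when the contact impedance is scaled
        # by 1/c along with the conductivity (pure scaling of the CEM)
        m = disc_model
        fr1 = fem.solve_forward(m)
        m2 = fem.EITModel(
            mesh=m.mesh,
            electrodes=fem.ElectrodeSet(m.electrodes.count, m.electrodes.arcs,
                                        m.electrodes.contact_impedance / 3.0,
                                        m.electrodes.perimeter),
            pattern=m.pattern, sigma_ref=3.0 * m.sigma_ref, contour=m.contour)
        fr2 = fem.solve_forward(m2)
        np.testing.assert_allclose(fr2.v, fr1.v / 3.0, rtol=1e-10)

    def test_rejects_nonpositive_sigma(self, disc_model):
        with pytest.raises(ValueError):
            fem.solve_forward(disc_model, np.zeros(disc_model.mesh.n_elements))

    def test_analytic_disc_series(self):
        """Homogeneous disc vs the closed-form Fourier series.

        Small electrodes (2% coverage) with high contact impedance behave
        as uniform-current-density arcs; the series carries the
        corresponding sinc^2 factors.  Error is measured relative to the
        largest channel voltage.
        """
        c = circle_contour(256)
        m = fem.build_model(c, coverage=0.02, contact_impedance=1.0,
                            max_area=0.0005)
        fr = fem.solve_forward(m)
        ang = 2 * np.pi * np.arange(16) / 16
        w = 0.02 * (2 * np.pi / 16) / 2
        n = np.arange(1, 200001)
        sinc2 = (np.sin(n * w) / (n * w)) ** 2

        def pot(theta, a, b):
            return (1 / np.pi) * np.sum(
                sinc2 / n * (np.cos(n * (theta - ang[a])) - np.cos(n * (theta - ang[b]))))

        drv = list(m.pattern.drive_pairs)
        va = np.array([pot(ang[p], *drv[d]) - pot(ang[q], *drv[d])
                       for d, p, q in fr.channels])
        assert np.abs(fr.v - va).max() / np.abs(va).max() < 0.01


class TestJacobian:
    def test_finite_difference_agreement(self, coarse_model):
        m = coarse_model
        assert m.mesh.n_elements <= 300
        J = fem.compute_jacobian(m).matrix
        v_r = fem.solve_forward(m).v
        delta = 1e-6
        rng = np.random.default_rng(0)
        cols = rng.choice(m.mesh.n_elements, size=25, replace=False)
        scale = np.abs(J).max()
        for e in cols:
            sp = m.sigma_ref.copy()
            sp[e] *= 1 + delta
            sm = m.sigma_ref.copy()
            sm[e] *= 1 - delta
            fd = (fem.solve_forward(m, sp).v - fem.solve_forward(m, sm).v) / (2 * delta) / v_r
            assert np.abs(fd - J[:, e]).max() / scale < 1e-5

    def test_global_scaling_direction(self, coarse_model):
        # directional derivative along uniform conductivity scaling
        m = coarse_model
        Jraw = fem.compute_jacobian(m, normalized=False).matrix
        delta = 1e-6
        vp = fem.solve_forward(m, m.sigma_ref * (1 + delta)).v
        vm = fem.solve_forward(m, m.sigma_ref * (1 - delta)).v
        fd = (vp - vm) / (2 * delta)
        total = Jraw @ m.sigma_ref
        np.testing.assert_allclose(total, fd, atol=1e-5 * np.abs(fd).max())

    def test_mirror_symmetry(self, disc_model):
        """Sensitivity of one channel is mirror-symmetric on the disc.

        Drive (0,1), measure (8,9): the configuration is symmetric about
        the line bisecting both pairs, up to mesh asymmetry.
        """
        m = disc_model
        J = fem.compute_jacobian(m).matrix
        chans = list(fem.solve_forward(m).channels)
        i = chans.index((0, 8, 9))
        cent = m.mesh.centroids
        # symmetry axis at angle (mean of drive and measure pair centers)
        phi = (2 * np.pi / 16) * ((0 + 1) / 2 + (8 + 9) / 2) / 2
        d = np.array([np.cos(phi), np.sin(phi)])
        proj = cent @ d
        perp = cent @ np.array([-d[1], d[0]])
        row = J[i]
        # compare each element with its nearest mirror element
        mirrored = np.column_stack([proj, -perp])
        orig = np.column_stack([proj, perp])
        from scipy.spatial import cKDTree
        tree = cKDTree(orig)
        dist, idx = tree.query(mirrored)
        ok = dist < 0.05
        corr = np.corrcoef(row[ok], row[idx[ok]])[0, 1]
        assert corr > 0.95


class TestSimulation:
    def test_factor_one_identity(self, disc_model):
        v_r, v = fem.simulate_target_frame(disc_model, (0.0, 0.0), 0.1, 1.0)
        np.testing.assert_array_equal(v_r.v, v.v)

    def test_central_target_signal(self, disc_model):
        v_r, v = fem.simulate_target_frame(disc_model, (0.0, 0.0), 0.15, 0.5)
        y = (v.v - v_r.v) / v_r.v
        assert np.all(np.isfinite(y))
        assert np.abs(y).max() > 0

    def test_target_outside_rejected(self, disc_model):
        with pytest.raises(ValueError):
            fem.simulate_target_frame(disc_model, (1.05, 0.0), 0.1, 0.5)

    def test_linearization_consistency(self, coarse_model):
        m = coarse_model
        J = fem.compute_jacobian(m).matrix
        sigma = fem.target_sigma(m, (0.3, 0.1), 0.2, 0.99)
        v_r = fem.solve_forward(m).v
        v = fem.solve_forward(m, sigma).v
        y = (v - v_r) / v_r
        x = sigma / m.sigma_ref - 1.0
        pred = J @ x
        assert np.abs(pred - y).max() / np.abs(y).max() < 0.05

    def test_lung_frame(self, disc_model):
        lungs = [0.45 * np.column_stack([np.cos(t), np.sin(t)]) + [s, 0.0]
                 for s, t in ((-0.5, np.linspace(0, 2 * np.pi, 32, endpoint=False)),
                              (0.5, np.linspace(0, 2 * np.pi, 32, endpoint=False)))]
        v_r, v = fem.simulate_lung_frame(disc_model, lungs, ratio=1.0)
        np.testing.assert_array_equal(v_r.v, v.v)
        v_r, v = fem.simulate_lung_frame(disc_model, lungs, ratio=0.1875)
        y1 = np.linalg.norm((v.v - v_r.v) / v_r.v)
        _, v2 = fem.simulate_lung_frame(disc_model, lungs, ratio=0.1)
        y2 = np.linalg.norm((v2.v - v_r.v) / v_r.v)
        assert y2 > y1 > 0  # lower lung conductivity, larger signal

    def test_lung_channels_near_lungs_strongest(self, disc_model):
        t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        lungs = [0.4 * np.column_stack([np.cos(t), np.sin(t)]) + [s, 0.0]
                 for s in (-0.5, 0.5)]
        v_r, v = fem.simulate_lung_frame(disc_model, lungs, ratio=0.1875)
        y = (v.v - v_r.v) / v_r.v
        # sensitivity-weighted oracle: |y| should correlate with J @ x
        J = fem.compute_jacobian(disc_model).matrix
        import shapely
        import shapely.geometry as geom
        cent = disc_model.mesh.centroids
        mask = np.zeros(len(cent), bool)
        for l in lungs:
            mask |= shapely.contains_xy(geom.Polygon(l), cent[:, 0], cent[:, 1])
        pred = J @ np.where(mask, 0.1875 - 1.0, 0.0)
        assert np.corrcoef(np.abs(y), np.abs(pred))[0, 1] > 0.9


class TestIO:
    def test_frame_csv_round_trip(self, disc_model, tmp_path):
        fr = fem.solve_forward(disc_model)
        p = tmp_path / "frame.csv"
        fem.write_frame_csv(fr, p)
        back = fem.read_frame_csv(p, disc_model.pattern)
        np.testing.assert_allclose(back.v, fr.v, rtol=1e-10)
        with pytest.raises(ValueError):
            fem.read_frame_csv(p, fem.adjacent_pattern(8))

    def test_mesh_exports(self, coarse_model, tmp_path):
        mesh = coarse_model.mesh
        fem.export_mesh_csv(mesh, tmp_path / "n.csv", tmp_path / "e.csv")
        nodes = np.genfromtxt(tmp_path / "n.csv", delimiter=",", names=True)
        assert len(nodes) == mesh.n_nodes
        fem.write_msh22(mesh, tmp_path / "m.msh")
        text = (tmp_path / "m.msh").read_text()
        assert text.startswith("$MeshFormat\n2.2")
        assert f"\n$Elements\n{mesh.n_elements + len(mesh.boundary_edges)}\n" in text


class TestNoise:
    def test_seed_reproducible(self, disc_model):
        fr = fem.solve_forward(disc_model)
        a = fem.add_noise(fr, snr=50, seed=42)
        b = fem.add_noise(fr, snr=50, seed=42)
        np.testing.assert_array_equal(a.v, b.v)
        c = fem.add_noise(fr, snr=50, seed=43)
        assert not np.array_equal(a.v, c.v)

    def test_high_snr_limit(self, disc_model):
        fr = fem.solve_forward(disc_model)
        out = fem.add_noise(fr, snr=1e12, seed=0)
        np.testing.assert_allclose(out.v, fr.v, rtol=1e-9)

    def test_empirical_noise_sd(self, disc_model):
        fr = fem.solve_forward(disc_model)
        nominal = np.linalg.norm(fr.v) / (np.sqrt(len(fr.v)) * 10.0)
        draws = np.concatenate([
            fem.add_noise(fr, snr=10.0, seed=s).v - fr.v for s in range(50)])
        assert np.std(draws) == pytest.approx(nominal, rel=0.03)
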