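"""Morphometric parameters on phantoms with analytic ground truth."""

from itertools import combinations

import numpy as np
import pytest

from trabarch import metrics as M
from trabarch.synthetic import PhantomSpec, make_phantom
from trabarch.volumes import VoxelVolume

from conftest import make_plate


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_otsu(data: np.ndarray) -> int:
    """Exhaustive scan over 256 thresholds maximising between-class variance."""
    flat = data.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(int(flat.min()), int(flat.max())):
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def clique_complex_euler(vol: np.ndarray) -> int:
    """Euler characteristic of the 26-connectivity continuous analog.

    Within every 2x2x2 cell all eight voxels are mutually 26-adjacent, so
    every subset of foreground voxels in a cell spans a simplex of the
    polyhedral analog; chi is the alternating simplex count.
    """
    vol = np.asarray(vol, bool)
    pad = np.pad(vol, 1)
    simplices: set = set()
    nz, ny, nx = vol.shape
    for z in range(nz + 1):
        for y in range(ny + 1):
            for x in range(nx + 1):
                fg = [
                    (z + dz, y + dy, x + dx)
                    for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)
                    if pad[z + dz, y + dy, x + dx]
                ]
                for r in range(1, len(fg) + 1):
                    for sub in combinations(fg, r):
                        simplices.add(frozenset(sub))
    return sum((-1) ** (len(s) - 1) for s in simplices)


def cast_mil_oracle(data: np.ndarray, direction_xyz, spacing_lines=1.0, step=0.5) -> float:
    """Plain-numpy MIL for one direction: parallel lines, nearest-voxel
    sampling, total in-volume length over boundary crossings."""
    shape = np.array(data.shape, float)
    centre = (shape - 1) / 2
    d = np.array([direction_xyz[2], direction_xyz[1], direction_xyz[0]])
    a = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    radius = np.linalg.norm(shape) / 2
    offs = np.arange(-radius, radius, spacing_lines)
    total_len, total_cross = 0.0, 0
    t = np.arange(-radius, radius, step)
    for ou in offs:
        for ov in offs:
            if ou * ou + ov * ov > radius * radius:
                continue
            pts = centre + ou * u + ov * v + t[:, None] * d
            idx = np.rint(pts).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(data.shape)), axis=1)
            vals = np.where(ok, data[idx[:, 0].clip(0, data.shape[0] - 1),
                                     idx[:, 1].clip(0, data.shape[1] - 1),
                                     idx[:, 2].clip(0, data.shape[2] - 1)], -1)
            run = vals[vals >= 0]
            if run.size > 1:
                total_len += (run.size - 1) * step
                total_cross += int(np.count_nonzero(np.diff(run)))
    return total_len / total_cross if total_cross else np.inf


# ---------------------------------------------------------------------------
# Thresholding and purify


class TestThreshold:
    def test_bimodal_threshold_separates_modes(self):
        rng = np.random.default_rng(0)
        data = rng.choice([40, 200], size=(16, 16, 16)).astype(np.uint8)
        t = M.optimise_threshold(VoxelVolume(data, spacing=20.0))
        assert 40 <= t < 200
        assert ((data > t) == (data == 200)).all()

    def test_gaussian_mixture_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        n = 24**3
        lo = rng.normal(50, 10, int(0.4 * n))
        hi = rng.normal(180, 10, n - lo.size)
        data = np.clip(np.concatenate([lo, hi]), 0, 255).astype(np.uint8)
        rng.shuffle(data)
        data = data.reshape(24, 24, 24)
        t = M.optimise_threshold(VoxelVolume(data, spacing=20.0))
        assert abs(t - brute_force_otsu(data)) <= 3

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            M.optimise_threshold(VoxelVolume(np.full((8, 8, 8), 3, np.uint8), spacing=20.0))

    def test_fixed_strategy(self):
        data = np.arange(8**3, dtype=np.uint16).reshape(8, 8, 8)
        assert M.optimise_threshold(VoxelVolume(data, spacing=1.0), "fixed:100") == 100.0


class TestPurify:
    def test_floating_island_removed(self):
        data = np.zeros((20, 20, 20), bool)
        data[2:18, 8:12, 8:12] = True  # main strut
        data[1, 1, 1:4] = True  # 3-voxel island
        out = M.purify(data)
        assert not out[1, 1, 1:4].any()
        assert out[2:18, 8:12, 8:12].all()

    def test_enclosed_cavity_filled(self):
        data = np.zeros((20, 20, 20), bool)
        data[5:15, 5:15, 5:15] = True
        data[9:11, 9:11, 9:11] = False  # cavity
        out = M.purify(data)
        assert out[9:11, 9:11, 9:11].all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        data = rng.random((24, 24, 24)) > 0.55
        once = M.purify(data)
        assert np.array_equal(M.purify(once), once)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            M.purify(np.zeros((8, 8, 8), bool))


# ---------------------------------------------------------------------------
# Scalar morphometry


class TestVolumeFraction:
    def test_solid_cube(self):
        vol = VoxelVolume(np.ones((100, 100, 100), bool), spacing=20.0)
        bv, tv, bvtv = M.bone_volume_fraction(vol)
        assert bvtv == 1.0
        assert tv == pytest.approx(8.0)

    def test_plate_stack_closed_form(self):
        vol = make_plate(size=130, period=10, thickness=4)
        _, _, bvtv = M.bone_volume_fraction(vol)
        assert bvtv == pytest.approx(0.400, abs=1e-12)

    def test_rod_lattice_closed_form(self):
        vol, truth = make_phantom(PhantomSpec("rod_lattice", size=130, period=10, thickness=2))
        _, _, bvtv = M.bone_volume_fraction(vol)
        assert truth.bvtv == pytest.approx(3 * 0.2**2 - 2 * 0.2**3)
        assert bvtv == pytest.approx(truth.bvtv, rel=0.02)

    def test_conservation(self):
        rng = np.random.default_rng(3)
        data = rng.random((30, 30, 30)) > 0.5
        vol = VoxelVolume(data, spacing=15.0)
        bv, tv, _ = M.bone_volume_fraction(vol)
        bg = VoxelVolume(~data, spacing=15.0)
        bv_bg, _, _ = M.bone_volume_fraction(bg)
        assert bv + bv_bg == pytest.approx(tv, rel=1e-12)


class TestBoneSurface:
    def test_ball_matches_closed_form(self, ball_volume):
        bs = M.bone_surface(ball_volume)
        assert bs == pytest.approx(4 * np.pi * 0.4**2, rel=0.03)

    def test_large_box_matches_closed_form(self):
        data = np.zeros((140, 120, 100), bool)
        data[5:125, 5:105, 5:85] = True
        bs = M.bone_surface(VoxelVolume(data, spacing=10.0))
        true = 2 * (120 * 100 + 100 * 80 + 120 * 80) * 0.01**2
        assert bs == pytest.approx(true, rel=0.03)

    def test_spacing_scaling(self, ball_volume):
        bs1 = M.bone_surface(ball_volume)
        double = VoxelVolume(ball_volume.data, spacing=20.0)
        assert M.bone_surface(double) == pytest.approx(4 * bs1, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.bone_surface(VoxelVolume(np.zeros((8, 8, 8), bool), spacing=10.0))


class TestLocalThickness:
    def test_isolated_ball_thickness_is_diameter(self):
        r, pad = 8, 4
        n = 2 * (r + pad) + 1  # odd: ball centred on a voxel
        zz, yy, xx = np.indices((n, n, n))
        c = (n - 1) / 2
        data = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 < r * r
        th = M.local_thickness(VoxelVolume(data, spacing=20.0), "foreground")
        assert th == pytest.approx(0.32, abs=0.02)  # 1 voxel

    def test_plate_stack_thickness_and_separation(self, plate_volume):
        th = M.local_thickness(plate_volume, "foreground")
        sp = M.local_thickness(plate_volume, "background")
        assert th == pytest.approx(0.08, abs=0.02)
        assert sp == pytest.approx(0.12, abs=0.02)

    def test_linear_in_spacing(self, plate_volume):
        th1 = M.local_thickness(plate_volume, "foreground")
        scaled = VoxelVolume(plate_volume.data, spacing=plate_volume.spacing * 3)
        assert M.local_thickness(scaled, "foreground") == pytest.approx(3 * th1, rel=1e-9)

    def test_empty_phase_rejected(self):
        solid = VoxelVolume(np.ones((8, 8, 8), bool), spacing=20.0)
        with pytest.raises(ValueError, match="background"):
            M.local_thickness(solid, "background")


class TestConnectivity:
    def test_solid_ball_simply_connected(self, ball_volume):
        conn, _ = M.connectivity(ball_volume)
        assert conn == 0

    def test_single_loop(self):
        data = np.zeros((20, 20, 20), bool)
        data[10, 5:15, 5] = data[10, 5:15, 14] = True
        data[10, 5, 5:15] = data[10, 14, 5:15] = True
        conn, _ = M.connectivity(VoxelVolume(data, spacing=20.0))
        assert conn == 1

    def test_wireframe_cube(self):
        vol, truth = make_phantom(PhantomSpec("wireframe_cube", size=40))
        conn, connd = M.connectivity(vol)
        assert conn == truth.conn == 5
        assert connd == pytest.approx(5 / (40 * 0.02) ** 3)

    def test_matches_clique_complex_oracle_on_random_volumes(self):
        rng = np.random.default_rng(4)
        for trial in range(8):
            n = int(rng.integers(5, 13))
            data = rng.random((n, n, n)) < rng.uniform(0.25, 0.75)
            conn, _ = M.connectivity(VoxelVolume(data, spacing=20.0))
            assert conn == 1 - clique_complex_euler(data)


# ---------------------------------------------------------------------------
# Fabric


class TestFabric:
    def test_plate_normal_is_smallest_mil_direction(self, plate_volume):
        fab = M.mil_fabric(plate_volume, n_directions=128, seed=1)
        v_min = fab.eigenvectors[:, 2]  # xyz; plate normal is z (axis 0)
        angle = np.degrees(np.arccos(abs(v_min[2])))
        assert angle < 5.0
        assert M.degree_of_anisotropy(fab) >= 0.8

    def test_aligned_rods_main_direction(self):
        vol, truth = make_phantom(PhantomSpec("aligned_rods", size=64, period=16, thickness=5))
        fab = M.mil_fabric(vol, n_directions=128, seed=1)
        v = fab.eigenvectors[:, 0]
        angle = np.degrees(np.arccos(abs(np.dot(v, truth.main_direction))))
        assert angle < 5.0

    def test_matches_brute_force_line_casting(self, plate_volume):
        from trabarch.metrics import _mil_one_direction

        grf, _ = make_phantom(PhantomSpec("grf", size=48, sigmas=(2, 3, 4),
                                          target_bvtv=0.4, seed=21))
        cases = [
            (plate_volume.data, [0.0, 0.0, 1.0]),  # across the plates
            (grf.data, [0.0, 0.0, 1.0]),
            (grf.data, [1.0, 0.0, 0.0]),
            (grf.data, [0.577, 0.577, 0.577]),
        ]
        for data, d in cases:
            d = np.asarray(d) / np.linalg.norm(d)
            mil_impl, _, _ = _mil_one_direction(
                data, d, np.random.default_rng(0), 1.0, 0.5)
            mil_oracle = cast_mil_oracle(data, d)
            assert mil_impl == pytest.approx(mil_oracle, rel=0.1)

    def test_isotropic_grf_nearly_isotropic_fabric(self):
        ratios = []
        for seed in (0, 1, 2):
            vol, _ = make_phantom(PhantomSpec("grf", size=96, sigmas=(3, 3, 3),
                                              target_bvtv=0.4, seed=seed))
            fab = M.mil_fabric(vol, n_directions=96, seed=seed)
            ratios.append(fab.eigenvalues[-1] / fab.eigenvalues[0])
        assert min(ratios) >= 0.85

    def test_da_monotone_in_grf_stretch(self):
        das = []
        for sz in (2.0, 4.0, 8.0):
            vol, _ = make_phantom(PhantomSpec("grf", size=96, sigmas=(sz, 2, 2),
                                              target_bvtv=0.4, seed=5))
            fab = M.mil_fabric(vol, n_directions=96, seed=5)
            das.append(M.degree_of_anisotropy(fab))
        assert das[0] < das[1] < das[2]

    def test_rotation_permutes_eigenvector_components(self):
        vol, _ = make_phantom(PhantomSpec("aligned_rods", size=48, period=16, thickness=5, axis=0))
        rot = VoxelVolume(np.rot90(vol.data, axes=(0, 2)).copy(), spacing=vol.spacing)
        f0 = M.mil_fabric(vol, n_directions=96, seed=2)
        f1 = M.mil_fabric(rot, n_directions=96, seed=2)
        # rods along array axis 0 (z) become rods along array axis 2 (x)
        assert abs(f0.eigenvectors[2, 0]) > 0.99
        assert abs(f1.eigenvectors[0, 0]) > 0.99
        assert M.degree_of_anisotropy(f0) == pytest.approx(M.degree_of_anisotropy(f1), abs=0.05)

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            M.mil_fabric(VoxelVolume(np.ones((8, 8, 8), bool), spacing=20.0))


class TestDAandMDT:
    def test_da_arithmetic(self):
        eye = np.eye(3)
        assert M.degree_of_anisotropy(M.FabricTensor(np.array([1.0, 1, 1]), eye)) == 0.0
        assert M.degree_of_anisotropy(M.FabricTensor(np.array([2.0, 1, 1]), eye)) == 0.5

    @pytest.mark.parametrize("vec,expected", [
        ((0.0, 0.0, 1.0), (0.0, 0.0)),
        ((1.0, 0.0, 0.0), (90.0, 0.0)),
        ((0.5, 0.5, np.sqrt(2) / 2), (45.0, 45.0)),
    ])
    def test_mdt_conventions(self, vec, expected):
        v1 = np.array(vec)
        # build an orthonormal triad with v1 first
        a = np.array([0.0, 1.0, 0.0]) if abs(v1[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
        v2 = np.cross(v1, a)
        v2 /= np.linalg.norm(v2)
        v3 = np.cross(v1, v2)
        fab = M.FabricTensor(np.array([2.0, 1.0, 0.5]), np.column_stack([v1, v2, v3]))
        theta, phi = M.main_direction(fab)
        assert theta == pytest.approx(expected[0], abs=1e-6)
        assert phi == pytest.approx(expected[1], abs=1e-6)


# ---------------------------------------------------------------------------
# QC


class TestQC:
    @pytest.mark.parametrize("tbth,spacing,ratio,passed", [
        (0.17, 34.0, 5.0, True),
        (0.12, 30.0, 4.0, False),
        (0.17, 17.0, 10.0, True),
    ])
    def test_relative_resolution(self, tbth, spacing, ratio, passed):
        r, ok = M.relative_resolution_check(tbth, spacing)
        assert r == pytest.approx(ratio)
        assert ok is passed

    def test_identical_repeats_zero_cv(self):
        row = {"DA": 0.5, "BVTV": 0.4, "TbTh": 0.1}
        out = M.repeatability_cv([row, dict(row), dict(row)])
        assert out["mean_cv"] == pytest.approx(0.0, abs=1e-9)

    def test_known_cv(self):
        out = M.repeatability_cv([{"x": 9.0}, {"x": 10.0}, {"x": 11.0}])
        assert out["x"] == pytest.approx(10.0)

    def test_jittered_re_extraction_cv_below_5pct(self):
        from trabarch.volumes import extract_cubic_voi

        vol, _ = make_phantom(PhantomSpec("grf", size=72, sigmas=(2.5, 2.5, 2.5),
                                          target_bvtv=0.4, seed=11))
        rng = np.random.default_rng(11)
        rows = []
        for rep in range(10):
            centre = tuple(36 + int(j) for j in rng.integers(-1, 2, 3))
            voi, _ = extract_cubic_voi(vol, centre, edge=49)
            m = M.compute_metrics(voi, already_binary=True, n_directions=64, seed=3)
            rows.append({k: v for k, v in m.as_dict().items()
                         if k in ("DA", "BVTV", "TbTh", "TbSp", "ConnD")})
        out = M.repeatability_cv(rows)
        assert out["mean_cv"] < 5.0


class TestPipelineDeterminism:
    def test_identical_inputs_identical_metrics(self):
        vol, _ = make_phantom(PhantomSpec("grf", size=48, sigmas=(2, 2, 3),
                                          target_bvtv=0.4, seed=9))
        m1 = M.compute_metrics(vol, already_binary=True, n_directions=64, seed=5)
        m2 = M.compute_metrics(vol, already_binary=True, n_directions=64, seed=5)
        assert m1.as_dict() == m2.as_dict()

    def test_mirror_preserves_rotation_invariant_metrics(self):
        data, _ = make_phantom(PhantomSpec("grf", size=48, sigmas=(2, 2, 4),
                                           target_bvtv=0.4, seed=13))
        left = VoxelVolume(data.data, spacing=data.spacing, side="left")
        from trabarch.volumes import mirror_left_bone

        right = mirror_left_bone(left)
        m_l = M.compute_metrics(VoxelVolume(left.data, spacing=20.0), already_binary=True,
                                n_directions=96, seed=1)
        m_r = M.compute_metrics(right, already_binary=True, n_directions=96, seed=1)
        # voxel-count metrics are exactly invariant
        assert m_l.BVTV == m_r.BVTV
        assert m_l.Conn == m_r.Conn
        assert m_l.TbTh == pytest.approx(m_r.TbTh, rel=1e-9)
        # fabric is estimated on a different line grid after mirroring
        assert m_l.DA == pytest.approx(m_r.DA, abs=0.05)
        # medial-lateral (x) component flips sign, up to hemisphere flips
        assert abs(abs(m_l.V11) - abs(m_r.V11)) < 0.1
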