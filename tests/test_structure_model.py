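import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from switchfret import generate_toy_complex
from switchfret.structure_model import (Conformer, DyeCloud, FretPairConfig,
                                        Structure, accessible_volume,
                                        clash_filter, generate_conformers,
                                        predict_pair_efficiency,
                                        predictions_for_conformer,
                                        rank_conformers, read_structure,
                                        rmsd_to_reference, tilt_angle,
                                        triangulate, write_structure,
                                        write_conformers_pdb)


@pytest.fixture(scope="module")
def toy():
    return generate_toy_complex(seed=0)


@pytest.fixture(scope="module")
def pairs():
    return [FretPairConfig("body_a", "dom_tip", 40.0),
            FretPairConfig("body_b", "dom_tip", 40.0),
            FretPairConfig("body_a", "dom_mid", 40.0)]


AV_SMALL = dict(target_points=(80, 160), linker_length=12.0)


class TestPdbIO:
    def test_write_read_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_structure(toy, path)
        loaded = read_structure(path)
        assert np.allclose(loaded.coords, toy.coords, atol=1.5e-3)  # PDB 3 decimals
        assert np.array_equal(loaded.elements, toy.elements)

    def test_residue_range_mask(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_structure(toy, path)
        dom_res = toy.res_ids[toy.domain_mask]
        loaded = read_structure(path, domain_residues=(dom_res.min(), dom_res.max()))
        assert np.array_equal(loaded.domain_mask, toy.domain_mask)

    def test_unknown_element_rejected(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        bad = Structure(coords=toy.coords, radii=toy.radii,
                        elements=np.full(toy.n_atoms, "XX"), res_ids=toy.res_ids,
                        chain_ids=toy.chain_ids, atom_names=toy.atom_names,
                        domain_mask=toy.domain_mask, anchor=toy.anchor)
        write_structure(bad, path)
        with pytest.raises(ValueError, match="unknown elements"):
            read_structure(path)

    def test_multi_model_export(self, toy, tmp_path):
        confs = generate_conformers(toy, grid_points_per_axis=2)
        path = tmp_path / "models.pdb"
        write_conformers_pdb(toy, confs[:3], path)
        text = path.read_text()
        assert text.count("MODEL") == 3


class TestConformerGrid:
    def test_default_grid_size(self, toy):
        confs = generate_conformers(toy)
        assert len(confs) == 15625

    def test_identity_rotation_included(self, toy):
        confs = generate_conformers(toy, grid_points_per_axis=5)
        rmsds = [np.sqrt(np.mean(np.sum((c.domain_coords
                                         - toy.domain_coords) ** 2, axis=1)))
                 for c in confs]
        assert min(rmsds) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_body_distances_preserved(self, toy):
        confs = generate_conformers(toy, grid_points_per_axis=4)
        d_ref = cdist(toy.domain_coords, toy.domain_coords)
        for c in confs[::13]:
            d = cdist(c.domain_coords, c.domain_coords)
            assert np.abs(d - d_ref).max() < 1e-6


class TestClashFilter:
    def test_two_atom_closed_form(self):
        # radii 1.7 + 1.7, threshold 0.3: contact limit 3.1 A
        def make(dz):
            return Structure(coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, dz]]),
                             radii=np.array([1.7, 1.7]),
                             elements=np.array(["C", "C"]),
                             res_ids=np.array([1, 2]),
                             chain_ids=np.array(["A", "B"]),
                             atom_names=np.array(["CA", "CA"]),
                             domain_mask=np.array([False, True]),
                             anchor=np.zeros(3))

        close = make(3.0)
        conf = Conformer(index=0, angles=np.zeros(3),
                         domain_coords=close.domain_coords)
        _, stats = clash_filter([conf], close)
        assert stats["n_clashing"] == 1  # 3.0 < 3.4 - 0.3

        far = make(3.2)
        conf = Conformer(index=0, angles=np.zeros(3),
                         domain_coords=far.domain_coords)
        survivors, _ = clash_filter([conf], far)
        assert len(survivors) == 1  # 3.2 >= 3.1

    def test_distant_domain_survives(self, toy):
        conf = Conformer(index=0, angles=np.zeros(3),
                         domain_coords=toy.domain_coords + [100.0, 0.0, 0.0])
        survivors, _ = clash_filter([conf], toy)
        assert len(survivors) == 1

    def test_agrees_with_all_pairs_oracle(self, toy):
        confs = generate_conformers(toy, grid_points_per_axis=9)
        _, _ = clash_filter(confs, toy)
        body = toy.body_coords
        br = toy.radii[~toy.domain_mask]
        dr = toy.radii[toy.domain_mask]
        limit = dr[:, None] + br[None, :] - 0.3
        for c in confs:
            oracle = bool(np.any(cdist(c.domain_coords, body) < limit))
            assert c.clash == oracle

    def test_threshold_monotonicity(self, toy):
        confs = generate_conformers(toy, grid_points_per_axis=7)
        loose, _ = clash_filter(confs, toy, threshold=0.6)
        strict, _ = clash_filter(confs, toy, threshold=0.1)
        assert {c.index for c in strict} <= {c.index for c in loose}


class TestAccessibleVolume:
    def test_isolated_site_fills_ball(self):
        coords = np.zeros((1, 3))
        cloud = accessible_volume(coords, np.array([1.7]), 0, linker_length=15.0,
                                  grid_spacing=1.5)
        expected = 4.0 / 3.0 * np.pi * 15.0 ** 3 / 1.5 ** 3
        assert cloud.n_positions == pytest.approx(expected, rel=0.1)

    def test_wall_confines_cloud_to_half_space(self):
        # slab of atoms at z ~ 0 blocks the lower half-space
        xs, ys = np.meshgrid(np.arange(-20, 21, 1.5), np.arange(-20, 21, 1.5))
        wall = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
        coords = np.vstack([[[0.0, 0.0, 6.0]], wall])
        radii = np.full(len(coords), 1.7)
        cloud = accessible_volume(coords, radii, 0, linker_length=10.0,
                                  grid_spacing=1.5, dye_radius=3.5)
        assert not cloud.empty
        assert np.all(cloud.positions[:, 2] > 0)
        # per-point oracle: every kept point respects both constraints
        d_attach = np.linalg.norm(cloud.positions - coords[0], axis=1)
        assert np.all(d_attach <= 10.0 + 1e-9)
        d_wall = cdist(cloud.positions, wall)
        assert np.all(d_wall >= 1.7 + 3.5 - 1e-9)

    def test_autotuned_cloud_size_in_range(self, toy):
        cloud = accessible_volume(toy.coords, toy.radii, toy.sites["dom_tip"])
        assert 600 <= cloud.n_positions <= 1200

    def test_fully_occluded_site_flagged(self):
        # attachment buried inside a dense cage
        g = np.arange(-6, 7, 2.0)
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        cage = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        cage = cage[np.linalg.norm(cage, axis=1) > 1.0]
        coords = np.vstack([[[0.0, 0.0, 0.0]], cage])
        cloud = accessible_volume(coords, np.full(len(coords), 1.7), 0,
                                  linker_length=8.0, grid_spacing=1.0)
        assert cloud.empty


class TestPairEfficiency:
    def _point_cloud(self, xyz):
        return DyeCloud(attachment_index=0, positions=np.atleast_2d(xyz),
                        linker_length=1.0, linker_width=1.0, dye_radius=1.0,
                        grid_spacing=1.0)

    @pytest.mark.parametrize("r,expected", [
        (40.0, 0.5),            # r = R0
        (1e-3, 1.0),            # contact
        (80.0, 1.0 / 65.0),     # r = 2 R0
    ])
    def test_closed_form_single_positions(self, r, expected):
        d = self._point_cloud([0.0, 0.0, 0.0])
        a = self._point_cloud([r, 0.0, 0.0])
        assert predict_pair_efficiency(d, a, R0=40.0) == pytest.approx(expected,
                                                                       rel=1e-6)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        d = self._point_cloud(rng.uniform(0, 10, (10, 3)))
        a = self._point_cloud(rng.uniform(30, 45, (10, 3)))
        e = predict_pair_efficiency(d, a, R0=40.0)
        acc = 0.0
        for p in d.positions:
            for q in a.positions:
                r = np.linalg.norm(p - q)
                acc += 1.0 / (1.0 + (r / 40.0) ** 6)
        assert e == pytest.approx(acc / 100.0, abs=1e-12)

    def test_monotone_in_translation_distance(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 5, (20, 3))
        d = self._point_cloud(base)
        es = []
        for shift in (20.0, 35.0, 50.0, 70.0):
            a = self._point_cloud(base + [shift, 0.0, 0.0])
            es.append(predict_pair_efficiency(d, a, R0=40.0))
        assert np.all(np.diff(es) < 0)

    def test_empty_cloud_rejected(self):
        d = self._point_cloud([0.0, 0.0, 0.0])
        empty = DyeCloud(attachment_index=0, positions=np.empty((0, 3)),
                         linker_length=1.0, linker_width=1.0, dye_radius=1.0,
                         grid_spacing=1.0, empty=True)
        with pytest.raises(ValueError):
            predict_pair_efficiency(d, empty, R0=40.0)


class TestRanking:
    def _conf(self, idx, pred):
        return Conformer(index=idx, angles=np.zeros(3),
                         domain_coords=np.zeros((1, 3)),
                         predicted_E=np.asarray(pred, dtype=float))

    def test_hand_computed_chi2(self):
        confs = [self._conf(0, [0.7, 0.6, 0.5]), self._conf(1, [0.8, 0.6, 0.4])]
        ranking = rank_conformers(confs, measured_E=[0.8, 0.6, 0.4])
        assert ranking.chi2[0] == pytest.approx(0.02, abs=1e-15)
        assert ranking.chi2[1] == 0.0
        assert list(ranking.order) == [1, 0]

    def test_missing_prediction_excluded(self):
        confs = [self._conf(0, [0.5, 0.5, 0.5]),
                 Conformer(index=1, angles=np.zeros(3),
                           domain_coords=np.zeros((1, 3)))]
        ranking = rank_conformers(confs, measured_E=[0.5, 0.5, 0.5])
        assert ranking.excluded == [1]

    def test_stable_tie_break(self):
        confs = [self._conf(i, [0.5]) for i in range(5)]
        ranking = rank_conformers(confs, measured_E=[0.5])
        assert list(ranking.order) == [0, 1, 2, 3, 4]


class TestGeometryMetrics:
    def _rod(self, n=8, spacing=2.0):
        c = np.zeros((n, 3))
        c[:, 2] = spacing * (np.arange(n) + 1)
        return c

    def test_rmsd_identity_and_translation(self):
        rod = self._rod()
        conf = Conformer(index=0, angles=np.zeros(3), domain_coords=rod.copy())
        assert rmsd_to_reference(conf, rod) == 0.0
        conf2 = Conformer(index=1, angles=np.zeros(3),
                          domain_coords=rod + [1.0, 0.0, 0.0])
        assert rmsd_to_reference(conf2, rod) == pytest.approx(1.0)

    def test_rmsd_rotation_closed_form(self):
        # rotating a rod about its base by theta moves each point by
        # 2 d_i sin(theta/2): RMSD = 2 sin(theta/2) sqrt(mean d_i^2)
        rod = self._rod()
        theta = np.radians(10.0)
        R = Rotation.from_euler("y", theta).as_matrix()
        conf = Conformer(index=0, angles=np.zeros(3), domain_coords=rod @ R.T)
        d = np.linalg.norm(rod, axis=1)
        expected = 2 * np.sin(theta / 2) * np.sqrt(np.mean(d ** 2))
        assert rmsd_to_reference(conf, rod) == pytest.approx(expected, rel=1e-9)

    def test_rmsd_atom_count_mismatch(self):
        conf = Conformer(index=0, angles=np.zeros(3), domain_coords=self._rod(5))
        with pytest.raises(ValueError):
            rmsd_to_reference(conf, self._rod(6))

    def test_tilt_identity_and_constructed_angle(self):
        rod = self._rod()
        conf0 = Conformer(index=0, angles=np.zeros(3), domain_coords=rod.copy())
        assert tilt_angle(conf0, rod) == pytest.approx(0.0, abs=1e-6)
        R = Rotation.from_euler("y", np.radians(40.0)).as_matrix()
        conf40 = Conformer(index=1, angles=np.zeros(3), domain_coords=rod @ R.T)
        assert tilt_angle(conf40, rod) == pytest.approx(40.0, abs=1e-6)

    def test_tilt_symmetric(self):
        rod = self._rod()
        R = Rotation.from_euler("x", np.radians(25.0)).as_matrix()
        tilted = rod @ R.T
        c1 = Conformer(index=0, angles=np.zeros(3), domain_coords=tilted)
        c2 = Conformer(index=1, angles=np.zeros(3), domain_coords=rod)
        assert tilt_angle(c1, rod) == pytest.approx(tilt_angle(c2, tilted),
                                                    abs=1e-9)

    def test_degenerate_axis_flagged(self):
        rng = np.random.default_rng(3)
        blob = rng.normal(0.0, 1.0, (200, 3))  # near-spherical
        conf = Conformer(index=0, angles=np.zeros(3), domain_coords=blob)
        with pytest.raises(ValueError, match="degenerate"):
            tilt_angle(conf, blob)


class TestEndToEnd:
    def test_toy_triangulation_recovers_truth(self, toy, pairs):
        confs = generate_conformers(toy, grid_points_per_axis=13)
        survivors, _ = clash_filter(confs, toy)
        # avoid the gimbal rows (beta = 0 or pi), where distinct grid points
        # are exact duplicates of each other by construction
        candidates = [c for c in survivors
                      if 0.1 < c.angles[1] < np.pi - 0.1]
        true_conf = candidates[len(candidates) // 3]
        measured = predictions_for_conformer(toy, true_conf, pairs, **AV_SMALL)
        result = triangulate(toy, pairs, {"state1": measured},
                             grid_points_per_axis=13, av_kwargs=AV_SMALL)
        ranking = result.rankings["state1"]
        best = result.survivors[ranking.order[0]]
        assert best.index == true_conf.index
        assert ranking.chi2[ranking.order[0]] == 0.0
        rmsds = [rmsd_to_reference(result.survivors[i], true_conf.domain_coords)
                 for i in ranking.top]
        assert max(rmsds) < 8.0
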