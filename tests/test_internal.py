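import numpy as np
import pytest

import batgen as bg
from batgen.internal import BATState

from conftest import dihedral_oracle, random_rigid_motion, wrap_angle


def random_conformations(toy, n, seed=0, torsion_only=False):
    """Random fixture conformations built through the BAT parametrization."""
    top, frame, idx = toy
    base = bg.cartesian_to_bat(frame, idx)
    rng = np.random.default_rng(seed)
    p = idx.n_placed
    bonds = base.bonds + (0 if torsion_only else rng.uniform(-0.05, 0.05, (n, p)))
    angles = np.clip(base.angles + rng.uniform(-0.2, 0.2, (n, p)), 0.2, np.pi - 0.2)
    torsions = wrap_angle(rng.uniform(-np.pi, np.pi, (n, p)))
    state = BATState(np.broadcast_to(base.root_coords, (n, 3, 3)).copy(),
                     np.broadcast_to(bonds, (n, p)).copy(), angles, torsions)
    return bg.bat_to_cartesian(state, idx)


class TestCartesianBat:
    def test_right_angle_construction(self):
        top = bg.MoleculeTopology(
            names=("A", "B", "C", "D"), elements=("C",) * 4,
            residue_indices=(0,) * 4, residue_names=("LIG",) * 4,
            bonds=((0, 1), (1, 2), (2, 3)),
        )
        idx = bg.build_bat_indexing(top, root=(0, 1, 2))
        frame = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=float)
        state = bg.cartesian_to_bat(frame, idx)
        assert state.bonds[0, 0] == pytest.approx(1.0)
        assert np.rad2deg(state.angles[0, 0]) == pytest.approx(90.0)
        assert abs(np.rad2deg(state.torsions[0, 0])) == pytest.approx(90.0)

    def test_exact_inverse_on_random_conformations(self, toy):
        _, _, idx = toy
        frames = random_conformations(toy, 100, seed=1)
        back = bg.bat_to_cartesian(bg.cartesian_to_bat(frames, idx), idx)
        assert np.abs(back - frames).max() < 1e-6

    def test_torsions_match_dihedral_oracle(self, toy):
        _, _, idx = toy
        frames = random_conformations(toy, 10, seed=2)
        state = bg.cartesian_to_bat(frames, idx)
        q = idx.placement_array
        for f in range(10):
            for p in range(idx.n_placed):
                i, j, k, l = q[p]
                expected = dihedral_oracle(frames[f, i], frames[f, j],
                                           frames[f, k], frames[f, l])
                assert abs(wrap_angle(state.torsions[f, p] - expected)) < 1e-9

    def test_torsions_match_mdanalysis(self, toy):
        from MDAnalysis.lib.distances import calc_dihedrals

        _, frame, idx = toy
        state = bg.cartesian_to_bat(frame, idx)
        q = idx.placement_array
        ref = calc_dihedrals(frame[q[:, 0]], frame[q[:, 1]],
                             frame[q[:, 2]], frame[q[:, 3]])
        assert np.abs(wrap_angle(state.torsions[0] - ref)).max() < 1e-5

    def test_collinear_triple_errors(self):
        top = bg.MoleculeTopology(
            names=("A", "B", "C", "D"), elements=("C",) * 4,
            residue_indices=(0,) * 4, residue_names=("LIG",) * 4,
            bonds=((0, 1), (1, 2), (2, 3)),
        )
        idx = bg.build_bat_indexing(top, root=(0, 1, 2))
        frame = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            bg.cartesian_to_bat(frame, idx)

    def test_torsion_shift_by_two_pi_is_identity(self, toy):
        _, frame, idx = toy
        state = bg.cartesian_to_bat(frame, idx)
        shifted = BATState(state.root_coords, state.bonds, state.angles,
                           state.torsions + 2 * np.pi)
        a = bg.bat_to_cartesian(state, idx)
        b = bg.bat_to_cartesian(shifted, idx)
        assert np.abs(a - b).max() < 1e-9

    def test_short_arc_near_180(self, toy):
        # 179° vs -179° torsions place the atom 2° apart, not 358°
        _, frame, idx = toy
        base = bg.cartesian_to_bat(frame, idx)

        def with_torsion(deg):
            t = np.array(base.torsions)
            t[0, -1] = np.deg2rad(deg)
            return bg.bat_to_cartesian(
                BATState(base.root_coords, base.bonds, base.angles, t), idx)[0]

        placed_atom = idx.placements[-1][0]
        d_short = np.linalg.norm(with_torsion(179)[placed_atom]
                                 - with_torsion(-179)[placed_atom])
        d_two_deg = np.linalg.norm(with_torsion(0)[placed_atom]
                                   - with_torsion(2)[placed_atom])
        assert d_short == pytest.approx(d_two_deg, rel=1e-6)

    def test_batched_call_accepts_thousands_of_frames(self, toy):
        _, frame, idx = toy
        frames = np.tile(frame, (5000, 1, 1))
        state = bg.cartesian_to_bat(frames, idx)
        assert state.torsions.shape[0] == 5000
        assert bg.bat_to_cartesian(state, idx).shape == frames.shape


class TestVBAT:
    def test_feature_lengths_for_study_systems(self):
        assert bg.feature_length(627) == 7488
        assert bg.feature_length(201) == 2376
        top, frame = bg.make_toy_molecule(201)
        idx = bg.build_bat_indexing(top)
        assert bg.cartesian_to_vbat(frame, idx).shape == (2376,)

    def test_round_trip_through_features(self, toy):
        _, _, idx = toy
        frames = random_conformations(toy, 100, seed=3)
        feats = bg.cartesian_to_vbat(frames, idx)
        ref = bg.cartesian_to_bat(frames, idx)
        back = bg.vbat_to_cartesian(feats, ref, idx)
        assert np.abs(back - frames).max() < 1e-6

    def test_rigid_motion_invariance(self, toy):
        _, frame, idx = toy
        feats = bg.cartesian_to_vbat(frame, idx)
        rng = np.random.default_rng(4)
        for _ in range(100):
            rot, trans = random_rigid_motion(rng)
            moved = frame @ rot.T + trans
            assert np.abs(bg.cartesian_to_vbat(moved, idx) - feats).max() < 1e-9

    def test_planar_quadruple_has_parallel_normals(self):
        top = bg.MoleculeTopology(
            names=("A", "B", "C", "D"), elements=("C",) * 4,
            residue_indices=(0,) * 4, residue_names=("LIG",) * 4,
            bonds=((0, 1), (1, 2), (2, 3)),
        )
        idx = bg.build_bat_indexing(top, root=(0, 1, 2))
        for torsion, sign in ((np.pi, -1.0), (1e-7, 1.0)):
            base = bg.cartesian_to_bat(
                np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0], [3.7, 1.4, 0.9]]),
                idx)
            state = BATState(base.root_coords, base.bonds, base.angles,
                             np.array([[torsion]]))
            feats = bg.cartesian_to_vbat(bg.bat_to_cartesian(state, idx), idx)
            n1, n2 = feats[0, :3], feats[0, 3:6]
            assert n1 @ n2 == pytest.approx(sign, abs=1e-5)

    def test_torsion_recovery_over_full_circle(self, toy):
        # 1° grid over (-π, π]: decode(encode) must restore the exact angle
        _, frame, idx = toy
        base = bg.cartesian_to_bat(frame, idx)
        grid = np.deg2rad(np.arange(-179.0, 180.1, 1.0))
        n = grid.size
        tors = np.broadcast_to(base.torsions, (n, idx.n_placed)).copy()
        tors[:, 2] = grid
        state = BATState(np.broadcast_to(base.root_coords, (n, 3, 3)).copy(),
                         np.broadcast_to(base.bonds, tors.shape).copy(),
                         np.broadcast_to(base.angles, tors.shape).copy(), tors)
        frames = bg.bat_to_cartesian(state, idx)
        feats = bg.cartesian_to_vbat(frames, idx)
        back = bg.vbat_to_cartesian(feats, base, idx)
        recovered = bg.cartesian_to_bat(back, idx).torsions[:, 2]
        assert np.abs(wrap_angle(recovered - grid)).max() < 1e-9

    def test_reference_supplies_bonds_features_supply_torsions(self, toy):
        _, _, idx = toy
        frame_a = random_conformations(toy, 1, seed=5)[0]
        state_a = bg.cartesian_to_bat(frame_a, idx)
        state_b = BATState(state_a.root_coords, state_a.bonds + 0.01,
                           state_a.angles, state_a.torsions)
        feats = bg.cartesian_to_vbat(frame_a, idx)
        out = bg.vbat_to_cartesian(feats, state_b, idx)
        decoded = bg.cartesian_to_bat(out, idx)
        assert np.abs(wrap_angle(decoded.torsions - state_a.torsions)).max() < 1e-6
        assert np.abs(decoded.angles - state_a.angles).max() < 1e-6
        assert np.abs(decoded.bonds - state_b.bonds).max() < 1e-9

    def test_decoding_renormalizes_noisy_normals(self, toy):
        _, frame, idx = toy
        ref = bg.reference_from_frame(frame, idx)
        feats = bg.cartesian_to_vbat(frame, idx)[None].copy()
        rng = np.random.default_rng(6)
        noisy = feats.reshape(1, idx.n_placed, 4, 3).copy()
        noisy[:, :, :2] *= rng.uniform(0.95, 1.05, (1, idx.n_placed, 2, 1))
        noisy = noisy.reshape(1, -1)
        a = bg.vbat_to_cartesian(noisy, ref, idx)
        b = bg.vbat_to_cartesian(feats, ref, idx)
        assert np.abs(a - b).max() < 1e-9

    def test_degenerate_normals_error(self, toy):
        _, frame, idx = toy
        feats = bg.cartesian_to_vbat(frame, idx)[None].copy()
        feats[0, :6] = 0.0
        with pytest.raises(ValueError, match="normal"):
            bg.vbat_to_cartesian(feats, bg.reference_from_frame(frame, idx), idx)


def test_feature_file_topology_guard(tmp_path, toy, two_state):
    top, frame, idx = toy
    feats = bg.cartesian_to_vbat(frame, idx)[None]
    path = tmp_path / "feats.h5"
    bg.save_features(path, feats, top)
    assert np.array_equal(bg.load_features(path, top), feats)
    other_top = two_state[0]
    with pytest.raises(ValueError, match="topology"):
        bg.load_features(path, other_top)
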