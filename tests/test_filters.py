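import numpy as np
import pytest

import batgen as bg
from batgen.filters import rmsd, rmsd_one_to_many

from conftest import random_rigid_motion


class TestRMSD:
    def test_zero_under_rigid_motion(self, toy):
        _, frame, _ = toy
        rng = np.random.default_rng(0)
        for _ in range(20):
            rot, trans = random_rigid_motion(rng)
            assert rmsd(frame, frame @ rot.T + trans) < 1e-9

    def test_symmetry(self, toy):
        _, frame, _ = toy
        rng = np.random.default_rng(1)
        other = frame + rng.normal(0, 0.5, frame.shape)
        assert rmsd(frame, other) == pytest.approx(rmsd(other, frame), abs=1e-9)

    def test_matches_mdanalysis(self, toy):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        _, frame, _ = toy
        rng = np.random.default_rng(2)
        for _ in range(10):
            other = frame + rng.normal(0, 0.8, frame.shape)
            expected = mda_rmsd(frame, other, center=True, superposition=True)
            assert rmsd(frame, other) == pytest.approx(expected, abs=1e-6)


class TestStandinEnergyModel:
    def test_clash_gives_enormous_energy(self, two_state):
        top, frame, _, _, _ = two_state
        clashed = np.array(frame)
        heavy = top.heavy_atoms()
        clashed[heavy[5]] = clashed[heavy[10]] + np.array([0.1, 0.0, 0.0])
        model = bg.StandinEnergyModel(top, frame)
        e_clash, terms = model.evaluate(clashed)
        e_ref, _ = model.evaluate(frame)
        assert e_clash > e_ref + 1e4
        assert terms["lj"] > 1e4

    def test_minimization_monotone_and_below_start(self, two_state):
        top, frame, _, traj, _ = two_state
        model = bg.StandinEnergyModel(top, frame)
        rng = np.random.default_rng(3)
        x = frame + rng.normal(0, 0.05, frame.shape)
        energies = [model.evaluate(x)[0]]
        for _ in range(20):
            x, e = model.minimize(x, steps=5)
            energies.append(e)
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        assert energies[-1] < energies[0]

    def test_gradient_matches_finite_differences(self, two_state):
        top, frame, _, _, _ = two_state
        model = bg.StandinEnergyModel(top, frame)
        rng = np.random.default_rng(4)
        x = frame + rng.normal(0, 0.05, frame.shape)
        g = model.gradient(x)
        eps = 1e-6
        for a in (0, 7, 19):
            for c in range(3):
                xp, xm = x.copy(), x.copy()
                xp[a, c] += eps
                xm[a, c] -= eps
                num = (model.evaluate(xp)[0] - model.evaluate(xm)[0]) / (2 * eps)
                assert g[a, c] == pytest.approx(num, abs=1e-5)

    def test_evaluate_deterministic_and_batched(self, two_state):
        top, frame, _, traj, _ = two_state
        model = bg.StandinEnergyModel(top, frame)
        e1, _ = model.evaluate(traj.coords[:10])
        e2, _ = model.evaluate(traj.coords[:10])
        assert np.array_equal(e1, e2)
        assert e1.shape == (10,)


class TestEnergyFilter:
    def test_cutoff_bounds(self, two_state):
        top, frame, _, traj, _ = two_state
        model = bg.StandinEnergyModel(top, frame)
        cands = traj.subset(range(20))
        out, _, rep = bg.energy_filter(cands, model, cutoff=np.inf, steps=0)
        assert out.n_frames == 20
        out, _, rep = bg.energy_filter(cands, model, cutoff=-np.inf, steps=0)
        assert out.n_frames == 0
        assert all(r == "energy" for r in rep.reasons.values())

    def test_overlapping_clash_eliminated_without_minimization(self, two_state):
        top, frame, _, traj, _ = two_state
        model = bg.StandinEnergyModel(top, frame)
        clashed = np.array(frame)
        heavy = top.heavy_atoms()
        clashed[heavy[3]] = clashed[heavy[12]] + np.array([0.1, 0, 0])
        cands = bg.Trajectory(np.stack([frame, clashed]), top)
        cutoff = model.evaluate(frame)[0] + 100.0
        out, energies, rep = bg.energy_filter(cands, model, cutoff, steps=0)
        assert out.n_frames == 1
        assert rep.reasons == {1: "energy"}


class TestGreedyDedup:
    def test_identical_conformations_collapse_to_one(self, two_state):
        top, frame, _, _, _ = two_state
        cands = bg.Trajectory(np.tile(frame, (6, 1, 1)), top)
        out, rep = bg.greedy_dedup(cands, 1.0)
        assert out.n_frames == 1

    def test_constructed_triple_keeps_first_and_third(self, two_state):
        # pairwise RMSDs (A,B)≈0.5, (A,C)≈1.5, (B,C)≈1.4 at 1.0 Å cutoff
        top, frame, _, _, _ = two_state
        heavy = top.heavy_atoms()
        n = top.n_atoms
        rng = np.random.default_rng(5)
        d1 = rng.normal(size=(n, 3))
        d1 /= np.sqrt((d1 ** 2).sum() / n)
        d2 = rng.normal(size=(n, 3))
        d2 -= d1 * (d2 * d1).sum() / (d1 ** 2).sum()
        d2 /= np.sqrt((d2 ** 2).sum() / n)
        A = frame
        B = frame + 0.5 * d1
        C = frame + 1.5 * d2
        ab, ac, bc = (rmsd(x[heavy], y[heavy])
                      for x, y in ((A, B), (A, C), (B, C)))
        assert ab < 1.0 < min(ac, bc)  # construction sanity
        out, rep = bg.greedy_dedup(bg.Trajectory(np.stack([A, B, C]), top), 1.0)
        assert out.n_frames == 2
        assert rep.reasons == {1: "duplicate"}
        assert np.array_equal(out.coords, np.stack([A, C]))

    def test_zero_cutoff_keeps_all(self, two_state):
        _, _, _, traj, _ = two_state
        out, _ = bg.greedy_dedup(traj.subset(range(15)), 0.0)
        assert out.n_frames == 15

    def test_matches_bruteforce_sequential_oracle(self, toy):
        top, frame, _ = toy
        heavy = top.heavy_atoms()
        rng = np.random.default_rng(6)
        for trial in range(50):
            n = int(rng.integers(2, 31))
            coords = frame + rng.normal(0, rng.uniform(0.05, 0.6),
                                        (n,) + frame.shape)
            traj = bg.Trajectory(coords, top)
            out, _ = bg.greedy_dedup(traj, 1.0)
            # independent sequential oracle with per-pair RMSD
            kept = []
            for i in range(n):
                if all(rmsd(coords[i][heavy], coords[j][heavy]) > 1.0
                       for j in kept):
                    kept.append(i)
            assert np.array_equal(out.coords, coords[kept])


class TestNoveltyFilter:
    def test_exact_copy_of_reference_eliminated(self, two_state):
        top, _, _, traj, _ = two_state
        cands = traj.subset([0])
        out, rep = bg.novelty_filter(cands, traj, 0.5)
        assert out.n_frames == 0
        assert rep.reasons == {0: "not-novel"}

    def test_empty_reference_keeps_all(self, two_state):
        top, frame, _, traj, _ = two_state
        empty = bg.Trajectory(np.empty((0, top.n_atoms, 3)), top)
        out, _ = bg.novelty_filter(traj.subset(range(5)), empty, 2.0)
        assert out.n_frames == 5

    def test_perturbed_conformations_survive(self, two_state):
        top, frame, idx, traj, _ = two_state
        base = bg.cartesian_to_bat(frame, idx)
        t = np.array(base.torsions)
        t[0, idx.n_placed // 2] += np.deg2rad(150.0)  # large torsion change
        far = bg.bat_to_cartesian(
            bg.BATState(base.root_coords, base.bonds, base.angles, t), idx)
        cands = bg.Trajectory(np.concatenate([far, traj.coords[:1]]), top)
        out, rep = bg.novelty_filter(cands, traj, 0.5)
        assert 0 not in rep.reasons      # the twisted conformation is novel
        assert rep.reasons.get(1) == "not-novel"


def test_pipeline_counts_monotone(two_state):
    top, frame, _, traj, _ = two_state
    model = bg.StandinEnergyModel(top, frame)
    rng = np.random.default_rng(7)
    cands = bg.Trajectory(
        traj.coords[:40] + rng.normal(0, 0.1, (40, top.n_atoms, 3)), top)
    survivors, report = bg.run_filter_pipeline(
        cands, traj, model, min_steps=20, dedup_rmsd=0.3, novelty_rmsd=0.3,
        reference_min_steps=5)
    counts = [n_out for _, _, n_out in report.steps]
    assert counts[0] == 40
    assert all(b <= a for a, b in zip(counts, counts[1:]))
    frame_rep = report.to_frame()
    assert ((frame_rep["fraction"] >= 0) & (frame_rep["fraction"] <= 1)).all()


def test_energy_distribution_of_survivors_overlaps_reference(two_state,
                                                             fixture_features,
                                                             trained_model):
    # minimized survivor energies should populate the same range as the
    # (briefly minimized) fixture ensemble's own energy distribution
    top, frame, idx, traj, _ = two_state
    _, _, ordered = fixture_features
    ref = bg.reference_from_frame(frame, idx)
    # candidates must span the whole trajectory (both wells) for the
    # distributions to be comparable
    cands, _ = bg.generate_candidates(
        trained_model, ordered,
        bg.InterpolationConfig(points_per_pair=2, jitter=0.1, seed=2),
        ref, idx, top)
    model = bg.StandinEnergyModel(top, frame)
    cutoff = bg.percentile_cutoff(model, traj, steps=50)
    survivors, energies, _ = bg.energy_filter(cands, model, cutoff, steps=300)
    surv_e, _ = model.evaluate(survivors.coords)
    _, ref_e = model.minimize(traj.coords, steps=50)
    lo = min(surv_e.min(), ref_e.min())
    hi = max(surv_e.max(), ref_e.max())
    bins = np.linspace(lo, hi, 30)
    p, _ = np.histogram(surv_e, bins=bins, density=True)
    q, _ = np.histogram(ref_e, bins=bins, density=True)
    width = bins[1] - bins[0]
    overlap = np.minimum(p, q).sum() * width
    assert overlap >= 0.5
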