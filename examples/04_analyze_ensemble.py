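"""Characterize a conformational ensemble.

Runs dihedral PCA and a free-energy surface on the two-state fixture, and
contact / turn / salt-bridge analyses on small posed peptides, printing the
quantities an ensemble study reports.
"""

import numpy as np

import batgen as bg

# --- dihedral PCA on the two-state fixture -------------------------------
topology, frame, indexing, traj, torsion_model = bg.two_state_fixture(
    n_frames=1000, seed=7)
torsions = bg.trajectory_torsions(traj, indexing)
result = bg.dihedral_pca(torsions)
share = result.eigenvalues[0] / result.total_variance
pair = torsion_model.concerted[0]
cols = [c for t in pair for c in (2 * t, 2 * t + 1)]
loading = np.linalg.norm(result.eigenvectors[cols, 0])
print(f"dPCA: leading component carries {share:.0%} of the variance; "
      f"{loading:.3f} of its norm sits on the concerted torsion pair")

# --- free-energy surface over (Rg, RMSD) ---------------------------------
fes = bg.free_energy_surface(traj, frame, bins=20, temperature=298.0)
occupied = np.isfinite(fes.free_energy)
spread = np.nanmax(fes.free_energy) - np.nanmin(fes.free_energy)
print(f"free-energy surface: {occupied.sum()} occupied bins spanning "
      f"{spread:.2f} kcal/mol")

# --- contacts and turns on a posed peptide -------------------------------
pep_top, pep_frame = bg.make_peptide_fixture("GGGGGG")
ca = pep_top.alpha_carbons()
folded = np.array(pep_frame)
shift = folded[ca[0]] + np.array([5.0, 0, 0]) - folded[ca[5]]
folded[np.array(pep_top.residue_indices) == 5] += shift
cmap = bg.contact_map(bg.Trajectory(folded[None], pep_top))
print(f"contact map: residues 1 and 6 in contact with probability "
      f"{cmap[0, 5]:.1f} (|i-j|<4 pairs excluded)")

defs = bg.TurnDefinitions(turns={"X": ((2, 4), (1, 5))})
for d in (5.0, 7.5, 9.5):
    posed = bg.pose_contact(pep_frame, pep_top, (0, "CA"), (4, "CA"), d)
    state = bg.classify_turns(bg.Trajectory(posed[None], pep_top), defs)["X"][0]
    print(f"turn probe at {d:.1f} Å -> {state}")

# --- salt bridge on a posed Asp...Lys contact ----------------------------
dk_top, dk_frame = bg.make_peptide_fixture("DGGK")
posed = bg.pose_contact(dk_frame, dk_top, (0, "OD1"), (3, "NZ"), 3.5)
bridges = bg.detect_salt_bridges(bg.Trajectory(posed[None], dk_top))
print(f"salt bridges detected: {bridges} "
      "(residue pair, fraction of frames with the contact)")
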