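# Methods

## Internal-coordinate representation

A conformation of an `N`-atom bonded molecule is parametrized by a
construction order: three sequentially bonded *root* atoms carry the six
external degrees of freedom, and each remaining atom `i` is placed from a
bond length `b_i` (Å), bond angle `α_i` and torsion `θ_i` relative to a
reference triple (j, k, l) of already-placed atoms. The placement order is
deterministic: the default root is the lowest-index terminal heavy atom,
its neighbour and that neighbour's next heavy neighbour; remaining atoms
are added lowest-index-first among atoms adjacent to the placed set, each
anchoring to its lowest-index placed neighbour and inheriting (k, l) from
that anchor's own reference chain. Atoms anchored directly at the *middle*
root atom cannot have three references bonded in sequence; they use the
improper quadruple (i, r1, r0, r2), which the placement formulas handle
identically (the torsion is measured against a non-bonded fourth atom).
Reconstruction is the standard NeRF-style placement and is exact: Cartesian
→ BAT → Cartesian round trips reproduce coordinates to machine precision.

The vBAT featurization replaces each (b, α, θ) triple with four 3-vectors —
the unit normals of the two torsion planes and the two inner bond vectors —
flattened to `12·(N−3)` numbers. Two choices deserve note:

* **Unit normals.** The plane normals are normalized to unit length, and
  the decoder re-normalizes them before use, so decoding tolerates the
  small norm violations a neural network's output exhibits. Bond-vector
  blocks contribute only the angle cosine and the torsion sign, which makes
  decoding robust to their scale as well.
* **Molecule-fixed frame.** All four vectors are expressed in the
  orthonormal frame spanned by the root triple (first root bond,
  orthogonalized second root bond, their cross product). This makes the
  features strictly *invariant* under rigid rotation and translation — not
  merely equivariant — which is the property the latent space should see.
  Decoding recovers angles and torsions from dot and cross products, which
  are unaffected by the change of basis.

During generation, bond lengths and the external block are taken verbatim
from a user-chosen reference conformation (default: the first training
frame); bond-length fluctuations are small enough in thermal ensembles that
fixing them loses almost nothing, and it removes a third of the decoder's
error surface.

## Autoencoder

The encoder maps `n_f` features through widths
`[n_f, n_f/4, n_f/8, n_f/16, n_f/32, n_f/64, n_f/64, latent]` with floor
division and `latent = 3` by default; the decoder mirrors the schedule.
All linear layers omit biases. LeakyReLU (negative slope 0.01, exposed in
`ModelConfig`) follows every layer except the final layer of each half.
Elementwise layer normalization (gain + shift, `2·(n_f/4)` parameters)
follows the first hidden layer's activation; dropout at rate 0.1 follows
the second hidden layer's activation, in the encoder only. Weights are
Xavier-uniform initialized. The total trainable-parameter count is exactly
`2·Σ_t w_t·w_{t+1} + 2·(n_f/4)`; for the two study-scale feature widths
2,376 and 7,488 this gives 3,294,964 and 32,721,156.

Training minimizes the mean Smooth L1 loss (transition point β = 1.0)
with Adam (β₁ = 0.9, β₂ = 0.999) on mini-batches drawn uniformly without
replacement per iteration (default 200 conformations). The default
learning-rate schedule halves 0.002 to 0.001 after 5,000 iterations; the
desk-scale examples use 0.01 → 0.005 after 300 of 500 iterations, which
reaches the fixture's loss floor in seconds. Features are standardized
per-column with training-set statistics stored on the model and inverted on
decode; this balances unit-normal components against ~1.5 Å bond vectors.
Validation loss is recorded every 50 iterations; there is no early
stopping. All randomness (initialization, batching, dropout) flows from
integer seeds, so loss histories are bitwise reproducible on a device.

The network is implemented directly in numpy with explicit
backpropagation. At these widths an optimized tensor framework buys
nothing, and the implementation keeps the package's dependency footprint to
the scientific-Python base stack.

## Candidate generation

The ordered ensemble (training + validation frames in original temporal
order) is encoded; for each consecutive latent pair a spherical arc is
built: the arc center is the midpoint displaced by `jitter` × (pair
separation) along a random direction (default jitter 0.1), the endpoints
are expressed in spherical coordinates (R, Θ, Φ) about the center with the
global z-axis as polar axis, and `k` interior points (default 10) are taken
at equal parameter steps with Φ along the shorter arc. Endpoints are
excluded — they decode to reconstructions of existing frames — so `m`
frames yield exactly `(m−1)·k` candidates. Degenerate pairs (coincident
points, zero jitter) return copies rather than failing.

## Filtering

1. **Energy.** Each candidate is minimized briefly (default 1,000 steps)
   and discarded if its energy exceeds a cutoff. The energy model is a
   contract (`evaluate` + `minimize`); the bundled `StandinEnergyModel` is
   a simplified molecular-mechanics surface — harmonic bonds and angles
   restrained to a reference geometry (k_b = 300 kcal/mol/Å²,
   k_a = 50 kcal/mol/rad²), 12-6 Lennard-Jones between atoms three or more
   bonds apart with element-wise radii, and Coulomb between formally
   charged atoms under a distance-dependent dielectric ε(r) = 4r. Its
   absolute scale is not that of a physics force field, so the default
   cutoff is the 99th percentile of the reference ensemble's own minimized
   energies (the reference is minimized 50 steps for comparability);
   absolute cutoffs in kcal/mol only make sense when a real implicit-solvent
   engine is plugged into the contract. Minimization is a batched
   backtracking steepest descent whose energy never increases; minimized
   coordinates are carried forward.
2. **Deduplication.** A sequential scan keeps a candidate iff its minimal
   heavy-atom RMSD after optimal (Kabsch) superposition to every previously
   kept candidate exceeds a cutoff — deterministic in input order. The
   conventional cutoff is 1 Å at peptide scale; the 25-atom fixture uses
   0.2 Å, scaled to its size.
3. **Novelty.** Candidates within an RMSD cutoff of *any* reference frame
   are discarded. Conventional cutoffs are 1–1.2 Å at peptide scale (2 Å
   for a stricter reading); the fixture pipeline uses 0.5 Å.

Survivor counts are monotonically non-increasing and are reported with
per-candidate elimination reasons.

## Ensemble analysis

* **Dihedral PCA** maps each torsion to (cos θ, sin θ) before the
  covariance eigendecomposition, so correlations across the ±180° seam are
  computed on the 2° short arc rather than a spurious 358° jump. The
  default torsion set is every placement torsion (backbone and sidechain);
  any subset may be selected.
* **Free-energy surfaces** histogram (mass-weighted heavy-atom Rg, backbone
  N/Cα/C/O RMSD to a chosen reference) and convert normalized populations
  by `F = −k_B·T·ln P` (k_B in kcal/(mol·K), T = 298 K default). Empty
  bins are masked; only differences are meaningful.
* **Contact maps** use Cα–Cα distances under 6.5 Å, zeroing pairs with
  |i−j| < 4.
* **Turn classification** labels a probe Cα pair formed below 6.5 Å,
  not-formed above 9.0 Å, ambiguous between. Defaults carry the four turn
  regions and probe pairs of the 42-residue amyloid-β monomer; any
  definition set may be supplied.
* **Salt bridges** score opposite-charge sidechain N–O contacts
  (Lys NZ / Arg NE,NH1,NH2 against Asp/Glu carboxylate O and C-terminal
  OXT) under 4.0 Å (configurable; no experimental consensus value).

## Synthetic data

The fixture generators emulate the statistical structure of MD input. The
toy molecule is a carbon chain (bonds 1.5 Å, angles 109.5°, extended
backbone) with optional single-atom branches; the peptide builder assembles
ideal chemical-component templates with standard atom names and 1.33 Å
peptide bonds, twisting residues to avoid clashes; `pose_contact` moves one
atom to a prescribed distance for posed fixtures (distorting its bond — a
posed fixture documents detector behaviour, not geometry realism). The
trajectory simulator holds bonds/angles at a base conformation and evolves
each torsion around metastable wells with Markov switching; *concerted*
groups share one Markov state and switch jointly. The canonical end-to-end
dataset (`two_state_fixture`) is a 25-atom chain whose middle torsion pair
hops concertedly between wells at ±60° (5° in-well noise, 3° jitter
elsewhere, switch probability 0.01 per frame), sized at 400 frames for
pipeline runs and 1,000 for analysis demonstrations.

What the fixtures do *not* emulate: force-field energetics, solvent
effects, gradual transition paths (well switches are instantaneous), or
the conformational statistics of any real peptide. Passing tests therefore
demonstrate the correctness of transforms, counts, filters and statistics
and the ability of the trained model to organize and interpolate a
two-state ensemble — not quantitative fidelity on real MD data.

## Numerical choices and limitations

* Angle tolerance: collinear reference triples (α near 0 or π) raise
  errors naming the offending atom rather than producing garbage.
* RMSD uses double-precision SVD with the proper-rotation determinant
  correction; rmsd(x, Rx+t) is zero to machine precision.
* The greedy deduplication is order-dependent by design (first-seen wins),
  matching a sequential scan oracle exactly.
* Problem sizes in the test-suite pipeline (400-frame trajectories, 3,990
  candidates, 300 minimization steps) were chosen so a complete run
  finishes in minutes on one CPU while every pipeline stage operates at
  non-trivial scale.
* Single polymer chain plus small molecules only; no multi-fragment BAT
  for large (>200-residue) proteins, no disulfide detection, no gradients
  of the coordinate transform.
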