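# Methods

`kirgate` implements an in-silico gating analysis for tetrameric
inward-rectifier (Kir-type) potassium channels: low-frequency normal
modes of an elastic network drive conformational exploration (MDeNM —
molecular dynamics with excited normal modes), the resulting structures
are clustered and relaxed, and each frame is classified into open,
closed and partially open gating states from purely geometric criteria.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## The gating model

The pore runs along z through a four-chain (A–D) channel.  Three
constriction residues (defaults 124, 129, 132) gate the conduction
pathway.  For each gate, the *shortest* inter-atomic distance is
computed between the residue on diametrically opposed chains (A–C and
B–D), all atoms included; hydrogens participate whenever they are
present, and every report records whether they were
(`hydrogens: present/absent` metadata).

A gate is **open** when the shortest diametric distance strictly exceeds
the unhydrated K⁺ ionic diameter, 3.5275 Å.  By default *both* diametric
pairs must clear the threshold (an ion cannot pass a gate closed on
either diagonal); the permissive `either` rule is available and logged.
Frames map onto five states in decision order: both main gates (124,
132) open → fully open if 129 is also open, else *129-closed*; exactly
one main gate open → the corresponding partially open state; both
closed → fully closed.  The 129 status is additionally reported in its
own column so no information is lost when the main gates dominate.
Population tables are frame-wise percentages and must sum to 100 ± 0.1.

## Elastic-network modes and gating-mode selection

Normal modes come from an anisotropic elastic network: uniform springs
(k = 1 arbitrary unit) join all atom pairs within a 12 Å cutoff, and the
3N×3N Hessian is diagonalised directly — dense `eigh` for small systems,
shift-invert Lanczos for large ones.  A connected network has exactly
six near-zero modes (tolerance: eigenvalue < 1e-8 × largest computed
eigenvalue); disconnected networks trigger a warning with the component
count.  Optional mass weighting (M^-1/2 H M^-1/2) is supported; mode
vectors are converted back to Cartesian displacement patterns for all
downstream use.

Gating modes are selected by the displacement protocol: the structure is
displaced ±2 Å RMSD along each candidate mode, and the mode's *channel
score* is the largest change of the diametric distance at the probe
residue (125).  The ten best-scoring modes are kept, classified by the
sign pattern of the two diametric distance changes at +2 Å: same sign
with amplitude ratio ≥ 0.5 → *spherical* opening; same sign with smaller
ratio, or opposite signs with both amplitudes above a 0.05 Å noise
floor → *elliptical*; anything else is excluded.  Redundant modes
(channel-region sub-vector cosine > 0.9) are dropped keeping the lower
frequency, and the four lowest-frequency survivors are returned (fewer,
with a warning, when the spectrum does not contain four distinct gating
motions).  The shape-ratio, noise-floor and redundancy thresholds are
configurable; no quantitative convention exists for "spherical",
"elliptical" or "redundant", so these are this package's operational
definitions and are recorded in the selection table of every run.

## MDeNM engine

Excitation directions are unit linear combinations of the selected
modes.  Coefficients are drawn uniformly on the unit hypersphere and
accepted only if the structures displaced 1 Å along them keep a minimum
pairwise RMSD of 0.8 × the expected nearest-neighbour spacing of
uniform points (estimated once by Monte Carlo with a fixed internal
seed) — a rejection rule that spreads replicas quasi-uniformly over the
mode space.  One mode admits exactly two directions, ±v.

Each replica runs Langevin dynamics (BAOAB splitting, 2 fs timestep,
1 ps⁻¹ friction, 300 K bath) on a pluggable potential.  At t = 0 and
after every relaxation interval (1 ps), velocities Δv = α·d are added
along the replica's direction, with α chosen so the injected kinetic
energy is exactly (3/2)·N·k_B·ΔT (ΔT = 4 K per excitation, 10
excitations — the standard schedule).  The direction is used
mass-unweighted by default; a mass-weighted option exists and is
logged.  Degrees of freedom are counted as 3N (no constraints on the
toy systems).  Units: Å, ps, amu, kcal/mol, with k_B =
0.0019872041 kcal/(mol·K).

The default potential is a harmonic elastic network anchored at the
input structure.  For open/close studies a double-well variant adds,
for each designated gate atom, a radial quartic
U(ρ) = h·((ρ−c)² − w²)²/w⁴ with minima at the open and closed gate
radii; network springs touching gate atoms are scaled down (×0.02) so
the well, not the network, governs the gate coordinate.

**Exploration fixture.** The bistable fixture used to demonstrate the
method's point — that mode-directed energy crosses barriers unbiased
thermal motion does not — is a ~116-atom channel fragment (residues
115–140) with a 5 kcal/mol barrier per gate atom (≈ 8 k_BT at 300 K;
the Kramers rate makes a spontaneous crossing over 10 ps negligible).
Because the energy injected along the mode, (3/2)·N·k_B·ΔT, scales with
system size, the fixture's ΔT is set to 30 K so that the toy system's
mode energy stands in the same proportion to its barrier as a 4 K rise
does for a full channel with 10⁵ atoms; the protocol default remains
4 K.  Open/closed "ranges" are derived from the construction geometry
(thresholds at 20–25 % of the open–closed distance gap from either
well).

## Clustering and relaxation

Excited structures are clustered by greedy leader clustering on the
channel-region (121–133) RMSD with a 0.9 Å threshold, after superposing
every frame onto the first frame on CA atoms (an un-superposed,
pore-axis-frame mode is available; the choice is logged).  The first
frame seeds cluster 1; each frame joins the nearest leader within the
threshold or seeds a new cluster, so unique structures become singleton
clusters and leaders are pairwise separated by more than the threshold.
Each cluster's representative is the member closest to the cluster's
mean channel coordinates, ties going to the earliest frame.  Note that
closest-to-mean representatives inherit the leaders' spacing guarantee
only when the underlying conformations are separated beyond the
threshold — which is the regime the procedure is designed for; the
clustering tests therefore use generator settings that separate the
states by ≥ 1.45 Å.

Representatives are relaxed by unexcited Langevin dynamics on a
potential anchored at each representative; the first ⌈0.25·n⌉ frames of
each trajectory are discarded and the rest retained with per-frame
provenance (replica, cluster, kinetic temperature).  On a harmonic
fixture the kept frames' mean kinetic temperature matches the bath to
within a few per cent (the discarded head contains the
basin-equilibration transient).

## Geometry operators

* **TM1 kink** — angle between the axes of the outer helix's two
  sub-segments (46–56 and 56–80), each axis the principal component of
  the segment's CA coordinates oriented N→C (an endpoint-vector mode is
  the logged alternative).  Exact for straight segments; invariant
  under rigid motions.
* **CTD rotation** — pseudo-dihedral of CA(108), its projection on the
  pore axis, the projection of CA(266), and CA(266), in (−180°, 180°],
  positive by the right-hand rule about +z.  Equivariant: rotating the
  cytoplasmic domain by θ shifts it by exactly θ.
* **Per-residue RMSD** — RMSD_i = √(1/N Σ_n |r_i(n) − r_i^ref|²) per
  atom, averaged over each residue's atoms; no superposition unless
  requested (flag recorded).  The reference (input model or ensemble
  mean) is an explicit choice.
* **Pore-radius profile** — per z-slab (1 Å default), min over atoms of
  (distance to axis − atom radius), floored at 0, NaN for empty slabs.
  A geometric stand-in for sphere-probe profiling: adequate for
  locating constrictions, not a replacement for Monte Carlo probe
  maximisation.

## Synthetic data

The generator produces what the operators measure, not chemistry: CA
pseudo-atom traces for residues 35–295 in C4 symmetry, a contractually
straight two-segment TM1 with a prescribed kink, side-chain pseudo-atoms
(`SC`) at the constriction residues placed at radius
(gate_radius − pseudo-atom radius) so gate distances are analytically
known, and a cytoplasmic-domain lattice block rotated by a prescribed
angle.  All other segments carry a helical winding — a straight
pseudo-atom chain is a floppy central-force network, and the winding is
what gives the elastic network its clean 6-zero-mode spectrum.  Default
radii (open 4.0 Å, closed 1.2 Å, pseudo-atom 0.5 Å) put the open and
closed gate distances (7.0 and 1.4 Å) on either side of the ionic
diameter with margins far exceeding 3× the default coordinate noise
(0.15 Å per atom), which is what makes ≥ 99 % classification accuracy a
construction guarantee rather than a tuning outcome.  Ensembles draw
states i.i.d. from declared probabilities — the two built-in scenarios
mirror an engineered-open channel (52.8 % fully open / 47.2 %
middle-gate closed) and a wild-type-like channel (6.8 / 50.2 / 28.8 /
14.2 / 0 %) — and are bitwise reproducible from the seed.

What passing tests show: the operators implement their definitions
exactly, the protocol's bookkeeping is exact, and planted ground truth
is recovered at the expected statistical accuracy.  What they do not
show: behaviour on real all-atom ensembles — side-chain rotamers,
correlated inter-frame dynamics, crystallographic asymmetry and
membrane effects are all outside the generator's scope, and the
population scenarios are frame-wise mixtures with no kinetics.

## Problem sizes

Tests and the acceptance script run on one CPU at deliberately small
scale: classifier checks at 1 000 frames, population recovery at
10 000, the full tetramer (1 056 pseudo-atoms) for mode analysis, the
116-atom fragment with 20 paired seeds for exploration, 150 frames for
clustering, and a 40 ps harmonic run for relaxation bookkeeping.

## Known limitations

* The elastic network uses uniform springs and a single cutoff; it
  reproduces low-frequency collective structure, not force-field
  energetics, and no interaction energies (kcal/mol between residue
  pairs) are computed anywhere.
* Greedy leader clustering depends on frame order (the spacing and
  representative guarantees do not).
* The pore profile ignores probe curvature along z.
* PDB output rounds coordinates to 3 decimals; round-trip tests use
  that precision.
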