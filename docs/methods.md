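# Methods

`rinmd` turns a protein structure — a single PDB model or a PSF/DCD molecular
dynamics trajectory — into residue interaction networks (RINs): multigraphs
whose nodes are amino-acid residues and whose typed edges are non-covalent
interactions detected from explicit geometric or energetic criteria. Over a
trajectory the per-frame graphs are summarised as a consensus network with
per-edge persistence, and the formation/rupture dynamics of each interaction
type is quantified with Pearson correlation matrices over per-residue
interaction counts.

## Interaction model

Nine interaction classes are detected independently in every frame. All
distances are in angstrom, angles in degrees, energies in kcal/mol; every
`<=` threshold is inclusive. Defaults (all configurable via
`InteractionCriteria`):

| class | criterion | defaults |
|---|---|---|
| C-alpha contact | d(CA_i, CA_j) <= d, in-chain \|i-j\| > 2 | d = 8 |
| hydrogen bond | d(D, A) <= d and angle(D-H...A) >= a | d = 3, a = 120 |
| salt bridge | min distance basic N (Arg NE/NH1/NH2, Lys NZ, His+ ND1/NE2) to acidic O (Asp OD1/OD2, Glu OE1/OE2) <= d | d = 6 |
| disulfide | d(SG, SG) <= d and \|chi(CB-S-S-CB)\| in [a, b] | d = 3, [60, 90] |
| pi-pi | aromatic ring centroid distance <= d | d = 6 |
| cation-pi | ring centroid to cation <= d, angle(normal, centroid->cation) in [0, 60] or [120, 180] | d = 7 |
| Arg-Arg | guanidinium centroid (CZ, NH1, NH2, NE) distance <= d | d = 5 |
| Coulomb | \|E\| >= t, E = 332.0636 sum q_a q_b / (eps_r r), pairs within 12 A | t = 1, eps_r = 1 |
| van der Waals | E <= t, 12-6 Lennard-Jones with CHARMM combining rules, pairs within 12 A | t = -0.1 |

Notes on the less obvious choices:

- **Hydrogen-bond chemistry.** Donors are N/O/S heavy atoms carrying at least
  one hydrogen (pairing from the PSF bond table, or by nearest-heavy-atom
  assignment within 1.3 A for PDB input); acceptors are all oxygens,
  nitrogens with no bound hydrogen, and the Met/Cys sulfurs. The distance is
  measured donor-to-acceptor and the angle at the hydrogen. Hydrogens are
  never built: PDB input lacking them simply yields no hydrogen bonds, with a
  warning. One record is emitted per (donor, H, acceptor) triple, so a
  bifurcated donor can contribute several bonds to one residue pair.
- **Histidine protonation** is inferred from the residue name when it encodes
  the state (HSP/HIP cationic, HSD/HSE/HID/HIE neutral) and otherwise from
  the hydrogen inventory: both HD1 and HE2 present means cationic. A cationic
  His contributes its ring-nitrogen midpoint as a cation and is excluded from
  the pi-system list; a neutral His ring is a pi system. Tryptophan is
  treated as a single fused 9-atom pi system with one centroid and normal.
- **Ring normals** come from a total-least-squares plane fit (smallest
  singular vector of the centered ring coordinates). Their sign is arbitrary,
  so every angle that involves a normal is evaluated sign-symmetrically (the
  cation-pi bands [0, 60] and [120, 180] are mirror images; the pi-pi
  inter-normal angle is folded to [0, 90] and reported as a descriptor only).
- **Energies.** The Coulomb edge criterion applies an atom-pair cutoff
  (default 12 A, shared with the vdW sum), a relative dielectric of 1 and no
  1-4 scaling; covalently adjacent residue pairs are excluded from both
  energy detectors because their interaction is dominated by through-bond
  terms the model does not describe. Adjacency comes from the PSF bond table
  when available, else from a sequence-numbering proxy (same chain,
  |resseq difference| = 1). The vdW edge threshold of -0.1 kcal/mol selects
  attractive contacts; the energy is stored on the edge so users can
  re-filter.
- **Sequence exclusion for C-alpha contacts** uses author residue numbering
  (|i-j| <= 2 within a chain), the usual contact-map convention; inter-chain
  pairs are never excluded.
- **No periodic boundary handling.** Distances are plain Euclidean on the
  stored coordinates; trajectories should be wrapped/centered beforehand.

## Consensus networks

Each frame yields a multigraph with one edge per (residue pair, type); the
within-frame multiplicity (e.g. two hydrogen bonds between one pair) is kept
as a `count` attribute but collapses to simple presence for persistence,
which is defined over frames, not interactions. The consensus network keeps
an edge iff it is present in at least `persistence_min` of the frames
(default 0.75) and stores the exact fraction, the frame count and
mean/min/max of each geometric descriptor over the frames where the edge
exists. Static input is the one-frame special case: with any cutoff <= 1 the
consensus equals the frame graph.

Edges are classified as intra-chain, inter-chain (same assembly) or
inter-assembly when a chain-to-assembly map is supplied — the natural
bookkeeping for oligomeric channels where "assembly" may mean one hemichannel
of a docked pair.

Centralities (degree, weighted degree, betweenness, closeness, eigenvector)
are computed on a simple-graph projection in which parallel typed edges
collapse and the weight is the number of distinct interaction types between a
pair, because shortest-path centralities are not well defined on multigraphs.
Betweenness and degree are normalized in the standard way; closeness uses the
within-component (Wasserman-Faust) convention; eigenvector centrality is the
leading eigenvector of the projection's adjacency matrix (meaningful per
connected component).

Node attributes: per-residue solvent-accessible surface area is computed
internally with the Shrake-Rupley algorithm (92 sphere points, 1.4 A probe,
via biotite); if a DSSP executable is configured its secondary-structure
assignment and accessibility are used instead. Neither is a hard dependency
of the network itself.

## Correlation analysis

For one interaction type, residue `i` is represented by the vector of the
number of such interactions it participates in per frame (undirected: a
hydrogen bond increments donor and acceptor alike). The Pearson correlation
between two residues' vectors measures coordinated formation/rupture of
interactions. Zero-variance vectors have no defined correlation: those
entries are NaN (written as "NA"), never silently zero, and are excluded from
correlated-pair counts — otherwise rate tables between time windows would be
corrupted. Windows are closed frame-index intervals supplied by the user
(typically chosen by inspecting a collective variable); the full-trajectory
matrix is the single spanning window. `correlated_pair_counts` counts
unordered off-diagonal pairs with |r| above each cutoff, and
`pair_count_rates` normalizes window counts by the first window, reporting
the rate as undefined (None) when the reference count is zero rather than
infinity.

The collective variable D0 is the mean, over user-defined atom groups (e.g.
beta strands), of the Euclidean distance between the group's mass-weighted
center and the center of mass of a reference selection (default: all atoms).
It tracks breathing/closure motions; a single group spanning the whole
selection gives exactly zero.

## Synthetic data generator

The `fixtures` module builds systems from idealized residue fragments
(standard bond lengths/angles, assembled by explicit rotations and
translations; no energy minimization or MD engine) so that exactly the
requested interaction holds at exactly the requested descriptor values:

- `make_dipeptide_pair` poses two residues realizing one interaction;
  negative plants (criterion violated) are allowed and must stay >= 0.2 A or
  >= 5 degrees away from the threshold so detection outcomes are unambiguous.
- `make_trajectory` toggles each pair between its formed pose and a broken
  pose (shifted along the separation axis to at least 2 A beyond threshold)
  according to a boolean presence schedule, adds optional Gaussian coordinate
  noise (rejected unless 6 sigma fits inside every planted margin), and lays
  pairs out 60 A apart so they cannot cross-interact. Schedules with known
  pairwise Bernoulli correlation rho use a shared-driver mixture (copy the
  driver with probability rho, redraw otherwise), which has corr = rho in
  expectation; a three-window variant plants coupling that decays from full
  to none, emulating an initially concerted conformational change.
- `make_assembly` builds multi-chain systems with hydrogen bonds planted
  within chains, between chains of one assembly, and across assemblies.
- `make_random_system` scatters fragment types (donors, acceptors, charged
  groups, rings, cysteines) at random poses in a box; it exists to cross-check
  every detector against exhaustive enumeration.

Generated systems can be written as PDB + PSF + DCD + CHARMM-format parameter
files, exercising the same readers used for real data; a fixed seed gives
byte-identical files. What the generator does **not** emulate: realistic
backbone connectivity and sterics, solvent, correlated thermal motion, or
force-field-consistent geometry. Passing tests therefore demonstrate the
correctness of the detection/aggregation/correlation machinery under
controlled geometry, not the biophysical realism of any particular
trajectory.

## Input handling and numerical choices

- PDB, PSF (standard and EXT widths) and DCD (either endianness) parsing is
  delegated to MDAnalysis; PSF charges are re-read from the text at float64
  so the total system charge equals the file's column sum exactly. DCD
  fixed-atom blocks are rejected explicitly. Alternate locations keep the
  highest-occupancy conformer (ties: first altloc identifier).
- Heteroatom stripping keeps the 20 standard residues plus protonation/
  bonding variants (HSD/HSE/HSP, HID/HIE/HIP, CYX); it is idempotent and
  re-derives all indexing.
- For static PDB input, atom types and partial charges come from a bundled
  residue template table in the CHARMM convention, with a small bundled
  NONBONDED parameter table for the Lennard-Jones terms; atoms a user's own
  CHARMM parameter file does not cover produce an error naming every missing
  type. The bundled tables are a convenience for self-contained analysis —
  for production work pass the parameter file of the force field the system
  was actually built with. Epsilon is stored as a magnitude (CHARMM prints it
  negative).
- Angle computations clamp the normalized dot product to [-1, 1]; degenerate
  geometry (zero vectors, collinear torsion frames, collinear ring points)
  raises an explicit error rather than returning NaN.
- Per-frame detection is pure; the frame-parallel executor partitions frames
  across worker processes and reduces in frame order, so outputs are
  byte-identical for any worker count. Descriptor names are emitted in sorted
  order everywhere for the same reason.

## Problem sizes used in the checks

The oracle-equivalence checks run on 30-50 residue random boxes; consensus
and correlation checks use planted trajectories of 12-500 frames; the
end-to-end determinism check uses a 100-residue, 200-frame planted
trajectory; `scripts/acceptance.py` uses a 100-residue, 120-frame pipeline
run plus 500-frame correlation fixtures. These sizes make every ground truth
exactly enumerable while keeping the full suite fast.

## Known limitations

- The Coulomb edge definition (cutoff, dielectric, adjacency exclusion,
  1 kcal/mol threshold) is an explicit documented model; charged-group-based
  variants from other tools will not match it edge-for-edge.
- No solvent, ion, ligand or metal nodes; no halogen bonds; no
  solvent-mediated interactions.
- No hydrogen or missing-atom reconstruction; no mmCIF/GRO/XTC/TRR readers.
- Correlations are raw Pearson values with no significance testing or
  multiple-testing correction.
- Eigenvector centrality on a disconnected network concentrates on the
  dominant component; nodes elsewhere get values near zero.
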