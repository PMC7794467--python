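# Methods

## Scope and model overview

`cypet` covers the stages of a de novo protocol for building
electron-transfer (ET) competent complexes of a membrane cytochrome P450
(CYP) and NADPH–cytochrome P450 oxidoreductase (CPR): diffusional encounter
generation by rigid-body Brownian dynamics (BD), funnel selection of
candidate complexes, membrane-aware geometric characterization, and
tunneling-pathway/rate analysis.  It analyzes externally produced structural
ensembles (multi-model PDB); it does not run molecular dynamics, model
missing residues, or estimate binding free energies.

## Structures

Structures are column-oriented atom tables read through gemmi (PDB and
mmCIF).  Alternate locations are collapsed to the highest-occupancy
conformer, ties resolved toward altloc `A`, so parsing is deterministic.
Author residue numbering is kept untouched because every named selection
(helix ranges, domain boundaries) is quoted in author numbering.  Hydrogens
are kept when present; centers of mass are mass-weighted over all atoms of a
selection by default (an unweighted-centroid mode exists), so results on
crystal structures (no H) and MD frames (with H) state the atom set used.
Canonical output is fixed-column PDB, multi-model for ensembles.

The C-helix of CYP 1A1 has no canonical numeric residue range; it must be
supplied in the configuration (`domain_map.c_helix`) and is never guessed.

## Brownian-dynamics encounter docking

Two rigid bodies: the CYP is fixed at the origin, CPR diffuses.  The update
rule is the Ermak–McCammon propagation

    Δr = (D_t/k_BT)·F·Δt + √(2 D_t Δt)·G,

with the rotational analogue (rotation vector about the body center) using
D_r and the torque.  Diffusion coefficients come from Stokes–Einstein with a
hydrodynamic radius of (radius of gyration + 2 Å); any fixed choice only
rescales time, not encounter geometry.  Moves that create inter-body overlap
(any atom pair closer than the sum of exclusion radii) are rejected and the
random displacement resampled.

Interaction forces are a direct screened-Coulomb (Debye–Hückel) pair sum
over formally charged atoms,

    U = Σ_ij 332.06 q_i q_j exp(−κ r_ij) / (ε_s r_ij)   [kcal/mol, Å, e],

with a 100 Å pair cutoff, solvent dielectric 78, temperature 298 K and ionic
strength 0.15 M (κ⁻¹ ≈ 7.8 Å) by default.  Formal charges: Asp/Glu −1
(split over the carboxylate oxygens), Lys/Arg +1, His 0, free termini ±1,
heme propionates −1 each, flavin phosphates −1 per phosphate.  Electrostatic
and nonpolar desolvation corrections are intentionally absent: no published
parameterization is reproducible from the protocol this package follows, so
the electrostatic term is a stated stand-in validated by physical property
checks (closed-form energies, Einstein relation, Boltzmann sampling in a
test potential, steering enrichment on a constructed dipolar pair) rather
than by matching any published encounter table.

Trajectories start with the mobile body at a uniformly random orientation
and position on a sphere of radius b = 450 Å and terminate at a
center-to-center separation of q = 600 Å (defaults; the toy demo uses
b = 50 Å / q = 80 Å scaled to the bead bodies).  The timestep schedule is
20 ps beyond 100 Å separation and 1 ps inside (10 ps / 45 Å for the toy).
An encounter pose is recorded when, strictly, D(Fe–N5) < 20 Å **and**
D(CYP, FMN-domain COM) < 60 Å; within a trajectory, poses within 1.0 Å RMSD
(charged + marker atoms) of an already-recorded pose are suppressed.  All
randomness flows from one seed through per-trajectory spawned substreams, so
an encounter set is bit-reproducible and a run with more trajectories is a
superset of a run with fewer.

## Selection funnel

Records are ranked by interaction energy (ties broken by trajectory and step
ids) and the top n (default 5000) are clustered by average-linkage
agglomerative clustering cut at k (default 10) clusters, ranked by size.
The metric is the RMSD of the mobile body's interface atoms between poses
with the fixed body superposed by construction.  Each cluster is represented
by its medoid (minimum mean intra-cluster distance; ties to the earlier
record).  Representatives then pass three screens in order — interaction
energy (threshold exposed in config, no default pretense of fidelity),
membrane compatibility, pairwise distinctness (interface RMSD ≥ threshold) —
and each discarded candidate carries exactly the first reason that failed.
Survivors are named `<chain><cluster rank>` (e.g. `C3`).

The membrane filter assumes the fixed CYP is positioned in the bilayer as
observed in membrane simulations and fails a pose if (a) any mobile heavy
atom lies inside the bilayer slab, or (b) the FMN-domain N-terminal anchor
atom sits higher above the membrane surface than an extended tether could
reach, operationalized as 15 residues × 3.5 Å ≈ 52.5 Å.

## Descriptors

All angles are in degrees, distances in Å; every membrane quantity is
defined in a membrane frame (unit normal = z axis, midplane point, half
thickness) which can be inferred from lipid phosphorus atoms (two leaflets
split along the best bimodal principal axis; ≥ 10 P atoms required) or
supplied in config.  Helix axes are principal-component fits of Cα
coordinates with the sign fixed N→C; θ (C-helix vs FMN-domain α1-helix) is
reported unfolded on [0°, 180°] because meaningful values exceed 90°.
The heme plane is fitted to the porphyrin macrocycle atoms (substituents and
Fe excluded); heme-tilt = 90° − ∠(plane normal, z) folded to [0°, 90°].
Orientation angles α, β, γ are the angles between z and v1 (I-helix axis),
v2 (C→F inter-helix centroid vector orthogonalized to v1) and v3 (TM-helix
axis).

Interface area is buried solvent-accessible surface area
SASA(A) + SASA(B) − SASA(A∪B) by Shrake–Rupley (biotite backend,
element-based Bondi radii, probe 1.4 Å, 500 sphere points by default).  The
default convention is the total buried area, not halved — the halved value
is available as `buried_half`.  Residue contacts use a 5 Å minimum
heavy-atom distance; hydrogen bonds use donor–acceptor < 3.5 Å plus a
D–H…A angle > 120° whenever an explicit hydrogen is present.  CPR
conformational state is classified from the FMN–FAD isoalloxazine-ring
centroid distance with boundaries at 25 and 55 Å, chosen to separate the
crystallographic anchor values (closed ≈ 14 Å, semi-open ≈ 45 Å, open
≈ 61 Å) with wide margins; the boundaries are configurable because only the
anchors, not the class edges, are established.

## Tunneling pathways and rates

The pathway graph contains all heavy atoms.  Covalent bonds are detected
geometrically (< 1.9 Å between light heavy atoms, < 2.8 Å for metal
coordination, so thiolate–Fe ligation counts as covalent); donor/acceptor
heteroatom pairs under 3.5 Å become hydrogen-bond edges; remaining pairs
under 6 Å become through-space jumps.  Decay factors follow the
pathways model: ε_C = 0.6, ε_H = ε_C²·e^(−1.7(R−2.8)), ε_S =
0.5 ε_C·e^(−1.7(R−1.4)), capped at 1.  Hydrogens are collapsed onto their
heavy-atom hosts for determinism.  The best path maximizes Πε, computed
exactly as a shortest path under weight −ln ε; ties are broken toward the
lexicographically smallest atom-index sequence reconstructed from the
forward/backward distance maps.  Disconnection is a regular no-path result
(ε = 0), not an exception.

Rates use k_ET = 10¹³ · ε² s⁻¹, an activationless golden-rule calibration:
without a driving-force/reorganization treatment the absolute scale is
indicative, so only orderings and ranges of k_ET should be compared across
complexes.  The ensemble census reports the relative occurrence of
residue-level routes (e.g. `FMN-K456-C457-HEME`) over frames, with a
separate no-path bin, per ensemble; pooled statistics can be formed by the
caller from per-ensemble tables.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their parameters and seed and attach
their construction parameters to the output.

* **Toy redox pair** — the electrostatic premise of CYP–CPR association: a
  ~200-bead sphere (radius 16 Å) with a +5 e patch (25° half-angle) and an
  iron marker buried 11 Å deep under the patch, against a ~100-bead sphere
  (radius 10 Å) with the complementary −5 e patch, a surface N5 marker and a
  tether-anchor atom.  Bead exclusion radii (1.4 Å) keep bead diameter below
  the minimum bead spacing.  With markers and patch aligned, contact
  geometry puts D(Fe–N5) ≈ 9 Å, well inside the 20 Å recording constraint;
  averted contact ≈ 47 Å, outside it — so recording genuinely reports
  orientational alignment.
* **Membrane systems** — ideal helices (I, C, F, TM, an FG-loop trace) and a
  heme ring posed at prescribed (α, β, heme-tilt, axial offset) over two
  planes of phosphorus pseudo-atoms at ±19 Å.  Helices are pre-aligned so
  their fitted principal axis equals the requested direction exactly, which
  is what makes sub-0.5° parameter recovery a fair test of the descriptor
  code rather than of the generator.  β is realized through the azimuth of
  the C→F vector and must satisfy |cos β| ≤ sin α.
* **Toy graphs** — random ≤ 12-node typed-edge graphs whose best coupling is
  enumerated exhaustively (independent DFS) at generation time and stored.
* **Mini redox site** — a hand-built, clearly synthetic arrangement of an
  FMN N5, K456/C457 backbone and heme iron whose strongest route is
  FMN-K456-C457-HEME; it exercises labelling and census code, it is not a
  deposited-model geometry.

None of these reproduce all-atom shape, desolvation, flexibility or lipid
dynamics; passing tests on them validates propagation, recording,
clustering, filtering and graph algorithms — not force-field realism on
real proteins.

At the default 0.15 M ionic strength the Debye length (7.8 Å) is short
relative to the bead bodies and rotational relaxation (~5 ns) is slow
relative to the diffusional approach, so electrostatic steering acts mainly
through capture and retention of aligned contacts rather than through
long-range orientation of incoming trajectories.  The steering observable is
therefore the number of recorded (deduplicated) encounter poses per
trajectory; with charges on versus off over paired-seed trajectory sets this
enrichment is around 3× in the study conditions used here.

## Problem sizes and numerical choices

The test suite and acceptance script use scaled-down problem sizes chosen as
the package's own study conditions: 200 BD trajectories per arm for the
steering comparison (b = 50 Å, q = 80 Å, ≤ 6000 steps/trajectory), 10⁴
propagation steps for the Einstein-relation calibration (tolerance ±5%),
10⁴ (tests) / 2×10³ (script) random graphs for the enumeration
cross-check, and four posed membrane systems for parameter recovery
(tolerances 0.5° / 0.1 Å, matching PDB coordinate resolution).  Tie-breaks
are deterministic throughout (energy ties by trajectory/step; cluster ties
by record order; path ties lexicographic).  Degenerate inputs raise
explicit errors: collinear ring atoms for plane fits, < 4 Cα for helix
fits, empty selections for centers of mass, missing lipids for membrane
inference, overlapping selections for interface area.

## Known limitations

* BD electrostatics omits desolvation and effective-charge corrections, and
  mutual polarization/hydrodynamic interactions; encounter energetics are
  comparative, not absolute.
* The ET rate prefactor is a calibration; absolute k_ET values carry the
  uncertainty of the unspecified driving force and reorganization energy.
* Covalent-bond detection is geometric; exotic bond lengths outside the
  cutoffs would be misclassified.
* The membrane filter treats the bilayer as a rigid slab and the tether as a
  freely extended chain; both are deliberately conservative approximations.
* Checks against published crystal/model geometry require the user to supply
  those structures (see `data/reference/README.md`); they are not shipped.
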