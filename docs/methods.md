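# Methods

## Scope and conventions

All structure coordinates are Angstrom (GRO output converted to nm);
the mean-field theory works in nm and kT.  The canonical monomer frame
puts the strand axis along +x (tail toward −x), the hydrogen-bond /
assembly-growth direction along +y, and the sheet-stacking direction
along z.

## Molecular composition and masses

A lipopeptide `C<n>-<seq>` is a peptide whose N-terminus carries a
fatty acyl group of n carbons.  The neutral-molecule formula is the sum
of standard residue formulas plus one water plus the acyl increment
C_nH_{2n−2}O (fatty acid minus the condensation water).  Monoisotopic
masses use exact isotope masses (H 1.00782503, C 12, N 14.0030740,
O 15.9949146, S 31.9720710); the "expected" mass convention of ESI-MS
comparisons is monoisotopic.  Titratable sites are populated from the
sequence: lysine ε-amine (base, pKa 10.54), tyrosine phenol (acid, pKa
10.5).  The C-terminus is built as neutral COOH and is non-titratable
by default (a flag enables it, bulk pKa 3.6): the atomistic protocol
represents it as COOH and the mean-field models keep it neutral.

## Monomer construction

Geometry is generated by natural-extension-of-reference-frame (NeRF)
placement from ideal internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.335 Å, C=O 1.231 Å, τ(N–CA–C) 111°, ω = 180°).  Defaults
φ = −139°, ψ = +135° lie in the parallel-β region; every residue gets
the same values, which the dihedral-measurement routine reproduces
exactly.  The acyl chain is all-trans (C–C 1.526 Å, 111.6°); its
carbonyl carbon serves as the "previous C" for φ of residue 1.
Side chains use one fixed extended rotamer (χ1 = 180°); the tryptophan
indole and tyrosine phenol are planar polygon templates (pentagon side
1.42 Å fused to a hexagon, hexagon side 1.39 Å) attached at a ring-roll
angle χ2 = 140°, the value (scanned once over 0–180°) at which sheets
of all four sequences are clash-free at the 4.8 Å strand spacing.
Hydrogens are explicit (needed for the H-bond angle test).  The monomer
is deterministic: identical inputs give bit-identical coordinates.

## Assembly construction

*Sheet.*  n copies translated along +y by the strand spacing (default
4.8 Å, the canonical β-sheet repeat; the physical window 4.2–5.5 Å is
enforced).  Because the canonical orientation points the backbone
carbonyls along ±y, plain translation produces a three-rung
N–H···O=C ladder between adjacent strands (N···O ≈ 3.0 Å, H–N···O
≈ 15–20°) in parallel registry.

*Bilayer nanotape.*  The sheet is duplicated by a 180° rotation about
the H-bond axis and placed tail-to-tail with a 6 Å interdigitation
overlap and a half-period stagger; the 2n-mer is then doubled twice
along z at 10 Å sheet spacing.  Clash relief is a deterministic grid
scan of lateral (y, z) offsets — y in fractions of the strand period so
half-period staggers are exact — followed, if shallow contacts remain,
by rigid-body soft-sphere relaxation restricted to lateral moves (which
preserves the leaflet interdigitation and the ~30 Å hydrophobic
thickness).  The result has peptides facing solvent on both faces and
8× the sheet's molecule count.

*Fibril.*  A fully extended C16 tail (~19 Å) is longer than the
observed fibril core radii, so each molecule's tail is tilted
tangentially at the acyl junction by 45° (pinwheel packing, referenced
to the actual tail direction so the monomer's intrinsic roll cancels);
sheets are placed at 8 angular slots about the fibril (H-bond) axis
with the junction at 15 Å radius, alternating tilt sense and
half-period axial stagger between neighbouring slots, then rigid-body
relaxed to the 2 Å clash cutoff.  The 95th percentile of tail-atom
radial distance comes out near 15 Å, consistent with a C16 core.

*Clash criterion.*  Minimum inter-molecular heavy-atom distance ≥ 2 Å
after build; permissive by design — downstream energy minimization in
an MD engine removes residual strain.

*Output.*  PDB (CRYST1 + ATOM, chains cycling A–Z) and GRO via biotite.
When a box is given, the assembly's principal extents are permuted onto
the box axes (longest-to-longest, chirality preserved) and centered; an
assembly that does not fit raises an error listing the per-axis extent.

## Mean-field theory of morphology

The theory ranks planar (lamella), cylindrical (fibril) and spherical
(micelle) aggregates by free energy per molecule, built from:
conformational entropy of the lipopeptides (Monte-Carlo conformer
ensemble, probabilities P(α)); translational entropy of water and
monovalent ions; short-range contact attractions; nonlinear
Poisson–Boltzmann electrostatics (uniform ε_r = 78.5, Bjerrum length
0.714 nm); and acid–base equilibria with charge regulation via the
per-site semi-grand factor ξ(r) (the local Henderson–Hasselbalch
relation f/(1−f) = 10^(pKa−pH)·e^∓ψ follows).  Intermolecular
repulsions enter through the packing constraint Σφ(r) = 1.

*Coarse graining.*  One bead per 4 CH2 (C16 → 4 tail beads), one
backbone + one side-chain bead per residue.  Volumes (nm³): tail bead
0.108, backbone 0.100, side chains K 0.105, W 0.186, Y 0.153; water
0.030.  Model 1 types: K backbone P5, W/Y backbone Nda, side chains
W/Y C5 and K C3.  Model 2: all backbones Nda, K side chain P1.

*Attractions.*  Pairwise strengths come from a transcription of the
published coarse-grained interaction-level scheme for these type names
(levels O…IX, 5.6…2.0 kJ/mol), multiplied by the single global
contact-strength factor g.  Two transcription choices matter: the
H-bonding backbone type Nda self-associates (Nda–Nda level II vs
Nda–water IV), representing β-sheet backbone cohesion, while the very
polar P5 backbone is indifferent between itself and water (both level
O); and the aromatic side-chain type C5 is mildly hydrophobic
(C5–water V vs C5–C5 IV).  g = 0.74 is the one calibrated constant: it
is chosen so that Model 1 yields micelles at pH 3 for every sequence
and places the micelle→aggregate transition of C16-WKK inside the
experimentally relevant window (computed value pH 8.8).

*Conformers.*  Self-avoiding off-lattice chains grown bead-by-bead
(bond 0.5 nm, bond angle 120°, three jittered rotational-isomeric
torsion states, contact distance 0.4 nm); dead ends are regrown and
counted; each conformer gets an independent uniform random rotation;
generation is vectorized and deterministic per seed (default ensemble
20 000 conformers, seed 2024, cached per molecule).  The tail/peptide
junction bead is grafted to the dividing surface whose radius follows
from filling the core with the tail volume: R = (a+1)·σ·v_tail for
curvature order a = 0, 1, 2.  For the lamella, beads are folded at the
midplane (|r|), which represents the mirror leaflet.

*Numerics.*  Lattice of 0.5 nm layers (40 by default).  The naive
damped fixed point diverges — a lattice fluid in which every contact
attracts has a total-density collapse mode with feedback gain well
above one — so incompressibility is enforced by construction
(φ_w ≡ 1 − Σφ, lateral pressure an explicit function of the densities)
and the remaining self-consistency equations are solved by Jacobian-
free Newton–Krylov to residuals below 10⁻⁸, with a short damped warm-up
as fallback.  Electrostatics is an inner damped-Newton solve of the
finite-volume PB equation (zero flux at the center, ψ = 0 beyond the
outer edge).  A `solver="picard"` mode performs the damped fixed point
with free-energy-descent step control (steps that raise F are rejected
and the damping halved), guaranteeing a monotone free-energy trace.

*Free energy.*  Evaluated from the converged fields: chain entropy
Σ P ln(n_conf P); per-site −ln ξ; Flory–Huggins solvent entropy
(φ_w ln φ_w)/v_w (its grand-canonical linear counterpart is a constant
per molecule and is dropped); the PB field action evaluated at its
saddle (field-gradient term plus ion grand terms); and the contact
energy counted once per pair relative to bulk water.  A dispersed-
chain contact reference is subtracted so the number reported is an
aggregation free energy per molecule.

*Morphology search.*  For each geometry the free energy is minimized
over the surface density σ on the fixed grid 0.5–2.0 nm⁻²
(the physical range from loosely to tightly packed amphiphile layers;
below it the mean-field description spuriously stabilizes sub-micellar
clusters — a (n−1)/n self-interaction correction is additionally
applied to the spherical branch, whose aggregation number is finite).
Ties within 0.01 kT/molecule break toward higher curvature, which makes
transition-pH bisection reproducible (0.1 pH resolution).

*What the calibrated model does and does not reproduce.*  With
g = 0.74, Model 1 gives micelles at pH 3 for all four lipopeptides and
fibrils at high pH, with the C16-WKK micelle→fibril transition at
pH 8.8.  It does **not** separate the nanotape formers (C16-KWK/KYK,
lamella) from the fibril formers (C16-WKK/YKK) at high pH, does not
swap outcomes between Models 1 and 2, and places the C16-YKK transition
at 8.9 rather than ~8.2: with only the bead types, two printed volumes
and one global scale available, the planar branch is underbound — the
original parametrization evidently carries stronger specific backbone
couplings than a uniformly scaled level table expresses, and the
sequence-order free-energy differences in this reduced model are
~0.05 kT/molecule.  The corresponding end-to-end test states the full
expected phase behavior and is left failing on exactly these points.

## Structural analysis

*Hydrogen bonds.*  Geometric criterion: donor–acceptor ≤ 3.5 Å AND
H–donor–acceptor angle ≤ 30° (angle test optional; covalent hydrogens
are detected within 1.25 Å of the donor).  Backbone selection uses
amide N donors and carbonyl/carboxyl O acceptors; intermolecular pairs
only by default.  Neighbor lists (k-d tree) are validated against an
O(N²) brute-force oracle in the tests.

*Aromatic RDF.*  Centroids of the six-membered rings (benzene ring of
the indole for W; phenol ring for Y); g(r) normalized by an ideal gas
of the same centroid density in the rectangular analysis volume; the
reported stacking period is the first local maximum above g = 1.  No
periodic images: finite-volume shell clipping depresses g near r_max,
so peaks are read well inside the analysis range.

*SASA / AP.*  Shrake–Rupley as implemented in biotite (per-element vdW
radii, probe 1.4 Å, 500 sphere points by default);
AP = SASA(first frame)/mean SASA(last window).  One frame → AP is None.

*Cohesive energy density.*  Intermolecular Lennard-Jones
(Lorentz–Berthelot over per-element σ/ε, cutoff 10 Å) plus optional
Coulomb with user charges, divided by the convex-hull volume of the
heavy atoms (deterministic; an explicit volume can be supplied).
Negative = cohesive.  Energy-minimized MD snapshots are the intended
input; freshly built assemblies sit at the 2 Å contact cutoff where the
r⁻¹² wall dominates.

*Density profiles.*  Mass density (g/cm³) binned along the bilayer
normal (relative to the center of mass) or radially about the fibril
axis; group selectors map atoms to tail / residue-type species.

*Ramachandran.*  (φ, ψ) histograms over residues and frames; φ of
residue 1 uses the acyl carbonyl carbon; −ln P offset so the minimum
is zero.

*Debye SAXS.*  Cromer–Mann atomic form factors (H, C, N, O, S) with a
displaced-solvent Gaussian subtraction (water electron density
0.334 e/Å⁻³, per-element displaced volumes); exact double sum for small
systems, element-pair distance-histogram acceleration (default bin
0.1 Å) otherwise.

## Analytic scattering models

*Core–shell cylinder.*  Standard Bessel-function amplitude,
orientation-averaged by composite Simpson integration whose node count
grows with qL (resolves the axial sinc oscillations; self-converges to
<10⁻³ against a 10× finer rule).  Default contrasts (−0.5 core, +1.0
shell) avoid the near-cancellation of the forward amplitude that occurs
for volume-balanced contrast pairs.  The L = 4000 Å, R = 16.5 Å default
shows the rod-like q⁻¹ low-q scaling.

*Bilayer.*  Symmetric three-slab cross-section (core fraction 0.6) with
the infinite-sheet q⁻² prefactor; a uniform slab's first cross-section
zero falls at q = 2π/t.

*Fitting.*  Trust-region least squares with σ-weights (or I-propor-
tional weights when no σ is present), bounds, covariance-derived 1σ
uncertainties, bound-hit flags, and a deterministic multi-start over
scaled geometric start values (early exit once the reduced χ² indicates
the global minimum) — the oscillatory form factors have local minima
that a single start can fall into.

*Synthetic data.*  I·(1 + ν·N(0,1)) per point with σ = ν·I, seeded;
non-positive draws are resampled from the same generator.

## Synthetic-data conditions

The generator defaults are the study conditions used throughout the
tests and the acceptance script: cylinder R = 16.5 Å, shell 10.0 Å,
L = 4000 Å (the fibril fit values; L set deep into the rod regime);
bilayer t = 24.0 Å (the nanotape fit value); 2 % multiplicative noise
(typical of well-exposed solution SAXS); q from 0.004–0.5 Å⁻¹, 150–300
points.  Refit starts are perturbed ±20 % on all generating parameters.
What these synthetic tests do not probe: instrument smearing, structure
factors, polydispersity and background mis-subtraction of real data.

## Problem sizes

The default test/acceptance workloads were sized for a desk-scale run:
256-molecule assemblies (≈29 000 atoms), 20 000-conformer ensembles,
40-layer lattices, 150-point scattering grids, 20-seed recovery
batches.  All are parameters, not limits.

## Known limitations

- Built assemblies are starting structures: no force-field topology,
  no solvation, no minimization beyond rigid-body clash relief.
- The mean-field model's morphology discrimination is limited by the
  transcribed interaction table (see above); quantities that require
  ns-scale explicit-solvent MD (absolute CED values, AP trajectories)
  are out of scope and covered instead by closed-form/limit tests.
- Antiparallel sheets, twist imposed at build time, lipopeptide
  mixtures and finite micelle size distributions are not implemented.
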