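# Methods

`catflex` analyses conformer ensembles of Rh–bisphosphine catalyst complexes
with a bound substrate: either the prochiral model substrate (an
α-acetamidoacrylate ester, "S", which can coordinate through its alkene and
amide oxygen in four orientations) or the symmetric norbornadiene placeholder
("NBD", one orientation). The pipeline ingests geometries and electronic
properties produced upstream (a metadynamics-based conformer search followed
by DFT re-optimization and population analysis) and computes everything
downstream of that point: retention filtering, energy-window selection,
deduplication, fragment-resolved flexibility profiles, and Boltzmann-weighted
descriptor statistics.

## Complex model and coordination-mode classification

A complex is partitioned by atom role (metal, two phosphorus donors, other
ligand atoms, substrate atoms). For fragment analysis each conformer is split
into a *ligand part* (ligand atoms + metal) and a *substrate part*
(substrate atoms + metal + the two donors, which give the substrate an
orientation reference).

The four substrate coordination modes (major1/major2/minor1/minor2 in the
Knowles quadrant picture) are assigned geometrically. A right-handed local
frame is built at the metal:

- **x** — bisector of the two metal→donor unit vectors,
- **z** — normal of the donor–metal–donor plane, oriented toward the midpoint
  of the two substrate anchor carbons (this makes the frame independent of
  donor ordering),
- **y** — z × x.

The quadrant is read off the signs of the (x, y) projection of an
out-of-plane reference atom (the directing-group oxygen): the y-sign
separates major from minor and the x-sign separates modes 1 and 2. The
major ↔ +y mapping is a documented convention flag (`major_positive_y`),
since the quadrant diagram fixes no algebraic sign. A projection within
1e-3 Å of a boundary plane raises an ambiguity error instead of silently
picking a side; the retention filter flags (but keeps) such members.

Axial chirality is checked as the sign of a dihedral over four designated
backbone atoms; the sign is invariant under proper rigid motion and flips
under reflection, so it detects enantiomerized conformers.

## Minimal RMSD

Superposition uses the Kabsch closed form (SVD of the cross-covariance after
centroid removal) with the determinant correction that forbids reflections —
essential for chiral complexes. Atom correspondence is positional: every
member of an ensemble descends from one input structure, so ordering is
stable and no graph matching is attempted. Hydrogens are excluded by
default. Profiles are computed relative to the lowest-energy conformer of
the set (ties broken by lowest member index); the ligand and substrate parts
are superposed independently so a rigid substrate scores near zero even
while the ligand rearranges.

## Ensemble statistics

- **Relative energies**: member minus the conformer-search input structure
  ("baseline"), reported in kJ/mol; negative means the search found more
  stable conformers than its starting point.
- **Energy window**: members within 6 kcal/mol (default, inclusive) of the
  ensemble minimum are retained, matching the selection convention of the
  upstream search.
- **Deduplication**: greedy clustering in ascending energy order; a member
  merges into an existing representative when heavy-atom minimal RMSD
  ≤ 0.25 Å **and** |ΔE| ≤ 1.0 kJ/mol (both configurable). Greedy ascending
  order makes every representative its cluster's energy minimum, the
  procedure deterministic and O(n·k), and the operation idempotent. The
  default tolerances are conservative: tight enough not to merge distinct
  wells, loose enough to merge numerically identical minima.

## Descriptors

Five descriptors per conformer: percent buried volume at the metal and at
the donors (donor-averaged), NPA charge on the metal and donors
(donor-averaged), and the HOMO–LUMO gap in eV.

%V_bur is integrated on a cubic grid: the fraction of grid points inside the
probe sphere (radius 3.5 Å, centred on the atom) that fall inside the union
of scaled van der Waals spheres (Bondi radii × 1.17; hydrogens and the
centre atom excluded). These four defaults are the de-facto community
convention for this descriptor, not values stated by any particular study;
all are configurable. The grid (spacing 0.05 Å) is anchored to the centre
atom, so the sphere discretization never rotates with the structure — the
estimate is stable under rigid motion and under grid halving to well within
0.05 percentage points. Bondi's compilation lacks most transition metals;
for Rh the table carries the Alvarez consistent value (2.10 Å). Unknown
elements raise rather than defaulting.

Electronic quantities are never computed from wavefunctions here: they are
ingested from a delimited property table (columns `energy_hartree`,
`homo_hartree`, `lumo_hartree`, `charge_<i>`), decoupling the pipeline from
any particular quantum-chemistry log dialect.

## Boltzmann weighting

Within each reporting group, conformer i gets w_i = exp(−(E_i − E_min)/k_BT)
with E_min the group minimum, then weights are normalized. Energies are
handled in kJ/mol with the molar gas constant as k_B (identical to the
per-molecule form). Reporting groups pool the two major sets into "S-major"
and the two minor sets into "S-minor", with "NBD" separate; per-set
summaries are also emitted. Dispersion is the population-form weighted
standard deviation sqrt(Σŵ(v−mean)²); an effective sample size 1/Σŵ² is
reported alongside.

The default working temperature is **289 K**, matching the conditions of the
analyses this package targets; note it sits just below the conventional
298 K (k_BT differs by ~3%, which changes no qualitative conclusion). The
temperature is a plain keyword argument everywhere.

## Synthetic data generator

The generator emulates the statistical structure of the real ensembles so
that every stage is testable without any download:

- **Geometry**: a schematic complex — Rh at the origin, two P donors, two
  rigid backbone atoms carrying the axial-chirality dihedral, flexible
  carbon arms, and a substrate block whose directing-group oxygen is placed
  in the quadrant of the requested coordination mode. Minimum interatomic
  distance 0.8 Å by construction.
- **Flexibility**: per-atom Gaussian displacements with role-dependent
  scales — flexible arms σ = 0.8 Å (ligand-part RMSDs of a few Å, like the
  broad ligand ranges seen in real ensembles), substrate/core/backbone
  σ = 0.05 Å (substrate-part RMSD well below 1 Å). Keeping the chiral
  backbone rigid mirrors the constraint the real search applies to the
  aryl rings on the chiral axis.
- **Energies**: ΔE ~ Exponential(mean 10 kJ/mol) above the minimum —
  right-skewed, minimum-anchored spreads of tens of kJ/mol — with the
  baseline placed 10 kJ/mol above the minimum so relative energies take
  both signs.
- **Electronic properties**: each modelled descriptor is a declared linear
  map of the true ligand distortion plus Gaussian noise, with all draws
  stored in a truth record, so weighted-mean recovery can be asserted
  against an analytic expectation.
- **Dedup fixtures**: n wells (large independent arm displacements,
  accepted only if all pairwise minimal RMSDs exceed the requested
  separation) × r jittered replicates; the planted well count is exact
  ground truth.
- Every conformer receives a random rigid motion so that alignment code
  cannot pass by coordinate coincidence. A single integer seed drives all
  randomness through per-purpose substreams.

What the generator does **not** emulate: bonded connectivity and realistic
force-field energetics, correlated (torsional) rather than independent
per-atom displacements, rotamer multiplicity, and any real relationship
between geometry and electronic structure beyond the declared linear model.
Passing tests therefore demonstrate correctness of the *analysis* machinery
under known ground truth, not predictive validity on laboratory systems.

## Numerical choices and problem sizes

- Energy conversions pivot through hartree with CODATA 2018 factors and
  round-trip to 1e-10 relative.
- RMSD engines are validated against two independent oracles: a dense
  rotation-space grid search (coarse Euler sweep, iterative zoom to 0.1°)
  on small instances, and scipy's `Rotation.align_vectors` on larger ones.
- %V_bur is validated against the closed-form single-sphere ratio
  ((2.0/3.5)³ = 18.66%) and a 10⁷-sample Monte-Carlo rejection oracle
  (agreement within 3 standard errors).
- Energy ties in reference selection break to the lowest member index.
- Test and acceptance runs use ensembles of 8–200 conformers, 22-atom
  complexes, and a 151-member/35-well dedup fixture; these sizes exercise
  every code path while keeping a full run in the tens of seconds.

## Known limitations

- Atom reordering/symmetry-corrected RMSD is out of scope; inputs must
  share atom ordering.
- The coordination-mode classifier operationalizes the quadrant diagram
  geometrically; other anchor choices are possible and the anchors are
  explicit configuration, not inferred.
- Conformer populations are electronic-energy Boltzmann weights; free-energy
  (entropy-corrected) weighting is out of scope.
- Fragment specs are explicit; no automatic inference from connectivity.
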