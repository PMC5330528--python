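# Methods

## The problem

NMR crystallography selects the correct crystal packing of a molecule from a
list of crystal-structure-prediction (CSP) candidates by comparing computed
chemical shifts with an experimental solid-state NMR assignment. The
computation chain is: per-nucleus isotropic magnetic shieldings σ (from a
plane-wave DFT engine, consumed here as data), conversion to chemical shifts,
averaging over molecular motion, and per-candidate RMSD scoring against the
assignment. This package implements that chain for three "approaches" —
static energy-minimized structures and one or more molecular-dynamics
(MD)-averaged variants — together with the selection logic, structure
overlays and lattice-energy bookkeeping around it.

## Shift referencing

Shieldings are converted with

    δ_calc = σ_ref − σ_calc

where σ_ref is a per-element, per-approach reference shielding obtained by
regressing the experimental shifts on the calculated shieldings with the
slope constrained to unity. With that constraint the least-squares solution
has the closed form

    σ_ref = mean over matched nuclei of (σ_calc + δ_exp),

which makes the mean signed residual identically zero; `compute_sigma_ref`
implements the closed form and the test suite checks it against a numeric
constrained-least-squares oracle. The pool for σ_ref is, by default, every
candidate scored under the approach; a restricted pool can be passed when a
user wants the reference fit only on shortlisted structures.

## Motional averaging

Per candidate, the MD stage averages shieldings over trajectory frames and
over the symmetry-equivalent molecule copies in the simulation cell, giving
one value per asymmetric-unit nucleus; copies map to asymmetric-unit labels
by site order within each molecule (an explicit map can override). The
frame-selection plan keeps the number of molecular spectra per candidate
fixed at 48: with m molecules per cell, 48/m frames at 96/(48/m) ps
intervals, which yields 24 frames at 4 ps for Z = 2, 12 at 8 ps for Z = 4,
and 6 at 16 ps for a Z = 1 structure replicated 2×2×2 — all inside a 100 ps
production window. Methyl protons exchange fast on the NMR timescale, so
after referencing, each methyl's three ¹H values are replaced by their mean
(idempotent, mean-conserving, and commuting with referencing since both are
affine).

Averaging order is: ensemble-average shieldings, then reference, then
methyl-average. All three operations are affine, so the order is
mathematically immaterial; it is fixed for reproducibility of intermediates.

## Selection logic

Benchmark windows encode the expected accuracy of the shielding protocol:
¹³C 1.9 ± 0.4 ppm and ¹H 0.33 ± 0.16 ppm by default (taken from published
static-DFT benchmark sets; configurable because no MD-averaged benchmark
exists). A candidate is

* **pre-filtered** when its static ¹³C RMSD exceeds mean + 3·sd = 3.1 ppm
  (strictly greater; boundary equality keeps the candidate). Pre-filtered
  candidates are not subjected to the MD stage.
* **shortlisted** for an element/approach when its RMSD lies inside
  mean ± k·sd (k = 1 by default, two-sided).

The consensus ranking orders candidates by total shortlist memberships
across approaches and elements (descending), then mean ¹H RMSD, then mean
¹³C RMSD, then id — a deterministic total order.

## Structure overlays and trajectory averages

Packing similarity is measured as the RMS Cartesian displacement (RMSCD)
over matched non-hydrogen atoms after an optimal proper rigid superposition
(closed-form SVD solution with a reflection guard; verified against a
numeric rotation-space minimizer to 1e-6 Å). Two comparison modes exist:
one molecule, or the full unit-cell cluster with the molecule-to-molecule
assignment minimized over permutations (exact to 8 molecules, greedy
centroid matching beyond); molecule centroids are wrapped into the cell
first, so moving a molecule by a lattice vector does not change the result.
The comparison mode is recorded in every result.

Average structures unwrap fractional coordinates frame-to-frame (each
coordinate shifted by integers to minimize displacement from the previous
frame, reference frame 0) before arithmetic averaging; cell parameters are
averaged arithmetically. A trajectory is flagged as a phase transition when
the average structure's cell-cluster RMSCD against its reference exceeds
0.35 Å — the midpoint between published stable (0.142 Å) and transitioned
(0.687 Å) exemplars — or when any averaged cell length drifts more than 5%
relative. Both thresholds are configurable.

## The synthetic study generator

The generator replaces the DFT shielding engine, the CSP search and the MD
integrators with declared statistical surrogates, so the whole pipeline runs
and is testable offline.

**Base crystal.** A methyl-hexanoate-like molecule (23 atoms: ester head,
four CH2 groups, two methyl rotors) built from an internal z-matrix, packed
with Z = 2, Z′ = 1 in a monoclinic-like P1 cell (13.2, 9.0, 7.8 Å, β = 96°);
the second molecule is a 180°-rotated copy at the body-diagonal offset. The
molecule provides ten spectroscopically distinct ¹H environments and seven
carbons — enough degrees of freedom that per-candidate RMSDs concentrate
(χ²-like with ~10 effective dimensions) instead of being dominated by one
or two noise draws. The packing density is looser than a real organic
crystal (~0.47 g/cm³); contacts, not density, are what the forward model
uses.

**Forward shift model.** δ(nucleus) = base shift + conformation term +
packing term + systematic noise, with σ = σ_ref_true − δ:

* base shifts are typical solution-state values for an aliphatic ester;
* the conformation term adds coeff × |Δφ| ppm to designated carbons for the
  deviation of a designated backbone torsion from the reference geometry
  (2.9 ppm/rad on the end methyl carbon, so a 180° conformational flip moves
  it by ≈ 9 ppm — the scale of an axial/equatorial N-methyl change, which is
  what lets the ¹³C pre-filter exclude wrong conformers);
* the packing term adds k·Σ 1/r³ (k = 12 ppm·Å³, 6 Å cutoff, periodic
  images included) over intermolecular contacts to each ¹H, centred per
  molecule over its protons: the bulk (density-like) component of the
  proximity sum is treated as absorbed into the base shift, leaving the
  differential pattern that actually distinguishes packings. ¹³C gets no
  packing term. This realizes the qualitative physics that ¹H senses
  intermolecular structure while ¹³C is conformation-dominated;
* noise is a Gaussian systematic error per spectroscopically distinct
  nucleus (symmetry-equivalent copies and the three exchange-averaged methyl
  protons share one draw) and per structure — not per frame and not per
  approach, because the shielding protocol, and hence its model error, is
  shared by the static and MD-averaged calculations; motional averaging must
  not wash it out. Defaults: 0.3 ppm ¹H, 1.5 ppm ¹³C.

**Assignment.** The experimental assignment is the truth candidate's clean
forward shifts plus an experiment-side noise of 0.137 ppm (¹H) and
1.166 ppm (¹³C) per distinct nucleus, chosen so the correct candidate's
total expected RMSD equals the benchmark-window mean (√(0.3² + 0.137²) =
0.33; √(1.5² + 1.166²) = 1.9): a correct candidate lands inside the
shortlist windows by construction.

**Candidates.** Decoys are rigid-molecule rotations (sd 30°) and
translations (sd 1.2 Å) with ±4% cell-length perturbations, resampled until
bond topology is intact, the closest intermolecular contact (periodic
images included, with a shift range that covers molecules longer than a
cell axis) is ≥ 1.5 Å, and the clean ¹H pattern differs from the truth by
at least 0.5 ppm RMS. The amplitudes put typical decoy separations at
0.5–1.5 ppm, the spread seen across real CSP candidate ¹H RMSDs. A
configurable number of decoys additionally get the designated torsion
flipped by 180° (conformational decoys destined for the 3σ pre-filter); the
flip rotates the chemical subtree along the reference bond graph.

**Trajectories.** Frames are the base structure plus i.i.d. Gaussian
Cartesian jitter (sd 0.15 Å for H, 0.08 Å for heavy atoms — thermal
displacement scale), methyl rotors hopping ±120° as a Poisson process
(0.1 jumps/ps), and an optional phase-transition surrogate: one molecule
displaced by a set distance (default direction along the centroid-separation
axis toward open space, ramped over the first 10% of the run and then held).
A whole-structure drift or a tangential slip would be absorbed by the rigid
overlay; the along-axis slip is the smallest planted change that a
cell-cluster RMSCD reliably sees. The cell is held fixed (small-cell NVT
picture). With all amplitudes zero the trajectory is constant.

**Energies.** Reference lattice energies place the truth lowest with a
configurable rank-1/2 gap (default 4.43 kJ/mol) and uniform spacings above;
per-force-field energy sets add a constant offset plus method-specific
Gaussian error, which exercises the offset-insensitive (mean-centred)
energy-RMSD comparison. Both centred and raw RMSDs are reported, since the
appropriate choice depends on whether two methods share an energy zero.

## What the synthetic tests do and do not show

Passing the recovery study shows that the pipeline's referencing, averaging,
scoring and selection logic are internally correct and that, when ¹H
patterns genuinely separate packings by ≥ 0.5 ppm RMS against ~0.3 ppm
noise, the consensus picks the planted truth and ¹H discriminates while ¹³C
does not. It does not validate DFT shielding accuracy, force-field quality,
or real spectral assignment — the forward model is a statistical stand-in,
not a shielding predictor, and its decoys are perturbations of one packing
rather than an exhaustive polymorph search.

## Numerical choices

* Fractional coordinates are storage; Cartesian conversion uses the
  lower-triangular cell matrix with *a* along x.
* Covalent radii from an embedded Cordero-style table; bond cutoff
  r_i + r_j + 0.40 Å; minimum-image by per-axis rounding (exact for
  orthogonal cells, standard at bond-length scales for the modest
  obliquities handled here).
* Duplicate symmetry images merged at 0.01 Å (typical CIF precision).
* "Side-to-side" supercell distance = perpendicular face-to-face width
  (V / face area), not axis length, so oblique cells replicate correctly.
* Disordered structures (occupancy < 1) are read but refused by the
  pipeline; only ordered candidates are handled.
* Reports round to 0.01 ppm (¹H) and 0.1 ppm (¹³C) in printed tables;
  internal arithmetic is double precision.
* Problem sizes in the shipped studies: 10 decoys + truth, 24 frames × 2
  molecules = 48 spectra per candidate, 10 seeds — sizes at which every
  statistical property tested is already stable.

## Known limitations

* Molecule correspondence in overlays is by label or explicit map; there is
  no chemistry-aware graph matching of arbitrary 15-molecule clusters.
* Anisotropic shift tensors are not modelled (isotropic values only).
* The energy model contains no vibrational/free-energy corrections.
* The published 0.0556 Å overlay against the experimental crystal structure
  requires externally licensed structure files (see tests); the machinery
  is present and exercised on synthetic structures.
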