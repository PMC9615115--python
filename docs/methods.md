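# Methods

This package computes chiral (χ⁽²⁾_zyx) and achiral (χ⁽²⁾_yyz)
sum-frequency-generation spectra of the water O–H stretch from molecular
configurations of an interfacial slab, and dissects the signal by
Voronoi-defined hydration shells and hydrogen-bond classes.  This note
records the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Spectroscopic model

Each water O–H bond is treated as a local-mode chromophore through an
electric-field map: the Coulomb field of all charged sites of *other*
molecules (within a spherical cutoff of the H atom, minimum image) is
projected onto the O→H unit vector, and empirical polynomials convert
the projected field E (atomic units) into

- the 1←0 transition frequency ω₁₀(E) (cm⁻¹),
- the position matrix element x₁₀(ω₁₀) (Å),
- the transition-dipole derivative μ′(E).

The lab-frame transition dipole is μ = μ′·x₁₀·û along the bond; the
transition polarizability is the axially symmetric bond tensor
α = x₁₀·[ρ·I + (1−ρ)·û⊗û], with ρ the transverse/parallel
polarizability-derivative ratio.  The two O–H chromophores of one
molecule are mixed by the intramolecular coupling
ω₁₂ = (c₀ + c₁(E₁+E₂))·x₁(ω₁)·x₂(ω₂) — a 2×2 vibrational exciton
problem whose eigenmodes carry eigenvector-weighted combinations of the
bond moments.  Intermolecular coupling is deliberately omitted so that
the spectrum of any union of disjoint molecule subsets is exactly the
sum of the subset spectra; this is what makes a clean shell-by-shell
decomposition possible.

All map numbers (polynomial coefficients, coupling constants, ρ, the
7.831 Å field cutoff, isotope masses) live in
`src/chiralsfg/data/oh_stretch_map.txt` and are configuration, not code;
the file documents its source lineage (the Skinner-group field-map
family for water) and can be swapped for any other parameterization.

The spectrum is assembled in the inhomogeneous limit: every eigenmode of
every frame contributes a stick at ω with weight α_ij·μ_k, where
(i,j,k) are the (SFG, visible, IR) lab polarization indices — (z,y,x)
for the chiral psp element, (y,y,z) for the achiral ssp element; z is
the interface normal with vacuum at +z.  Sticks are broadened with a
normalized complex Lorentzian (half-width 5 cm⁻¹ by default; a Gaussian
is available) and averaged over frames on a 2800–4000 cm⁻¹ grid at
1 cm⁻¹.  Im χ is the reported observable, matching phase-resolved
detection; Re χ is retained in all outputs.  The overall amplitude is
arbitrary — no absolute-intensity calibration is attempted — so only
ratios and signs of spectra are meaningful.  The width only smooths the
lineshape; it moves no peak positions or signs.

An optional ¹⁶O→¹⁸O toggle multiplies ω₁₀ by the harmonic reduced-mass
ratio √(μ₁₆/μ₁₈) ≈ 0.99669, a ≈12 cm⁻¹ redshift at 3500 cm⁻¹.  This is
a convenience for comparing against isotope-labeling experiments, not a
full isotopic remapping.

Not modeled, by construction: Fermi resonance with the bend overtone,
intermolecular vibrational coupling, motional narrowing / frequency
dynamics, and the protein's own N–H stretch.

## Hydration shells and hydrogen bonds

Shells are defined by an unweighted Voronoi tessellation of atomic
centers (virtual charge sites excluded, all atoms including hydrogens)
under full periodic boundary conditions.  The first hydration shell is
every water with at least one atom whose cell shares a face with a
solute atom's cell; the second shell borders the first.  The
backbone/side-chain split assigns a first-shell water to a region by the
class of solute atom its cells touch; a water touching both classes is
deliberately in both regions, so the two region sizes sum to slightly
more than the first shell.

Implementation: the periodic tessellation tiles the cell with its 26
images (pruned to a 14 Å buffer) and runs qhull; ridges with face area
below 10⁻⁶ Å² are discarded as numerical slivers, and degenerate inputs
(exact lattices) are retried with a deterministic 10⁻⁹ Å jitter.

Hydrogen bonds use two geometric criteria: donor–acceptor heavy-atom
distance < 3.5 Å and donor–H···acceptor angle measured *at the
hydrogen* > 135° (180° = linear).  The at-H vertex is the only
convention for which a >135° threshold is geometrically sensible.
Donors are water O–H and solute N–H (amide and ammonium) pairs;
acceptors are O atoms.  Amide and protonated-ammonium nitrogens are not
acceptors (no accessible lone pair).  The "strong C=O" subclass keeps
water H···carbonyl-O contacts of ≤ 1.6 Å.  Monatomic ions are excluded
from the solute definition but contribute to field evaluation.

## Water-ordering diagnostics

- **Molecular dipole**: classical point-charge dipole of the water's
  sites, sign-fixed to bisect the H–O–H angle pointing *toward the
  oxygen* (1 e·Å = 4.8032 D).
- **Dipole grid**: dipoles accumulated on a 1 Å in-plane grid by the
  oxygen's position, restricted to a depth window (default 0–14 Å)
  below the instantaneous water surface, which is located as the mean
  height of the top decile of water oxygens — a robust density proxy,
  configurable.  Both raw vector sums and occupancies are stored; unit
  and mean fields derive from them.
- **Annulus profile**: magnitude of the vector sum of cell dipoles in
  concentric 1 Å rings around a center (default: the solute's in-plane
  centroid); both the 3-vector and in-plane magnitudes are reported
  because published vector-field figures are ambiguous about the normal
  component.
- **Mirror-asymmetry score**: RMS difference between the per-cell mean
  dipole field and its mirror image across a chosen vertical plane
  (mirror-odd component negated), over cell pairs occupied on both
  sides.  Zero for a mirror-symmetric field.
- **Retention time**: membership of a subset sampled at a fixed stride
  (1 ps in production use); episodes are maximal runs of consecutive
  membership, and the mean arrival-to-exit duration is taken over all
  episodes of all molecules.  Edge-truncated episodes are included in
  the mean and reported as a censored count — the plain reading of
  "arrival to exit", and the alternative (dropping them) would bias
  short trajectories toward short retentions.
- **Dangling O–H**: a subset water counts if at least one O–H points
  within 60° of the vacuum normal *and* that H donates no hydrogen
  bond.  The 60° cone is a tunable with no canonical value; vary it to
  report sensitivity.

## Synthetic systems

The generators provide every study condition as code:

- **Rigid waters** from the TIP4P-Ew table (r_OH = 0.9572 Å,
  θ = 104.52°, q_H = 0.52422 e, q_M = −1.04844 e, O–M = 0.125 Å).
- **Chiral helix**: n waters on one helical turn, dipoles tilted
  inward/upward, molecular planes twisted about the bisector (default
  40°) to break every vertical mirror plane.  The left-handed variant
  is *defined* as the exact yz-plane reflection of the right-handed
  one, so enantiomer pairs are exact by construction; handedness 0
  gives an untwisted planar ring with explicit vertical mirror planes
  (the achiral control).
- **Mirror-symmetric cluster**: random waters plus their literal
  reflections — the χ_zyx-null fixture with exact pair cancellation.
- **Slab**: oxygens rejection-sampled at liquid density with a 2.4 Å
  minimum O–O distance (preventing unphysical field singularities),
  uniform random orientations, vacuum along z.
- **Strand mimic**: an idealized extended β-strand presenting
  alternating backbone C=O and N–H sites (±0.51 e pairs) in a plane
  just above the water surface, with ammonium-like +1 side-chain groups
  every second residue dipping ~2.5 Å into the water.  It reproduces
  the *interaction classes* of an interfacial β-sheet — carbonyl
  acceptors, amide donors, charged side chains — not any particular
  peptide's geometry; the package's conclusions are exercised through
  symmetry and electrostatics, which is exactly what the mimic
  controls.

## Thermalization

`build_slab_fixture(thermalize=True)` equilibrates the slab with the
in-package canonical Metropolis Monte Carlo sampler
(`chiralsfg.montecarlo`): single-molecule translation (±0.22 Å) and
rotation (±25°) moves of rigid TIP4P-Ew waters at 298 K, site–site
Coulomb plus O–O Lennard-Jones energies truncated molecule-wise at a
9 Å O–O cutoff (clamped to half the smallest lateral box edge), minimum
image in all directions.  Frozen external charges (the strand mimic)
enter via Coulomb plus a soft excluded volume on the oxygens.

The sampler draws configurations from the same 298 K canonical ensemble
that thermostatted dynamics would sample, so equilibrium structural
statistics (energies, H-bond counts, orientation distributions) are
directly comparable; dynamical quantities (true residence times,
correlation functions) are not defined by it.  A block of 30 sweeps is
treated as the 1 ps analysis stride — comparable orientational
decorrelation — and 4000 sweeps of equilibration corresponds to well
past the observed relaxation of the potential energy (−10.7 kcal/mol
per water with this truncation) and of the H-bond count from a random
start (plateau by ≈2500 sweeps).  Electrostatic truncation rather than
Ewald summation is the main physical approximation; it perturbs
H-bond statistics only mildly but is not suitable for long-range
orientational correlations.

## Problem sizes

Desk-scale runs use fixtures of 8–40 waters for symmetry and
decomposition checks (where the assertions are exact and size-
independent) and a 240-water slab, 4000 equilibration sweeps and 40–80
sampled frames for the thermalized H-bond statistic — sizes chosen so a
full verification pass completes on a single CPU while keeping the slab
interior genuinely bulk-like (≈19 Å thick).  The statistical error of
the H-bond mean at these sizes is ≈0.01, far below the physical spread
of published criterion-dependent values.

## Numerical choices

- Minimum image via fractional rounding (exact for orthorhombic cells),
  refined by a 27-image search for triclinic cells.
- Reflections are implemented as coordinate negation about 0, which is
  exact in floating point; mirror-antisymmetry assertions therefore
  hold to machine precision rather than to a loose tolerance.
- The 2×2 exciton problem uses a symmetric eigensolver; the trace
  ω₊+ω₋ = ω₁+ω₂ is conserved exactly.
- Field singularities (a foreign charged site within 0.1 Å of an H)
  raise an error naming the frame and atoms rather than producing a
  huge frequency silently.
- Spectrum tables are written with repr precision and round-trip
  bit-exactly; PDB coordinate round trips are exact to the format's
  10⁻³ Å.
- The t-test comparing a signal band against a baseline band returns
  p = 1 by convention when both bands are the same constant.

## What passing tests do and do not show

The synthetic generators emulate controlled geometry, chirality,
interaction-site classes, and liquid-like slab statistics.  They do not
emulate a real protein's conformational ensemble, polarizability,
long-range electrostatics (Ewald), or genuine dynamics.  Passing the
symmetry, additivity and oracle tests therefore validates the
*machinery* — that the code computes the model it claims, with the
claimed invariants — on conditions where the truth is known by
construction.  Quantitative agreement with a real protein experiment
additionally requires production-quality input trajectories.

## Running at full scale (production trajectories)

The pipeline consumes any PDB/GRO + DCD/XTC trajectory through
`chiralsfg run-all` with a YAML config (see `examples/template.yaml`).
For a production protein-slab study of first-hydration-shell
selectivity, the intended protocol is: an all-atom protein + 4-site
water slab with two vacuum interfaces, thermostatted dynamics at 298 K
(Ewald electrostatics, rigid waters), configurations stored every 10 fs
for spectra and every 1 ps for shells/dipoles/retention, ~100 ns of
sampling, and a charge table matching the force field.  On such input
the pipeline produces the full dissection — all-water / first / second
shell spectra (expect the first hydration shell to carry ~90% of the
chiral band area, with positive ~3400 and negative ~3600 cm⁻¹
features), the eight H-bond-taxonomy subset spectra per water, H-bond
count means per subset, retention times, and the dipole grid and
annulus diagnostics.  These production-scale numbers are statements
about that input trajectory; the in-repo fixtures verify the machinery,
not the protein-specific values.

## Known limitations

- Truncated electrostatics in the Monte Carlo sampler (no Ewald).
- The per-water normalization divides the mean spectrum by the mean
  subset size; with strongly fluctuating subsets this differs from
  averaging per-frame per-water spectra (both behaviors are tested and
  the difference documented).
- The Voronoi backend tessellates up to 27 tiled copies; systems beyond
  ~10⁴ atoms per frame will want a native periodic tessellation
  library.
- Retention episodes are not corrected for censoring beyond counting
  them; retention means on short trajectories are lower bounds.
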