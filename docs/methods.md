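# Methods

## Model and scope

The package implements the energy–entropy multiscale cell correlation
(EE-MCC) decomposition for solvated systems. Free energy is assembled
per molecule as G = H − TS, with enthalpy taken directly from per-atom
kinetic and potential energies and entropy summed over nested length
scales: united atoms (a heavy atom with its bonded hydrogens), monomers
(residues or small molecules), and whole polymers. Protein molecules are
resolved at all three levels, multi-united-atom solutes at united-atom
and monomer levels, and water and monatomic ions at the united-atom
level only. These level declarations are derived from the topology
(`Topology.levels_of_molecule`) rather than hard-coded per molecule
name, so any species labelled `protein`, `polyanion`, `buffer`,
`cation`, `anion` or `water` runs through the same machinery.

The pipeline assumes its input frames already carry a physically
meaningful per-atom energy decomposition (many-body and long-range mesh
terms divided evenly over involved atoms). It never re-derives that
split; the enthalpy module documents the contract and simply sums.

## Units

Coordinates in Å, energies in kJ mol⁻¹, forces in kJ mol⁻¹ Å⁻¹, masses
in amu, entropies in J K⁻¹ mol⁻¹, temperatures in K (default 298 K).
T·S products in tables are kJ mol⁻¹. Conversion to SI happens only
inside the vibrational eigenvalue step. Boxes are orthorhombic with
minimum-image convention; triclinic cells are rejected.

## Vibrational entropy

Forces on each unit are summed over its atoms, rotated into the unit's
body frame, and mass-weighted (F/√M); torques about the unit's centre
of mass are resolved along instantaneous principal inertia axes and
weighted by 1/√I. Covariance eigenvalues λ give ν = (1/2π)√(λ/k_BT) and
each mode contributes quantum harmonic oscillator entropy.

Choices that were genuinely open:

- **Body frames.** United-atom frames come from covalent geometry (bond
  to the first bonded atom defines one axis, a second bonded atom the
  plane; heavy partners preferred, principal axes as fallback, lab
  frame for isolated atoms). Monomer and polymer frames use
  instantaneous principal inertia axes, sign-fixed and right-handed so
  the decomposition is deterministic. Any consistent body frame leaves
  well-sampled covariance eigenvalues unchanged; rotational invariance
  is asserted by test.
- **Mean-field halving** applies to polymer-level forces and to torques
  at every level, before accumulation.
- **Mode removal.** At every level below a molecule's highest, the six
  lowest force-covariance modes are removed; torque modes are not
  (configurable nowhere on purpose — forces-only is the implemented and
  tested variant). Fewer than seven translational modes at a
  non-highest level is a hard error rather than a silent truncation.
- **Zero frequencies** surviving removal contribute zero entropy and
  warn: they are rigid-body modes that should have been removed, and a
  crash would punish harmless degenerate fixtures.
- Rotational mode counts follow rigid-body convention: 3 nonlinear,
  2 linear (inertia eigenvalue ratio below 10⁻⁸ treated as degenerate),
  0 monatomic.

## Conformational entropy

Dihedral angles live in [−180°, 180°) and are binned into twelve 30°
bins. Peak bins must strictly exceed both circular neighbours; among
peaks closer than 60° the more populated survives (ties to the lower
bin index). Every angle joins its nearest surviving peak by periodic
distance. A flat histogram with no strict peak collapses to a single
conformer with a warning — the conservative zero-entropy reading of a
degenerate distribution. Joint states are the per-frame vectors over a
monomer's dihedrals; probabilities are frame-weight aware.

## Orientational entropy of water

Hydrogen bonds are topological: each donor hydrogen binds the acceptor
in its united atom's coordination shell with the most negative
q_D·q_A/r², or none if no candidate has a negative product. Donation
and acceptance fractions per neighbour type give
p(HBᵢ) = p(Dᵢ)p(Aᵢ)/(p(Dᵢ)+p(Aᵢ))², which is 0.25 when unbiased and 0
when fully one-sided; N_eff = Σᵢ p(HBᵢ)Nᵢ/0.25 and the entropy is
k_B Σ_c p(c) ln[(N_eff π)^{3/2} p(HB_av)/σ] with σ = 2 for water.

- The shell-type key *c* is the sorted multiset of neighbour labels.
  Non-water neighbours take their species role; a neighbouring water
  takes `near-<role>` of the nearest solute whose shell holds it, and
  `bulk` otherwise. Neighbour waters never trigger a solute category in
  environment classification.
- The phase-space exponent is pinned to (N_eff·π)^{3/2}; the alternative
  grouping N_eff^{3/2}·π^{1/2} is selectable and differs by the constant
  k_B·ln π per shell type, so absolute comparisons must fix one form.
- Shell types with N_eff·p(HB_av) = 0 carry no orientational freedom:
  they are dropped, p(c) is renormalised and the dropped weight is
  reported, rather than flooring a logarithm at an arbitrary value.
- Waters with empty shells are excluded and tallied.
- Excipient orientational entropy is deliberately not computed; for the
  weakly bound solutes this pipeline targets it is assumed unchanged
  between states, and solute–water contact counts serve as a
  qualitative proxy for positional entropy.

## Coordination shells and contacts

RAD shells use the unnormalised, distance-sorted blocking test: within
a candidate cutoff (default 8 Å, the usual non-bonded truncation),
neighbour j of centre i is rejected when a strictly closer candidate k
satisfies 1/r_ij² < cos θ_jik/r_ik². Equal distances never block.
Shells are directional by construction; nothing assumes per-pair
symmetry. Contact tables count each unordered intermolecular
united-atom pair once per frame if either shell contains the other, and
aggregate to species-role pairs; the per-molecule variant divides rows
by the molecule count of the row species. The rational switching
function s(r) = 1/(1+x⁶), x = (r−d₀)/r₀ (the simplified form of
(1−x⁶)/(1−x¹²), with the removable singularity at x = 1 equal to ½) is
provided for reproducing sampling-time collective variables; distances
below d₀ count as full contacts. All thermodynamic post-processing uses
RAD shells, not the switching function.

## Water environments

Each water is labelled per frame from its shell's species content:
WP (one protein), WPP (two or more proteins), WEP/WEPP (the same plus
any excipient or counterion — polyanion, buffer, cation or anion all
count), WE (excipient/counterion only), bulk otherwise. Excipient
presence takes precedence, so a shell with protein and ion content is
WEP, not WP. Labels partition the waters exactly in every frame, and
per-environment energy statistics are frame-local: a water contributes
to WP only in frames it is labelled WP.

## Reweighting

Well-tempered metadynamics frames are unbiased with
w(t) = exp(+V(s,t)/k_BT) using the time-matched saved bias; weights are
rescaled by the maximum bias for numerical range, which cancels in all
weighted means. The sign is fixed by the requirement that reweighted
toy-sampler populations reproduce unbiased reference sampling (asserted
in the acceptance suite); an inverted-sign option exists for bias files
written with the opposite convention. No time-dependent offset c(t) is
applied: it is a frame-independent shift at fixed analysis time and
cancels in normalised weights. By convention, weights apply to
water/excipient statistics, energies and contacts, but not to protein
entropy terms, whose conformations the bias does not drive; a flag
enables full weighting.

## Synthetic generators

The generators emulate exactly the statistical structures the analysis
assumes, not real molecular systems:

- **Harmonic ensembles** draw positions from the exact Boltzmann
  distribution of an isotropic 3-D spring (variance k_BT/k per axis),
  with F = −k·Δx, U = |F|²/2k and Maxwell–Boltzmann kinetic energies.
  Defaults k = 10 kJ mol⁻¹ Å⁻², m = 18 amu, T = 298 K place hν/k_BT
  near 0.2 — the soft, entropy-rich regime typical of the lowest
  covariance modes. Units are monatomic molecules (highest level), so
  no mode removal applies.
- **Dihedral series** are von Mises mixtures (κ = 50, ≈8° spread) at
  staggered-rotamer centres — narrow enough that bin misassignment is
  negligible against the 30° bins.
- **Water-shell streams** emit label-level shell compositions and
  donation/acceptance events with prescribed probabilities, feeding the
  same accumulator as the geometric pathway; geometric RAD retention is
  exercised separately by the solution-scene generator and the
  brute-force oracle tests.
- **Toy WT-MTD** integrates overdamped Langevin dynamics (dt = 0.005,
  friction 1, exact stationary-distribution control is the reason for
  choosing this integrator) on analytic double wells
  U(s) = b(s²−1)² + δs/2, depositing Gaussians every 500 steps with
  W₀ = 1.5 kJ mol⁻¹, width 0.2 (about a fifth of the well separation)
  and bias factor γ = 20, the parameter style of production
  metadynamics on contact-count variables. The bias is an explicit
  kernel sum, so saved per-frame bias values are exact. The acceptance
  comparison is against unbiased sampling with the *same* integrator,
  so the finite-step discretisation bias (visible as a small shift from
  the quadrature populations) cancels; the analytic population is
  reported alongside for context. The converged-bias free-energy read
  uses G(s) = −γ/(γ−1)·V(s) and integrates exp(−G/k_BT) per well; the
  stated tolerance for matching the quadrature asymmetry is
  1.5 kJ mol⁻¹ (≈0.6 k_BT), the observed seed-to-seed convergence noise
  scale of a 400k-step single run.
- **Solution scenes** place two 3-residue proteins, a 3-site polyanion,
  two cations and a water grid with harmonic jitter and consistent
  forces/energies, so shells, hydrogen bonds, classification, contacts,
  energies and covariances all run end to end on one small input.

What passing these tests shows — and does not. The oracles certify the
estimators (covariance → frequency → entropy; binning → Shannon sum;
event fractions → orientational formula; bias → weights) on inputs
whose ground truth is known exactly. They do not certify force-field
realism, sampling adequacy on rugged landscapes, or the per-atom energy
decomposition of any particular simulation engine, all of which are
properties of the trajectory producer.

## Problem sizes

Test and acceptance runs use 5000-frame harmonic ensembles, 20000-angle
dihedral series, 4×200k-step biased plus 64×20k-step unbiased Langevin
trajectories, and solution scenes of 20–40 waters over 6–20 frames —
sizes at which every closed-form comparison resolves well inside its
stated tolerance on a single CPU.

## Reference-table arithmetic

The packaged CSVs carry a published free-energy decomposition, contact
matrix and water-environment census for buffered lysozyme–polyanion
systems at ~20 mM excipient, plus the 129-residue hen-egg-white
lysozyme sequence. They are inputs to arithmetic (per-molecule
normalisation, column totals, mean formal charge over a 4⁻/5⁻ charge
mix, and integer titration at pH 9 with Arg/Lys protonated, His
neutral, and disulfide-bonded cysteines non-titratable), not quantities
this package claims to reproduce from simulation: the originals derive
from ~550 ns of all-atom multi-walker metadynamics. Consistency checks
on such tables use a printed-precision slack of ±1 kJ mol⁻¹ per row
identity and allow small accumulation drift in ten-row column sums.

## Known limitations

- Orthorhombic boxes only; no trajectory alignment or fitting.
- The enthalpy module cannot detect a wrong upstream energy split.
- RAD shell construction is O(n²) per frame in united atoms — adequate
  for the tested scales, not for production solvation boxes.
- Conformer detection on 30° bins cannot resolve peaks closer than one
  bin, by construction of the discretisation.
- Titration is integer-valued; fractional protonation near a pKa is out
  of scope.
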