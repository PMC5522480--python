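# Methods

`helixsans` re-implements, as a tested pipeline on synthetic data, the
quantitative analyses used to establish that protonation of side-chain
1,2,3-triazoles drives a coil-to-helix transition in cationic
polypeptides: helix-geometry and hydrogen-bond analysis of peptide
conformations, hydration-shell radial distribution functions, and
contrast-variation small-angle neutron scattering (SANS) modelling with a
water-volume-fraction estimator. This note records the models, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices.

## The model system

The peptide is a homopolymer whose every residue carries a long flexible
side-chain ending in a quaternary trimethylammonium (+1 e, pH-independent
solubiliser) with a hydrogen-bonding ligand part-way along the chain. The
ligand's donor/acceptor roles are the science:

| ligand            | donors            | acceptors | pattern |
|-------------------|-------------------|-----------|---------|
| amide             | N-H               | C=O       | binary (BHB) |
| ester             | -                 | C=O       | unitary, acceptor-only |
| 1,2,3-triazole    | C5-H              | N3        | binary (BHB) |
| 1,2,3-triazolium  | N3-H, C5-H        | -         | unitary, donor-only |

Binary-pattern side-chains compete with the backbone's own i -> i+4 amide
ladder and destabilise the helix; protonating the triazole at N3 (pKa near
4.1 on the polymer) removes the acceptor, and the backbone refolds. The
topology model (`peptide_model`) tracks exactly this: per-residue
protonation flags, formal charges (+1 per ammonium, +1 per triazolium,
zwitterionic termini cancelling), and donor/acceptor site tables. A
10-mer is +10 e neutral and +20 e fully protonated. Side-chain atoms
beyond the H-bond sites and the charged terminus are coarse linker
pseudo-atoms: the analyses need only backbone atoms, ligand sites, charges
and excluded volume, so no force-field topology is carried.

## Synthetic conformations and trajectories

C-alpha traces are generated exactly: ideal helices on a cylinder (defaults
radius 0.23 nm, twist 100 deg, rise 0.15 nm - the canonical ideal
alpha-helix; virtual C-alpha bond 0.38 nm) and random coils as fixed-step
self-avoiding walks (step 0.38 nm, non-bonded minimum separation 0.4 nm).
Backbone N/H/C/O atoms are placed from the C-alpha trace by fixed offsets
in a local frame (tangent, inward bisector, their cross product). The
offsets were calibrated once against an alpha-helical backbone built from
standard internal coordinates (phi = -57 deg, psi = -47 deg), so a
generated ideal helix carries the full i -> i+4 hydrogen-bond ladder: an
n-mer has exactly n - 4 backbone-backbone bonds under the default
criterion, hence 4 free N-H groups at the N-terminus and 4 free C=O at the
C-terminus - the dangling-end counts the analyses report.

Trajectories are ensembles, not dynamics: `stable_helix` / `stable_coil`
perturb one reference with isotropic Gaussian noise (default per-axis
amplitude 0.025 nm, chosen so the helical-state C-alpha RMSD to the ideal
helix sits near 0.04 nm, the magnitude the folded state shows), and
`folding` interpolates linearly from an aligned coil to the helix,
completing at 40 % of the run. Water is geometric: rigid O + 2 H
(0.1 nm, 104.5 deg) placed uniformly in a cubic periodic box (default
6 nm, a size that comfortably hosts the 10-mer; the number of waters is
set by the sampling the analyses need, not by liquid density), excluding a
configurable depletion sphere around the backbone centre of mass and
0.25 nm clashes with peptide atoms. A water within H-bond range of a
peptide acceptor points one O-H at it, emulating first-shell orientational
ordering - without this, randomly oriented water would almost never pass a
20-30 deg angle criterion and the backbone-water statistics of real
simulations could not be reproduced. The generator does **not** emulate
water-water structure, residence times, side-chain conformational
sampling, or any energetics; passing tests show the *analyses* are
correct on data with planted structure, not that the physics of folding is
reproduced.

## Helix geometry

Axis estimation: second differences of consecutive C-alpha positions are
exactly perpendicular to the axis of a circular helix, so the axis is
taken as the least-significant right singular vector of the stacked second
differences, the centre from an algebraic (Kasa) circle fit of the
projected points, and both are refined by nonlinear least squares
minimising the spread of perpendicular distances. This is exact on
noiseless input and robust under thermal noise. Radius = mean
perpendicular distance; twist = mean signed rotation of consecutive radial
vectors about the axis (right-handed positive; the magnitude is reported,
the sign as a handedness flag); rise = mean axial step. RMSD to the ideal
helix superposes an equal-length ideal reference by the Kabsch
least-squares rotation, per frame (whether the original analysis
superposed per frame or against a fixed orientation is not stated;
per-frame optimal superposition is standard practice). Chain-end exclusion
defaults to two residues per end for noisy data, zero for exact synthetic
helices. A collinear trace is returned flagged with radius 0 rather than
raising.

## Hydrogen bonds

Geometric criterion: donor-acceptor distance <= 0.35 nm and
hydrogen-donor-acceptor angle <= 30 deg - the conventional MD-analysis
defaults, config-exposed because the original work reports counts but no
criterion. One bond per donor hydrogen per frame (closest acceptor wins,
ties to the lower atom id) prevents double counting in dense water.
Covalently connected pairs are excluded: atoms of one water, atoms of one
residue, and backbone atoms of adjacent residues (the amide N and the
preceding carbonyl are directly bonded). Donor/acceptor eligibility comes
from the ligand table: a triazolium N3 never accepts; an ester only
accepts. Bonds are classed backbone-backbone (B-B), backbone-water (B-W),
backbone-side-chain (B-S) or other; per-residue statistics divide
per-frame class counts by the number of included residues, with excluded
terminal residues contributing neither bonds nor denominator. Whether the
reported per-residue histograms excluded termini is not stated; the
exclusion count is a parameter.

## Hydration

g(r) between the per-frame mass-weighted backbone centre of mass and water
oxygens, with minimum-image distances in the cubic box, bin width 0.04 nm,
normalised by shell volume times the mean instantaneous water density so a
uniform ideal gas gives g = 1. Errors by block averaging over five
contiguous blocks (standard error = s.d. across blocks / sqrt(n_blocks));
a single block is flagged with zero errors. The depletion radius is the
lower edge of the first bin reaching g >= 0.1 - a near-zero threshold
chosen because none is stated; the planted exclusion radius is recovered
within one bin. Note that with the molecular clash exclusion active the
measured depletion zone reflects the peptide's excluded volume (~0.45 nm
for the compact helix), which is the physically meaningful signal;
planted-radius recovery tests disable the clash term.

## SANS forward model and fitting

I(q) = scale * phi * P_cyl(q) * S_HP(q) + A q^-n + B, with q in 1/A,
lengths in A, SLDs in 1e-6 A^-2 and I in 1/cm.

* **Form factor**: orientationally averaged cylinder,
  f = contrast * V * sinc(q L cos a / 2) * 2 J1(q R sin a)/(q R sin a),
  averaged with weight sin a over a in [0, pi/2] by 76-point
  Gauss-Legendre quadrature (config-exposed), returned as f^2/V so
  P(q -> 0) = contrast^2 V.
* **Structure factor**: rescaled mean-spherical approximation (RMSA) for
  charged hard spheres with a screened-Coulomb tail, evaluated at the
  cylinder's equivalent-volume-sphere diameter (direct product coupling;
  the decoupling beta(q) correction for non-spherical particles is a known
  omission). The contact potential is gamma = Z^2 l_B / (d (1 + k/2)^2),
  k = d / lambda_Debye; screening is given either as a Debye length or as
  ionic strength + temperature + dielectric, exactly one. The MSA closure
  (g = 0 inside the core, c = -beta u outside) is solved numerically from
  the Ornstein-Zernike equation on a dimensionless grid (512 points per
  diameter, range 32 diameters) with sine-transform convolutions and
  Anderson-accelerated fixed-point iteration, ramping the coupling from
  zero; whenever the contact value of g is negative the Hansen-Hayter
  rescaling maps to effective spheres of larger diameter (same density,
  same physical tail) chosen by bisection so g(contact) = 0. The Z = 0
  limit reproduces the analytic Percus-Yevick solution - kept in the code
  as an independent closed form - to 1e-4 across q d in [0.1, 20] up to
  phi = 0.4. Below phi = 1e-6 the solver short-circuits to S = 1 (the
  rescaling is ill-posed as the density vanishes and the correction is
  negligible). Very strong coupling at high packing (e.g. gamma ~ 50 at
  phi = 0.4) can lack a reachable solution and raises rather than
  returning a wrong answer. Solver inputs are quantised to four
  significant digits so repeated evaluations during fitting hit an LRU
  cache.
* **Water SLDs**: derived from coherent scattering lengths (b_D = 6.671,
  b_H = -3.739, b_O = 5.803 fm) over a 30 A^3 molecular volume:
  6.382e-6 A^-2 (D2O) and -0.558e-6 A^-2 (H2O); solvent mixes linearly in
  volume fraction. A hydrated particle has SLD
  phi_water * SLD_solvent + (1 - phi_water) * SLD_dry.

Fitting is bounded trust-region least squares weighted by 1/sigma
(finite-difference Jacobian, five jittered starts against the P*S
landscape's local minima). During each inner optimisation S(q) is held
fixed and then recomputed at the fitted geometry, iterating to
self-consistency (at most 4 passes) - at the dilute fractions this model
targets S barely moves with geometry, and a full RMSA solve per step would
dominate runtime. In the simultaneous multi-contrast fit the geometry
(R, L) and power-law exponent are shared, while particle SLD, power-law
amplitude and background are per-curve; volume fraction, charge, screening
and the intensity scale are held fixed by default because scale is exactly
degenerate with the particle SLD and the interaction parameters are not
determined by dilute data (all config-exposed). The water fraction is the
ordinary-least-squares slope of fitted particle SLD against solvent SLD
across contrasts; the intercept gives the dry SLD as intercept/(1 - phi);
a slope outside [0, 1] is clipped and flagged. Because intensity depends
on contrast squared, each curve's SLD has a mirror solution 2 * s - p with
identical chi^2; after the joint fit the per-curve branches are reconciled
by choosing the combination that makes particle SLD linear in solvent SLD
with a slope inside [0, 1] (maximum r^2) - the contrast-variation
consistency a practitioner imposes by hand.

Synthetic beam data use the instrument q range 0.0057-0.32 1/A, three
contrasts (100/75/50 % v/v D2O) and 2 % relative Gaussian noise. The two
presets encode the measured states: radius 13 A with length 75 A and
phi_water 0.51 (acidic, helical) versus length 62 A and phi_water 0.59
(basic, coil); dry SLD 2.0e-6 A^-2 (a generic protonated organic
polymer), volume fraction 0.005, effective charge 20 e, Debye length 30 A
(plausible values - the originals are unpublished - treated as fixed
nuisance parameters in fits). The additive power law uses exponent 3.6
and an amplitude chosen so it dominates below ~0.017 1/A, as the measured
curves show.

## Titration

Protonated fraction f(pH) = 1/(1 + 10^(pH - pKa)), simulated with optional
Gaussian noise clipped to [0, 1] and fitted by least squares. Flat curves
(span < 0.2) and fractions increasing with pH are flagged instead of
silently fitted. The default planted pKa is 4.1. Whether intermediate pH
should imply partially protonated ensembles is left to the caller: the
topology exposes a per-residue flag (`set_protonation`).

## Problem sizes and reproducibility

All randomness flows through `numpy.random.default_rng` seeds; generators
are bit-reproducible, and pipeline reports echo the resolved configuration
and hash so identical config + seed reproduces a report byte for byte.
The shipped tests and the acceptance script run at desk scale: 10-mer
peptides, hundreds to a few thousand waters per frame, tens of frames,
80-point q grids, ten-seed recovery ensembles - sizes chosen so each check
isolates one property with comfortable statistics.

## Known limitations

* Backbone reconstruction from C-alpha traces uses helical-frame offsets;
  on random coils the inter-residue bonded geometry is approximate (hence
  the covalent-neighbour exclusion in H-bond detection).
* The folding trajectory is a geometric interpolation; no kinetics or
  energetics are implied.
* The structure-factor coupling ignores the decoupling correction for
  cylinders, and the numerical RMSA truncates the Yukawa tail at 32
  diameters (inaccurate only for extremely weak screening, k << 0.1).
* Instrument resolution smearing and polydispersity are out of scope; the
  synthetic curves are generated without them.
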