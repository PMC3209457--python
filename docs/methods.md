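# Methods

## The model

`motifdyn` represents a folded protein as an anisotropic elastic network
(ANM) over its Cα sites: every pair of sites within a cutoff r_c interacts
through a Hookean spring, and the potential is the second-order expansion
of the total spring energy about the input coordinates.  The input
structure is therefore the energy minimum *by construction* — no
minimization precedes the normal-mode analysis, which is the decisive
practical advantage of the elastic network over force-field NMA.  The
assumptions this buys:

* fluctuations are harmonic and small; anharmonic transitions, unfolding
  and side-chain rearrangements are outside the model;
* one isotropic spring constant describes all native contacts; chemistry
  enters only through the contact topology and the mutation perturbation;
* solvent appears solely as friction and thermal noise in the Langevin
  dynamics — no hydrodynamics, no explicit water.

What the model is good for is precisely what this package asks of it:
*relative* statements about collective motion — which residues move
together, where flexibility concentrates, and how a local perturbation
shifts those patterns.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `cutoff` (r_c) | 13.0 | Å | common Cα-ANM practice; large enough that compact folds are rigid (exactly 6 zero modes), small enough to keep contact maps sparse-ish |
| `gamma` (γ) | 1.0 | energy/Å² (arbitrary) | sets the overall energy scale only; all reported quantities are either γ-normalized or carry an arbitrary prefactor |
| `masses` | 1.0 per site | arbitrary | with uniform masses, mass-weighted diagonalization reduces to the plain Hessian; per-residue masses are accepted for fidelity experiments |
| `n_modes` | 50 | — | number of lowest nonzero modes entering the correlation map; clamped (with a warning) on systems with fewer internal modes |
| `spring_scale` | 0.5 | — | mutation model: multiplies every spring incident to the mutated site; 0.5 encodes "roughly half the local packing interactions lost", the package's stand-in for a hydrophobic→hydrophilic substitution |
| `timestep` (Δt) | 0.01 | reduced time | keeps λ_max·Δt/ζ ≪ 2 (Euler–Maruyama stability) with a comfortable margin on all shipped fixtures |
| `n_steps` | 200 000 | steps | with `save_every=100` gives 2 001 frames; trailing-half analyses then average hundreds of correlation times of the slowest modes |
| `kT` | 1.0 | reduced energy | fluctuation scale; B-factors are reported with an arbitrary prefactor, so only ratios and correlations are meaningful |
| `friction` (ζ) | 1.0 | reduced | sets the time scale only |
| `window` | 0.5 | fraction | "analyze the trailing half of the run" convention for mean RMSD and windowed B-factors |

The correlation map accumulates the covariance with each mode weighted by
1/λ_k (the thermal covariance truncated to the requested modes).  An
equal-weight per-mode average is exposed as
`weighting="equal"` for comparison with conventions that average
normalized per-mode correlations; the 1/λ weighting is the default because
it is the one with a closed-form ground truth (the Hessian pseudo-inverse
when all modes are used), which the test suite exploits.

Mutations at both endpoints of the same contact multiply their scales; a
single mutation rescales each incident spring once.

## Langevin sampling and rigid-body modes

The integrator is Euler–Maruyama Brownian dynamics on the network
potential.  One deliberate deviation from the textbook scheme: by default
the thermal noise is projected onto the internal-mode subspace
(`remove_rigid_motion=True`).  The linearized network exerts no restoring
force along the six rigid-body modes, so unprojected noise makes their
amplitudes diffuse without bound — and because a *finite* displacement
along an infinitesimal-rotation mode is a shear, not a rotation, that
drift distorts the molecule in a way no rigid-body superposition can
remove afterwards (a two-site network's bond length random-walks tens of
Å over a standard run).  Projection is the coarse-grained analogue of the
center-of-mass motion removal every MD engine applies, and it makes the
sampler's stationary distribution exactly the Boltzmann distribution of
the internal modes — which is what lets the test suite assert
equipartition (trajectory B-factors vs. NMA B-factors) quantitatively.
Setting `remove_rigid_motion=False` recovers the unprojected scheme.

The Euler–Maruyama discretization biases each mode's stationary variance
by a factor 1/(1 − λΔt/2ζ); at the default timestep this is ≤ ~1% on the
modes that dominate B-factors, well inside the 5–10% tolerances the tests
use.

## Trajectory statistics

RMSD series are measured against the starting conformation after a
least-squares (Kabsch) superposition.  Two motif conventions are provided
and neither is privileged: `fit_all` (superpose on all Cα, measure over
the motif — motif motion relative to the frame counts) and `fit_motif`
(superpose on the motif itself — internal deformation only).  `fit_all`
is the default, matching common MD-analysis practice.

Windowed B-factors superpose each window frame onto the iteratively
refined mean structure (3 rounds of fit → re-average), then report
(8π²/3)⟨|r_i − ⟨r_i⟩|²⟩.  Whole-structure fitting is used; per-domain
fitting is not implemented.  The 2-site system, whose Kabsch problem is
underdetermined, is fitted by centroid matching plus the minimal rotation
aligning the inter-site vectors — the exact least-squares solution there.

## Synthetic structures

The generators produce the geometric situations the analysis assumes,
with none of the biochemical detail it ignores:

* `helix` — ideal α-helical Cα trace (rise 1.5 Å/residue, twist 100°,
  radius 2.3 Å, giving the canonical 3.8 Å virtual bond);
* `helix_loop_helix` — two packed antiparallel helices (axes 9 Å apart)
  joined by a 4-residue loop; the loop is recorded as the default "motif"
  and the last residue of the first helix as the suggested motif-adjacent
  mutation site.  This emulates a cofactor-binding segment sitting on the
  connector between secondary-structure elements;
* `cloud` — uniform points in a sphere with a 3.5 Å minimum-separation
  rejection rule, a fold-free control at realistic packing density.

Every generated fixture yields a connected network with exactly six zero
modes at the default cutoff, and all generation is deterministic given the
seed.  What these fixtures do **not** emulate: real secondary-structure
heterogeneity, side-chain packing, sequence-dependent contact energies,
or the size of a real protein domain.  Passing tests therefore demonstrate
that the machinery is correct and that the spring-weakening mutation model
behaves directionally as designed — not that any particular real mutation
is destabilizing.

## Numerical choices

* Zero modes are identified by |λ| < 10⁻⁸·λ_max; more than six means a
  floppy network and is an error, not a warning.
* The contact graph must be connected at the chosen cutoff; disconnection
  raises an error suggesting a larger cutoff rather than silently
  producing spurious zero modes.
* Collinear structures are rejected (the pair potential leaves transverse
  motion unrestrained), with one exception: the 2-site dimer is admitted
  as the closed-form reference case (one stretch mode at 2γ, five
  rigid-body modes).
* A single integration step displacing any coordinate by more than 10³
  reduced length units aborts the run with the offending step named.
* Superposition refuses reflections (proper rotations only) and refuses
  collinear references, where the rotation is underdetermined.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; the pipeline derives per-variant seeds from the configured
  base seed with a fixed affine map, and records them in the report's
  provenance block.

## Problem sizes

The shipped tests and the acceptance script run on 2–60-site networks,
with Langevin runs of 20 000–200 000 steps; at these sizes the full suite
and the acceptance script each complete in well under a minute on one
core.  These sizes were chosen because every assertion made at them has a
closed-form or brute-force ground truth; nothing in the implementation is
specific to them, and the same code runs unchanged on a ~600-residue
single-chain Cα model (the Hessian is then 1800×1800, still comfortable
for dense diagonalization).

## Known limitations

* Cα-only: minimum distances between selections are backbone-level and
  systematically longer than all-atom closest-contact distances; the CLI
  help says so.
* The spring-scale mutation model captures "weakened local packing" with
  a single dial; it cannot distinguish chemically different substitutions
  at the same site, and its default (0.5) is a modeling choice, not a
  fitted constant.
* Insertion codes and mmCIF input are unsupported; multi-chain selections
  must name their chain.
* B-factors and RMSDs are in reduced units with arbitrary prefactors —
  comparisons are meaningful within a run (wild type vs. mutant), absolute
  values are not experimental B-factors.
* The harmonic model cannot show the *mechanism* of FAD-type cofactor
  release or any other binding event; it shows changed flexibility and
  coupling, which is evidence for, not proof of, a functional effect.
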