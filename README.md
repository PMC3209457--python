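# motifdyn

Coarse-grained structural dynamics for a recurring question in molecular
disease genetics: a missense mutation sits *near* a protein's functional
motif — a cofactor-binding loop, say — without touching it directly, so how
could it impair function?  One mechanistic answer is dynamic: the mutation
perturbs the packing around the motif and changes the motif's flexibility
and collective motion rather than its static structure.  `motifdyn` makes
that hypothesis computable at the Cα level for anyone with a PDB file, a
motif residue range, and a list of mutation sites.

The package targets structural bioinformaticians and clinical-genetics
researchers who want a fast, fully reproducible screen before (or instead
of) committing to all-atom simulations.

## Model

The protein is an **anisotropic elastic network**: one site per Cα, with a
Hookean spring of constant γ between every pair of sites closer than a
cutoff r_c (default 13 Å).  The second-order expansion of the network
energy about the input structure gives the 3N×3N Hessian **H** with, per
contact, the super-element

    H_ij = − γ_ij (d_ij d_ijᵀ) / |d_ij|²,     d_ij = r_i⁰ − r_j⁰,

and diagonal blocks minus the row sums.  Diagonalizing the mass-weighted
Hessian M^(−1/2) H M^(−1/2) yields six zero-frequency rigid-body modes and
3N−6 internal modes (λ_k, u_k).  From the lowest nonzero modes the package
computes the standard NMA observables:

* **cross-correlation map** C_ij = K_ij / √(K_ii K_jj) with
  K_ij = Σ_k u_k,i·u_k,j / λ_k summed over the n lowest nonzero modes
  (n = 50 by default) — +1 is concerted motion, −1 anti-correlated motion;
* **B-factors** B_i = (8π²/3) k_BT K_ii;
* a **coupling score**: the mean |C_ij| between a mutation site and the
  motif residues.

A **point mutation** enters as a perturbation of the network: every spring
incident to the mutated site is rescaled by `spring_scale` (default 0.5,
modeling the weakened hydrophobic packing of a hydrophobic→hydrophilic
substitution).

On the same potential, **overdamped Langevin (Brownian) dynamics**

    x ← x − (Δt/ζ) H (x − x₀) + √(2 k_BT Δt/ζ) η

generates trajectories whose stationary distribution is exactly the
Boltzmann distribution of the harmonic model, so every trajectory
statistic — RMSD vs. the starting conformation (whole chain or motif),
trailing-window means, windowed B-factors — can be validated against the
mode spectrum in closed form.  Wild type and mutants are compared as
deltas under paired random seeds.

A small `popgen` module supplies the Hardy–Weinberg arithmetic
((1−p)², 2p(1−p), p²) used to translate a recessive allele frequency into
carrier and affected-homozygote rates.

## Worked example

Everything below runs in a few seconds with no input files; the structure
is a generated helix–loop–helix toy whose 4-residue connector loop plays
the role of the binding motif (residues 19–22), with a mutation at the
adjacent residue 18.

```text
$ motifdyn synth --kind helix_loop_helix -n 40 -o toy.pdb
motif residues: 19-22
suggested mutation site: 18
wrote 40 sites to toy.pdb

$ motifdyn nma toy.pdb --motif 19-22 --site 18 --site 30
40 sites, 114 nonzero modes (50 used), 6 zero modes
mean motif B-factor (NMA): 75.853166
coupling(residue 18 ↔ motif): 0.093869
coupling(residue 30 ↔ motif): 0.187045
```

The network is rigid (exactly 6 zero modes), and the coupling scores show
that even residue 30 — far in sequence, but packed against the loop in the
second helix — moves with the motif more strongly than the sequence
neighbour: exactly the kind of long-range dynamic coupling the model is
built to surface.

The full pipeline compares wild type against mutants from a YAML config:

```yaml
structure: toy.pdb
motif: {start: 19, stop: 22}
mutations:
  - {residue: 18, from: A, to: T, spring_scale: 0.5}
simulation: {n_steps: 20000, save_every: 50, seed: 1}
output_dir: out
```

```text
$ motifdyn run config.yaml
report written to out/report.txt
          delta_coupling  delta_mean_motif_bfactor_nma  delta_mean_motif_rmsd  ...
variant
Ala18Thr       -0.015739                      2.575286               0.013527  ...
```

Weakening the springs at residue 18 raises the motif's NMA B-factor
(+2.58 on a wild-type mean of 75.85, i.e. +3.4%) and its trailing-window
motif RMSD (+0.014 Å): the mutant motif is more mobile.  Single-trajectory
quantities fluctuate seed to seed; the test suite asserts the direction on
5-seed ensemble means.  Every number in `out/report.txt` is traceable to a
CSV in `out/`, and the provenance block records the config hash and the
per-variant seeds.

The population-genetics side:

```text
$ motifdyn hw --allele-freq 0.004
convention            rare_approx
allele_freq           0.004
carrier_freq          0.008  (1 in 125)
homozygote_freq       1.6e-05  (1 in 62500)
```

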