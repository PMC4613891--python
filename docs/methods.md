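# Methods

## The model

The Electronegativity Equalization Method (EEM) assigns every atom an
effective electronegativity that is linear in the partial charges and
requires all of them to be equal at equilibrium. With per-atom-type
electronegativity parameter `A_i`, hardness parameter `B_i`, a set-level
coupling constant `kappa` and interatomic distances `R_ij` in Angstrom,
the charges `q_i` (units of the elementary charge e) solve

    B_i q_i + kappa * sum_{j != i} q_j / R_ij  -  chi_bar = -A_i   for each atom i
    sum_i q_i = Q

where `chi_bar` (the equalized molecular electronegativity) is an unknown
solved alongside the charges and `Q` is the total molecular charge. Writing
`lambda = -chi_bar` makes the (N+1)-dimensional augmented system symmetric:
the charge block `B + K` (with `K_ij = kappa / R_ij`, zero diagonal) is
bordered by a row and column of ones and an exactly zero corner. The full
solver assembles this dense matrix and factorizes it directly (LAPACK
symmetric-indefinite solve): O(N^3) time, O(N^2) memory. EEM charges are
conformationally sensitive by construction — they depend on all pairwise
distances — and inherit EEM's known polarizability exaggeration: charge
separation across a large system is overestimated relative to quantum
references, which is why analyses of large systems should compare
conformers rather than read single-conformer charges literally.

Parameters are *empirical*: each set is fitted elsewhere against a
particular QM level and molecule class, and has a matching applicability
domain. This package treats parameter sets as data (an XML schema with
element- or bond-order-granular entries), validates them, and checks
applicability before any solve. The shipped built-in sets are synthetic
(generated; see below) and say so in their provenance strings: fitted
literature values must be imported by the user as XML.

## Fragment solvers

For tens of thousands of atoms the dense solve is impractical, so two
fragment approximations are provided.

**Cutoff.** For each atom, a fragment collects all atoms within radius `R`
(uniform cell grid, cell edge `R`, 27-cell scan; near-linear construction).
Each fragment's EEM system is solved with its own total-charge constraint
and the *central* atom keeps its charge. Fragment systems are small
(~ 4/3 pi R^3 rho atoms), so memory never exceeds the largest fragment's
system and time is linear in N for fixed R.

The one free choice is the fragment's total-charge constraint, and it
matters more than anything else in the scheme. A constrained fragment solve
is insensitive to any *uniform* shift of the surrounding electrostatic
potential (the shift is absorbed into the fragment's chi_bar), so the
residual error is dominated by how much charge the constraint forces into
the fragment. Two passes are therefore used:

1. *Proportional pass*: fragment charge `Q * m / N` for an `m`-atom
   fragment. This preserves neutrality for neutral systems but ignores
   where the equilibrium actually puts charge.
2. *Refinement pass* (default): every fragment is re-solved with its charge
   constraint set to the sum of pass-1 charges over its members — a
   self-consistent estimate of the charge the full solution places inside
   the fragment.

On the synthetic benchmark globules (below), the refinement pass reduces
the maximum deviation from full EEM by roughly a factor of three (e.g.
0.042 -> 0.013 e at 8 A on a 2,000-atom globule) and brings the method
inside the accuracy envelope expected of cutoff-type EEM solvers: at
10,000 atoms, max |dq| ~ 0.015 e / mean ~ 0.002 e at 8 A and
max ~ 0.007 e / mean ~ 0.0006 e at 12 A. Accuracy improves monotonically
with the radius and becomes exact (1e-9 e) once the radius covers the
molecular diameter. Additional passes converge to the scheme's fixed point
without consistent further gain (and can slightly worsen large radii, whose
pass-2 result already sits near the fixed point), so the default is
`passes=2`; `passes=1` gives the plain proportional scheme.

Assembled fragment charges do not conserve `Q` exactly. The residual
`sum(q) - Q` (typically well below 1e-3 e per atom equivalent) is reported
in the job tag and *not* redistributed by default, because renormalization
would distort exactly the per-atom deviations one wants to inspect;
`redistribute_residual=True` spreads it uniformly when a strictly
conserving set is required.

**Cover.** Fragments are built only for a covering subset of atoms: a
greedy scan in input order makes an atom a center unless it is already
within `R/2` of one, and every atom then takes its charge from its nearest
center's fragment (ties to the lower center index). Every atom sits within
`R/2` of its assigned center — well inside that fragment — which is what
keeps accuracy close to Cutoff. At liquid-like densities an `R/2` ball
holds tens of atoms, so the number of solved systems falls far below N/2
(about 1-2 % of N on the benchmark globules, ~10 % on a 1.5 A-spaced
chain at 8 A). The same two-pass charge scheme applies.

## Synthetic study systems

The globule generator places `n` points uniformly in a sphere whose radius
follows from the target density (`R = (3n / 4 pi rho)^(1/3)`),
rejection-sampling to keep all pairs at least `min_separation` apart, and
draws elements i.i.d. from a fixed frequency table. Defaults: density 0.1
atoms/A^3, minimum separation 1.0 A, H/C/N/O at 0.5/0.3/0.1/0.1 — the
packing regime of a protein interior. Pseudo-residues of 10 atoms give
deterministic aggregation structure. The generated parameter sets draw
A ~ U[2, 8], B ~ U[6, 14], kappa ~ U[0.3, 0.6]; systems built from them are
well conditioned (condition numbers ~ 10-100 in a survey over seeds).

What these fixtures do *not* emulate: bonds and chemically structured
element placement (hydrogens attached to heavy atoms, locally
quasi-neutral residues). Real molecules are locally better charge-balanced
than an i.i.d. element cloud, so fragment-method errors measured here are,
if anything, conservative for real structures; conversely, nothing here
validates parameter-set quality against QM references — that is the job of
fitted literature sets, which are out of scope. A chain generator (uniform
spacing, collinear) provides analytically checkable neighbor counts and
degenerate fragment cases.

Two independent oracles guard the solvers: a pure-Python matrix build +
textbook Gaussian elimination (never sharing code with the production
path), and the closed-form diatomic solution
`q1 = (A2 - A1 + Q (B2 - kappa/R)) / (B1 + B2 - 2 kappa/R)` obtained by
symbolic elimination.

## Numerical choices

* Degenerate geometry: any pair closer than 1e-4 A (below real coordinate
  precision) is rejected before assembly, naming both atoms.
* 64-bit solves verify a relative residual <= 1e-8 and charge conservation
  to 1e-6 e; 32-bit mode assembles and factorizes in single precision (the
  memory-saving option) and reports results in 64-bit containers, agreeing
  with 64-bit to ~1e-4 e on hundred-atom systems.
* The constraint corner of the augmented matrix is written exactly 0; the
  charge-conservation unit test exists specifically because a wrapped
  diagonal fill writing `B_0` into that corner produces a plausible-looking
  but non-conserving solution.
* Statistics use the population standard deviation (`ddof=0`); comparison
  correlations on a constant vector are NaN with an explicit
  `correlation_defined=False` flag; Spearman uses average ranks on ties.
* Cross-validation follows the repeated-random-subsampling protocol
  (k independent rounds of `train_size` draws without replacement,
  validating on the remainder); classical disjoint folds are available as
  `mode="disjoint"`.

## Problem sizes used in the checks

`scripts/acceptance.py` runs the benchmark at its natural scale: three
10,000-atom globules (seeds derived from `--seed`), full EEM vs Cutoff at
8 A and 12 A, plus cover-center selection on the globules and a
10,000-atom chain (spacing 1.5 A) — about ten minutes on one CPU. The test
suite repeats the same contract on one 10,000-atom globule and uses
1,000-2,000-atom fixtures for property tests (radius monotonicity, cover
economy, memory bounds), keeping the whole suite within a few minutes.

## Known limitations

* Fragment methods conserve total charge only approximately (residual
  reported, optional redistribution).
* The Cover assignment is greedy and input-order dependent; it guarantees
  coverage and the R/2 bound but not minimality.
* Element inference for formats without element columns follows PDB v3
  name-alignment rules and fails loudly on ambiguity rather than guessing.
* mmCIF reading is delegated to gemmi and lightly exercised; PQR and MOL2
  use this package's own dialects, documented in `eemkit.io`.
* Multiplicity-granular (bond-order) parameter sets require inputs with
  bond blocks (MOL/SDF/MOL2); PDB/PQR inputs must use element-granular
  sets.
* The shipped QSPR model file is synthetic (workflow demonstration only);
  real pKa prediction requires a literature-fitted model supplied as JSON.
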