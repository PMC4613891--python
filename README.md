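# eemkit

Empirical partial atomic charges that respond to molecular conformation,
via the Electronegativity Equalization Method (EEM) — for structural
bioinformatics and molecular-modelling workflows that need per-atom,
per-residue or per-subunit charges for systems from drug-like molecules to
biomacromolecular complexes, without a quantum-chemistry calculation.

EEM equates every atom's effective electronegativity to a common molecular
value χ̄, which turns charge assignment into a linear system: with
electronegativity and hardness parameters A_i, B_i per atom type, coupling
constant κ, and distances R_ij in Å,

    B_i q_i + κ Σ_{j≠i} q_j / R_ij − χ̄ = −A_i ,    Σ_i q_i = Q .

The package provides:

* **Full EEM** — dense symmetric solve of the (N+1)×(N+1) system
  (O(N³) time, O(N²) memory), 64- or 32-bit.
* **EEM Cutoff** — one small EEM system per atom over its neighbors within
  a cutoff radius; linear in N at fixed radius, never allocates an N²
  matrix. A two-pass fragment-charge scheme keeps deviations from the full
  solve at the 0.01 e level at 8 Å and below 0.008 e at 12 Å on
  10,000-atom test systems.
* **EEM Cover** — fragments only for a greedy covering subset (typically a
  few percent of N; guaranteed ≤ N/2 at realistic densities), for systems
  with hundreds of thousands of atoms.
* Structure I/O (PDB, mmCIF, PQR, MOL, MOL2, SDF), water stripping,
  charge-annotated output (MOL2 `USER_CHARGES`, PQR, plain table).
* EEM parameter sets as validated XML (element- or bond-order-granular),
  applicability checking, automatic set selection, and parameter aliasing
  (e.g. giving deuterium the hydrogen parameters).
* Charge analysis: residue/group sums, descriptive statistics, and
  pairwise comparison (R², Spearman, RMSD, sum of absolute differences).
* A QSPR pKa workflow: linear models over named charge descriptors,
  dissociated-form construction, OLS fitting, repeated-random-split
  cross-validation, and Henderson–Hasselbalch ionization fractions.
* A `eemkit` CLI: config-driven batch runs plus `charges`, `compare`,
  `stats` and `pka` commands.

The built-in parameter sets and the shipped QSPR model are **synthetic**
(clearly labelled in their provenance): they exercise every code path and
match the value ranges of protein-applicable sets, but literature-fitted
sets/models must be supplied by the user as XML/JSON for production use.

## Worked example

```python
import numpy as np
from eemkit import (GlobuleSpec, generate_globule, generate_parameter_set,
                    solve_full_eem, solve_eem_cutoff, residue_charges,
                    compare_charge_sets)

# a 2,000-atom synthetic globule at protein-like density, and a seeded
# protein-like parameter set
mol = generate_globule(GlobuleSpec(n_atoms=2000, seed=2))
params = generate_parameter_set(["H", "C", "N", "O"], seed=2)

full = solve_full_eem(mol, params, total_charge=0)
cut = solve_eem_cutoff(mol, params, total_charge=0, radius=8.0)

print(f"sum(q) full  = {full.total():+.2e} e, chi_bar = {full.chi_bar:.3f}")
print(f"sum(q) cutoff= {cut.total():+.2e} e (residual reported, not hidden)")
dev = np.abs(cut.values - full.values)
print(f"cutoff vs full at 8 A: max {dev.max():.4f} e, mean {dev.mean():.4f} e")
m = compare_charge_sets(cut, full)
print(f"R^2 = {m.r_squared:.6f}, RMSD = {m.rmsd:.5f} e")
rc = residue_charges(mol, full)
print(f"{len(rc)} residues, most positive residue charge {rc.values.max():+.3f} e")
```

prints

```
sum(q) full  = -2.76e-13 e, chi_bar = 4.791
sum(q) cutoff= -1.74e+00 e (residual reported, not hidden)
cutoff vs full at 8 A: max 0.0135 e, mean 0.0029 e
R^2 = 0.999745, RMSD = 0.00361 e
200 residues, most positive residue charge +1.572 e
```

i.e. the full solve conserves the total charge to machine precision, the
8 Å cutoff approximation tracks it to a few thousandths of an elementary
charge per atom (R² ≈ 0.9999 against the dense solve), and residue-level
aggregation is available for coarse-grained electrostatic analysis.

From the shell:

```sh
eemkit charges protein.pdb --method cutoff --radius 12 --charge 7 -o out/
eemkit compare out/protein-charges.mol2 other_charges.mol2
eemkit pka --model model.json --molecule phenol.pdb --map q_HO=HO4,q_O=O4,q_C=C4
```

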