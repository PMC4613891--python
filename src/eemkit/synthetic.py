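"""Synthetic molecules, parameter sets and QSPR data for testing at scale.

The globule generator emulates the one feature of biomacromolecules that
drives EEM's computational behaviour: many atoms at liquid-like packing
density (default 0.1 atoms/A^3, about what a protein interior has) with a
realistic minimum interatomic separation. It makes no attempt at bonding,
secondary structure or chemically sensible element placement -- fragments,
neighbor searches and dense solves do not care, and the parameter layer is
exercised through element-granularity sets exactly as with PDB inputs.

Also home to deliberately naive reference implementations (textbook Gaussian
elimination on an independently hand-built matrix) used as oracles in tests;
they share no code with :mod:`eemkit.core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ChargeSet, JobTag
from .errors import PackingError
from .molecule import Atom, Molecule, Residue
from .parameters import AtomTypeKey, EEMParameterSet
from .qspr import DescriptorVector, QSPRModel

_DEFAULT_FREQS = {"H": 0.5, "C": 0.3, "N": 0.1, "O": 0.1}

#: Atoms per pseudo-residue in generated molecules (fixed so residue
#: aggregation tests have a deterministic group structure).
PSEUDO_RESIDUE_SIZE = 10


@dataclass
class GlobuleSpec:
    """Recipe for a random globular point-cloud molecule."""

    n_atoms: int
    density: float = 0.1  # atoms / A^3
    min_separation: float = 1.0  # A
    element_frequencies: dict = field(default_factory=lambda: dict(_DEFAULT_FREQS))
    seed: int = 0
    total_charge: int = 0


def _to_molecule(coords: np.ndarray, elements: Sequence[str],
                 total_charge: int, source: str) -> Molecule:
    n = len(coords)
    n_res = (n + PSEUDO_RESIDUE_SIZE - 1) // PSEUDO_RESIDUE_SIZE
    residues = [Residue(chain="A", seq_number=i + 1, insertion_code="",
                        name="SYN") for i in range(n_res)]
    atoms = []
    counts: dict[str, int] = {}
    for i in range(n):
        el = elements[i]
        counts[el] = counts.get(el, 0) + 1
        atoms.append(Atom(index=i, element=el, name=f"{el}{counts[el]}",
                          x=float(coords[i, 0]), y=float(coords[i, 1]),
                          z=float(coords[i, 2]),
                          residue_key=i // PSEUDO_RESIDUE_SIZE))
    return Molecule(atoms, residues, total_charge, source)


def generate_globule(spec: GlobuleSpec) -> Molecule:
    """Uniform random points in a sphere, rejection-sampled to respect the
    minimum separation; deterministic under ``spec.seed``.

    Sphere radius follows from the density: R = (3 n / (4 pi rho))^(1/3).
    """
    n = spec.n_atoms
    if n < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(spec.seed)
    radius = (3.0 * n / (4.0 * math.pi * spec.density)) ** (1.0 / 3.0)
    sep2 = spec.min_separation ** 2
    inv = 1.0 / spec.min_separation
    coords = np.empty((n, 3))
    cells: dict[tuple, list[int]] = {}
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while placed < n:
        if attempts > max_attempts:
            raise PackingError(
                f"could not place {n} atoms at density {spec.density}/A^3 with "
                f"min separation {spec.min_separation} A after {attempts} draws")
        attempts += 1
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        p = direction / norm * radius * rng.random() ** (1.0 / 3.0)
        key = (int(np.floor(p[0] * inv)), int(np.floor(p[1] * inv)),
               int(np.floor(p[2] * inv)))
        ok = True
        for dx in (-1, 0, 1):
            if not ok:
                break
            for dy in (-1, 0, 1):
                if not ok:
                    break
                for dz in (-1, 0, 1):
                    for j in cells.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = p - coords[j]
                        if d @ d < sep2:
                            ok = False
                            break
                    if not ok:
                        break
        if ok:
            coords[placed] = p
            cells.setdefault(key, []).append(placed)
            placed += 1
    symbols = list(spec.element_frequencies)
    probs = np.array([spec.element_frequencies[s] for s in symbols])
    probs = probs / probs.sum()
    elements = [symbols[k] for k in rng.choice(len(symbols), size=n, p=probs)]
    return _to_molecule(coords, elements, spec.total_charge,
                        f"globule(n={n},seed={spec.seed})")


def generate_chain(n_atoms: int, spacing: float, seed: int = 0,
                   element: str = "C", total_charge: int = 0) -> Molecule:
    """Collinear atoms at uniform spacing along x (analytic neighbor counts)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.zeros((n_atoms, 3))
    coords[:, 0] = np.arange(n_atoms) * spacing
    return _to_molecule(coords, [element] * n_atoms, total_charge,
                        f"chain(n={n_atoms},spacing={spacing})")


def generate_parameter_set(elements: Sequence[str], seed: int = 0,
                           name: Optional[str] = None) -> EEMParameterSet:
    """Random element-granularity set: A ~ U[2, 8], B ~ U[6, 14],
    kappa ~ U[0.3, 0.6] -- ranges that mimic protein-applicable sets and
    keep EEM systems well conditioned."""
    if not elements:
        raise ValueError("element list must be non-empty")
    rng = np.random.default_rng(seed)
    entries = {}
    for el in elements:
        a = float(rng.uniform(2.0, 8.0))
        b = float(rng.uniform(6.0, 14.0))
        entries[AtomTypeKey(el)] = (a, b)
    kappa = float(rng.uniform(0.3, 0.6))
    return EEMParameterSet(
        name or f"synthetic-{''.join(elements)}-s{seed}", kappa, entries,
        provenance=f"synthetic random set, seed {seed}")


# -- independent oracles ---------------------------------------------------


def _oracle_build_matrix(mol: Molecule, params: EEMParameterSet,
                         total_charge: float) -> tuple[list[list[float]], list[float]]:
    """Hand-built EEM matrix using plain Python arithmetic only."""
    atoms = mol.atoms
    n = len(atoms)
    a_of = {}
    b_of = {}
    for atom in atoms:
        key = AtomTypeKey(atom.element, atom.multiplicity)
        a_of[atom.index], b_of[atom.index] = params.get(key)
    mat = [[0.0] * (n + 1) for _ in range(n + 1)]
    rhs = [0.0] * (n + 1)
    for i in range(n):
        ai = atoms[i]
        for j in range(n):
            if i == j:
                mat[i][i] = b_of[i]
            else:
                aj = atoms[j]
                r = math.sqrt((ai.x - aj.x) ** 2 + (ai.y - aj.y) ** 2
                              + (ai.z - aj.z) ** 2)
                mat[i][j] = params.kappa / r
        mat[i][n] = 1.0
        mat[n][i] = 1.0
        rhs[i] = -a_of[i]
    rhs[n] = float(total_charge)
    return mat, rhs


def _gaussian_elimination(mat: list[list[float]], rhs: list[float]) -> list[float]:
    """Textbook Gaussian elimination with partial pivoting."""
    n = len(rhs)
    m = [row[:] + [rhs[i]] for i, row in enumerate(mat)]
    for col in range(n):
        pivot = max(range(col, n), key=lambda r: abs(m[r][col]))
        if abs(m[pivot][col]) < 1e-14:
            raise ZeroDivisionError("oracle matrix is singular")
        if pivot != col:
            m[col], m[pivot] = m[pivot], m[col]
        for r in range(col + 1, n):
            f = m[r][col] / m[col][col]
            if f != 0.0:
                for c in range(col, n + 1):
                    m[r][c] -= f * m[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        s = m[r][n] - sum(m[r][c] * x[c] for c in range(r + 1, n))
        x[r] = s / m[r][r]
    return x


def oracle_full_solve(mol: Molecule, params: EEMParameterSet,
                      total_charge: Optional[int] = None) -> ChargeSet:
    """Naive, independent full-EEM reference (N <= 200).

    Builds the matrix with plain Python loops and solves it by Gaussian
    elimination with partial pivoting; shares no code with the production
    solver.
    """
    if total_charge is None:
        total_charge = mol.total_charge
    n = mol.n_atoms
    if n > 200:
        raise ValueError("oracle_full_solve is deliberately naive; N <= 200 only")
    mat, rhs = _oracle_build_matrix(mol, params, total_charge)
    x = _gaussian_elimination(mat, rhs)
    tag = JobTag(method="full", parameter_set=params.name,
                 total_charge=int(total_charge))
    return ChargeSet(values=np.array(x[:n]), chi_bar=-x[n], job=tag)


def diatomic_closed_form(a1: float, a2: float, b1: float, b2: float,
                         kappa: float, r: float, total_charge: float = 0.0
                         ) -> tuple[float, float]:
    """Closed-form diatomic EEM charges, by symbolic elimination.

    For Q = 0: q1 = (A2 - A1) / (B1 + B2 - 2 kappa / R), q2 = -q1. The
    general-Q form adds the capacitance split of the total charge.
    """
    c = kappa / r
    denom = b1 + b2 - 2.0 * c
    q1 = (a2 - a1 + total_charge * (b2 - c)) / denom
    return q1, total_charge - q1


# -- synthetic QSPR data ---------------------------------------------------


def generate_qspr_dataset(true_model: QSPRModel, n: int, noise_sigma: float,
                          seed: int = 0) -> tuple[list[DescriptorVector], np.ndarray]:
    """Descriptors drawn in carboxyl-charge-like ranges (|q| <= 1 e), pKa
    from the model plus Gaussian noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = true_model.descriptor_names
    descriptors = []
    for _ in range(n):
        values = {name: float(rng.uniform(-0.7, 0.7)) for name in names}
        descriptors.append(DescriptorVector(values))
    observed = np.array([true_model.predict(d) for d in descriptors])
    observed = observed + rng.normal(0.0, noise_sigma, size=n)
    return descriptors, observed
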