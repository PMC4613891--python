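"""Full EEM: build and solve the dense (N+1)x(N+1) matrix equation.

The Electronegativity Equalization Method assigns partial charges by
requiring every atom's effective electronegativity to equal a common
molecular value chi_bar:

    B_i q_i + kappa * sum_{j != i} q_j / R_ij - chi_bar = -A_i    (per atom)
    sum_i q_i = Q                                                 (constraint)

with distances R_ij in Angstrom. Writing lambda = -chi_bar makes the
augmented system symmetric (charge block bordered by a row and column of
ones), which is the layout built here and solved by a direct dense
symmetric factorization -- an O(N^3)-time, O(N^2)-space computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateGeometryError, EEMNumericalError
from .molecule import Molecule
from .parameters import AtomTypeKey, EEMParameterSet

#: Below this interatomic distance (Angstrom) the 1/R coupling is treated as
#: degenerate. Well under any real coordinate precision.
DEGENERATE_DISTANCE = 1e-4

#: Conservation tolerance for the full method at 64-bit, in e.
CONSERVATION_TOL = 1e-6

#: Relative residual bound for the 64-bit dense solve.
RESIDUAL_TOL = 1e-8


class AllocationMeter:
    """Counts matrix elements allocated by EEM solvers.

    Used by tests to assert that fragment methods never allocate an N^2
    system: their peak single allocation stays bounded by the largest
    fragment's system size.
    """

    def __init__(self) -> None:
        self.peak_single = 0
        self.total = 0

    def record(self, n_elements: int) -> None:
        self.total += n_elements
        if n_elements > self.peak_single:
            self.peak_single = n_elements


#: Module-level hook; ``None`` disables instrumentation.
_active_meter: Optional[AllocationMeter] = None


def set_allocation_meter(meter: Optional[AllocationMeter]) -> None:
    global _active_meter
    _active_meter = meter


def _record_allocation(n_elements: int) -> None:
    if _active_meter is not None:
        _active_meter.record(n_elements)


@dataclass
class JobTag:
    """What produced a charge set: method, parameters and options."""

    method: str  # "full" | "cutoff" | "cover"
    parameter_set: str
    total_charge: int
    precision: int = 64  # 64 or 32
    radius: Optional[float] = None
    charge_residual: Optional[float] = None  # sum(q) - Q, fragment methods

    def label(self) -> str:
        parts = [self.method, self.parameter_set, f"Q={self.total_charge:+d}",
                 f"{self.precision}bit"]
        if self.radius is not None:
            parts.append(f"R={self.radius:g}A")
        return " ".join(parts)


@dataclass
class ChargeSet:
    """Partial atomic charges (e), one per atom, plus the equalized
    electronegativity chi_bar where the method yields a single one."""

    values: np.ndarray
    chi_bar: Optional[float]
    job: JobTag

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class EEMSystem:
    """Assembled dense EEM system for one molecule."""

    matrix: np.ndarray  # (N+1, N+1), symmetric
    rhs: np.ndarray  # (N+1,)
    atom_order: np.ndarray  # row -> atom index (identity unless permuted)
    precision: int = 64

    @property
    def n_atoms(self) -> int:
        return len(self.rhs) - 1


def _check_degenerate(coords: np.ndarray, mol: Molecule) -> None:
    """Raise naming both atoms if any pair is closer than the degeneracy
    threshold. Uses a KD-tree so large systems stay cheap."""
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(DEGENERATE_DISTANCE)
    if pairs:
        i, j = sorted(pairs)[0]
        ai, aj = mol.atoms[i], mol.atoms[j]
        raise DegenerateGeometryError(
            f"atoms {i} ({ai.name}) and {j} ({aj.name}) are "
            f"{np.linalg.norm(coords[i] - coords[j]):.2e} A apart "
            f"(threshold {DEGENERATE_DISTANCE} A)")


def atom_parameters(mol: Molecule, params: EEMParameterSet
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (A, B) vectors for a molecule under a parameter set."""
    a = np.empty(mol.n_atoms)
    b = np.empty(mol.n_atoms)
    for i, atom in enumerate(mol.atoms):
        a[i], b[i] = params.get(AtomTypeKey(atom.element, atom.multiplicity))
    return a, b


def build_eem_system(mol: Molecule, params: EEMParameterSet,
                     total_charge: Optional[int] = None,
                     precision: int = 64) -> EEMSystem:
    """Assemble the symmetric augmented EEM matrix and right-hand side.

    Row/column N carry the charge-conservation constraint; the last unknown
    is lambda = -chi_bar.
    """
    params.require_applicable(mol)
    if total_charge is None:
        total_charge = mol.total_charge
    dtype = np.float64 if precision == 64 else np.float32
    n = mol.n_atoms
    coords = mol.coordinates
    if n > 1:
        _check_degenerate(coords, mol)
    avec, bvec = atom_parameters(mol, params)

    matrix = np.zeros((n + 1, n + 1), dtype=dtype)
    _record_allocation((n + 1) * (n + 1))
    if n > 1:
        dist = squareform(pdist(coords.astype(dtype, copy=False)))
        np.fill_diagonal(dist, 1.0)  # placeholder; diagonal overwritten below
        matrix[:n, :n] = (dtype(params.kappa) / dist).astype(dtype)
    matrix[np.arange(n), np.arange(n)] = bvec.astype(dtype)
    matrix[:n, n] = 1.0
    matrix[n, :n] = 1.0
    # matrix[n, n] stays exactly 0: the constraint row has no diagonal term

    rhs = np.zeros(n + 1, dtype=dtype)
    rhs[:n] = -avec.astype(dtype)
    rhs[n] = dtype(total_charge)
    return EEMSystem(matrix=matrix, rhs=rhs, atom_order=np.arange(n),
                     precision=precision)


def solve_system(system: EEMSystem) -> tuple[np.ndarray, float]:
    """Solve an assembled EEM system; return (charges, chi_bar)."""
    try:
        x = scipy.linalg.solve(system.matrix, system.rhs, assume_a="sym",
                               check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        cond = None
        if system.matrix.shape[0] <= 4000:
            cond = np.linalg.cond(system.matrix.astype(np.float64))
        raise EEMNumericalError(
            f"EEM system could not be solved ({exc}); condition number "
            f"{'unknown' if cond is None else format(cond, '.3e')}")
    n = system.n_atoms
    if system.precision == 64:
        resid = np.linalg.norm(system.matrix @ x - system.rhs)
        scale = np.linalg.norm(system.rhs)
        if scale > 0 and resid / scale > RESIDUAL_TOL:
            cond = np.linalg.cond(system.matrix) if n <= 4000 else float("nan")
            raise EEMNumericalError(
                f"solution residual {resid / scale:.2e} exceeds {RESIDUAL_TOL:.0e}; "
                f"condition number {cond:.3e}")
    q = np.asarray(x[:n], dtype=np.float64)
    chi_bar = -float(x[n])
    return q, chi_bar


def solve_full_eem(mol: Molecule, params: EEMParameterSet,
                   total_charge: Optional[int] = None,
                   precision: int = 64) -> ChargeSet:
    """Charges from the dense full-system solve.

    Guarantees sum(q) = Q to :data:`CONSERVATION_TOL` at 64-bit precision.
    """
    if total_charge is None:
        total_charge = mol.total_charge
    system = build_eem_system(mol, params, total_charge, precision)
    q, chi_bar = solve_system(system)
    if precision == 64 and abs(q.sum() - total_charge) > CONSERVATION_TOL:
        raise EEMNumericalError(
            f"charge conservation violated: sum(q) - Q = {q.sum() - total_charge:.3e}")
    tag = JobTag(method="full", parameter_set=params.name,
                 total_charge=int(total_charge), precision=precision)
    return ChargeSet(values=q, chi_bar=chi_bar, job=tag)
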