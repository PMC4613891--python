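"""Shared fixtures: small synthetic molecules and parameter sets."""

import numpy as np
import pytest

from eemkit import (GlobuleSpec, generate_chain, generate_globule,
                    generate_parameter_set)
from eemkit.molecule import Atom, Molecule, Residue


@pytest.fixture(scope="session")
def hcno_params():
    return generate_parameter_set(["H", "C", "N", "O"], seed=7)


@pytest.fixture(scope="session")
def small_globule():
    return generate_globule(GlobuleSpec(n_atoms=60, seed=11))


@pytest.fixture(scope="session")
def medium_globule():
    return generate_globule(GlobuleSpec(n_atoms=500, seed=12))


@pytest.fixture
def diatomic():
    atoms = [Atom(0, "C", "C1", 0.0, 0.0, 0.0, 0),
             Atom(1, "N", "N1", 1.5, 0.0, 0.0, 0)]
    return Molecule(atoms, [Residue("A", 1, "", "SYN")], 0)


@pytest.fixture
def water_protein_mix():
    """10 'protein' atoms in one residue plus 3 waters of 3 atoms each."""
    atoms = []
    residues = [Residue("A", 1, "", "GLY")]
    rng = np.random.default_rng(3)
    for i in range(10):
        p = rng.uniform(0, 5, 3)
        atoms.append(Atom(i, "C", f"C{i+1}", *p, 0))
    for w in range(3):
        residues.append(Residue("W", w + 1, "", "HOH"))
        base = rng.uniform(10 + 4 * w, 12 + 4 * w, 3)
        for k, el in enumerate(["O", "H", "H"]):
            atoms.append(Atom(10 + 3 * w + k, el, f"{el}{k or ''}".strip(),
                              base[0] + 0.4 * k, base[1], base[2], w + 1))
    return Molecule(atoms, residues, 0)
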