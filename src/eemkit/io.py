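"""Structure and charge file I/O.

Readers return the unified :class:`~eemkit.molecule.Molecule`; every chemical
entity in a file (protein, ligands, waters...) becomes one molecule. PDB and
mmCIF parsing is delegated to gemmi, MOL/SDF (V2000) to RDKit; PQR and MOL2
are parsed and written here directly because charge round-tripping at a
controlled printed precision is part of this package's contract and no
installed library writes MOL2 ``USER_CHARGES`` or PQR dialects verbatim.

Conventions (documented choices where formats leave room):

* multi-model files: model 1 only;
* altloc duplicates: highest occupancy wins, ties go to the first in file;
* elements: taken from the file when present, otherwise inferred from the
  atom name by PDB v3 alignment rules -- ambiguity is a loud error, and
  deuterium stays ``"D"``;
* MOL2 output: charges under ``USER_CHARGES``, coordinates and charges
  printed to 4 decimals; PQR output prints coordinates, charges and radii
  to 4 decimals;
* the plain tabular charge table has the whitespace-separated header
  ``index name chain resnum resname charge``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import gemmi
import numpy as np

from .core import ChargeSet, JobTag
from .errors import (DimensionError, ElementError, EmptyInputError,
                     FormatError)
from .molecule import (Atom, Molecule, Residue, WATER_RESIDUE_NAMES,
                       element_from_atom_name, normalize_element)

_EXTENSION_FORMATS = {
    ".pdb": "pdb", ".ent": "pdb", ".pqr": "pqr", ".mol": "mol",
    ".sdf": "sdf", ".sd": "sdf", ".mol2": "mol2", ".cif": "mmcif",
    ".mmcif": "mmcif",
}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in set(_EXTENSION_FORMATS.values()):
            raise FormatError(f"unknown structure format {fmt!r}")
        return fmt
    ext = path.suffix.lower()
    if ext not in _EXTENSION_FORMATS:
        raise FormatError(
            f"cannot infer format from extension {ext!r} of {path.name}; "
            "pass format= explicitly")
    return _EXTENSION_FORMATS[ext]


def read_structure(path: Union[str, Path], format: Optional[str] = None
                   ) -> Molecule:
    """Read one molecule from a structure file.

    For multi-record SDF files the first record is returned (use
    :func:`read_structures` for all of them); for multi-model PDB/mmCIF
    files, model 1.
    """
    mols = read_structures(path, format)
    return mols[0]


def read_structures(path: Union[str, Path], format: Optional[str] = None
                    ) -> list[Molecule]:
    """Read all molecules from a file (one per SDF record; single-element
    list for every other format)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path.name} is empty")
    fmt = _infer_format(path, format)
    if fmt in ("pdb", "mmcif"):
        return [_read_gemmi(path, fmt)]
    if fmt == "pqr":
        return [_read_pqr(path)]
    if fmt in ("mol", "sdf"):
        return _read_rdkit(path, fmt)
    if fmt == "mol2":
        return [_read_mol2(path)]
    raise FormatError(f"unknown structure format {fmt!r}")  # pragma: no cover


# -- PDB / mmCIF (gemmi) ---------------------------------------------------


def _read_gemmi(path: Path, fmt: str) -> Molecule:
    try:
        coor = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name} as {fmt}: {exc}")
    if len(st) == 0:
        raise EmptyInputError(f"{path.name} contains no models")
    model = st[0]  # first model only (NMR ensembles, multi-model files)

    residues: list[Residue] = []
    res_index: dict[tuple, int] = {}
    # altloc resolution: (residue key, atom name) -> (position, occupancy)
    picked: dict[tuple, int] = {}
    occupancy: dict[tuple, float] = {}
    records: list[tuple] = []  # (res_key_idx, gemmi atom, name)

    for chain in model:
        for res in chain:
            rkey = (chain.name, res.seqid.num, res.seqid.icode.strip(),
                    res.name)
            if rkey not in res_index:
                res_index[rkey] = len(residues)
                residues.append(Residue(chain=chain.name,
                                        seq_number=res.seqid.num,
                                        insertion_code=res.seqid.icode.strip(),
                                        name=res.name))
            ridx = res_index[rkey]
            for atom in res:
                akey = (ridx, atom.name)
                occ = atom.occ
                if akey in picked:
                    # keep highest occupancy; ties keep first-in-file
                    if occ > occupancy[akey]:
                        records[picked[akey]] = (ridx, atom, atom.name)
                        occupancy[akey] = occ
                    continue
                picked[akey] = len(records)
                occupancy[akey] = occ
                records.append((ridx, atom, atom.name))

    if not records:
        raise EmptyInputError(f"{path.name} contains no atoms")
    atoms = []
    for i, (ridx, g_atom, name) in enumerate(records):
        el = g_atom.element
        if el.name != "X" and el.atomic_number > 0:
            element = el.name
        else:
            try:
                element = element_from_atom_name(g_atom.padded_name() or name)
            except ElementError as exc:
                raise ElementError(
                    f"{path.name}: atom {i} ({name!r} in "
                    f"{residues[ridx]}): {exc}")
        element = normalize_element(element)
        atoms.append(Atom(
            index=i, element=element, name=name,
            x=g_atom.pos.x, y=g_atom.pos.y, z=g_atom.pos.z,
            residue_key=ridx,
            formal_metadata={"serial": g_atom.serial, "altloc": g_atom.altloc,
                             "occupancy": g_atom.occ}))
    return Molecule(atoms, residues, 0, f"{path.name} ({fmt})")


# -- PQR -------------------------------------------------------------------


def _read_pqr(path: Path) -> Molecule:
    residues: list[Residue] = []
    res_index: dict[tuple, int] = {}
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            # ATOM serial name resName [chain] resSeq x y z charge radius
            if len(rec) == 11:
                _, serial, name, resname, chain, resseq = rec[:6]
                rest = rec[6:]
            elif len(rec) == 10:
                _, serial, name, resname, resseq = rec[:5]
                chain = ""
                rest = rec[5:]
            else:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 10 or 11 fields on a "
                    f"PQR atom record, got {len(rec)}")
            try:
                x, y, z, charge, radius = (float(v) for v in rest)
                seq = int(resseq)
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric coordinate/charge field")
            rkey = (chain, seq, "", resname)
            if rkey not in res_index:
                res_index[rkey] = len(residues)
                residues.append(Residue(chain=chain, seq_number=seq,
                                        insertion_code="", name=resname))
            try:
                element = element_from_atom_name(name)
            except ElementError as exc:
                raise ElementError(f"{path.name}:{lineno}: {exc}")
            atoms.append(Atom(
                index=len(atoms), element=element, name=name, x=x, y=y, z=z,
                residue_key=res_index[rkey],
                formal_metadata={"serial": int(serial), "charge": charge,
                                 "radius": radius}))
    if not atoms:
        raise EmptyInputError(f"{path.name} contains no atom records")
    return Molecule(atoms, residues, 0, f"{path.name} (pqr)")


# -- MOL / SDF (RDKit) -----------------------------------------------------

_BOND_ORDER = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": 2,
               "AMIDE": 1}


def _rdkit_to_molecule(rdmol, record: int, source: str) -> Molecule:
    from rdkit import Chem

    if rdmol.GetNumAtoms() == 0:
        raise EmptyInputError(f"{source}: record {record} has no atoms")
    if rdmol.GetNumConformers() == 0:
        raise FormatError(f"{source}: record {record} carries no coordinates")
    conf = rdmol.GetConformer()
    title = (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "").strip()
    resname = "LIG"
    residues = [Residue(chain="", seq_number=1, insertion_code="",
                        name=resname)]
    # highest incident bond order per atom; aromatic counts as 2
    mult = [1] * rdmol.GetNumAtoms()
    for bond in rdmol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType().name, 1)
        for k in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
            mult[k] = max(mult[k], order)
    atoms = []
    counts: dict[str, int] = {}
    for i, rd_atom in enumerate(rdmol.GetAtoms()):
        symbol = rd_atom.GetSymbol()
        if symbol == "H" and rd_atom.GetIsotope() == 2:
            symbol = "D"
        element = normalize_element(symbol)
        counts[element] = counts.get(element, 0) + 1
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(index=i, element=element,
                          name=f"{element}{counts[element]}",
                          x=pos.x, y=pos.y, z=pos.z, residue_key=0,
                          multiplicity=mult[i] if rdmol.GetNumBonds() else None,
                          formal_metadata={"title": title}))
    charge = Chem.GetFormalCharge(rdmol)
    return Molecule(atoms, residues, charge, source)


def _read_rdkit(path: Path, fmt: str) -> list[Molecule]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.warning")
    if fmt == "mol":
        rdmol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
        if rdmol is None:
            raise FormatError(f"cannot parse {path.name} as MOL V2000")
        return [_rdkit_to_molecule(rdmol, 1, f"{path.name} (mol)")]
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for rec, rdmol in enumerate(supplier, 1):
        if rdmol is None:
            raise FormatError(f"cannot parse record {rec} of {path.name}")
        mols.append(_rdkit_to_molecule(rdmol, rec, f"{path.name}#{rec} (sdf)"))
    if not mols:
        raise EmptyInputError(f"{path.name} contains no records")
    return mols


# -- MOL2 ------------------------------------------------------------------

_MOL2_BOND_ORDER = {"1": 1, "2": 2, "3": 3, "ar": 2, "am": 1, "du": 1,
                    "un": 1, "nc": 1}


def _read_mol2(path: Path) -> Molecule:
    lines = Path(path).read_text().splitlines()
    section = None
    atom_rows: list[tuple] = []
    bond_rows: list[tuple] = []
    name = ""
    mol_line = 0
    for lineno, line in enumerate(lines, 1):
        s = line.strip()
        if s.startswith("@<TRIPOS>"):
            section = s[len("@<TRIPOS>"):].upper()
            mol_line = 0
            continue
        if not s or s.startswith("#"):
            continue
        if section == "MOLECULE":
            mol_line += 1
            if mol_line == 1:
                name = s
        elif section == "ATOM":
            rec = s.split()
            if len(rec) < 6:
                raise FormatError(
                    f"{path.name}:{lineno}: MOL2 atom record needs at least "
                    "6 fields")
            try:
                atom_rows.append((
                    rec[1], float(rec[2]), float(rec[3]), float(rec[4]),
                    rec[5],
                    int(rec[6]) if len(rec) > 6 else 1,
                    rec[7] if len(rec) > 7 else "UNL",
                    float(rec[8]) if len(rec) > 8 else None, lineno))
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: malformed MOL2 atom record")
        elif section == "BOND":
            rec = s.split()
            if len(rec) >= 4:
                bond_rows.append((int(rec[1]), int(rec[2]), rec[3].lower()))
    if not atom_rows:
        raise EmptyInputError(f"{path.name} has no @<TRIPOS>ATOM records")
    mult = [None] * len(atom_rows)
    for a1, a2, btype in bond_rows:
        order = _MOL2_BOND_ORDER.get(btype, 1)
        for k in (a1 - 1, a2 - 1):
            if 0 <= k < len(mult):
                mult[k] = max(mult[k] or 1, order)
    residues: list[Residue] = []
    res_index: dict[tuple, int] = {}
    atoms: list[Atom] = []
    for i, (aname, x, y, z, sybyl, subst_id, subst_name, charge,
            lineno) in enumerate(atom_rows):
        base = sybyl.split(".")[0]
        try:
            element = normalize_element(base)
        except ElementError:
            try:
                element = element_from_atom_name(aname)
            except ElementError as exc:
                raise ElementError(f"{path.name}:{lineno}: {exc}")
        rkey = ("", subst_id, "", subst_name)
        if rkey not in res_index:
            res_index[rkey] = len(residues)
            residues.append(Residue(chain="", seq_number=subst_id,
                                    insertion_code="", name=subst_name))
        meta = {"sybyl_type": sybyl}
        if charge is not None:
            meta["charge"] = charge
        atoms.append(Atom(index=i, element=element, name=aname, x=x, y=y,
                          z=z, residue_key=res_index[rkey],
                          multiplicity=mult[i], formal_metadata=meta))
    return Molecule(atoms, residues, 0, f"{path.name} (mol2)")


# -- water stripping -------------------------------------------------------


def strip_waters(mol: Molecule) -> Molecule:
    """Copy of the molecule without water residues (HOH/WAT/H2O/DOD, case
    insensitive); atom indices contiguous, total charge unchanged. A
    molecule with no waters comes back equal; an all-water molecule is an
    empty-molecule error."""
    keep = [a.index for a in mol.atoms
            if mol.residue_of(a).name.upper() not in WATER_RESIDUE_NAMES]
    if len(keep) == mol.n_atoms:
        return mol.subset(range(mol.n_atoms))
    if not keep:
        raise EmptyInputError(
            "molecule consists only of water; nothing left to compute on")
    return mol.subset(keep)


# -- charge-annotated output ----------------------------------------------


def write_charges(mol: Molecule, charges: ChargeSet, path: Union[str, Path],
                  format: Optional[str] = None) -> None:
    """Write the molecule with per-atom charges (MOL2 ``USER_CHARGES``, PQR,
    or the plain tabular format). Format is inferred from the extension when
    not given (.mol2 / .pqr / anything else -> tabular)."""
    if len(charges) != mol.n_atoms:
        raise DimensionError(
            f"{len(charges)} charges for {mol.n_atoms} atoms")
    path = Path(path)
    if format is None:
        format = {".mol2": "mol2", ".pqr": "pqr"}.get(path.suffix.lower(),
                                                      "tabular")
    format = format.lower()
    if format == "mol2":
        _write_mol2(mol, charges.values, path)
    elif format == "pqr":
        _write_pqr(mol, charges.values, path)
    elif format in ("tabular", "txt", "chg"):
        _write_tabular(mol, charges.values, path)
    else:
        raise FormatError(f"unknown charge output format {format!r}")


def _write_mol2(mol: Molecule, q: np.ndarray, path: Path) -> None:
    lines = ["@<TRIPOS>MOLECULE", mol.source or "eemkit molecule",
             f"{mol.n_atoms} 0 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for a in mol.atoms:
        res = mol.residue_of(a)
        sybyl = a.formal_metadata.get("sybyl_type", a.element)
        lines.append(
            f"{a.index + 1:>7d} {a.name:<8s} {a.x:>10.4f} {a.y:>10.4f} "
            f"{a.z:>10.4f} {sybyl:<8s} {a.residue_key + 1:>4d} "
            f"{res.name:<8s} {q[a.index]:>10.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_pqr(mol: Molecule, q: np.ndarray, path: Path) -> None:
    lines = []
    for a in mol.atoms:
        res = mol.residue_of(a)
        radius = a.formal_metadata.get("radius", 1.5)
        chain = (res.chain or "A")[:1]
        lines.append(
            f"ATOM {a.index + 1:>6d} {a.name:<4s} {res.name:<4s} {chain} "
            f"{res.seq_number:>4d} {a.x:>10.4f} {a.y:>10.4f} {a.z:>10.4f} "
            f"{q[a.index]:>9.4f} {radius:>7.4f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_tabular(mol: Molecule, q: np.ndarray, path: Path) -> None:
    lines = ["index name chain resnum resname charge"]
    for a in mol.atoms:
        res = mol.residue_of(a)
        lines.append(f"{a.index} {a.name} {res.chain or '-'} "
                     f"{res.seq_number} {res.name} {q[a.index]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_charge_file(path: Union[str, Path]) -> ChargeSet:
    """Read per-atom charges back from MOL2, PQR or the tabular format,
    in atom order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".mol2":
        mol = _read_mol2(path)
        vals = []
        for a in mol.atoms:
            if "charge" not in a.formal_metadata:
                raise FormatError(
                    f"{path.name}: atom {a.index + 1} carries no charge column")
            vals.append(a.formal_metadata["charge"])
    elif ext == ".pqr":
        mol = _read_pqr(path)
        vals = [a.formal_metadata["charge"] for a in mol.atoms]
    else:
        vals = _read_tabular_charges(path)
    tag = JobTag(method="external", parameter_set=path.name,
                 total_charge=int(round(float(np.sum(vals)))))
    return ChargeSet(values=np.asarray(vals, dtype=float), chi_bar=None,
                     job=tag)


def _read_tabular_charges(path: Path) -> list[float]:
    vals: list[float] = []
    with open(path) as fh:
        header = fh.readline().split()
        if "charge" not in header:
            raise FormatError(
                f"{path.name}: tabular charge file must start with the "
                "header 'index name chain resnum resname charge'")
        col = header.index("charge")
        for lineno, line in enumerate(fh, 2):
            rec = line.split()
            if not rec:
                continue
            if len(rec) <= col:
                raise FormatError(f"{path.name}:{lineno}: missing charge field")
            try:
                vals.append(float(rec[col]))
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: charge field {rec[col]!r} is not "
                    "a number")
    if not vals:
        raise EmptyInputError(f"{path.name} contains no charge rows")
    return vals


# -- PDB output (used by the synthetic generators and tests) ---------------


def write_pdb(mol: Molecule, path: Union[str, Path]) -> None:
    """Minimal single-model PDB v3 writer (ATOM/HETATM records with element
    column)."""
    lines = []
    for a in mol.atoms:
        res = mol.residue_of(a)
        record = "HETATM" if res.name in WATER_RESIDUE_NAMES or \
            res.name in ("LIG", "UNL") else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        el = a.element.rjust(2)
        lines.append(
            f"{record}{(a.index + 1) % 100000:>5d} {name:<4.4s} "
            f"{res.name:<3.3s} {(res.chain or 'A')[:1]}"
            f"{res.seq_number % 10000:>4d}{res.insertion_code or ' ':1.1s}   "
            f"{a.x:>8.3f}{a.y:>8.3f}{a.z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
            f"          {el}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
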