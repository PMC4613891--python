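"""EEM parameter sets: representation, XML I/O, applicability, selection.

An EEM parameter set supplies, per atom type, the electronegativity-like
parameter A and the hardness-like parameter B (both in the set's own energy
units, consistent with distances in Angstrom), plus one set-level constant
kappa scaling the 1/R interatomic coupling. Atom types are either bare
elements or (element, multiplicity) pairs, where multiplicity is the highest
bond order of the atom (1, 2 or 3; aromatic counts as 2). A set must be
uniformly element-granular or uniformly multiplicity-granular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from .errors import (ApplicabilityError, MissingParameterError,
                     ParameterValidationError)
from .molecule import Molecule, normalize_element

_VALID_MULTIPLICITIES = (1, 2, 3)


@dataclass(frozen=True)
class AtomTypeKey:
    """Element symbol plus optional bond-order multiplicity."""

    element: str
    multiplicity: Optional[int] = None

    def __post_init__(self):
        if self.multiplicity is not None and self.multiplicity not in _VALID_MULTIPLICITIES:
            raise ParameterValidationError(
                f"multiplicity must be one of {_VALID_MULTIPLICITIES}, "
                f"got {self.multiplicity}")

    def __str__(self) -> str:
        if self.multiplicity is None:
            return self.element
        return f"{self.element}({self.multiplicity})"


@dataclass
class ApplicabilityReport:
    """Which of a molecule's atom types a parameter set covers."""

    covered: set = field(default_factory=set)
    missing: set = field(default_factory=set)

    @property
    def applicable(self) -> bool:
        return not self.missing


class EEMParameterSet:
    """Named collection of (A, B) entries keyed by :class:`AtomTypeKey`.

    Invariants: kappa > 0, every B > 0, and granularity is uniform (either
    every entry has a multiplicity or none does).
    """

    def __init__(self, name: str, kappa: float,
                 entries: dict[AtomTypeKey, tuple[float, float]],
                 provenance: str = ""):
        if kappa <= 0:
            raise ParameterValidationError(f"kappa must be positive, got {kappa}")
        if not entries:
            raise ParameterValidationError("parameter set has no entries")
        grains = {k.multiplicity is None for k in entries}
        if len(grains) > 1:
            raise ParameterValidationError(
                "mixed granularity: entries must all or none carry multiplicity")
        for key, (a, b) in entries.items():
            if b <= 0:
                raise ParameterValidationError(f"B must be positive for {key}, got {b}")
        self.name = name
        self.kappa = float(kappa)
        self.entries = dict(entries)
        self.provenance = provenance

    @property
    def element_granular(self) -> bool:
        return next(iter(self.entries)).multiplicity is None

    @property
    def elements(self) -> set[str]:
        return {k.element for k in self.entries}

    def get(self, key: AtomTypeKey) -> tuple[float, float]:
        """(A, B) for an atom type; element-granular sets ignore the key's
        multiplicity."""
        if self.element_granular:
            key = AtomTypeKey(key.element)
        try:
            return self.entries[key]
        except KeyError:
            raise MissingParameterError(
                f"parameter set {self.name!r} has no entry for atom type {key}")

    # -- applicability -----------------------------------------------------

    def molecule_atom_keys(self, mol: Molecule) -> set[AtomTypeKey]:
        """Atom-type keys occurring in a molecule at this set's granularity.

        Multiplicity-granular sets require bond information on the molecule
        (atoms parsed from MOL/SDF/MOL2); PDB/PQR inputs carry none and are
        rejected with a clear error.
        """
        keys: set[AtomTypeKey] = set()
        if self.element_granular:
            for el in mol.element_set:
                keys.add(AtomTypeKey(el))
            return keys
        for atom in mol.atoms:
            if atom.multiplicity is None:
                raise ApplicabilityError(
                    f"parameter set {self.name!r} is bond-order aware but atom "
                    f"{atom.index} ({atom.name}) has no bond information; "
                    "use an element-granularity set for PDB/PQR inputs")
            keys.add(AtomTypeKey(atom.element, atom.multiplicity))
        return keys

    def check_applicability(self, mol: Molecule) -> ApplicabilityReport:
        report = ApplicabilityReport()
        for key in self.molecule_atom_keys(mol):
            if self.element_granular:
                present = key in self.entries
            else:
                present = key in self.entries
            (report.covered if present else report.missing).add(key)
        return report

    def require_applicable(self, mol: Molecule) -> None:
        rep = self.check_applicability(mol)
        if not rep.applicable:
            missing = ", ".join(sorted(str(k) for k in rep.missing))
            raise ApplicabilityError(
                f"parameter set {self.name!r} does not cover atom types: {missing}")

    # -- derived sets ------------------------------------------------------

    def derive_alias(self, from_element: str, to_element: str) -> "EEMParameterSet":
        """Copy with ``to_element`` entries duplicated from ``from_element``
        at every multiplicity (e.g. give deuterium the hydrogen parameters)."""
        from_element = normalize_element(from_element)
        to_element = normalize_element(to_element)
        src = {k: v for k, v in self.entries.items() if k.element == from_element}
        if not src:
            raise MissingParameterError(
                f"parameter set {self.name!r} has no entries for {from_element}")
        entries = dict(self.entries)
        overwritten = False
        for k, v in src.items():
            new_key = AtomTypeKey(to_element, k.multiplicity)
            if new_key in entries and entries[new_key] != v:
                overwritten = True
            entries[new_key] = v
        if overwritten:
            warnings.warn(
                f"alias {from_element}->{to_element} overwrites existing "
                f"{to_element} entries in {self.name!r}", stacklevel=2)
        name = self.name if from_element == to_element else \
            f"{self.name}+{to_element}from{from_element}"
        return EEMParameterSet(name, self.kappa, entries, self.provenance)

    # -- XML I/O -----------------------------------------------------------

    @classmethod
    def from_xml(cls, path: Union[str, Path]) -> "EEMParameterSet":
        return load_parameter_set_xml(path)

    def to_xml(self, path: Union[str, Path]) -> None:
        root = etree.Element("ParameterSet", Name=self.name,
                             Kappa=repr(self.kappa))
        if self.provenance:
            root.set("Provenance", self.provenance)
        by_element: dict[str, list[AtomTypeKey]] = {}
        for key in self.entries:
            by_element.setdefault(key.element, []).append(key)
        for el in sorted(by_element):
            node = etree.SubElement(root, "Element", Symbol=el)
            for key in sorted(by_element[el], key=lambda k: k.multiplicity or 0):
                a, b = self.entries[key]
                if key.multiplicity is None:
                    etree.SubElement(node, "Parameters", A=repr(a), B=repr(b))
                else:
                    etree.SubElement(node, "Bond", Type=str(key.multiplicity),
                                     A=repr(a), B=repr(b))
        tree = etree.ElementTree(root)
        tree.write(str(path), pretty_print=True, xml_declaration=True,
                   encoding="UTF-8")

    def __repr__(self) -> str:
        kind = "element" if self.element_granular else "bond-order"
        return (f"<EEMParameterSet {self.name!r} kappa={self.kappa} "
                f"{len(self.entries)} {kind} entries>")


def _attr(node, name: str, path: str) -> str:
    val = node.get(name)
    if val is None:
        raise ParameterValidationError(f"{path}: missing attribute {name!r}")
    return val


def _float_attr(node, name: str, path: str) -> float:
    try:
        return float(_attr(node, name, path))
    except ValueError:
        raise ParameterValidationError(
            f"{path}: attribute {name!r} is not a number ({node.get(name)!r})")


def load_parameter_set_xml(path: Union[str, Path]) -> EEMParameterSet:
    """Load a parameter set from the XML template.

    Schema: root ``<ParameterSet Name Kappa>`` containing ``<Element Symbol>``
    children, each holding either one ``<Parameters A B/>`` (element
    granularity) or one or more ``<Bond Type A B/>`` (multiplicity
    granularity). Duplicate atom-type entries are rejected.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParameterValidationError(f"cannot parse parameter XML {path}: {exc}")
    root = tree.getroot()
    if root.tag != "ParameterSet":
        raise ParameterValidationError(
            f"/{root.tag}: expected root element 'ParameterSet'")
    name = _attr(root, "Name", "/ParameterSet")
    kappa = _float_attr(root, "Kappa", "/ParameterSet")
    if kappa <= 0:
        raise ParameterValidationError(f"/ParameterSet: Kappa must be > 0, got {kappa}")
    provenance = root.get("Provenance", "")
    entries: dict[AtomTypeKey, tuple[float, float]] = {}
    for i, el_node in enumerate(root):
        path_el = f"/ParameterSet/Element[{i + 1}]"
        if el_node.tag != "Element":
            raise ParameterValidationError(
                f"{path_el}: unexpected element {el_node.tag!r}")
        symbol = normalize_element(_attr(el_node, "Symbol", path_el))
        children = list(el_node)
        if not children:
            raise ParameterValidationError(f"{path_el}: no parameter entries")
        for child in children:
            cpath = f"{path_el}/{child.tag}"
            if child.tag == "Parameters":
                key = AtomTypeKey(symbol)
            elif child.tag == "Bond":
                bond_type = _attr(child, "Type", cpath)
                try:
                    mult = int(bond_type)
                except ValueError:
                    raise ParameterValidationError(
                        f"{cpath}: Type must be 1, 2 or 3, got {bond_type!r}")
                if mult not in _VALID_MULTIPLICITIES:
                    raise ParameterValidationError(
                        f"{cpath}: Type must be 1, 2 or 3, got {mult}")
                key = AtomTypeKey(symbol, mult)
            else:
                raise ParameterValidationError(
                    f"{cpath}: expected 'Parameters' or 'Bond'")
            a = _float_attr(child, "A", cpath)
            b = _float_attr(child, "B", cpath)
            if b <= 0:
                raise ParameterValidationError(f"{cpath}: B must be > 0, got {b}")
            if key in entries:
                raise ParameterValidationError(
                    f"{cpath}: duplicate entry for atom type {key}")
            entries[key] = (a, b)
    return EEMParameterSet(name, kappa, entries, provenance)


# -- built-in registry -----------------------------------------------------

#: Registry file names in default selection order (stable, documented; a
#: caller may pass its own ordered registry to :func:`select_default_set`).
_BUILTIN_ORDER = (
    "synthetic_hcno.xml",
    "synthetic_hcnosp.xml",
    "synthetic_organic_bonds.xml",
)


def builtin_sets() -> list[EEMParameterSet]:
    """Load the built-in parameter sets, in registry order.

    The shipped sets are synthetic (generated, with well-conditioned values
    in the ranges this package's synthetic molecules use); they are intended
    for testing and for synthetic workflows, and say so in their provenance.
    """
    sets = []
    pkg_data = resources.files("eemkit") / "data"
    for fname in _BUILTIN_ORDER:
        with resources.as_file(pkg_data / fname) as p:
            sets.append(load_parameter_set_xml(p))
    return sets


def select_default_set(mol: Molecule,
                       registry: Optional[Sequence[EEMParameterSet]] = None
                       ) -> EEMParameterSet:
    """First registry set fully covering the molecule's atom types.

    If none covers it, return the set with the fewest missing atom types
    (ties broken by registry order) and emit a warning.
    """
    if registry is None:
        registry = builtin_sets()
    registry = list(registry)
    if not registry:
        raise ParameterValidationError("empty parameter-set registry")
    best = None
    best_missing = None
    for pset in registry:
        try:
            rep = pset.check_applicability(mol)
        except ApplicabilityError:
            continue  # bond-order set on a bond-less molecule: not a candidate
        if rep.applicable:
            return pset
        if best_missing is None or len(rep.missing) < best_missing:
            best, best_missing = pset, len(rep.missing)
    if best is None:
        best = registry[0]
        best_missing = -1
    warnings.warn(
        f"no built-in parameter set covers the molecule; falling back to "
        f"{best.name!r} ({best_missing} atom types missing)", stacklevel=2)
    return best
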