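"""Linear QSPR models mapping EEM charge descriptors to pKa.

A model is a plain linear form pKa = p + sum_d p_d * q_d over named charge
descriptors (e.g. the charges on the phenolic O, H and the carbon bearing
them, or the carboxyl-group charges of the neutral and dissociated forms).
Descriptors bind by atom *name* via a per-molecule-family name map, because
that is how dissociable sites are identified chemically; atom indices are an
accident of file order.

Also provides the Henderson-Hasselbalch ionization fraction and the
construction of dissociated forms (remove an acidic H, decrement the total
charge), plus OLS fitting and repeated-random-split cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import ChargeSet
from .errors import (CollinearityError, DescriptorError, DimensionError,
                     InvalidDeprotonationError)
from .molecule import Molecule


@dataclass
class QSPRModel:
    """pKa = intercept + coefficients . descriptors."""

    name: str
    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    provenance: str = ""

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if len(self.coefficients) != len(self.descriptor_names):
            raise DimensionError(
                f"{len(self.descriptor_names)} descriptors but "
                f"{len(self.coefficients)} coefficients")

    def predict(self, descriptors: "DescriptorVector") -> float:
        return predict_pka(self, descriptors)

    # JSON model files: {name, descriptor_names[], coefficients[], intercept,
    # provenance}
    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "name": self.name,
            "descriptor_names": list(self.descriptor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "QSPRModel":
        payload = json.loads(Path(path).read_text())
        return cls(name=payload["name"],
                   descriptor_names=list(payload["descriptor_names"]),
                   coefficients=np.array(payload["coefficients"], dtype=float),
                   intercept=float(payload["intercept"]),
                   provenance=payload.get("provenance", ""))


@dataclass
class DescriptorVector:
    """Named charge descriptors for one molecule (units of e)."""

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def row(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.values]
        if missing:
            raise DescriptorError(f"missing descriptor(s): {', '.join(missing)}")
        return np.array([self.values[n] for n in names], dtype=np.float64)


def predict_pka(model: QSPRModel, descriptors: DescriptorVector) -> float:
    """Evaluate the linear model on one descriptor vector."""
    return float(model.intercept + model.coefficients @ descriptors.row(model.descriptor_names))


def extract_descriptors(mol: Molecule, charges: ChargeSet,
                        name_map: dict[str, str]) -> DescriptorVector:
    """Descriptors from named atoms: ``name_map`` maps descriptor name ->
    atom name in this molecule (e.g. {"q_HO4": "HO4", "q_O4": "O4"})."""
    if len(charges) != mol.n_atoms:
        raise DimensionError("charge set does not match molecule")
    by_name = {a.name: a.index for a in mol.atoms}
    values = {}
    for desc, atom_name in name_map.items():
        if atom_name not in by_name:
            raise DescriptorError(
                f"descriptor {desc!r}: no atom named {atom_name!r} in molecule")
        values[desc] = float(charges.values[by_name[atom_name]])
    return DescriptorVector(values)


def make_dissociated(mol: Molecule, acidic_h: int) -> Molecule:
    """Dissociated form: remove one acidic H (or D) and decrement the total
    charge by 1 (a neutral acid becomes the -1 anion)."""
    if not (0 <= acidic_h < mol.n_atoms):
        raise IndexError(f"atom index {acidic_h} out of range")
    atom = mol.atoms[acidic_h]
    if atom.element not in ("H", "D"):
        raise InvalidDeprotonationError(
            f"atom {acidic_h} ({atom.name}) is {atom.element}, not H or D")
    keep = [i for i in range(mol.n_atoms) if i != acidic_h]
    return mol.subset(keep, total_charge=mol.total_charge - 1,
                      source_suffix=f" -{atom.name}")


def ionized_fraction(pka: float, ph: float) -> float:
    """Henderson-Hasselbalch ionized fraction of a monoprotic acid:
    10^(pH-pKa) / (1 + 10^(pH-pKa)), computed stably at extreme pH."""
    x = ph - pka
    if x >= 0:
        return 1.0 / (1.0 + 10.0 ** (-x))
    t = 10.0 ** x
    return t / (1.0 + t)


def fit_qspr(descriptors: Sequence[DescriptorVector],
             observed_pka: Sequence[float],
             descriptor_names: Optional[Sequence[str]] = None,
             name: str = "fitted") -> QSPRModel:
    """Ordinary least squares fit of a linear charge->pKa model.

    Requires n >= p + 1 observations for p descriptors and a full-rank
    design; exact collinearity raises naming the dependent columns.
    """
    if descriptor_names is None:
        descriptor_names = list(descriptors[0].values)
    names = list(descriptor_names)
    y = np.asarray(observed_pka, dtype=np.float64)
    if len(descriptors) != len(y):
        raise DimensionError("descriptor and pKa counts differ")
    if len(y) < len(names) + 1:
        raise DimensionError(
            f"need at least {len(names) + 1} observations to fit "
            f"{len(names)} descriptors + intercept, got {len(y)}")
    x = np.vstack([d.row(names) for d in descriptors])
    design = np.column_stack([np.ones(len(y)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        dependent = _dependent_columns(design, names)
        raise CollinearityError(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(dependent))
    from sklearn.linear_model import LinearRegression

    reg = LinearRegression().fit(x, y)
    return QSPRModel(name=name, descriptor_names=names,
                     coefficients=reg.coef_.copy(),
                     intercept=float(reg.intercept_),
                     provenance=f"OLS fit on {len(y)} molecules")


def _dependent_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns whose removal restores full rank (QR pivot diagnostics)."""
    import scipy.linalg

    _, r, piv = scipy.linalg.qr(design, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    labels = ["intercept"] + list(names)
    return [labels[piv[k]] for k in range(rank, design.shape[1])]


@dataclass
class CVReport:
    """Cross-validation summary: one fitted model and error pair per round."""

    fold_models: list[QSPRModel]
    fold_mae: np.ndarray
    fold_rmse: np.ndarray

    @property
    def mean_mae(self) -> float:
        return float(self.fold_mae.mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.fold_rmse.mean())

    def to_dict(self) -> dict:
        return {
            "folds": len(self.fold_models),
            "fold_mae": [float(v) for v in self.fold_mae],
            "fold_rmse": [float(v) for v in self.fold_rmse],
            "mean_mae": self.mean_mae,
            "mean_rmse": self.mean_rmse,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"fold": np.arange(1, len(self.fold_mae) + 1),
                             "mae": self.fold_mae, "rmse": self.fold_rmse})


def cross_validate(descriptors: Sequence[DescriptorVector],
                   observed_pka: Sequence[float], k: int = 5,
                   train_size: int = 35, seed: int = 0,
                   mode: str = "subsample",
                   descriptor_names: Optional[Sequence[str]] = None) -> CVReport:
    """k rounds of train/validation splitting.

    ``mode="subsample"`` (default) draws ``train_size`` molecules without
    replacement independently each round and validates on the remainder --
    repeated random subsampling, k x (train_size / rest). ``mode="disjoint"``
    uses classical disjoint k-fold partitions instead (``train_size``
    ignored).
    """
    y = np.asarray(observed_pka, dtype=np.float64)
    n = len(y)
    if len(descriptors) != n:
        raise DimensionError("descriptor and pKa counts differ")
    if mode == "subsample" and n < train_size + 1:
        raise DimensionError(
            f"need at least train_size+1={train_size + 1} molecules, got {n}")
    rng = np.random.default_rng(seed)
    models, maes, rmses = [], [], []
    if mode == "disjoint":
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        splits = [(np.setdiff1d(perm, f), f) for f in folds]
    elif mode == "subsample":
        splits = []
        for _ in range(k):
            train = rng.choice(n, size=train_size, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[train] = False
            splits.append((train, np.nonzero(mask)[0]))
    else:
        raise ValueError(f"unknown CV mode {mode!r}")
    for rnd, (train, val) in enumerate(splits):
        model = fit_qspr([descriptors[i] for i in train], y[train],
                         descriptor_names=descriptor_names,
                         name=f"cv-round-{rnd + 1}")
        pred = np.array([model.predict(descriptors[i]) for i in val])
        err = pred - y[val]
        models.append(model)
        maes.append(np.abs(err).mean())
        rmses.append(np.sqrt((err ** 2).mean()))
    return CVReport(fold_models=models, fold_mae=np.array(maes),
                    fold_rmse=np.array(rmses))
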