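"""Charge aggregation, descriptive statistics and pairwise comparison.

Residue charges (per-residue sums of atomic charges) are the analysis unit
for peptides and large complexes, where single-atom values are noisy but
group sums track biologically meaningful electron-density shifts. Statistics
tables use the population standard deviation (the atom set is the whole
population, not a sample). Comparisons report squared Pearson correlation,
Spearman rank correlation (average ranks on ties), RMSD and the sum of
absolute differences; correlations on a zero-variance vector are flagged
undefined (NaN) rather than silently zeroed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChargeSet
from .errors import DimensionError, EmptyInputError
from .molecule import Molecule, Residue


@dataclass
class ResidueChargeSet:
    """Summed charge per residue, in molecule residue order."""

    residues: list[Residue]
    values: np.ndarray
    source_job: Optional[object] = None  # JobTag of the atomic set, if any

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.residues) != len(self.values):
            raise DimensionError("residue and value counts differ")

    def __len__(self) -> int:
        return len(self.values)

    def total(self) -> float:
        return float(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [r.chain for r in self.residues],
            "seq_number": [r.seq_number for r in self.residues],
            "insertion_code": [r.insertion_code for r in self.residues],
            "residue": [r.name for r in self.residues],
            "charge": self.values,
        })


def residue_charges(mol: Molecule, charges: ChargeSet) -> ResidueChargeSet:
    """Sum atomic charges within each residue (residue order preserved)."""
    if len(charges) != mol.n_atoms:
        raise DimensionError(
            f"{len(charges)} charges for {mol.n_atoms} atoms")
    sums = np.zeros(len(mol.residues))
    for atom in mol.atoms:
        sums[atom.residue_key] += charges.values[atom.index]
    return ResidueChargeSet(residues=list(mol.residues), values=sums,
                            source_job=charges.job)


def group_charge(rcs: ResidueChargeSet,
                 selection: Callable[[Residue], bool]) -> float:
    """Sum of residue charges over residues matching a predicate (e.g. a
    chain for subunit charges). Empty selection sums to 0."""
    total = 0.0
    for res, val in zip(rcs.residues, rcs.values):
        if selection(res):
            total += val
    return total


@dataclass
class StatsTable:
    """Descriptive statistics per group; ``group=None`` labels the whole set."""

    frame: pd.DataFrame  # columns: group, count, min, max, mean, median, std

    def to_csv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.frame.to_dict(orient="records"), indent=2) + "\n")

    def row(self, group: str) -> pd.Series:
        hit = self.frame[self.frame["group"] == group]
        if hit.empty:
            raise KeyError(f"no statistics group {group!r}")
        return hit.iloc[0]


def _stats_row(group: str, vals: np.ndarray) -> dict:
    return {
        "group": group,
        "count": int(len(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        # population standard deviation: these are all the atoms there are
        "std": float(vals.std(ddof=0)),
    }


def charge_statistics(values: Union[ChargeSet, ResidueChargeSet],
                      mol: Optional[Molecule] = None,
                      group_by: str = "none") -> StatsTable:
    """Per-group count/min/max/mean/median/std of a charge set.

    ``group_by`` is ``"element"`` (atomic sets; requires ``mol``),
    ``"residue_name"`` (atomic or residue sets) or ``"none"`` for one row
    over the whole set. An "all" row is always included.
    """
    if isinstance(values, ChargeSet):
        vals = values.values
        if group_by == "element":
            if mol is None:
                raise ValueError("grouping by element requires the molecule")
            labels = np.array(mol.elements)
        elif group_by == "residue_name":
            if mol is None:
                raise ValueError("grouping by residue name requires the molecule")
            labels = np.array([mol.residue_of(a).name for a in mol.atoms])
        elif group_by == "none":
            labels = None
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
    else:
        vals = values.values
        if group_by == "residue_name":
            labels = np.array([r.name for r in values.residues])
        elif group_by == "none":
            labels = None
        else:
            raise ValueError(
                f"group_by {group_by!r} not available for residue charge sets")
    if len(vals) == 0:
        raise EmptyInputError("cannot compute statistics of an empty value set")
    rows = [_stats_row("all", vals)]
    if labels is not None:
        for g in sorted(set(labels)):
            rows.append(_stats_row(g, vals[labels == g]))
    return StatsTable(frame=pd.DataFrame(rows))


@dataclass
class ComparisonMetrics:
    """Pairwise charge-set comparison indicators.

    ``r_squared``/``spearman`` are NaN with ``correlation_defined=False``
    when either vector has zero variance.
    """

    r_squared: float
    spearman: float
    rmsd: float
    sum_abs_diff: float
    n: int
    correlation_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "spearman": self.spearman,
            "rmsd": self.rmsd,
            "sum_abs_diff": self.sum_abs_diff,
            "n": self.n,
            "correlation_defined": self.correlation_defined,
        }


def compare_charge_sets(a: Union[ChargeSet, ResidueChargeSet, np.ndarray],
                        b: Union[ChargeSet, ResidueChargeSet, np.ndarray]
                        ) -> ComparisonMetrics:
    """Squared Pearson, Spearman, RMSD and sum of absolute differences."""
    va = a.values if hasattr(a, "values") else np.asarray(a, dtype=float)
    vb = b.values if hasattr(b, "values") else np.asarray(b, dtype=float)
    if len(va) != len(vb):
        raise DimensionError(f"charge sets differ in length: {len(va)} vs {len(vb)}")
    if len(va) < 2:
        raise DimensionError("need at least 2 values to compare charge sets")
    diff = va - vb
    rmsd = float(np.sqrt((diff ** 2).mean()))
    sad = float(np.abs(diff).sum())
    if va.max() == va.min() or vb.max() == vb.min():
        return ComparisonMetrics(r_squared=float("nan"), spearman=float("nan"),
                                 rmsd=rmsd, sum_abs_diff=sad, n=len(va),
                                 correlation_defined=False)
    pearson = stats.pearsonr(va, vb).statistic
    spearman = stats.spearmanr(va, vb).statistic
    return ComparisonMetrics(r_squared=float(pearson ** 2),
                             spearman=float(spearman), rmsd=rmsd,
                             sum_abs_diff=sad, n=len(va))
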