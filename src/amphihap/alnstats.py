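"""Site-class statistics and pairwise p-distances on a DNA alignment.

Missing-data convention: gaps and N are missing. A column is *constant*
when exactly one determinate state (A/C/G/T) occurs among its non-missing
entries; *parsimony-informative* when at least two states each occur in at
least two sequences; remaining variable columns are uninformative;
columns with no determinate state at all are counted separately. The four
classes partition the alignment exactly.

Distances use pairwise deletion: for each taxon pair, only columns where
both are determinate are compared, which is how whole-plastome percent
divergences are conventionally quoted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import _dna
from .errors import AlignmentError, InputError
from .io import Alignment

log = logging.getLogger("amphihap.alnstats")

__all__ = [
    "SiteClassSummary",
    "DistanceMatrix",
    "classify_sites",
    "p_distance_matrix",
    "group_divergence",
]


@dataclass(frozen=True)
class SiteClassSummary:
    aligned_length: int
    constant: int
    variable_uninformative: int
    parsimony_informative: int
    all_missing: int

    def __post_init__(self) -> None:
        total = (
            self.constant
            + self.variable_uninformative
            + self.parsimony_informative
            + self.all_missing
        )
        if total != self.aligned_length:
            raise AlignmentError("site classes do not partition the alignment")

    @property
    def constant_fraction(self) -> float:
        return self.constant / self.aligned_length

    @property
    def parsimony_informative_fraction(self) -> float:
        return self.parsimony_informative / self.aligned_length


@dataclass
class DistanceMatrix:
    """Pairwise p-distances (fractions) with pairwise-deletion site counts."""

    taxa: list[str]
    d: np.ndarray
    n_eff: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def classify_sites(aln: Alignment) -> SiteClassSummary:
    """Count constant / variable / parsimony-informative / all-missing columns."""
    matrix = aln.to_matrix()
    counts = np.stack([(matrix == b).sum(axis=0) for b in _dna.DETERMINATE])
    n_det = counts.sum(axis=0)
    k_states = (counts >= 1).sum(axis=0)
    k_shared = (counts >= 2).sum(axis=0)
    all_missing = n_det == 0
    constant = k_states == 1
    informative = k_shared >= 2
    uninformative = ~all_missing & ~constant & ~informative
    return SiteClassSummary(
        aligned_length=aln.length,
        constant=int(constant.sum()),
        variable_uninformative=int(uninformative.sum()),
        parsimony_informative=int(informative.sum()),
        all_missing=int(all_missing.sum()),
    )


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise-deletion p-distances between all taxon pairs.

    Pairs with no comparable site get distance NaN (with a warning) rather
    than an exception — an all-gap taxon should not abort a whole-matrix
    computation.
    """
    matrix = aln.to_matrix()
    determinate = np.isin(matrix, _dna.DETERMINATE)
    n = len(aln.taxa)
    d = np.zeros((n, n), dtype=float)
    n_eff = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        n_eff[i, i] = int(determinate[i].sum())
        for j in range(i + 1, n):
            both = determinate[i] & determinate[j]
            m = int(both.sum())
            n_eff[i, j] = n_eff[j, i] = m
            if m == 0:
                log.warning(
                    "taxa %s and %s share no comparable sites; distance undefined",
                    aln.taxa[i],
                    aln.taxa[j],
                )
                d[i, j] = d[j, i] = np.nan
                continue
            mismatches = int(((matrix[i] != matrix[j]) & both).sum())
            d[i, j] = d[j, i] = mismatches / m
    return DistanceMatrix(taxa=list(aln.taxa), d=d, n_eff=n_eff)


def group_divergence(
    dm: DistanceMatrix, partition: Mapping[str, str]
) -> pd.DataFrame:
    """Min/mean/max p-distance for every (ordered-once) group pair.

    Within-group rows are included; a singleton group has no within-group
    pair, which is reported as NaN with ``n_pairs`` 0 rather than an error.
    Every taxon must be assigned to a group.
    """
    missing = [t for t in dm.taxa if t not in partition]
    if missing:
        raise InputError(f"taxa not assigned to any group: {missing}")
    groups = sorted(set(partition[t] for t in dm.taxa))
    index = {t: i for i, t in enumerate(dm.taxa)}
    rows = []
    for gi, ga in enumerate(groups):
        for gb in groups[gi:]:
            ta = [index[t] for t in dm.taxa if partition[t] == ga]
            tb = [index[t] for t in dm.taxa if partition[t] == gb]
            if ga == gb:
                values = [
                    dm.d[i, j] for k, i in enumerate(ta) for j in ta[k + 1 :]
                ]
            else:
                values = [dm.d[i, j] for i in ta for j in tb]
            values = [v for v in values if not np.isnan(v)]
            if not values:
                log.warning("group pair (%s, %s) has no comparable taxon pair", ga, gb)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "n_pairs": len(values),
                    "min": min(values) if values else np.nan,
                    "mean": float(np.mean(values)) if values else np.nan,
                    "max": max(values) if values else np.nan,
                }
            )
    return pd.DataFrame(rows)
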