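"""Attribute-driven contrasts on the incidence matrix.

Two analyses live here:

* a paired supplement contrast — the same panel of conditions run with
  and without a supplement (e.g. rumen fluid), compared on union richness
  and on the proportion of arm-specific species with a Pearson chi-square;
* the atmosphere × oxygen-phenotype cross-tabulation — each species is
  assigned to exactly one recovery class (anaerobic-only, aerobic-only or
  both) from the union of same-atmosphere conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .cover import round_half_up
from .errors import DegenerateTableError
from .model import OXYGEN_PHENOTYPES, IncidenceMatrix

RECOVERY_CLASSES = ("anaerobic_only", "aerobic_only", "both")


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square result on a 2×2 table (df = 1)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p_value: float
    correction: bool


@dataclass(frozen=True)
class PairedContrast:
    """Paired with/without-supplement comparison of two condition arms."""

    arm_a: tuple[str, ...]
    arm_b: tuple[str, ...]
    richness_a: int
    richness_b: int
    specific_a: int
    specific_b: int
    shared: int
    test: ContingencyResult


def pearson_chi2(table, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square test of homogeneity on a 2×2 count table.

    The statistic is the classical cellwise sum of
    ``(observed - expected)^2 / expected`` with expected counts from the
    row/column margins; with ``correction`` (Yates), ``|O - E|`` is
    reduced by 0.5 (floored at 0) before squaring.  The p-value is the
    exact df-1 upper tail, ``erfc(sqrt(chi2 / 2))``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError(
            f"zero margin in table {obs.astype(int).tolist()}"
        )
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(erfc(math.sqrt(chi2 / 2)))
    return ContingencyResult(
        table=tuple(tuple(int(x) for x in row) for row in np.asarray(table)),
        chi2=chi2,
        df=1,
        p_value=max(p, 0.0) if p > 0 else 5e-324,  # keep p in (0, 1]
        correction=correction,
    )


def paired_supplement_contrast(
    matrix: IncidenceMatrix,
    arm_a: Sequence[str],
    arm_b: Sequence[str],
    correction: bool = False,
) -> PairedContrast:
    """Compare two equal-length condition arms (with vs without supplement).

    Per arm: union species richness, arm-specific species (recovered by
    that arm and not the other) and the shared count.  The chi-square
    contrasts the proportion of arm-specific species on the table
    ``[[specific_a, shared], [specific_b, shared]]``.  When both arms
    recover exactly the same species set there is nothing to test and the
    result is chi2 = 0, p = 1.
    """
    if not arm_a or not arm_b:
        raise ValueError("both arms must be non-empty")
    if set(arm_a) & set(arm_b):
        raise ValueError(f"arms overlap: {sorted(set(arm_a) & set(arm_b))}")
    if len(arm_a) != len(arm_b):
        raise ValueError(
            f"paired arms must have equal length ({len(arm_a)} vs {len(arm_b)})"
        )
    a = matrix.species_for_any(arm_a)
    b = matrix.species_for_any(arm_b)
    spec_a, spec_b, shared = len(a - b), len(b - a), len(a & b)
    table = ((spec_a, shared), (spec_b, shared))
    if spec_a == 0 and spec_b == 0:
        test = ContingencyResult(table, 0.0, 1, 1.0, correction)
    else:
        test = pearson_chi2(table, correction=correction)
    return PairedContrast(
        arm_a=tuple(arm_a),
        arm_b=tuple(arm_b),
        richness_a=len(a),
        richness_b=len(b),
        specific_a=spec_a,
        specific_b=spec_b,
        shared=shared,
        test=test,
    )


def atmosphere_crosstab(
    matrix: IncidenceMatrix,
    species_meta: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Recovery-class × oxygen-phenotype species counts with margins.

    Each species falls in exactly one recovery class from the union of
    its detections over same-atmosphere conditions.  ``species_meta`` maps
    normalized species name → phenotype; species without a phenotype are
    counted under ``"unknown"``, never dropped.  By default phenotypes
    come from the matrix's own species metadata.  The returned frame has
    a ``total`` margin row and column; percentages of the grand total are
    attached in ``DataFrame.attrs["percent"]`` (half-up integers).
    """
    anaero = [c for c in matrix.conditions if matrix.condition(c).atmosphere == "anaerobic"]
    aero = [c for c in matrix.conditions if matrix.condition(c).atmosphere == "aerobic"]
    in_an = matrix.mask_for_any(anaero)
    in_ae = matrix.mask_for_any(aero)

    if species_meta is None:
        species_meta = {
            n: matrix.species_record(n).oxygen_phenotype
            for n in matrix.normalized_species()
        }
    phenos = []
    for n in matrix.normalized_species():
        p = species_meta.get(n, "unknown")
        phenos.append(p if p in OXYGEN_PHENOTYPES else "unknown")

    classes = np.where(in_an & in_ae, "both", np.where(in_an, "anaerobic_only", "aerobic_only"))
    df = pd.DataFrame({"recovery": classes, "phenotype": phenos})
    tab = pd.crosstab(df["recovery"], df["phenotype"])
    tab = tab.reindex(index=list(RECOVERY_CLASSES), fill_value=0)
    tab.loc["total"] = tab.sum()
    tab["total"] = tab.sum(axis=1)
    grand = int(tab.loc["total", "total"])
    tab.attrs["percent"] = tab.map(
        lambda v: round_half_up(100 * v / grand) if grand else 0
    )
    return tab
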