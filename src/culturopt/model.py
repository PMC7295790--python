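"""Domain types: culture conditions, species records, and the binary
species × condition incidence matrix.

The incidence matrix is the substrate of the whole analysis: cell
``(i, j)`` is 1 when species ``i`` was isolated at least once under
condition ``j``.  Two structural invariants are enforced at construction:

* every species row has at least one 1 (a species only exists in the data
  because some condition grew it, so all-zero rows are a data error);
* all-zero condition columns are legal (a condition that grew nothing is
  still a condition that was run).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MatrixValidationError, UnknownConditionError

ATMOSPHERES = frozenset({"aerobic", "anaerobic"})
SUPPLEMENTS = frozenset({"rumen_fluid", "sheep_blood", "lamb_serum", "none"})
PRETREATMENTS = frozenset(
    {"none", "alcohol", "thermic_shock", "filtration_0_45um", "filtration_5um"}
)
OXYGEN_PHENOTYPES = frozenset(
    {"strict_anaerobe", "oxygen_tolerant", "strict_aerobe", "unknown"}
)

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical species-name form: stripped, case-folded, internal
    whitespace collapsed to single spaces.

    Species identity throughout the package is exact match on this form;
    no fuzzy synonym resolution is attempted.
    """
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class Condition:
    """A culture condition and its design attributes.

    ``id`` is a machine-safe slug (e.g. ``"HRS_Ana_37"``); ``label`` holds
    the free-text description.  ``group`` is an optional panel tag used by
    the partition analysis (e.g. ``"18_standard"``).
    """

    id: str
    label: str = ""
    atmosphere: str = "anaerobic"
    temperature_c: float = 37.0
    supplements: frozenset[str] = field(default_factory=lambda: frozenset({"none"}))
    pretreatment: str = "none"
    group: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("condition id must be non-empty")
        if self.atmosphere not in ATMOSPHERES:
            raise ValueError(
                f"atmosphere {self.atmosphere!r} not in {sorted(ATMOSPHERES)}"
            )
        if not self.temperature_c > 0:
            raise ValueError("temperature_c must be > 0")
        unknown = set(self.supplements) - SUPPLEMENTS
        if unknown:
            raise ValueError(f"unknown supplements: {sorted(unknown)}")
        if self.pretreatment not in PRETREATMENTS:
            raise ValueError(
                f"pretreatment {self.pretreatment!r} not in {sorted(PRETREATMENTS)}"
            )


@dataclass(frozen=True)
class SpeciesRecord:
    """A bacterial species: phylum, oxygen phenotype and novelty status."""

    name: str
    phylum: str = "unknown"
    oxygen_phenotype: str = "unknown"
    is_new_taxon: bool = False
    accession: str | None = None

    def __post_init__(self):
        if not self.name.strip():
            raise ValueError("species name must be non-empty")
        if self.oxygen_phenotype not in OXYGEN_PHENOTYPES:
            raise ValueError(
                f"oxygen_phenotype {self.oxygen_phenotype!r} "
                f"not in {sorted(OXYGEN_PHENOTYPES)}"
            )


class IncidenceMatrix:
    """Binary species × condition detection matrix.

    Parameters
    ----------
    cells
        Boolean/0-1 array of shape (n_species, n_conditions).
    species
        Species names, one per row.  Names are normalized for identity
        (see :func:`normalize_name`); the first-seen surface form is kept
        for display.
    conditions
        Condition ids, one per column.
    condition_meta, species_meta
        Optional maps from condition id / normalized species name to
        :class:`Condition` / :class:`SpeciesRecord`.  Ids absent from the
        maps fall back to default attributes on access.
    """

    def __init__(
        self,
        cells,
        species: Sequence[str],
        conditions: Sequence[str],
        condition_meta: Mapping[str, Condition] | None = None,
        species_meta: Mapping[str, SpeciesRecord] | None = None,
    ):
        cells = np.asarray(cells)
        if cells.ndim != 2:
            raise MatrixValidationError("cells must be 2-dimensional")
        cells = cells.astype(bool)
        if cells.shape != (len(species), len(conditions)):
            raise MatrixValidationError(
                f"cells shape {cells.shape} does not match "
                f"{len(species)} species × {len(conditions)} conditions"
            )
        if len(set(conditions)) != len(conditions):
            raise MatrixValidationError("duplicate condition ids")
        norm = [normalize_name(s) for s in species]
        if len(set(norm)) != len(norm):
            dupes = sorted({n for n in norm if norm.count(n) > 1})
            raise MatrixValidationError(f"duplicate species after normalization: {dupes}")
        empty = [species[i] for i in np.flatnonzero(~cells.any(axis=1))]
        if empty:
            raise MatrixValidationError(
                f"{len(empty)} species with zero incidences: {empty[:10]}"
            )
        self._cells = cells
        self._cells.setflags(write=False)
        self.species: tuple[str, ...] = tuple(str(s).strip() for s in species)
        self.conditions: tuple[str, ...] = tuple(str(c) for c in conditions)
        self._norm_species = tuple(norm)
        self._col = {c: j for j, c in enumerate(self.conditions)}
        self._row = {n: i for i, n in enumerate(norm)}
        self.condition_meta = dict(condition_meta or {})
        self.species_meta = dict(species_meta or {})

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        condition_meta: Mapping[str, Condition] | None = None,
        species_meta: Mapping[str, SpeciesRecord] | None = None,
        extra_conditions: Iterable[str] = (),
    ) -> "IncidenceMatrix":
        """Build from (species, condition) detection pairs.

        Duplicate pairs collapse to a single 1.  ``extra_conditions`` adds
        all-zero columns for conditions that were run but grew nothing.
        Row order follows first appearance of each species; column order
        follows first appearance of each condition.
        """
        species_order: dict[str, str] = {}  # normalized -> surface form
        cond_order: dict[str, None] = {}
        pairs: set[tuple[str, str]] = set()
        for sp, cond in records:
            key = normalize_name(sp)
            if not key:
                raise MatrixValidationError("empty species name in records")
            species_order.setdefault(key, str(sp).strip())
            cond_order.setdefault(str(cond), None)
            pairs.add((key, str(cond)))
        for cond in extra_conditions:
            cond_order.setdefault(str(cond), None)
        species = list(species_order.values())
        conditions = list(cond_order)
        cells = np.zeros((len(species), len(conditions)), dtype=bool)
        rown = {k: i for i, k in enumerate(species_order)}
        coln = {c: j for j, c in enumerate(conditions)}
        for key, cond in pairs:
            cells[rown[key], coln[cond]] = True
        return cls(cells, species, conditions, condition_meta, species_meta)

    # -- basic queries ----------------------------------------------------

    @property
    def cells(self) -> np.ndarray:
        return self._cells

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def shape(self) -> tuple[int, int]:
        return self._cells.shape

    def column(self, condition: str) -> np.ndarray:
        """Boolean detection vector for one condition."""
        try:
            return self._cells[:, self._col[condition]]
        except KeyError:
            raise UnknownConditionError(condition) from None

    def richness(self, condition: str) -> int:
        """Number of distinct species the condition isolated."""
        return int(self.column(condition).sum())

    def species_for(self, condition: str) -> frozenset[str]:
        """Set of (normalized) species names detected under a condition."""
        col = self.column(condition)
        return frozenset(
            n for n, hit in zip(self._norm_species, col) if hit
        )

    def species_for_any(self, conditions: Iterable[str]) -> frozenset[str]:
        """Union of species over several conditions."""
        mask = self.mask_for_any(conditions)
        return frozenset(
            n for n, hit in zip(self._norm_species, mask) if hit
        )

    def mask_for_any(self, conditions: Iterable[str]) -> np.ndarray:
        """Boolean species mask: detected under at least one of ``conditions``."""
        idx = [self._col[c] if c in self._col else self._missing(c) for c in conditions]
        if not idx:
            return np.zeros(self.n_species, dtype=bool)
        return self._cells[:, idx].any(axis=1)

    def _missing(self, c: str):
        raise UnknownConditionError(c)

    def condition(self, condition_id: str) -> Condition:
        """Condition metadata, defaulting when none was supplied."""
        if condition_id not in self._col:
            raise UnknownConditionError(condition_id)
        return self.condition_meta.get(condition_id, Condition(id=condition_id))

    def species_record(self, name: str) -> SpeciesRecord:
        key = normalize_name(name)
        if key not in self._row:
            raise KeyError(name)
        return self.species_meta.get(key, SpeciesRecord(name=self.species[self._row[key]]))

    def normalized_species(self) -> tuple[str, ...]:
        return self._norm_species

    def to_frame(self) -> pd.DataFrame:
        """Wide 0/1 DataFrame: species rows, condition columns."""
        return pd.DataFrame(
            self._cells.astype(int), index=list(self.species), columns=list(self.conditions)
        )

    def _relation(self) -> frozenset[tuple[str, str]]:
        i, j = np.nonzero(self._cells)
        return frozenset(
            (self._norm_species[a], self.conditions[b]) for a, b in zip(i, j)
        )

    def __eq__(self, other) -> bool:
        """Equality of the detection relation: same species set, same
        condition set, same cells — row/column order is presentational."""
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            set(self._norm_species) == set(other._norm_species)
            and set(self.conditions) == set(other.conditions)
            and self._relation() == other._relation()
        )

    def __repr__(self) -> str:
        return (
            f"IncidenceMatrix({self.n_species} species × "
            f"{self.n_conditions} conditions, {int(self._cells.sum())} detections)"
        )
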