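"""Readers and writers for the tabular interchange formats.

Two matrix dialects are supported:

* **long TSV** (canonical): header + one ``species<TAB>condition`` row per
  detection; an optional third ``count`` column is tolerated (presence is
  what matters, the value is ignored).
* **wide CSV**: first column ``species``, remaining columns condition ids,
  cells ``0``/``1`` — the spreadsheet-friendly view.

Condition metadata TSV columns:
``id, label, atmosphere, temperature_c, supplements, pretreatment, group``
(``supplements`` is a semicolon-separated list).  Species metadata TSV
columns: ``name, phylum, oxygen_phenotype, is_new_taxon, accession``.
All files are UTF-8 with a header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import EmptyInputError, FormatError
from .model import Condition, IncidenceMatrix, SpeciesRecord, normalize_name

log = logging.getLogger(__name__)


def _read_table(path, sep: str, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{what} file {path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{what} file {path} has a header but no rows")
    return df


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_condition_meta(path) -> dict[str, Condition]:
    """Parse a condition-metadata TSV into ``{id: Condition}``."""
    df = _read_table(path, "\t", "condition metadata")
    _require_columns(df, ["id"], path)
    meta: dict[str, Condition] = {}
    for _, row in df.iterrows():
        supplements = frozenset(
            s.strip() for s in str(row.get("supplements") or "none").split(";") if s.strip()
        ) or frozenset({"none"})
        group = row.get("group")
        meta[str(row["id"])] = Condition(
            id=str(row["id"]),
            label=str(row.get("label") or ""),
            atmosphere=str(row.get("atmosphere") or "anaerobic"),
            temperature_c=float(row.get("temperature_c") or 37.0),
            supplements=supplements,
            pretreatment=str(row.get("pretreatment") or "none"),
            group=None if pd.isna(group) or group == "" else str(group),
        )
    return meta


def read_species_meta(path) -> dict[str, SpeciesRecord]:
    """Parse a species-metadata TSV into ``{normalized name: SpeciesRecord}``."""
    df = _read_table(path, "\t", "species metadata")
    _require_columns(df, ["name"], path)
    meta: dict[str, SpeciesRecord] = {}
    for _, row in df.iterrows():
        acc = row.get("accession")
        rec = SpeciesRecord(
            name=str(row["name"]),
            phylum=str(row.get("phylum") or "unknown"),
            oxygen_phenotype=str(row.get("oxygen_phenotype") or "unknown"),
            is_new_taxon=str(row.get("is_new_taxon") or "false").strip().lower()
            in {"1", "true", "yes"},
            accession=None if pd.isna(acc) or acc == "" else str(acc),
        )
        meta[normalize_name(rec.name)] = rec
    return meta


def _attach_meta(
    matrix_species: tuple[str, ...],
    matrix_conditions: tuple[str, ...],
    condition_meta: Mapping[str, Condition] | None,
    species_meta: Mapping[str, SpeciesRecord] | None,
):
    """Warn about metadata rows that reference nothing in the matrix."""
    if condition_meta:
        unused = sorted(set(condition_meta) - set(matrix_conditions))
        if unused:
            log.warning("ignoring %d condition metadata rows not in matrix: %s",
                        len(unused), unused[:5])
    if species_meta:
        norm = {normalize_name(s) for s in matrix_species}
        unused = sorted(set(species_meta) - norm)
        if unused:
            log.warning("ignoring %d species metadata rows not in matrix: %s",
                        len(unused), unused[:5])


def read_long_tsv(path, condition_meta=None, species_meta=None) -> IncidenceMatrix:
    """Read a long-format detection TSV into a validated matrix.

    ``condition_meta`` / ``species_meta`` may be file paths or pre-parsed
    dicts.  Matrix entries without metadata get default attributes;
    metadata rows without matrix entries are ignored with a warning.
    """
    df = _read_table(path, "\t", "incidence")
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: long format needs >= 2 columns (species, condition); "
            f"found {list(df.columns)}"
        )
    cols = [c.lower() for c in df.columns]
    if "species" in cols and "condition" in cols:
        sp_col = df.columns[cols.index("species")]
        cond_col = df.columns[cols.index("condition")]
    else:  # positional fallback: first = species, second = condition
        sp_col, cond_col = df.columns[:2]
    cmeta = read_condition_meta(condition_meta) if isinstance(condition_meta, (str, Path)) else condition_meta
    smeta = read_species_meta(species_meta) if isinstance(species_meta, (str, Path)) else species_meta
    records = list(zip(df[sp_col].astype(str), df[cond_col].astype(str)))
    extra = [c for c in (cmeta or {}) if c not in set(df[cond_col])]
    m = IncidenceMatrix.from_records(
        records, condition_meta=cmeta, species_meta=smeta, extra_conditions=extra
    )
    _attach_meta(m.species, m.conditions, cmeta, smeta)
    return m


def write_long_tsv(matrix: IncidenceMatrix, path) -> None:
    """Write the matrix as the canonical long TSV (one row per detection)."""
    rows = []
    for i, sp in enumerate(matrix.species):
        for j, cond in enumerate(matrix.conditions):
            if matrix.cells[i, j]:
                rows.append((sp, cond))
    pd.DataFrame(rows, columns=["species", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def read_wide_csv(path, condition_meta=None, species_meta=None) -> IncidenceMatrix:
    """Read a wide 0/1 CSV (species rows × condition columns)."""
    df = _read_table(path, ",", "incidence")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: wide format needs a species column plus >= 1 condition column")
    sp_col = df.columns[0]
    cond_cols = list(df.columns[1:])
    try:
        cells = df[cond_cols].astype(int).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in wide matrix: {exc}") from None
    cmeta = read_condition_meta(condition_meta) if isinstance(condition_meta, (str, Path)) else condition_meta
    smeta = read_species_meta(species_meta) if isinstance(species_meta, (str, Path)) else species_meta
    m = IncidenceMatrix(cells, list(df[sp_col].astype(str)), cond_cols, cmeta, smeta)
    _attach_meta(m.species, m.conditions, cmeta, smeta)
    return m


def write_wide_csv(matrix: IncidenceMatrix, path) -> None:
    """Write the wide 0/1 CSV; all-zero condition columns are preserved."""
    df = matrix.to_frame()
    df.index.name = "species"
    df.to_csv(path)


def read_catalogue(path) -> frozenset[str]:
    """Read a reference species catalogue: plain text, one name per line.

    Names are normalized the same way as matrix species, so catalogue
    comparison is exact-match on the canonical form.
    """
    names = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(normalize_name(line))
    if not names:
        raise EmptyInputError(f"catalogue {path} contains no names")
    return frozenset(names)
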