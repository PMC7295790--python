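"""End-to-end analysis runner: rank → cover panel → group partition →
supplement contrast → atmosphere crosstab, with all reports written to an
output directory together with the resolved configuration (provenance).

Every report is a deterministic function of the inputs and the seeds in
the configuration, so a rerun with the same config reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import contrasts, cover, partitions
from .errors import StageError
from .io import read_long_tsv, read_wide_csv
from .model import IncidenceMatrix

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for :func:`run_full_analysis`.

    Exactly one of ``matrix_path`` (long TSV or wide CSV, by extension)
    must be set.  Optional stages run only when their parameters are
    given: ``groups`` for the partition, ``arm_a``/``arm_b`` for the
    supplement contrast.
    """

    matrix_path: str = ""
    condition_meta_path: str | None = None
    species_meta_path: str | None = None
    out_dir: str = "culturopt_out"
    top_k: int | None = None
    target_fraction: float = 1.0
    seed_condition: str | None = None
    force_include: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    arm_a: list[str] = field(default_factory=list)
    arm_b: list[str] = field(default_factory=list)
    n_permutations: int = 0  # accumulation curve off by default
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_matrix(config: RunConfig) -> IncidenceMatrix:
    path = Path(config.matrix_path)
    reader = read_wide_csv if path.suffix.lower() == ".csv" else read_long_tsv
    return reader(path, config.condition_meta_path, config.species_meta_path)


def _cleanup(written: list[Path]) -> None:
    for p in written:
        if p.exists():
            p.rename(p.with_suffix(p.suffix + ".failed"))


def run_full_analysis(
    config: RunConfig, matrix: IncidenceMatrix | None = None
) -> dict[str, Path]:
    """Run every configured stage and write the report bundle.

    Returns ``{report name: path}``.  On a stage failure the partial
    outputs are renamed with a ``.failed`` suffix and a
    :class:`~culturopt.errors.StageError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    reports: dict[str, Path] = {}
    summary: list[str] = []

    def emit(name: str, path: Path) -> None:
        written.append(path)
        reports[name] = path

    stage = "load"
    try:
        if matrix is None:
            matrix = load_matrix(config)
        log.info("loaded matrix: %d species × %d conditions",
                 matrix.n_species, matrix.n_conditions)
        summary.append(f"matrix: {matrix.n_species} species x {matrix.n_conditions} conditions")

        stage = "config"
        cfg_path = out / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8")
        emit("config", cfg_path)

        stage = "rank"
        ranked = cover.rank_by_richness(matrix, config.top_k)
        rank_path = out / "rank.tsv"
        with open(rank_path, "w", encoding="utf-8") as fh:
            fh.write("condition\trichness\n")
            for c, r in ranked:
                fh.write(f"{c}\t{r}\n")
        emit("rank", rank_path)
        summary.append(f"richest condition: {ranked[0][0]} ({ranked[0][1]} species)")

        stage = "cover"
        result = cover.greedy_cover(
            matrix,
            target_fraction=config.target_fraction,
            seed_condition=config.seed_condition,
            force_include=config.force_include,
        )
        report = cover.panel_report(result, matrix)
        panel_path = out / "panel.tsv"
        report.to_csv(panel_path, sep="\t", index=False)
        emit("panel", panel_path)
        log.info("cover: %d conditions for %.1f%% of %d species",
                 len(result), 100 * result.fraction, result.total_species)
        summary.append(
            f"panel: {len(result)} conditions cover {result.covered}/"
            f"{result.total_species} species ({100 * result.fraction:.1f}%)"
        )

        if config.n_permutations > 0:
            stage = "accumulation"
            curve = cover.accumulation_curve(matrix, config.n_permutations, config.seed)
            curve_path = out / "accumulation.tsv"
            curve.to_csv(curve_path, sep="\t", index=False, float_format="%.4f")
            emit("accumulation", curve_path)

        if config.groups:
            stage = "groups"
            part = partitions.partition(matrix, config.groups)
            part_path = out / "partition.json"
            payload = {
                "groups": list(part.groups),
                "region_counts": part.region_counts,
                "union_size": part.union_size,
                "common": part.common,
                "percent_common": part.percent_common,
                "group_totals": {g: part.group_total(g) for g in part.groups},
            }
            part_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                                 encoding="utf-8")
            emit("partition", part_path)
            summary.append(
                f"groups {'/'.join(part.groups)}: union {part.union_size}, "
                f"common {part.common} ({part.percent_common}%)"
            )

        if config.arm_a or config.arm_b:
            stage = "contrast"
            res = contrasts.paired_supplement_contrast(matrix, config.arm_a, config.arm_b)
            contrast_path = out / "contrast.json"
            payload = {
                "arm_a": list(res.arm_a),
                "arm_b": list(res.arm_b),
                "richness_a": res.richness_a,
                "richness_b": res.richness_b,
                "specific_a": res.specific_a,
                "specific_b": res.specific_b,
                "shared": res.shared,
                "table": [list(r) for r in res.test.table],
                "table_layout": "[[specific_a, shared], [specific_b, shared]]",
                "chi2": res.test.chi2,
                "df": res.test.df,
                "p_value": res.test.p_value,
                "correction": res.test.correction,
            }
            contrast_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                                     encoding="utf-8")
            emit("contrast", contrast_path)
            log.info("contrast: richness %d vs %d, chi2 %.2f",
                     res.richness_a, res.richness_b, res.test.chi2)
            summary.append(
                f"supplement contrast: richness {res.richness_a} vs {res.richness_b}, "
                f"specific {res.specific_a} vs {res.specific_b}, "
                f"chi2 {res.test.chi2:.2f} (p {res.test.p_value:.3g})"
            )

        stage = "crosstab"
        tab = contrasts.atmosphere_crosstab(matrix)
        crosstab_path = out / "crosstab.tsv"
        tab.to_csv(crosstab_path, sep="\t")
        emit("crosstab", crosstab_path)

        stage = "summary"
        summary_path = out / "summary.txt"
        summary_path.write_text("\n".join(summary) + "\n", encoding="utf-8")
        emit("summary", summary_path)
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        if isinstance(exc, StageError):
            raise
        _cleanup(written)
        raise StageError(stage, exc) from exc
    return reports
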