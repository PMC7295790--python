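"""Seeded generator of synthetic culturomics incidence matrices.

The generator emulates the statistical shape of a large stool-culturomics
screen: a few hundred species × a few dozen conditions, one dominant
condition capturing ~62% of all species, a long non-increasing tail of
marginal gains, anaerobic conditions jointly capturing nearly every
species, and a detectability boost on supplemented (rumen-fluid)
conditions.

Model: cell ``(i, j)`` is an independent Bernoulli draw with probability

``p[i, j] = clip( base_i × effect_j × supplement_boost^{rumen_j}
                  × aerobic_penalty^{anaerobe_i & aerobic_j} , 0, 1)``

where ``base_i`` is a clipped log-normal per-species detectability (the
heavy tail produces both ubiquitous and rare species) and ``effect_j`` a
log-normal per-condition productivity multiplier (the long tail of
low-richness conditions).  Species rows that come out all-zero are
redrawn up to a retry cap so the matrix invariant (every species isolated
at least once) holds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .model import Condition, IncidenceMatrix, SpeciesRecord, normalize_name

PHYLA = (
    "Bacillota",
    "Bacteroidota",
    "Actinomycetota",
    "Pseudomonadota",
    "Fusobacteriota",
    "Verrucomicrobiota",
    "Synergistota",
)
PHYLUM_WEIGHTS = (0.55, 0.15, 0.12, 0.12, 0.03, 0.02, 0.01)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults reproduce the study-scale structure.

    ``base_median``/``base_sigma`` parameterize the log-normal per-species
    baseline detection probability (median 0.08 ⇒ a typical condition
    isolates ~13% of species).  ``dominant_condition_boost`` multiplies the
    designated dominant condition so that — together with its rumen
    supplement — it captures ~62% of species in expectation.
    ``aerobic_penalty`` multiplies a strict anaerobe's detection
    probability under aerobic conditions (0 ⇒ never recovered aerobically).
    Non-dominant condition effects are capped at ``condition_effect_cap``
    so the designated dominant condition stays dominant while the effect
    distribution keeps its long lower tail.
    """

    n_species: int = 497
    n_conditions: int = 58
    seed: int = 0
    base_median: float = 0.08
    base_sigma: float = 1.0
    condition_effect_sigma: float = 0.7
    dominant_condition_boost: float = 4.6
    supplement_boost: float = 1.6
    condition_effect_cap: float = 3.0
    anaerobe_fraction: float = 0.67
    aerobic_penalty: float = 0.08
    new_taxon_rate: float = 0.15
    aerobic_fraction: float = 18 / 58
    supplement_fraction: float = 10 / 58
    max_retries: int = 100

    def __post_init__(self):
        if self.n_species < 1 or self.n_conditions < 1:
            raise ValueError("n_species and n_conditions must be >= 1")
        for name in ("dominant_condition_boost", "supplement_boost"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("anaerobe_fraction", "new_taxon_rate", "aerobic_fraction",
                     "supplement_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.aerobic_penalty:
            raise ValueError("aerobic_penalty must be >= 0")


def _species_frame(params: SyntheticParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_species
    width = max(4, len(str(n)))
    names = [f"Simulatobacter sp{i:0{width}d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {
            "name": names,
            "phylum": rng.choice(PHYLA, size=n, p=PHYLUM_WEIGHTS),
            "oxygen_phenotype": np.where(
                rng.random(n) < params.anaerobe_fraction,
                "strict_anaerobe",
                "oxygen_tolerant",
            ),
            "is_new_taxon": rng.random(n) < params.new_taxon_rate,
            "accession": "",
        }
    )


def _generic_conditions(params: SyntheticParams, rng: np.random.Generator) -> pd.DataFrame:
    """Condition table for :func:`generate`: a dominant rumen condition plus
    a random aerobic/supplemented assignment of the remainder."""
    nc = params.n_conditions
    n_aero = int(round(params.aerobic_fraction * nc))
    n_aero = min(n_aero, nc - 1)  # keep the dominant condition anaerobic
    atmo = np.array(["anaerobic"] * (nc - n_aero) + ["aerobic"] * n_aero)
    width = max(2, len(str(nc)))
    ids = [f"cond_{i:0{width}d}" for i in range(1, nc + 1)]
    n_rumen = max(1, int(round(params.supplement_fraction * nc)))
    rumen = np.zeros(nc, dtype=bool)
    rumen[0] = True  # dominant condition carries the supplement
    if n_rumen > 1 and nc > 1:
        rumen[rng.choice(np.arange(1, nc), size=min(n_rumen - 1, nc - 1), replace=False)] = True
    effect = np.minimum(
        rng.lognormal(0.0, params.condition_effect_sigma, nc),
        params.condition_effect_cap,
    )
    effect[0] = params.dominant_condition_boost
    return pd.DataFrame(
        {
            "id": ids,
            "label": [f"synthetic condition {i}" for i in ids],
            "atmosphere": atmo,
            "temperature_c": 37.0,
            "supplements": ["rumen_fluid" if r else "none" for r in rumen],
            "pretreatment": "none",
            "group": "",
            "arm": "",
            "effect": effect,
        }
    )


def _study_conditions(params: SyntheticParams, rng: np.random.Generator) -> pd.DataFrame:
    """Condition table mirroring the study design: 58 conditions
    (40 anaerobic / 18 aerobic), three disjoint group tags sized
    18/18/22 (the third alcohol-pretreated), and a 7-condition rumen arm
    whose members share their medium (condition effect) with a matched
    7-condition rumen-free arm."""
    ids = [f"ana_{i:02d}" for i in range(1, 41)] + [f"ae_{i:02d}" for i in range(1, 19)]
    atmo = ["anaerobic"] * 40 + ["aerobic"] * 18
    group = {}
    for i in range(1, 11):
        group[f"ana_{i:02d}"] = "18_standard"
    for i in range(11, 21):
        group[f"ana_{i:02d}"] = "18_new"
    for i in range(21, 41):
        group[f"ana_{i:02d}"] = "22_alcohol"
    for i in range(1, 9):
        group[f"ae_{i:02d}"] = "18_standard"
    for i in range(9, 17):
        group[f"ae_{i:02d}"] = "18_new"
    for i in range(17, 19):
        group[f"ae_{i:02d}"] = "22_alcohol"
    alcohol = {c for c, g in group.items() if g == "22_alcohol"}

    # rumen arm / matched arm: pairs (with, without) sharing one medium
    pairs = [
        ("ana_01", "ana_02"),
        ("ana_04", "ana_05"),
        ("ana_06", "ana_07"),
        ("ana_21", "ana_23"),
        ("ana_22", "ana_24"),
        ("ae_01", "ae_02"),
        ("ae_17", "ae_18"),
    ]
    rumen_arm = [a for a, _ in pairs]
    matched_arm = [b for _, b in pairs]

    effect = np.minimum(
        rng.lognormal(0.0, params.condition_effect_sigma, len(ids)),
        params.condition_effect_cap,
    )
    eff = dict(zip(ids, effect))
    for with_r, without_r in pairs:
        eff[without_r] = eff[with_r]
    eff["ana_01"] = params.dominant_condition_boost

    rows = []
    for c, a in zip(ids, atmo):
        supp = {"rumen_fluid", "sheep_blood"} if c in rumen_arm else {"none"}
        rows.append(
            {
                "id": c,
                "label": f"synthetic study condition {c}",
                "atmosphere": a,
                "temperature_c": 37.0,
                "supplements": ";".join(sorted(supp)),
                "pretreatment": "alcohol" if c in alcohol else "none",
                "group": group[c],
                "arm": "rumen" if c in rumen_arm else ("matched" if c in matched_arm else ""),
                "effect": eff[c],
            }
        )
    return pd.DataFrame(rows)


def _sample(
    params: SyntheticParams,
    cond_df: pd.DataFrame,
    species_df: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    base = np.clip(
        rng.lognormal(np.log(params.base_median), params.base_sigma, params.n_species),
        0.0,
        1.0,
    )
    effect = cond_df["effect"].to_numpy(float)
    rumen = cond_df["supplements"].str.contains("rumen_fluid").to_numpy()
    aerobic = (cond_df["atmosphere"] == "aerobic").to_numpy()
    anaerobe = (species_df["oxygen_phenotype"] == "strict_anaerobe").to_numpy()

    p = base[:, None] * effect[None, :]
    p = p * np.where(rumen[None, :], params.supplement_boost, 1.0)
    p = p * np.where(aerobic[None, :] & anaerobe[:, None], params.aerobic_penalty, 1.0)
    p = np.clip(p, 0.0, 1.0)

    cells = rng.random(p.shape) < p
    failed = 0
    for i in np.flatnonzero(~cells.any(axis=1)):
        for _ in range(params.max_retries):
            cells[i] = rng.random(p.shape[1]) < p[i]
            if cells[i].any():
                break
        else:
            failed += 1
    if failed:
        raise GenerationError(
            f"{failed} species still undetected after {params.max_retries} "
            "redraws; detection probabilities are pathologically low"
        )
    return cells


def _assemble(
    params: SyntheticParams, cond_df: pd.DataFrame, rng: np.random.Generator
) -> tuple[IncidenceMatrix, pd.DataFrame, pd.DataFrame]:
    species_df = _species_frame(params, rng)
    cells = _sample(params, cond_df, species_df, rng)
    cmeta = {
        r["id"]: Condition(
            id=r["id"],
            label=r["label"],
            atmosphere=r["atmosphere"],
            temperature_c=float(r["temperature_c"]),
            supplements=frozenset(r["supplements"].split(";")),
            pretreatment=r["pretreatment"],
            group=r["group"] or None,
        )
        for r in cond_df.to_dict("records")
    }
    smeta = {
        normalize_name(r["name"]): SpeciesRecord(
            name=r["name"],
            phylum=r["phylum"],
            oxygen_phenotype=r["oxygen_phenotype"],
            is_new_taxon=bool(r["is_new_taxon"]),
            accession=None,
        )
        for r in species_df.to_dict("records")
    }
    matrix = IncidenceMatrix(
        cells, list(species_df["name"]), list(cond_df["id"]), cmeta, smeta
    )
    return matrix, cond_df, species_df


def generate(params: SyntheticParams) -> tuple[IncidenceMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic incidence matrix plus condition and species
    metadata tables.  Deterministic under a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    cond_df = _generic_conditions(params, rng)
    return _assemble(params, cond_df, rng)


def study_shaped_fixture(
    seed: int, **overrides
) -> tuple[IncidenceMatrix, pd.DataFrame, pd.DataFrame]:
    """Preset mirroring the study design: 497 species × 58 conditions
    (40 anaerobic / 18 aerobic), group tags 18/18/22, 67% strict
    anaerobes, and a paired 7-vs-7 rumen/no-rumen arm."""
    params = replace(SyntheticParams(seed=seed), **overrides)
    rng = np.random.default_rng(params.seed)
    cond_df = _study_conditions(params, rng)
    if len(cond_df) != params.n_conditions:
        raise ValueError("study preset requires n_conditions = 58")
    return _assemble(params, cond_df, rng)


def arm_conditions(cond_df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Extract the (rumen, matched) arm condition ids from a metadata table."""
    rumen = list(cond_df.loc[cond_df["arm"] == "rumen", "id"])
    matched = list(cond_df.loc[cond_df["arm"] == "matched", "id"])
    return rumen, matched
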