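"""16S rRNA identity thresholds for taxon novelty.

An isolate's percent identity to its nearest named species classifies it:
below 95% it is a candidate new genus, from 95% up to (but excluding)
98.65% a candidate new species, and at or above 98.65% a known species.
Both thresholds are strict on the low side — equality falls in the higher
(less novel) class.  Computing the identity itself (alignment) is outside
this package; the percentage is an input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

NEW_GENUS_THRESHOLD = 95.0
NEW_SPECIES_THRESHOLD = 98.65

CALLS = ("known_species", "new_species", "new_genus")


@dataclass(frozen=True)
class IdentityCall:
    percent_identity: float
    call: str


def classify_identity(percent_identity: float) -> IdentityCall:
    """Classify a 16S percent identity into a novelty call."""
    if not 0 <= percent_identity <= 100:
        raise ValueError(
            f"percent identity must be in [0, 100], got {percent_identity}"
        )
    if percent_identity < NEW_GENUS_THRESHOLD:
        call = "new_genus"
    elif percent_identity < NEW_SPECIES_THRESHOLD:
        call = "new_species"
    else:
        call = "known_species"
    return IdentityCall(float(percent_identity), call)


def tally_novelty(calls: Iterable[IdentityCall]) -> dict[str, int]:
    """Count calls per novelty class; all classes present, missing = 0."""
    counts = Counter(c.call for c in calls)
    return {cls: counts.get(cls, 0) for cls in CALLS}
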