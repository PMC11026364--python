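"""Canonical brain-region vocabulary for dorsal-subiculum input mapping.

The tracing protocol assigns every rabies-labeled cell to one of 21 named
input regions (hippocampal CA1/CA2/CA3 sublayers, subicular complex,
septal, thalamic, retrosplenial, sensory-cortical and entorhinal areas).
Very sparsely labeled structures outside this list (contralateral CA1,
hypothalamus, dentate gyrus, cingulate cortex, midbrain) are pooled into
the ``OTHER_SPARSE`` sink: they contribute to whole-brain input totals but
never appear in per-region comparisons.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

#: Ordered canonical codes for the 21 named input regions.
CANONICAL_REGIONS: tuple[str, ...] = (
    "CA1_py", "CA1_or", "CA1_rad", "CA1_lmol",
    "CA2_py", "CA2_or",
    "CA3_py", "CA3_or",
    "SUB", "PostSUB",
    "MS-DB", "Thalamus", "RSC",
    "Vis", "Aud", "SS", "TeA",
    "Prh", "Ect", "LEC", "MEC",
)

#: Sink code for sparse, non-compared structures.
OTHER_SPARSE = "OTHER_SPARSE"

#: Anatomical parent grouping (used for table layout / plotting only).
PARENT_GROUPS: dict[str, str] = {
    "CA1_py": "hippocampus", "CA1_or": "hippocampus", "CA1_rad": "hippocampus",
    "CA1_lmol": "hippocampus", "CA2_py": "hippocampus", "CA2_or": "hippocampus",
    "CA3_py": "hippocampus", "CA3_or": "hippocampus",
    "SUB": "SUB complex", "PostSUB": "SUB complex",
    "Vis": "sensory cortex", "Aud": "sensory cortex", "SS": "sensory cortex",
    "LEC": "EC", "MEC": "EC",
}


class VocabularyError(ValueError):
    """A region string cannot be resolved to a canonical code."""


@lru_cache(maxsize=1)
def synonym_table() -> dict[str, str]:
    """Load the shipped synonym table, keyed by casefolded synonym."""
    mapping: dict[str, str] = {}
    ref = resources.files("tracequant.data").joinpath("region_synonyms.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            mapping[row["synonym"].strip().casefold()] = row["canonical"].strip()
    # every canonical code maps to itself
    for code in CANONICAL_REGIONS + (OTHER_SPARSE,):
        mapping.setdefault(code.casefold(), code)
    return mapping


def resolve_region(name: str) -> str:
    """Map a free-text region string to its canonical code.

    Raises
    ------
    VocabularyError
        If the string matches neither a canonical code nor a shipped synonym.
    """
    key = str(name).strip().casefold()
    table = synonym_table()
    if key not in table:
        raise VocabularyError(f"unmappable region string: {name!r}")
    return table[key]
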