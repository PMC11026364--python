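"""Reading, validation and quality filtering of cell-count tables.

The canonical inputs are two UTF-8 CSV/TSV tables:

* **section table** — one row per (mouse, section, region): columns
  ``mouse_id, ap_mm, region, n_input, n_starter``. ``n_input`` counts
  single-labeled (rabies-only) presynaptic cells; ``n_starter`` counts
  double-labeled (helper-AAV + rabies) starter cells, which can legitimately
  occur only in the dorsal subiculum (SUB).
* **mouse table** — one row per animal: ``mouse_id, genotype, age_group,
  sex`` plus optional ``included`` / ``exclusion_reason``.

Counts are per sampled section (one of every three 30 µm sections); no
sampling-fraction correction is applied anywhere because every downstream
index is a ratio of counts collected under the same scheme, so the factor
cancels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import CANONICAL_REGIONS, OTHER_SPARSE, VocabularyError, resolve_region

__all__ = [
    "SECTION_COLUMNS",
    "MOUSE_COLUMNS",
    "SchemaError",
    "read_section_table",
    "write_section_table",
    "read_mouse_table",
    "apply_inclusion_rules",
    "QCReport",
]

SECTION_COLUMNS = ("mouse_id", "ap_mm", "region", "n_input", "n_starter")
MOUSE_COLUMNS = ("mouse_id", "genotype", "age_group", "sex")

GENOTYPES = {"wt": "WT", "5xfad": "5xFAD", "fad5x": "5xFAD"}
AGE_GROUPS = {"young": "young", "middle": "middle", "middle-age": "middle", "middle_age": "middle"}
SEXES = {"m": "M", "male": "M", "f": "F", "female": "F"}

AP_RANGE_MM = (-8.0, 3.0)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _parse_count(raw: str, column: str, row: int) -> int:
    try:
        value = float(raw)
    except ValueError:
        raise ValueError(f"row {row}: {column}={raw!r} is not a number") from None
    if not float(value).is_integer():
        raise ValueError(f"row {row}: {column}={raw!r} is not an integer count")
    value = int(value)
    if value < 0:
        raise ValueError(f"row {row}: {column}={value} is negative")
    return value


def read_section_table(path) -> pd.DataFrame:
    """Read and validate a per-section cell-count table.

    Region strings are resolved through the shipped synonym table; row order
    is preserved. Raises :class:`SchemaError` for missing columns,
    :class:`~tracequant.regions.VocabularyError` (citing the row) for
    unmappable region strings, and ``ValueError`` for non-integer or
    negative counts.
    """
    raw = _read_delimited(path)
    _require_columns(raw, SECTION_COLUMNS, "section table")
    records = []
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            region = resolve_region(row.region)
        except VocabularyError as err:
            raise VocabularyError(f"row {i}: {err}") from None
        ap = float(row.ap_mm)
        if not (AP_RANGE_MM[0] <= ap <= AP_RANGE_MM[1]):
            raise ValueError(f"row {i}: ap_mm={ap} outside {AP_RANGE_MM}")
        records.append((
            str(row.mouse_id), ap, region,
            _parse_count(row.n_input, "n_input", i),
            _parse_count(row.n_starter, "n_starter", i),
        ))
    return pd.DataFrame(records, columns=list(SECTION_COLUMNS))


def write_section_table(records: pd.DataFrame, path) -> None:
    """Write a section table back to CSV (round-trips with the reader)."""
    records.loc[:, list(SECTION_COLUMNS)].to_csv(path, index=False)


def read_mouse_table(path) -> pd.DataFrame:
    """Read and validate per-animal metadata.

    Genotype / age-group / sex tokens are parsed case-insensitively;
    ``included`` defaults to True. Duplicate ``mouse_id`` values raise.
    """
    raw = _read_delimited(path)
    _require_columns(raw, MOUSE_COLUMNS, "mouse table")
    dup = raw["mouse_id"][raw["mouse_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate mouse_id(s): {sorted(set(dup))}")

    def _enum(raw_val: str, table: dict, what: str, row: int) -> str:
        key = str(raw_val).strip().casefold()
        if key not in table:
            raise ValueError(f"row {row}: unknown {what} token {raw_val!r}")
        return table[key]

    out = []
    for i, row in enumerate(raw.itertuples(index=False)):
        included = True
        if "included" in raw.columns:
            tok = str(getattr(row, "included")).strip().casefold()
            included = tok not in {"false", "0", "no", "f"} if tok else True
        out.append((
            str(row.mouse_id),
            _enum(row.genotype, GENOTYPES, "genotype", i),
            _enum(row.age_group, AGE_GROUPS, "age_group", i),
            _enum(row.sex, SEXES, "sex", i),
            included,
            str(getattr(row, "exclusion_reason", "")) if "exclusion_reason" in raw.columns else "",
        ))
    return pd.DataFrame(
        out,
        columns=["mouse_id", "genotype", "age_group", "sex", "included", "exclusion_reason"],
    )


@dataclass
class QCReport:
    """Per-mouse totals and the exclusion ledger from inclusion filtering."""

    per_mouse: pd.DataFrame  # mouse_id, starters_total, inputs_total, included, exclusion_reason
    n_recoded_sparse: int

    def to_json(self, path=None) -> str:
        payload = {
            "per_mouse": self.per_mouse.to_dict(orient="records"),
            "n_recoded_sparse": int(self.n_recoded_sparse),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def apply_inclusion_rules(
    records: pd.DataFrame, metas: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Apply the study's case-inclusion rules; idempotent.

    1. Any mouse with starter cells outside SUB is excluded ("starter
       leakage") — the tracing is only interpretable when initial infection
       stays within the dorsal SUB target.
    2. Any mouse with zero starters is excluded ("no starters") — indices
       are starter-normalized.
    3. Sparse out-of-vocabulary structures are already pooled as
       ``OTHER_SPARSE`` by the reader; their records are retained (they
       enter whole-brain input totals) but never appear in per-region
       comparisons.

    Records of excluded mice are dropped. Raises ``ValueError`` for record
    mouse_ids absent from the metadata.
    """
    records = records.copy()
    metas = metas.copy()
    orphans = set(records["mouse_id"]) - set(metas["mouse_id"])
    if orphans:
        raise ValueError(f"section records reference unknown mouse_id(s): {sorted(orphans)}")

    leak = records.loc[(records["n_starter"] > 0) & (records["region"] != "SUB"), "mouse_id"]
    starters = records.groupby("mouse_id")["n_starter"].sum()
    inputs = records.groupby("mouse_id")["n_input"].sum()

    for idx in metas.index:
        mid = metas.at[idx, "mouse_id"]
        if not metas.at[idx, "included"]:
            continue
        if mid in set(leak):
            metas.at[idx, "included"] = False
            metas.at[idx, "exclusion_reason"] = "starter leakage"
        elif int(starters.get(mid, 0)) == 0:
            metas.at[idx, "included"] = False
            metas.at[idx, "exclusion_reason"] = "no starters"

    included_ids = set(metas.loc[metas["included"], "mouse_id"])
    filtered = records[records["mouse_id"].isin(included_ids)].reset_index(drop=True)

    per_mouse = metas.loc[:, ["mouse_id", "included", "exclusion_reason"]].copy()
    per_mouse["starters_total"] = per_mouse["mouse_id"].map(starters).fillna(0).astype(int)
    per_mouse["inputs_total"] = per_mouse["mouse_id"].map(inputs).fillna(0).astype(int)
    report = QCReport(
        per_mouse=per_mouse[
            ["mouse_id", "starters_total", "inputs_total", "included", "exclusion_reason"]
        ],
        n_recoded_sparse=int((records["region"] == OTHER_SPARSE).sum()),
    )
    return filtered, metas, report
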