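"""Starter-normalized connectivity indices.

For an animal with S starter cells (double-labeled, SUB) and per-region
single-labeled input counts N_r:

* **CSI** (connectivity strength index): ``CSI_r = N_r / S`` — an absolute,
  starter-normalized measure of a region's input strength.
* **PI** (proportion of input): ``PI_r = 100 · N_r / Σ_r N_r`` — the
  region's share of all labeled inputs, in percent. The total includes the
  sparse out-of-vocabulary pool (OTHER_SPARSE), so named-region PI values
  sum to slightly less than 100.
* **overall connectivity**: ``Σ_r N_r / S`` — brain-wide inputs per starter.

Starter cells are never counted as inputs (they are double-labeled, not
presynaptic). Aggregation is per-mouse-first: group summaries average the
per-animal ratios, not the pooled counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import CANONICAL_REGIONS, OTHER_SPARSE

__all__ = ["ConnectivityProfile", "profile_mouse", "profile_cohort", "summarize_group"]

ALL_REGIONS = CANONICAL_REGIONS + (OTHER_SPARSE,)


@dataclass(frozen=True)
class ConnectivityProfile:
    """Per-animal connectivity indices over the region vocabulary."""

    mouse_id: str
    starters_total: int
    inputs_total: int
    csi: dict  # region -> N_r / starters_total (incl. OTHER_SPARSE)
    pi: dict  # region -> percent of inputs_total (incl. OTHER_SPARSE)
    overall_csi: float

    def as_row(self) -> dict:
        row = {
            "mouse_id": self.mouse_id,
            "starters_total": self.starters_total,
            "inputs_total": self.inputs_total,
            "overall_csi": self.overall_csi,
        }
        for r in ALL_REGIONS:
            row[f"csi_{r}"] = self.csi[r]
            row[f"pi_{r}"] = self.pi[r]
        return row


def profile_mouse(records: pd.DataFrame) -> ConnectivityProfile:
    """Compute the connectivity profile of one included mouse.

    ``records`` holds all section rows of a single animal. Region counts are
    summed over sections; a region with no sections counts zero.
    """
    ids = records["mouse_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records must belong to one mouse, got {sorted(ids)}")
    starters = int(records["n_starter"].sum())
    if starters < 1:
        raise ValueError(f"mouse {ids[0]!r} has zero starters; should have been excluded")
    counts = records.groupby("region")["n_input"].sum()
    region_counts = {r: int(counts.get(r, 0)) for r in ALL_REGIONS}
    total = sum(region_counts.values())
    csi = {r: c / starters for r, c in region_counts.items()}
    pi = {r: (100.0 * c / total if total > 0 else 0.0) for r, c in region_counts.items()}
    return ConnectivityProfile(
        mouse_id=str(ids[0]),
        starters_total=starters,
        inputs_total=total,
        csi=csi,
        pi=pi,
        overall_csi=total / starters,
    )


def profile_cohort(records: pd.DataFrame, metas: pd.DataFrame) -> pd.DataFrame:
    """Profile every included mouse; one row per animal, wide layout.

    Vectorized over the cohort. Output columns: mouse_id, genotype,
    age_group, sex, starters_total, inputs_total, overall_csi and
    ``csi_<region>`` / ``pi_<region>`` for the full vocabulary.
    """
    included = metas.loc[metas["included"]]
    recs = records[records["mouse_id"].isin(included["mouse_id"])]
    starters = recs.groupby("mouse_id")["n_starter"].sum()
    counts = (
        recs.pivot_table(index="mouse_id", columns="region", values="n_input",
                         aggfunc="sum", fill_value=0)
        .reindex(columns=list(ALL_REGIONS), fill_value=0)
        .reindex(starters.index, fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (starters < 1).any():
        bad = sorted(starters.index[starters < 1])
        raise ValueError(f"zero-starter mice present after filtering: {bad}")

    out = included.set_index("mouse_id").loc[starters.index,
                                             ["genotype", "age_group", "sex"]].copy()
    out["starters_total"] = starters.astype(int)
    out["inputs_total"] = totals.astype(int)
    out["overall_csi"] = totals / starters
    for r in ALL_REGIONS:
        out[f"csi_{r}"] = counts[r] / starters
    safe_total = totals.replace(0, np.nan)
    for r in ALL_REGIONS:
        out[f"pi_{r}"] = (100.0 * counts[r] / safe_total).fillna(0.0)
    return out.reset_index()


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size <= 1:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def summarize_group(profiles: pd.DataFrame, key: dict) -> pd.DataFrame:
    """Mean ± SEM summary of one cohort group, in the standard table layout.

    ``key`` maps metadata columns to required values, e.g.
    ``{"genotype": "WT", "age_group": "young"}``. Rows are the 21 named
    regions (CSI then PI blocks) followed by cohort-level rows for starter
    count, total labeled neurons and overall connectivity. SEM uses the
    n−1 denominator and is NaN for a single animal.
    """
    mask = np.ones(len(profiles), dtype=bool)
    for col, val in key.items():
        mask &= (profiles[col] == val).to_numpy()
    sub = profiles.loc[mask]
    if sub.empty:
        raise ValueError(f"no mice in group {key}")

    rows = []
    for metric in ("csi", "pi"):
        for r in CANONICAL_REGIONS:
            vals = sub[f"{metric}_{r}"].to_numpy(dtype=float)
            rows.append((metric.upper(), r, float(np.mean(vals)), _sem(vals)))
    for label, col in (
        ("# of starters", "starters_total"),
        ("# of total labeled neurons", "inputs_total"),
        ("Overall connectivity", "overall_csi"),
    ):
        vals = sub[col].to_numpy(dtype=float)
        rows.append(("cohort", label, float(np.mean(vals)), _sem(vals)))
    summary = pd.DataFrame(rows, columns=["block", "row", "mean", "sem"])
    summary.attrs["n_mice"] = int(len(sub))
    summary.attrs["group"] = dict(key)
    return summary
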