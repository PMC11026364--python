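"""Amyloid-plaque morphometrics and the mixed Wilcoxon/LME comparison scheme.

Inputs are pre-extracted measurement tables (no image analysis here):

* **plaque table** — one row per extracellular plaque: ``mouse_id,
  plaque_id, area_um2, intensity_au``.
* **per-mouse table** — ``mouse_id, field_area_mm2, intraneuronal_count``
  for the quantified field of view (one representative section per animal).

Four per-animal metrics: plaque density (mm⁻²), mean plaque size (µm²),
mean intensity (AU), intraneuronal-aggregate density (mm⁻²). Group
comparisons follow the repeated-measures logic of the assay: densities are
one value per animal and are compared with the exact Wilcoxon rank-sum
test; size and intensity are measured once per plaque (hundreds per
animal), so they are compared with a linear mixed-effects model with a
per-animal random intercept — pooling plaques across animals without the
random intercept pseudo-replicates the animal and inflates false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import fit_lme_two_group, rank_sum_test, star_level

__all__ = [
    "PLAQUE_COLUMNS",
    "MOUSE_FIELD_COLUMNS",
    "read_plaque_table",
    "read_mouse_field_table",
    "summarize_plaques",
    "compare_plaque_groups",
    "render_plaque_tables",
]

PLAQUE_COLUMNS = ("mouse_id", "plaque_id", "area_um2", "intensity_au")
MOUSE_FIELD_COLUMNS = ("mouse_id", "field_area_mm2", "intraneuronal_count")

#: Which statistical route each metric takes.
METRIC_TESTS = {
    "density_mm2": "rank_sum",
    "intraneuronal_density_mm2": "rank_sum",
    "size_um2": "lme",
    "intensity_au": "lme",
}


def read_plaque_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLAQUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plaque table missing column(s): {missing}")
    if (df["area_um2"] <= 0).any():
        raise ValueError("plaque areas must be positive")
    if (df["intensity_au"] < 0).any():
        raise ValueError("plaque intensities must be non-negative")
    return df.loc[:, list(PLAQUE_COLUMNS)].assign(mouse_id=df["mouse_id"].astype(str))


def read_mouse_field_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MOUSE_FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"per-mouse field table missing column(s): {missing}")
    if (df["field_area_mm2"] <= 0).any():
        raise ValueError("field areas must be positive")
    return df.loc[:, list(MOUSE_FIELD_COLUMNS)].assign(mouse_id=df["mouse_id"].astype(str))


def summarize_plaques(records: pd.DataFrame, fields: pd.DataFrame) -> pd.DataFrame:
    """Per-animal plaque summary; one row per mouse in ``fields``.

    Animals with no plaque records (e.g. wild types, which show no
    amyloid-positive staining) get density 0 and missing mean size /
    intensity. ``density × field_area = n_plaques`` holds exactly.
    """
    if (fields["field_area_mm2"] <= 0).any():
        raise ValueError("field areas must be positive")
    grouped = records.groupby("mouse_id") if not records.empty else None
    rows = []
    for row in fields.itertuples(index=False):
        mid = str(row.mouse_id)
        if grouped is not None and mid in grouped.groups:
            sub = grouped.get_group(mid)
            n = len(sub)
            mean_size = float(sub["area_um2"].mean())
            mean_intensity = float(sub["intensity_au"].mean())
        else:
            n, mean_size, mean_intensity = 0, float("nan"), float("nan")
        area = float(row.field_area_mm2)
        rows.append({
            "mouse_id": mid,
            "field_area_mm2": area,
            "n_plaques": n,
            "density_mm2": n / area,
            "mean_size_um2": mean_size,
            "mean_intensity_au": mean_intensity,
            "intraneuronal_count": int(row.intraneuronal_count),
            "intraneuronal_density_mm2": int(row.intraneuronal_count) / area,
        })
    return pd.DataFrame(rows)


def compare_plaque_groups(
    summaries: pd.DataFrame,
    records: pd.DataFrame,
    metas: pd.DataFrame,
    group_cols: tuple[str, ...] = ("genotype", "age_group"),
    pairs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Pairwise group comparisons of the four plaque metrics.

    Density metrics use the exact rank-sum test on per-animal values;
    per-plaque size and intensity use the two-group LME with a per-animal
    random intercept (sample size = number of plaques, animal n reported
    separately). Groups are tuples of the ``group_cols`` metadata values.
    """
    meta_idx = metas.set_index("mouse_id")
    summaries = summaries.merge(
        meta_idx[list(group_cols)], left_on="mouse_id", right_index=True, how="left")
    records = records.merge(
        meta_idx[list(group_cols)], left_on="mouse_id", right_index=True, how="left")

    def _key(df):
        return df[list(group_cols)].astype(str).agg(" ".join, axis=1)

    summaries["_group"] = _key(summaries)
    records = records.assign(_group=_key(records))

    if pairs is None:
        groups = sorted(set(summaries["_group"]))
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    else:
        pairs = [
            (a if isinstance(a, str) else " ".join(a),
             b if isinstance(b, str) else " ".join(b))
            for a, b in pairs
        ]

    rows = []
    for a, b in pairs:
        sub_a = summaries[summaries["_group"] == a]
        sub_b = summaries[summaries["_group"] == b]
        if len(sub_a) < 2 or len(sub_b) < 2:
            raise ValueError(f"group {a} or {b} has fewer than 2 mice")
        label = f"{a} vs {b}"
        for metric, col in (("density_mm2", "density_mm2"),
                            ("intraneuronal_density_mm2", "intraneuronal_density_mm2")):
            res = rank_sum_test(sub_a[col].to_numpy(float), sub_b[col].to_numpy(float))
            va, vb = sub_a[col].mean(), sub_b[col].mean()
            rows.append({
                "metric": metric, "pair": label, "test": "wilcoxon_rank_sum",
                "p": res.p_two_sided, "stars": star_level(res.p_two_sided),
                "n_a": len(sub_a), "n_b": len(sub_b),
                "n_animals_a": len(sub_a), "n_animals_b": len(sub_b),
                "mean_a": float(va), "mean_b": float(vb),
                "direction": int(np.sign(va - vb)),
            })
        rec_a = records[records["_group"] == a]
        rec_b = records[records["_group"] == b]
        for metric, col in (("size_um2", "area_um2"), ("intensity_au", "intensity_au")):
            both = pd.concat([rec_a, rec_b])
            if both.empty or rec_a.empty or rec_b.empty:
                continue  # no plaques in a group: LME undefined (WT cohorts)
            values = both[col].to_numpy(float)
            if np.var(values) == 0.0:
                test_name, p = "degenerate_zero_variance", 1.0
            else:
                fit = fit_lme_two_group(
                    values,
                    both["mouse_id"].to_numpy(),
                    np.where(both["_group"] == a, "A:" + a, "B:" + b),
                )
                test_name, p = "lme_random_intercept", fit.p_beta1
            va, vb = rec_a[col].mean(), rec_b[col].mean()
            rows.append({
                "metric": metric, "pair": label, "test": test_name,
                "p": p, "stars": star_level(p),
                "n_a": len(rec_a), "n_b": len(rec_b),
                "n_animals_a": rec_a["mouse_id"].nunique(),
                "n_animals_b": rec_b["mouse_id"].nunique(),
                "mean_a": float(va), "mean_b": float(vb),
                "direction": int(np.sign(va - vb)),
            })
    return pd.DataFrame(rows)


def render_plaque_tables(summaries: pd.DataFrame, comparisons: pd.DataFrame,
                         metas: pd.DataFrame, out_dir) -> list[Path]:
    """Write the per-group plaque summary and comparison CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged = summaries.merge(
        metas.set_index("mouse_id")[["genotype", "age_group", "sex"]],
        left_on="mouse_id", right_index=True, how="left")
    rows = []
    for (g, a), sub in merged.groupby(["genotype", "age_group"], sort=True):
        entry = {"group": f"{g} {a}", "n_mice": len(sub)}
        for col in ("density_mm2", "mean_size_um2", "mean_intensity_au",
                    "intraneuronal_density_mm2"):
            vals = sub[col].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            entry[f"{col} mean"] = float(vals.mean()) if vals.size else 0.0
            entry[f"{col} sem"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan"))
        rows.append(entry)
    paths = []
    p1 = out_dir / "plaque_summary.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    paths.append(p1)
    p2 = out_dir / "plaque_comparisons.csv"
    comparisons.to_csv(p2, index=False)
    paths.append(p2)
    return paths
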